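"""Majority-rule consensus from an alignment of TE copies.

The consensus approximates the ancestral active element ("master gene") that
seeded the copies.  Calls follow a strict-plurality rule with a depth cutoff;
ambiguous columns are written as ``N`` and columns in which gaps hold a
strict majority are dropped altogether, so the consensus is the element
itself rather than the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import AlignmentError
from .io_formats import SequenceRecord

_CALLABLE = frozenset("ACGT")


@dataclass(frozen=True)
class CopyAlignment:
    """TE copies aligned in common (consensus/master) coordinates."""

    copy_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(self.copy_ids) != len(self.rows):
            raise AlignmentError("copy_ids and rows differ in length")
        ncol = len(self.rows[0])
        for cid, row in zip(self.copy_ids, self.rows):
            if len(row) != ncol:
                raise AlignmentError(
                    f"row {cid!r} has length {len(row)}, expected {ncol}")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "CopyAlignment":
        return cls(tuple(r.id for r in records),
                   tuple(r.residues for r in records))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def record(self, copy_id: str) -> SequenceRecord:
        idx = self.copy_ids.index(copy_id)
        return SequenceRecord(copy_id, self.rows[idx])

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(c, r) for c, r in zip(self.copy_ids, self.rows)]


@dataclass(frozen=True)
class ConsensusSequence:
    """Consensus record plus per-position support.

    ``support[i]`` is the fraction of non-gap residues that match the call
    at retained column ``columns[i]``; positions called ``N`` carry support
    0.  ``columns`` maps consensus positions back to alignment columns.
    """

    record: SequenceRecord
    support: tuple[float, ...]
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.record) == len(self.support) == len(self.columns)):
            raise AlignmentError("consensus fields of inconsistent length")

    def __len__(self) -> int:
        return len(self.record)


def build_consensus(aln: CopyAlignment,
                    min_depth: int = 3,
                    majority_fraction: float = 0.5,
                    name: str = "consensus") -> ConsensusSequence:
    """Majority-rule consensus of an aligned set of TE copies.

    Per column, counts are taken over unambiguous residues (A/C/G/T; ``N``
    and other ambiguity codes are treated as missing).  The residue with a
    strict plurality is called if its fraction of the counted residues is
    >= ``majority_fraction`` and the counted depth is >= ``min_depth``;
    otherwise the column is written as ``N`` with support 0.  Columns in
    which gaps form a strict majority of all rows are dropped.

    ``min_depth`` defaults to 3 so that thinly covered flanks come out as
    ``N`` rather than as single-copy idiosyncrasies; note that with this
    default a single-row alignment yields all-``N`` (use ``min_depth=1`` to
    recover the row itself).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 <= majority_fraction <= 1.0:
        raise ValueError("majority_fraction must be in [0.5, 1]")
    calls: list[str] = []
    support: list[float] = []
    columns: list[int] = []
    n = aln.n_rows
    for j in range(aln.n_columns):
        col = [row[j] for row in aln.rows]
        gaps = col.count("-")
        if gaps * 2 > n:  # strict gap majority: column not part of element
            continue
        counts = Counter(c for c in col if c in _CALLABLE)
        depth = sum(counts.values())
        call, frac = "N", 0.0
        if depth >= min_depth:
            ranked = counts.most_common(2)
            if ranked and (len(ranked) == 1 or ranked[0][1] > ranked[1][1]):
                top, cnt = ranked[0]
                if cnt / depth >= majority_fraction:
                    call, frac = top, cnt / depth
        calls.append(call)
        support.append(frac if call != "N" else 0.0)
        columns.append(j)
    if not calls:
        raise AlignmentError("every column was gap-majority; no consensus")
    return ConsensusSequence(SequenceRecord(name, "".join(calls)),
                             tuple(support), tuple(columns))


def write_support_table(cons: ConsensusSequence, path: str | Path) -> None:
    """Tab-separated per-position support: position, alignment column,
    called residue, support fraction."""
    with open(path, "w") as fh:
        fh.write("position\talignment_column\tcall\tsupport\n")
        for i, (col, sup) in enumerate(zip(cons.columns, cons.support)):
            fh.write(f"{i}\t{col}\t{cons.record.residues[i]}\t{sup:.4f}\n")
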