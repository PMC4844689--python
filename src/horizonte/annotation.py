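"""Full-length copy detection and ORF integrity assessment.

Recently active TE families leave near-complete genomic copies; whether
any of them still encodes an intact protein (no frameshifts, no premature
stop codons) decides whether a "master gene" could still be active.  The
assessment here is alignment-guided: the copy is read in the reading frame
of the consensus ORF, the frame being re-anchored by consensus coordinates
after every indel run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .consensus import ConsensusSequence, CopyAlignment
from .errors import AnnotationError
from .io_formats import SequenceRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV-", "TGCAANYRSWMKVHDB-")


@dataclass(frozen=True)
class OrfReport:
    """Frameshift/stop summary of one copy over the consensus ORF."""

    copy_id: str
    frameshift_count: int
    premature_stop_count: int

    @property
    def intact(self) -> bool:
        return self.frameshift_count == 0 and self.premature_stop_count == 0


def _consensus_record(consensus) -> SequenceRecord:
    return consensus.record if isinstance(consensus, ConsensusSequence) \
        else consensus


def find_full_length(copies: CopyAlignment,
                     consensus: SequenceRecord | ConsensusSequence,
                     min_fraction: float = 0.9,
                     end_margin: int = 50) -> list[str]:
    """Ids of copies spanning the consensus nearly end to end.

    A copy qualifies when its aligned span covers at least ``min_fraction``
    of the consensus length and both termini fall within ``end_margin``
    consensus bp of the consensus ends.  Copies are given in consensus
    coordinates (same columns).
    """
    cons = _consensus_record(consensus)
    if copies.n_columns != len(cons):
        raise AnnotationError(
            "copies and consensus are in different coordinates")
    # map alignment column -> consensus (ungapped) position
    cons_pos = []
    p = 0
    for c in cons.residues:
        cons_pos.append(p)
        if c != "-":
            p += 1
    length = p
    if length == 0:
        raise AnnotationError("consensus has no residues")
    out = []
    for cid, row in zip(copies.copy_ids, copies.rows):
        first = next((j for j, c in enumerate(row) if c != "-"), None)
        if first is None:
            continue
        last = next(j for j in range(len(row) - 1, -1, -1)
                    if row[j] != "-")
        start, end = cons_pos[first], cons_pos[last]
        span = end - start + 1
        if (span / length >= min_fraction
                and start <= end_margin
                and (length - 1 - end) <= end_margin):
            out.append(cid)
    return out


def orf_integrity(copy: SequenceRecord,
                  consensus: SequenceRecord | ConsensusSequence,
                  orf_start: int, orf_end: int,
                  strand: str = "+") -> OrfReport:
    """Frameshifts and premature stops of a copy over the consensus ORF.

    ``orf_start``/``orf_end`` are 0-based half-open coordinates on the
    ungapped consensus; the ORF length must be divisible by 3.  ``copy``
    and ``consensus`` are a pairwise alignment (equal column counts).
    ``strand='-'`` marks an alignment stored reverse-complemented: both
    rows are flipped back and the interval remapped so that codons are
    always read on the coding strand.

    * frameshift_count — maximal runs of consecutive indel columns inside
      the ORF whose run length is not a multiple of 3;
    * premature_stop_count — stop codons read in the consensus frame
      strictly before the final codon, the frame being re-anchored by
      consensus coordinates after each indel (insertions relative to the
      consensus are skipped; codons touched by deletion gaps or ambiguous
      bases are never counted as stops).
    """
    cons = _consensus_record(consensus)
    if len(copy) != len(cons):
        raise AnnotationError(
            f"copy {copy.id!r} and consensus differ in column count")
    if strand == "-":
        copy, cons, orf_start, orf_end = reverse_complement_alignment(
            copy, cons, orf_start, orf_end)
    elif strand != "+":
        raise AnnotationError(f"strand must be '+' or '-', got {strand!r}")
    orf_len = orf_end - orf_start
    if orf_len <= 0:
        raise AnnotationError("empty ORF interval")
    if orf_len % 3 != 0:
        raise AnnotationError(
            f"ORF length {orf_len} is not divisible by 3")

    # frameshifts: walk columns whose consensus position lies in the ORF
    frameshifts = 0
    run = 0
    pos = 0  # consensus (ungapped) position of the current column
    in_orf_cols = []
    for j, (x, y) in enumerate(zip(copy.residues, cons.residues)):
        inside = (orf_start <= pos < orf_end) if y != "-" else \
                 (orf_start < pos <= orf_end)  # insertion between positions
        if inside:
            in_orf_cols.append(j)
            if ("-" in (x, y)) and x != y:
                run += 1
            else:
                if run % 3 != 0:
                    frameshifts += 1
                run = 0
        if y != "-":
            pos += 1
    if run % 3 != 0:
        frameshifts += 1

    # premature stops: consensus-frame codons, insertions skipped
    codon: list[str] = []
    stops = 0
    codon_index = 0
    n_codons = orf_len // 3
    pos = 0
    for x, y in zip(copy.residues, cons.residues):
        if y != "-":
            if orf_start <= pos < orf_end:
                codon.append(x)
                if len(codon) == 3:
                    tri = "".join(codon)
                    if tri in STOP_CODONS and codon_index < n_codons - 1:
                        stops += 1
                    codon = []
                    codon_index += 1
            pos += 1
    return OrfReport(copy_id=copy.id, frameshift_count=frameshifts,
                     premature_stop_count=stops)


def reverse_complement_alignment(copy: SequenceRecord,
                                 consensus: SequenceRecord,
                                 orf_start: int, orf_end: int,
                                 ) -> tuple[SequenceRecord, SequenceRecord,
                                            int, int]:
    """Reverse-complement both rows of a pairwise alignment and remap the
    ORF interval onto the flipped consensus coordinates."""
    if len(copy) != len(consensus):
        raise AnnotationError("rows differ in column count")
    rc = lambda s: s.translate(_COMPLEMENT)[::-1]
    length = sum(1 for c in consensus.residues if c != "-")
    new_start = length - orf_end
    new_end = length - orf_start
    return (SequenceRecord(copy.id, rc(copy.residues)),
            SequenceRecord(consensus.id, rc(consensus.residues)),
            new_start, new_end)


def write_orf_reports(reports: Sequence[OrfReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tframeshift_count\tpremature_stop_count\tintact\n")
        for r in reports:
            fh.write(f"{r.copy_id}\t{r.frameshift_count}\t"
                     f"{r.premature_stop_count}\t{str(r.intact).lower()}\n")
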