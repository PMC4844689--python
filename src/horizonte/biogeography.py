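"""Event-parsimony dispersal-vicariance (DIVA) ancestral-area inference.

Classic DIVA costs on a fixed rooted binary tree: at each internal node the
ancestral area set either splits by vicariance into two non-empty,
mutually exclusive parts (cost 0) or, when it is a single area, is passed
to both daughters by duplication/sympatry (cost 0); along each branch,
every area gained costs 1 (dispersal) and every area lost costs 1
(extinction).  Ancestral sets are capped at ``max_areas`` areas (the
analysis here uses two, matching the idea that most bird lineages occupy
at most two avifaunal regions at a time).

The optimisation is exact (dynamic programming over all area subsets of
size <= max_areas), and *all* co-optimal reconstructions are counted by an
inside–outside pass, giving exact per-node frequencies of each ancestral
set among the optima — the quantity that is thresholded for display
("show areas receiving more than a third of the ancestral distribution").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from .errors import BiogeographyError
from .io_formats import LabeledTree, TreeNode

#: The five tropical avifaunal regions used as the default area universe.
DEFAULT_AREAS = ("Neotropics", "Africa", "Madagascar", "Indomalaya",
                 "Australasia")


@dataclass(frozen=True)
class AreaAssignment:
    """Per-leaf area sets over a named universe."""

    universe: tuple[str, ...]
    leaf_areas: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise BiogeographyError("duplicate areas in universe")
        for leaf, areas in self.leaf_areas.items():
            if not areas:
                raise BiogeographyError(f"leaf {leaf!r} has an empty set")
            unknown = set(areas) - uni
            if unknown:
                raise BiogeographyError(
                    f"leaf {leaf!r} has unknown areas: "
                    + ", ".join(sorted(unknown)))

    @classmethod
    def from_dict(cls, leaf_areas: Mapping[str, Sequence[str]],
                  universe: Sequence[str] = DEFAULT_AREAS,
                  ) -> "AreaAssignment":
        return cls(tuple(universe),
                   {k: frozenset(v) for k, v in leaf_areas.items()})


@dataclass(frozen=True)
class AreaReconstruction:
    """Optimal cost plus per-node co-optimal area-set frequencies.

    ``node_frequencies`` maps an internal-node id (postorder index over
    the whole tree) to a list of (area set, frequency) pairs sorted by
    decreasing frequency; frequencies at each node sum to 1.
    """

    cost: int
    node_frequencies: dict[int, list[tuple[frozenset[str], float]]]
    node_labels: dict[int, str]
    n_optimal: float


def _mask(areas: frozenset[str], order: dict[str, int]) -> int:
    m = 0
    for a in areas:
        m |= 1 << order[a]
    return m


def _unmask(mask: int, universe: tuple[str, ...]) -> frozenset[str]:
    return frozenset(a for i, a in enumerate(universe) if mask >> i & 1)


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _scenarios(S: int) -> list[tuple[int, int]]:
    """Allowed (start set child1, start set child2) pairs for a node whose
    set is S: vicariance partitions for widespread sets, duplication for
    single areas."""
    bits = [b for b in range(S.bit_length()) if S >> b & 1]
    if len(bits) == 1:
        return [(S, S)]
    out = []
    # every non-empty proper subset, both orders (child identity matters
    # for branch costs even though the reconstruction only records S)
    for r in range(1, len(bits)):
        for combo in combinations(bits, r):
            A = 0
            for b in combo:
                A |= 1 << b
            out.append((A, S & ~A))
    return out


def _branch_cost(start: int, end: int) -> int:
    """Dispersals (areas gained) + extinctions (areas lost)."""
    return _popcount(start ^ end)


def _node_cost_table(states: list[int]) -> dict[int, dict[tuple[int, int], int]]:
    """cost[S][(S1, S2)] = min over scenarios of the two branch costs."""
    table: dict[int, dict[tuple[int, int], int]] = {}
    for S in states:
        sub: dict[tuple[int, int], int] = {}
        scen = _scenarios(S)
        for S1 in states:
            for S2 in states:
                best = min(_branch_cost(T1, S1) + _branch_cost(T2, S2)
                           for T1, T2 in scen)
                sub[(S1, S2)] = best
        table[S] = sub
    return table


def diva_reconstruct(tree: LabeledTree, leaves: AreaAssignment,
                     max_areas: int = 2,
                     enforce_leaf_limit: bool = True,
                     ) -> AreaReconstruction:
    """Exact DIVA ancestral-area reconstruction on a fixed binary tree.

    Ancestral (internal-node) sets are restricted to at most ``max_areas``
    areas.  Observed leaf sets are fixed; by default a leaf set wider than
    ``max_areas`` is an error, but ``enforce_leaf_limit=False`` accepts
    wide observed ranges while still capping the searched ancestral
    states (useful for widest-distribution codings of widespread taxa).
    """
    if not tree.is_binary():
        raise BiogeographyError("tree must be binary")
    if max_areas < 1:
        raise BiogeographyError("max_areas must be >= 1")
    order = {a: i for i, a in enumerate(leaves.universe)}
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}

    leaf_mask: dict[int, int] = {}
    for i, node in enumerate(nodes):
        if node.is_leaf:
            if node.name not in leaves.leaf_areas:
                raise BiogeographyError(f"leaf {node.name!r} unassigned")
            areas = leaves.leaf_areas[node.name]
            if enforce_leaf_limit and len(areas) > max_areas:
                raise BiogeographyError(
                    f"leaf {node.name!r} has {len(areas)} areas, "
                    f"max_areas is {max_areas}")
            leaf_mask[i] = _mask(areas, order)

    nbits = len(leaves.universe)
    states = [m for m in range(1, 1 << nbits)
              if _popcount(m) <= max_areas]
    # include wide leaf sets in the scenario/cost domain
    all_states = sorted(set(states) | set(leaf_mask.values()))
    cost_tab = _node_cost_table(all_states)

    INF = 10 ** 9
    Cin: dict[int, dict[int, int]] = {}
    Nin: dict[int, dict[int, float]] = {}
    children: dict[int, tuple[int, int]] = {}
    for i, node in enumerate(nodes):
        if node.is_leaf:
            Cin[i] = {leaf_mask[i]: 0}
            Nin[i] = {leaf_mask[i]: 1.0}
            continue
        x, y = (index[id(c)] for c in node.children)
        children[i] = (x, y)
        Cin[i] = {}
        Nin[i] = {}
        for S in states:
            tab = cost_tab[S]
            best, cnt = INF, 0.0
            for S1, c1 in Cin[x].items():
                for S2, c2 in Cin[y].items():
                    tot = tab[(S1, S2)] + c1 + c2
                    if tot < best:
                        best, cnt = tot, Nin[x][S1] * Nin[y][S2]
                    elif tot == best:
                        cnt += Nin[x][S1] * Nin[y][S2]
            Cin[i][S] = best
            Nin[i][S] = cnt

    root = len(nodes) - 1
    opt = min(Cin[root].values())
    n_optimal = sum(Nin[root][S] for S, c in Cin[root].items() if c == opt)

    # outside pass
    Cout: dict[int, dict[int, int]] = {root: {S: 0 for S in Cin[root]}}
    Nout: dict[int, dict[int, float]] = {root: {S: 1.0 for S in Cin[root]}}
    for i in reversed(range(len(nodes))):  # preorder-ish over internals
        if i not in children:
            continue
        x, y = children[i]
        for child, sib in ((x, y), (y, x)):
            Cout[child] = {}
            Nout[child] = {}
            for Sc in Cin[child]:
                best, cnt = INF, 0.0
                for Sv, cv in Cout[i].items():
                    if cv >= INF:
                        continue
                    tab = cost_tab[Sv]
                    for Ss, cs in Cin[sib].items():
                        tot = cv + tab[(Sc, Ss)] + cs
                        if tot < best:
                            best, cnt = tot, Nout[i][Sv] * Nin[sib][Ss]
                        elif tot == best:
                            cnt += Nout[i][Sv] * Nin[sib][Ss]
                Cout[child][Sc] = best
                Nout[child][Sc] = cnt

    node_frequencies: dict[int, list[tuple[frozenset[str], float]]] = {}
    node_labels: dict[int, str] = {}
    for i, node in enumerate(nodes):
        if node.is_leaf:
            continue
        rows = []
        for S in Cin[i]:
            if Cin[i][S] + Cout[i][S] == opt:
                rows.append((S, Nin[i][S] * Nout[i][S]))
        total = sum(w for _, w in rows)
        freq = [(_unmask(S, leaves.universe), w / total) for S, w in rows]
        freq.sort(key=lambda t: (-t[1], sorted(t[0])))
        node_frequencies[i] = freq
        node_labels[i] = node.name or f"node{i}"
    return AreaReconstruction(cost=int(opt),
                              node_frequencies=node_frequencies,
                              node_labels=node_labels,
                              n_optimal=n_optimal)


def filter_display(rec: AreaReconstruction, threshold: float = 1 / 3,
                   ) -> dict[int, list[frozenset[str]]]:
    """Per node, the area sets whose co-optimal frequency strictly exceeds
    ``threshold`` (the display rule for reconstruction figures)."""
    if not 0 <= threshold < 1:
        raise BiogeographyError("threshold must lie in [0, 1)")
    return {node: [s for s, f in freqs if f > threshold]
            for node, freqs in rec.node_frequencies.items()}


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_leaf_areas(path: str | Path,
                    universe: Sequence[str] = DEFAULT_AREAS,
                    ) -> AreaAssignment:
    """Two-column TSV: leaf name, comma-separated areas."""
    leaf_areas: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            leaf, areas = line.split("\t")
        except ValueError as exc:
            raise BiogeographyError(
                f"malformed leaf-area line: {line!r}") from exc
        leaf_areas[leaf] = frozenset(a.strip() for a in areas.split(","))
    return AreaAssignment.from_dict(leaf_areas, universe)


def write_reconstruction_tsv(rec: AreaReconstruction,
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# optimum_cost\t{rec.cost}\n")
        fh.write("node\tareas\tfrequency\n")
        for node, freqs in rec.node_frequencies.items():
            for areas, f in freqs:
                fh.write(f"{rec.node_labels[node]}\t"
                         f"{','.join(sorted(areas))}\t{f:.4f}\n")
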