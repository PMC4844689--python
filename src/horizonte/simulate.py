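"""Synthetic TE evolution: amplification, host switches, area histories.

Three generators produce inputs with the statistical structure the
analysis assumes, together with their ground truth, so every stage of the
pipeline can be tested end to end without genome-scale data:

* :func:`simulate_amplification` — master-gene amplification: copies are
  sampled from a single active master sequence during a bounded activity
  window and accumulate neutral substitutions (transition bias, optional
  CpG hypermutability) independently after insertion, with geometric 5'
  truncation.  Because the master lineage keeps evolving at the same rate,
  the expected K2P divergence of a copy of age t to the *present-day*
  master is 2·mu·t — the quantity the d/(2·mu) dating rule inverts.
* :func:`simulate_transfers` — a TE tree grown congruently on a host tree
  with k planted host switches (prune-free construction: each switch
  copies the TE lineage from a donor edge into an incomparable recipient
  subtree, where it cospeciates).
* :func:`simulate_areas` — an area history evolved root-to-tip with free
  vicariance/duplication plus d planted dispersals.

All generators are fully deterministic given their seed (NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import CopyAlignment
from .errors import SimulationError
from .io_formats import LabeledTree, SequenceRecord, TreeNode
from .landscape import RateSpec

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_A, _C, _G, _T = 0, 1, 2, 3
# transition partner of each base (A<->G, C<->T)
_TS = np.array([_G, _T, _A, _C])
# the two transversion partners of each base
_TV = np.array([[_C, _T], [_A, _G], [_C, _T], [_A, _G]])


def random_sequence(length: int, rng: np.random.Generator,
                    name: str = "master") -> SequenceRecord:
    """Uniform-random nucleotide sequence."""
    codes = rng.integers(0, 4, size=length)
    return SequenceRecord(name, "".join(_BASES[c] for c in codes))


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq], dtype=np.int8)


def _decode(codes: np.ndarray, template: str) -> str:
    return "".join(_BASES[c] if c >= 0 else template[i]
                   for i, c in enumerate(codes))


def _is_cpg(codes: np.ndarray, i: int) -> bool:
    n = len(codes)
    if codes[i] == _C and i + 1 < n and codes[i + 1] == _G:
        return True
    if codes[i] == _G and i - 1 >= 0 and codes[i - 1] == _C:
        return True
    return False


def _mutate(codes: np.ndarray, i: int, kappa: float,
            rng: np.random.Generator) -> None:
    if rng.random() < kappa / (kappa + 1.0):
        codes[i] = _TS[codes[i]]
    else:
        codes[i] = _TV[codes[i], rng.integers(0, 2)]


class _IndexedSet:
    """Set of ints with O(1) add/discard/uniform-choice, deterministic."""

    __slots__ = ("items", "pos")

    def __init__(self, items: Sequence[int] = ()):
        self.items: list[int] = list(items)
        self.pos: dict[int, int] = {v: i for i, v in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, v: int) -> bool:
        return v in self.pos

    def add(self, v: int) -> None:
        if v not in self.pos:
            self.pos[v] = len(self.items)
            self.items.append(v)

    def discard(self, v: int) -> None:
        i = self.pos.pop(v, None)
        if i is None:
            return
        last = self.items.pop()
        if last != v:
            self.items[i] = last
            self.pos[last] = i

    def choose(self, rng: np.random.Generator) -> int:
        return self.items[int(rng.integers(0, len(self.items)))]


def _evolve_codes(codes: np.ndarray, t_myr: float, r_per_myr: float,
                  kappa: float, cpg_multiplier: float,
                  rng: np.random.Generator) -> int:
    """Continuous-time K2P substitution process, in place; returns the
    number of substitution events.  Sites coded -1 (gaps, ambiguity) are
    inert and break CpG context."""
    live = np.flatnonzero(codes >= 0)
    if live.size == 0 or t_myr <= 0 or r_per_myr <= 0:
        return 0
    if cpg_multiplier == 1.0:
        # homogeneous rates: event count is Poisson, sites uniform
        k = rng.poisson(r_per_myr * t_myr * live.size)
        sites = live[rng.integers(0, live.size, size=k)]
        for i in sites:
            _mutate(codes, i, kappa, rng)
        return int(k)
    # context-dependent rates: exact Gillespie with two rate classes
    cpg = _IndexedSet([int(i) for i in live if _is_cpg(codes, i)])
    normal = _IndexedSet([int(i) for i in live if not _is_cpg(codes, i)])
    t_cur = 0.0
    events = 0
    while True:
        total = r_per_myr * (len(normal) + cpg_multiplier * len(cpg))
        if total <= 0:
            break
        t_cur += rng.exponential(1.0 / total)
        if t_cur > t_myr:
            break
        p_cpg = cpg_multiplier * len(cpg) / \
            (len(normal) + cpg_multiplier * len(cpg))
        pool = cpg if (len(cpg) and rng.random() < p_cpg) else normal
        i = pool.choose(rng)
        _mutate(codes, i, kappa, rng)
        events += 1
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(codes) and codes[j] >= 0:
                if _is_cpg(codes, j):
                    cpg.add(j)
                    normal.discard(j)
                else:
                    normal.add(j)
                    cpg.discard(j)
    return events


def evolve_k2p(seq: SequenceRecord, t: float, rate: RateSpec,
               kappa: float = 2.0, cpg_multiplier: float = 1.0,
               seed: int | None = None,
               rng: np.random.Generator | None = None) -> SequenceRecord:
    """Evolve a sequence for ``t`` Myr under a K2P substitution process.

    ``kappa`` is the expected transition:transversion *count* ratio;
    sites currently in CpG context mutate at ``cpg_multiplier`` times the
    base rate.  Gap and ambiguity characters are untouched.
    """
    if t < 0:
        raise SimulationError("t must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = _encode(seq.residues)
    _evolve_codes(codes, t, rate.per_myr(), kappa, cpg_multiplier, rng)
    return SequenceRecord(seq.id, _decode(codes, seq.residues))


# ---------------------------------------------------------------------------
# Master-gene amplification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplificationParams:
    """Parameters of a master-gene amplification run.

    The activity window runs from ``window_start`` back in time to
    ``window_end`` (Myr ago, start >= end >= 0); insertion times are
    uniform within it.  ``truncation_p`` is the geometric parameter of 5'
    truncation (expected truncated bp = (1-p)/p; 1.0 disables truncation);
    at least ``min_copy_bp`` bp of every copy are retained.
    """

    master_length: int = 1000
    window_start: float = 20.0
    window_end: float = 15.0
    n_copies: int = 500
    rate: RateSpec = field(default_factory=lambda: RateSpec(2.5e-9))
    kappa: float = 2.0
    cpg_multiplier: float = 1.0
    truncation_p: float = 0.004
    min_copy_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.master_length < 1:
            raise SimulationError("master_length must be >= 1")
        if not self.window_start >= self.window_end >= 0:
            raise SimulationError("require window_start >= window_end >= 0")
        if self.n_copies < 1:
            raise SimulationError("n_copies must be >= 1")
        if not 0 < self.truncation_p <= 1:
            raise SimulationError("truncation_p must lie in (0, 1]")
        if self.kappa < 0 or self.cpg_multiplier < 1:
            raise SimulationError("kappa >= 0 and cpg_multiplier >= 1")


@dataclass(frozen=True)
class AmplificationTruth:
    """Ground truth of one amplification run.

    ``insertion_times`` are Myr ago, oldest first (matching copy order);
    ``copy_events`` are realized substitution counts on each copy's own
    branch; ``master_final`` is the present-day state of the master
    lineage — the natural divergence reference, against which a copy of
    age t has expected K2P distance 2·mu·t.
    """

    insertion_times: tuple[float, ...]
    copy_events: tuple[int, ...]
    truncations: tuple[int, ...]
    master_final: SequenceRecord
    params: AmplificationParams


def simulate_amplification(p: AmplificationParams) -> tuple[
        SequenceRecord, CopyAlignment, AmplificationTruth]:
    """Master-gene amplification: (founder master, copies, truth).

    The master is drawn uniformly at random and evolves throughout the
    activity window and on to the present; each copy branches off the
    master at its insertion time and then evolves independently to the
    present, after which it is 5'-truncated.  Copies are returned as an
    alignment in master coordinates (truncation padded with gaps).
    """
    rng = np.random.default_rng(p.seed)
    founder = random_sequence(p.master_length, rng)
    r = p.rate.per_myr()
    times = np.sort(rng.uniform(p.window_end, p.window_start,
                                size=p.n_copies))[::-1]
    master_codes = _encode(founder.residues)
    copies: list[str] = []
    copy_ids: list[str] = []
    copy_events: list[int] = []
    truncations: list[int] = []
    t_master = p.window_start  # current age of the master state
    width = len(str(p.n_copies))
    for i, t_ins in enumerate(times):
        _evolve_codes(master_codes, t_master - t_ins, r, p.kappa,
                      p.cpg_multiplier, rng)
        t_master = t_ins
        copy_codes = master_codes.copy()
        ev = _evolve_codes(copy_codes, t_ins, r, p.kappa,
                           p.cpg_multiplier, rng)
        if p.truncation_p < 1.0:
            trunc = int(rng.geometric(p.truncation_p)) - 1
            trunc = min(trunc, max(p.master_length - p.min_copy_bp, 0))
        else:
            trunc = 0
        row = "-" * trunc + _decode(copy_codes, founder.residues)[trunc:]
        cid = f"copy{i + 1:0{width}d}"
        copies.append(row)
        copy_ids.append(cid)
        copy_events.append(ev)
        truncations.append(trunc)
    _evolve_codes(master_codes, t_master, r, p.kappa, p.cpg_multiplier, rng)
    master_final = SequenceRecord("master_final",
                                  _decode(master_codes, founder.residues))
    truth = AmplificationTruth(
        insertion_times=tuple(float(t) for t in times),
        copy_events=tuple(copy_events),
        truncations=tuple(truncations),
        master_final=master_final,
        params=p,
    )
    return founder, CopyAlignment(tuple(copy_ids), tuple(copies)), truth


# ---------------------------------------------------------------------------
# Planted host switches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferTruth:
    """Planted host-switch events as (donor host leaf-set root, recipient
    subtree root) label pairs, in the order applied."""

    events: tuple[tuple[str, str], ...]


def _node_label(node: TreeNode, idx: dict[int, str]) -> str:
    return idx[id(node)]


def simulate_transfers(host: LabeledTree, k: int, seed: int = 0,
                       max_tries: int = 1000) -> tuple[
        LabeledTree, dict[str, str], TransferTruth]:
    """TE tree grown on a host tree with ``k`` planted transfers.

    Starts from a host-congruent TE tree (one copy per host leaf, suffix
    ``|v``).  Each transfer copies the TE lineage from a random donor edge
    of the vertical tree into a random recipient host subtree
    *incomparable* to the donor, where it cospeciates (leaf suffix
    ``|t<i>``).  Recipients are pairwise non-nested so no event overwrites
    another.  Returns the TE tree, the leaf -> host map and the event
    list; raises :class:`SimulationError` when no valid placement exists.
    """
    if k < 0:
        raise SimulationError("k must be >= 0")
    if not host.is_binary():
        raise SimulationError("host tree must be binary")
    rng = np.random.default_rng(seed)
    nodes = list(host.postorder())
    # descendant-or-self relation over host nodes
    below: dict[int, set[int]] = {}
    for node in nodes:
        s = {id(node)}
        for c in node.children:
            s |= below[id(c)]
        below[id(node)] = s
    non_root = [n for n in nodes if n.parent is not None]

    def comparable(a: TreeNode, b: TreeNode) -> bool:
        return id(b) in below[id(a)] or id(a) in below[id(b)]

    events: list[tuple[TreeNode, TreeNode]] = []
    for _ in range(max_tries):
        events.clear()
        ok = True
        for _ev in range(k):
            cands = []
            for d in non_root:
                for r in non_root:
                    if comparable(d, r):
                        continue
                    if any(comparable(r, r0) for _, r0 in events):
                        continue
                    cands.append((d, r))
            if not cands:
                ok = False
                break
            events.append(cands[rng.integers(0, len(cands))])
        if ok:
            break
    else:
        raise SimulationError(
            f"could not place {k} non-overlapping transfers on this tree")

    by_donor: dict[int, list[tuple[int, TreeNode]]] = {}
    for i, (d, r) in enumerate(events):
        by_donor.setdefault(id(d), []).append((i, r))

    def mirror(node: TreeNode, suffix: str) -> TreeNode:
        if node.is_leaf:
            return TreeNode(name=f"{node.name}{suffix}")
        out = TreeNode()
        for c in node.children:
            out.add_child(build(c, suffix))
        return out

    def build(node: TreeNode, suffix: str) -> TreeNode:
        """Mirror subtree, inserting transfer nodes above donor edges of
        the vertical tree (suffix '|v') only."""
        sub = mirror(node, suffix)
        if suffix == "|v":
            for i, r in sorted(by_donor.get(id(node), []), reverse=True):
                wrap = TreeNode()
                wrap.add_child(mirror(r, f"|t{i + 1}"))
                wrap.add_child(sub)
                sub = wrap
        return sub

    te_root = TreeNode()
    for c in host.root.children:
        te_root.add_child(build(c, "|v"))
    if not host.root.children:  # single-leaf host tree
        te_root = build(host.root, "|v")
    te = LabeledTree(te_root)
    host_map = {leaf: leaf.split("|")[0] for leaf in te.leaf_names}
    truth = TransferTruth(events=tuple(
        (d.name or "internal", r.name or "internal") for d, r in events))
    return te, host_map, truth


# ---------------------------------------------------------------------------
# Planted area histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaTruth:
    """Planted per-node area sets and dispersal placements."""

    node_areas: dict[str, frozenset[str]]
    root_areas: frozenset[str]
    dispersals: tuple[tuple[str, str], ...]  # (child node label, area)


def simulate_areas(tree: LabeledTree, universe: Sequence[str],
                   d: int = 0, seed: int = 0,
                   max_tries: int = 200):
    """Area history with free vicariance/duplication plus ``d`` planted
    dispersals; returns (AreaAssignment, AreaTruth).

    The root receives a random set of one or two areas.  Down each branch
    the set is inherited unchanged except on the ``d`` chosen branches,
    where one new area is gained (only branches whose incoming set is a
    single area are eligible, keeping every node within the two-area cap).
    At each widespread internal node the set splits by vicariance; single
    areas duplicate.
    """
    from .biogeography import AreaAssignment  # local: avoid cycle

    if d < 0:
        raise SimulationError("d must be >= 0")
    rng = np.random.default_rng(seed)
    nodes = list(tree.postorder())
    labels = {id(n): (n.name or f"node{i}") for i, n in enumerate(nodes)}
    branches = [n for n in nodes if n.parent is not None]
    if d > len(branches):
        raise SimulationError("more dispersals than branches")

    for _try in range(max_tries):
        chosen = set()
        if d:
            idx = rng.choice(len(branches), size=d, replace=False)
            chosen = {id(branches[int(i)]) for i in idx}
        uni = list(universe)
        root_size = 1 + int(rng.random() < 0.5)
        root_set = frozenset(
            uni[int(i)] for i in rng.choice(len(uni), size=root_size,
                                            replace=False))
        node_areas: dict[str, frozenset[str]] = {}
        dispersals: list[tuple[str, str]] = []
        failed = False

        def descend(node: TreeNode, incoming: frozenset[str]) -> None:
            nonlocal failed
            if failed:
                return
            current = incoming
            if id(node) in chosen:
                if len(current) != 1:
                    failed = True
                    return
                gains = [a for a in uni if a not in current]
                gain = gains[int(rng.integers(0, len(gains)))]
                current = current | {gain}
                dispersals.append((labels[id(node)], gain))
            node_areas[labels[id(node)]] = current
            if node.is_leaf:
                return
            if len(current) >= 2:  # vicariance
                items = sorted(current)
                pick = rng.permutation(len(items))
                left = frozenset([items[int(pick[0])]])
                right = frozenset(current - left)
                if rng.random() < 0.5:
                    left, right = right, left
            else:  # duplication
                left = right = current
            descend(node.children[0], left)
            descend(node.children[1], right)

        descend(tree.root, root_set)
        if not failed and len(dispersals) == d:
            leaf_areas = {n.name: node_areas[labels[id(n)]]
                          for n in tree.leaves()}
            assignment = AreaAssignment.from_dict(
                leaf_areas, universe=tuple(universe))
            truth = AreaTruth(node_areas=node_areas,
                              root_areas=root_set,
                              dispersals=tuple(dispersals))
            return assignment, truth
    raise SimulationError(
        f"could not place {d} dispersals after {max_tries} attempts")


# ---------------------------------------------------------------------------
# Random trees (shared by tests and simulations)
# ---------------------------------------------------------------------------

def random_binary_tree(leaf_names: Sequence[str],
                       rng: np.random.Generator) -> LabeledTree:
    """Uniform random coalescent-style rooted binary topology."""
    if not leaf_names:
        raise SimulationError("need at least one leaf")
    pool: list[TreeNode] = [TreeNode(name=n) for n in leaf_names]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(int(j))
        a = pool.pop(int(i))
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    return LabeledTree(pool[0])
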