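"""Minimum-transfer reconciliation of a TE tree with a host species tree.

Incongruence between a TE phylogeny and the phylogeny of its host genomes
is explained by horizontal transfer events.  The model is transfer-only
event parsimony on rooted binary trees, undated:

* cospeciation — a TE node maps to a host node whose two child subtrees
  separate the images of the TE node's children: cost 0;
* within-host duplication — both children map to the same *terminal* host
  genome as the node itself: cost 0 (TE subfamilies diversify freely
  within a genome);
* loss — implicit and free: a TE lineage may descend from its host into
  any node of that host's subtree between events;
* transfer — one child's image escapes the host subtree of its parent's
  image: cost 1.

Duplication is restricted to terminal genomes on purpose: if free
duplication were allowed at internal host nodes, any incongruence could be
explained at zero cost by duplicating at the host root and losing copies,
and the parsimony would be vacuous.  Under this model a TE tree congruent
with its host tree costs 0, and each topological conflict costs one
transfer.

Computed by dynamic programming over (TE node, host node) pairs, with
exact counting and deterministic enumeration of co-optimal mappings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterator, Literal, Mapping

import numpy as np

from .errors import ReconciliationError
from .io_formats import LabeledTree, TreeNode

INF = np.int32(10 ** 6)

Admissibility = Literal["incomparable", "any"]


class _TreeIndex:
    """Postorder array view of a binary LabeledTree."""

    def __init__(self, tree: LabeledTree, what: str):
        if not tree.is_binary():
            raise ReconciliationError(f"{what} tree is not binary")
        self.nodes: list[TreeNode] = list(tree.postorder())
        self.index: dict[int, int] = {id(n): i for i, n in
                                      enumerate(self.nodes)}
        n = len(self.nodes)
        self.is_leaf = np.array([nd.is_leaf for nd in self.nodes])
        self.children = np.full((n, 2), -1, dtype=int)
        self.parent = np.full(n, -1, dtype=int)
        for i, nd in enumerate(self.nodes):
            for k, ch in enumerate(nd.children):
                self.children[i, k] = self.index[id(ch)]
                self.parent[self.index[id(ch)]] = i
        # desc[i, j]: j lies in the subtree rooted at i (inclusive)
        self.desc = np.zeros((n, n), dtype=bool)
        for i, nd in enumerate(self.nodes):
            self.desc[i, i] = True
            for c in self.children[i]:
                if c >= 0:
                    self.desc[i] |= self.desc[c]
        self.leaf_by_name = {nd.name: i for i, nd in enumerate(self.nodes)
                             if nd.is_leaf}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def label(self, i: int) -> str:
        nd = self.nodes[i]
        return nd.name if nd.name else f"node{i}"


def _cost_tensor(host: _TreeIndex,
                 admissibility: Admissibility) -> np.ndarray:
    """T[h, hx, hy]: cost of the event at a TE node mapped to host h whose
    children map to hx and hy.  INF marks forbidden combinations."""
    H = host.n
    comparable = host.desc | host.desc.T
    if admissibility == "incomparable":
        esc_ok = ~comparable
    elif admissibility == "any":
        esc_ok = ~host.desc  # may escape to ancestors as well
    else:
        raise ReconciliationError(
            f"unknown transfer admissibility {admissibility!r}")
    T = np.full((H, H, H), INF, dtype=np.int32)
    for h in range(H):
        within = host.desc[h]
        # transfer: one child stays within, the other escapes
        stay_x = within[:, None] & esc_ok[h][None, :]
        stay_y = within[None, :] & esc_ok[h][:, None]
        T[h][stay_x | stay_y] = 1
        if host.is_leaf[h]:
            T[h, h, h] = 0  # within-host duplication
        else:
            L, R = host.children[h]
            sep = (host.desc[L][:, None] & host.desc[R][None, :]) | \
                  (host.desc[R][:, None] & host.desc[L][None, :])
            T[h][sep] = 0  # cospeciation
    return T


@dataclass
class TransferEvent:
    """A single inferred host switch: the TE child edge whose image left
    its parent's host subtree."""

    te_parent: str
    te_child: str
    donor_host: str
    recipient_host: str


@dataclass
class ReconciliationResult:
    transfer_count: int
    mapping: dict[str, str]
    edge_events: dict[tuple[str, str], str]  # (parent, child) -> label
    events: list[TransferEvent]
    n_optimal: int
    time_consistent: bool
    warnings: list[str] = field(default_factory=list)


def _validate_map(te_idx: _TreeIndex, host_idx: _TreeIndex,
                  host_map: Mapping[str, str]) -> dict[int, int]:
    out: dict[int, int] = {}
    for name, i in te_idx.leaf_by_name.items():
        if name not in host_map:
            raise ReconciliationError(f"TE leaf {name!r} is unmapped")
        target = host_map[name]
        if target not in host_idx.leaf_by_name:
            raise ReconciliationError(
                f"host leaf {target!r} (image of {name!r}) not in host tree")
        out[i] = host_idx.leaf_by_name[target]
    return out


class _DP:
    """Shared DP state for min_transfers / enumerate_optimal."""

    def __init__(self, te: LabeledTree, host: LabeledTree,
                 host_map: Mapping[str, str],
                 admissibility: Admissibility):
        self.te = _TreeIndex(te, "TE")
        self.host = _TreeIndex(host, "host")
        self.leaf_images = _validate_map(self.te, self.host, host_map)
        self.T = _cost_tensor(self.host, admissibility)
        H = self.host.n
        V = self.te.n
        self.C = np.full((V, H), INF, dtype=np.int64)
        self.N = np.zeros((V, H), dtype=float)  # co-optimal counts
        for v in range(V):
            if self.te.is_leaf[v]:
                img = self.leaf_images[v]
                self.C[v, img] = 0
                self.N[v, img] = 1.0
                continue
            x, y = self.te.children[v]
            pair = self.C[x][:, None] + self.C[y][None, :]
            wpair = self.N[x][:, None] * self.N[y][None, :]
            for h in range(H):
                M = pair + self.T[h]
                best = M.min()
                self.C[v, h] = best
                if best < INF:
                    self.N[v, h] = wpair[M == best].sum()
        root = V - 1
        self.opt = int(self.C[root].min())
        if self.opt >= INF:
            raise ReconciliationError("no feasible reconciliation")
        self.n_optimal = float(self.N[root][self.C[root] == self.opt].sum())

    def assignments(self) -> Iterator[dict[int, int]]:
        """All optimal TE-node -> host-node assignments, lexicographic by
        (TE postorder id, host postorder id)."""
        root = self.te.n - 1

        def expand(v: int, h: int) -> Iterator[dict[int, int]]:
            if self.te.is_leaf[v]:
                yield {v: h}
                return
            x, y = self.te.children[v]
            target = self.C[v, h]
            M = self.C[x][:, None] + self.C[y][None, :] + self.T[h]
            for hx, hy in zip(*np.nonzero(M == target)):
                for ax in expand(x, int(hx)):
                    for ay in expand(y, int(hy)):
                        yield {v: h, **ax, **ay}

        for h in range(self.host.n):
            if self.C[root, h] == self.opt:
                yield from expand(root, h)

    def label_assignment(self, assign: dict[int, int]) -> tuple[
            dict[str, str], dict[tuple[str, str], str],
            list[TransferEvent]]:
        mapping = {self.te.label(v): self.host.label(h)
                   for v, h in sorted(assign.items())}
        edge_events: dict[tuple[str, str], str] = {}
        events: list[TransferEvent] = []
        for v, h in assign.items():
            if self.te.is_leaf[v]:
                continue
            for c in self.te.children[v]:
                hc = assign[c]
                key = (self.te.label(v), self.te.label(c))
                if self.host.desc[h, hc]:
                    edge_events[key] = "vertical"
                else:
                    edge_events[key] = "transfer"
                    events.append(TransferEvent(
                        te_parent=self.te.label(v),
                        te_child=self.te.label(c),
                        donor_host=self.host.label(h),
                        recipient_host=self.host.label(hc)))
        return mapping, edge_events, events

    def time_consistent(self, assign: dict[int, int]) -> bool:
        """Heuristic undated cycle check (Stolzer-style): each transfer
        from donor d to recipient e requires the edges above d and e to
        overlap in time, encoded as precedence arcs parent(e) -> d and
        parent(d) -> e on top of host ancestry arcs; reconciliation is
        flagged inconsistent if the resulting graph has a cycle."""
        graph: dict[int, set[int]] = {h: set() for h in range(self.host.n)}
        for h in range(self.host.n):
            p = self.host.parent[h]
            if p >= 0:
                graph[h].add(p)  # predecessor relation: parent before child
        for v, h in assign.items():
            if self.te.is_leaf[v]:
                continue
            for c in self.te.children[v]:
                hc = assign[c]
                if not self.host.desc[h, hc]:  # transfer h -> hc
                    pd = self.host.parent[h]
                    pe = self.host.parent[hc]
                    if pe >= 0:
                        graph[h].add(pe)
                    if pd >= 0:
                        graph[hc].add(pd)
        try:
            TopologicalSorter(graph).static_order()
            return True
        except CycleError:
            return False


def min_transfers(te: LabeledTree, host: LabeledTree,
                  host_map: Mapping[str, str],
                  admissibility: Admissibility = "incomparable",
                  ) -> ReconciliationResult:
    """Minimum number of host switches reconciling the TE tree with the
    host tree, with one optimal mapping and the count of co-optima.

    ``host_map`` sends every TE leaf to a host leaf (many-to-one allowed).
    ``admissibility`` controls transfer targets: ``"incomparable"``
    (default, standard undated rule — a transfer cannot go to an ancestor
    of the donor) or ``"any"`` (any node outside the donor subtree).
    """
    dp = _DP(te, host, host_map, admissibility)
    assign = next(dp.assignments())
    mapping, edge_events, events = dp.label_assignment(assign)
    consistent = dp.time_consistent(assign)
    warnings = []
    if not consistent:
        warnings.append(
            "reported optimal mapping is not time-consistent (undated "
            "parsimony; count is still the topological optimum)")
    n_opt = dp.n_optimal
    return ReconciliationResult(
        transfer_count=dp.opt,
        mapping=mapping,
        edge_events=edge_events,
        events=events,
        n_optimal=int(n_opt) if n_opt < 2 ** 53 else -1,
        time_consistent=consistent,
        warnings=warnings,
    )


def enumerate_optimal(te: LabeledTree, host: LabeledTree,
                      host_map: Mapping[str, str],
                      limit: int = 100,
                      admissibility: Admissibility = "incomparable",
                      ) -> list[dict[str, str]]:
    """Up to ``limit`` distinct optimal TE-node -> host-node mappings, in
    deterministic lexicographic order of the DP backtrace."""
    if limit < 1:
        raise ReconciliationError("limit must be >= 1")
    dp = _DP(te, host, host_map, admissibility)
    out = []
    for assign in itertools.islice(dp.assignments(), limit):
        mapping, _, _ = dp.label_assignment(assign)
        out.append(mapping)
    return out


def write_reconciliation_tsv(result: ReconciliationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# transfer_count\t{result.transfer_count}\n")
        fh.write(f"# n_optimal\t{result.n_optimal}\n")
        fh.write(f"# time_consistent\t{result.time_consistent}\n")
        fh.write("te_node\thost_node\n")
        for te_node, host_node in result.mapping.items():
            fh.write(f"{te_node}\t{host_node}\n")
        fh.write("te_parent\tte_child\tevent\n")
        for (p, c), label in result.edge_events.items():
            fh.write(f"{p}\t{c}\t{label}\n")
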