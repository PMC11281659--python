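"""Circular split networks from Venn-incidence data.

Pipeline: binary incidence matrix (taxa x features) -> uncorrected-P
distances -> NeighborNet agglomeration for a circular taxon ordering ->
non-negative least squares over the ordering-compatible splits for weights
-> optional column bootstrap for split supports.

The agglomeration follows the canonical scheme: cluster pairs are chosen by
the neighbor-joining Q criterion on cluster-averaged distances, node pairs
within the chosen clusters by the same criterion at node level, and joined
paths are collapsed back to two nodes with the 2/3-1/3 reduction, which is
undone at the end to yield the full circular ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .venn import VennGroup


class NetworkError(ValueError):
    pass


@dataclass
class IncidenceMatrix:
    """Binary taxa-by-features membership matrix."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_features) of 0/1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if len(self.taxa) < 3:
            raise NetworkError("need >= 3 taxa")
        if self.data.shape[0] != len(self.taxa):
            raise NetworkError("incidence rows must match taxa")
        if self.data.shape[1] and (self.data.sum(axis=0) == 0).any():
            raise NetworkError("all-zero feature column")


def venn_incidence(
    vg: Mapping[str, VennGroup] | Sequence[VennGroup],
    taxa: Sequence[str] = ("A", "B", "E", "V"),
) -> IncidenceMatrix:
    """One column per feature; cell 1 iff the feature's group contains the taxon."""
    groups = list(vg.values()) if isinstance(vg, Mapping) else list(vg)
    taxa = list(taxa)
    if len(taxa) < 3:
        raise NetworkError("need >= 3 taxa")
    data = np.zeros((len(taxa), len(groups)), dtype=np.int8)
    for j, g in enumerate(groups):
        members = g.members if isinstance(g, VennGroup) else frozenset(g)
        for i, t in enumerate(taxa):
            data[i, j] = 1 if t in members else 0
    return IncidenceMatrix(taxa=taxa, data=data)


def uncorrected_p(inc: IncidenceMatrix) -> pd.DataFrame:
    """Proportion of differing columns per taxon pair."""
    if inc.data.shape[1] == 0:
        raise NetworkError("incidence matrix has no features")
    n = len(inc.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(inc.data[i] != inc.data[j])
    return pd.DataFrame(d, index=inc.taxa, columns=inc.taxa)


@dataclass
class Split:
    side: frozenset[str]  # canonical: the side without the smallest taxon
    weight: float
    support: float | None = None

    def is_trivial(self, n_taxa: int) -> bool:
        return len(self.side) == 1 or len(self.side) == n_taxa - 1


@dataclass
class SplitSystem:
    ordering: list[str]  # circular taxon ordering
    splits: list[Split]

    def split_map(self) -> dict[frozenset[str], Split]:
        return {s.side: s for s in self.splits}

    def fitted_distance(self, a: str, b: str) -> float:
        total = 0.0
        for s in self.splits:
            if (a in s.side) != (b in s.side):
                total += s.weight
        return total

    def to_nexus(self, path) -> None:
        n = len(self.ordering)
        idx = {t: i + 1 for i, t in enumerate(self.ordering)}
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={n};",
            "    TAXLABELS " + " ".join(f"'{t}'" for t in self.ordering) + ";",
            "END;",
            "BEGIN SPLITS;",
            f"    DIMENSIONS NTAX={n} NSPLITS={len(self.splits)};",
            "    FORMAT LABELS=NO WEIGHTS=YES"
            + (" CONFIDENCES=YES" if any(s.support is not None for s in self.splits) else "")
            + ";",
            "    CYCLE " + " ".join(str(idx[t]) for t in self.ordering) + ";",
            "    MATRIX",
        ]
        for s in self.splits:
            members = " ".join(str(idx[t]) for t in sorted(s.side, key=idx.get))
            if s.support is None:
                lines.append(f"        {s.weight:.6g}\t{members},")
            else:
                lines.append(f"        {s.weight:.6g}\t{s.support:.4f}\t{members},")
        lines += ["    ;", "END;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "split": "|".join(sorted(s.side)),
                "weight": s.weight,
                "support": s.support,
            }
            for s in self.splits
        ]
        return pd.DataFrame(rows)


def _canonical_side(side: frozenset[str], taxa: Sequence[str]) -> frozenset[str]:
    ref = min(taxa)
    if ref in side:
        return frozenset(set(taxa) - side)
    return side


# ---------------------------------------------------------------------------
# NeighborNet agglomeration
# ---------------------------------------------------------------------------


def _nn_ordering(D: np.ndarray) -> list[int]:
    """Circular ordering of taxon indices via NeighborNet agglomeration."""
    n = D.shape[0]
    if n == 3:
        return [0, 1, 2]
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dist[(j, i)] = float(D[i, j])
    next_id = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    expansions: list[tuple[int, int, int, int, int]] = []

    def d(x: int, y: int) -> float:
        return 0.0 if x == y else dist[(x, y)]

    def dc(A: list[int], B: list[int]) -> float:
        return float(np.mean([d(x, y) for x in A for y in B]))

    while len(clusters) > 3:
        N = len(clusters)
        R = [sum(dc(A, C) for C in clusters if C is not A) for A in clusters]
        best, best_q = None, None
        for ai in range(N):
            for bi in range(ai + 1, N):
                q = (N - 2) * dc(clusters[ai], clusters[bi]) - R[ai] - R[bi]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (ai, bi)
        ai, bi = best
        A, B = clusters[ai], clusters[bi]
        # node-level choice: NJ criterion over active nodes, ends only
        nodes = [x for C in clusters for x in C]
        M = len(nodes)
        Rn = {x: sum(d(x, z) for z in nodes if z != x) for x in nodes}
        best_pair, best_q = None, None
        for x in A:
            for y in B:
                q = (M - 2) * d(x, y) - Rn[x] - Rn[y]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (x, y)
        x, y = best_pair
        pa = list(A) if A[-1] == x else list(reversed(A))
        pb = list(B) if B[0] == y else list(reversed(B))
        path = pa + pb
        other_nodes = [
            z for k, C in enumerate(clusters) if k not in (ai, bi) for z in C
        ]
        # collapse back to a 2-node cluster via 3-point reductions at the join
        while len(path) > 2:
            p, q_, r = path[0], path[1], path[2]
            u, v = next_id, next_id + 1
            next_id += 2
            for s in other_nodes + path[3:]:
                dist[(u, s)] = dist[(s, u)] = 2 / 3 * d(p, s) + 1 / 3 * d(q_, s)
                dist[(v, s)] = dist[(s, v)] = 2 / 3 * d(r, s) + 1 / 3 * d(q_, s)
            dist[(u, v)] = dist[(v, u)] = (d(p, q_) + d(q_, r) + d(p, r)) / 3
            expansions.append((u, v, p, q_, r))
            path = [u, v] + path[3:]
        clusters = [C for k, C in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(path)

    cycle: list[int] = [x for C in clusters for x in C]
    # undo reductions, innermost last; u,v are cyclically adjacent and expand
    # to p,q,r with the same orientation (u-side = p)
    for (u, v, p, q_, r) in reversed(expansions):
        m = len(cycle)
        k = next(
            k
            for k in range(m)
            if {cycle[k], cycle[(k + 1) % m]} == {u, v}
        )
        rot = cycle[k:] + cycle[:k]
        if rot[0] == u:
            cycle = [p, q_, r] + rot[2:]
        else:
            cycle = [r, q_, p] + rot[2:]
    return cycle


def _circular_splits(order: Sequence[str]) -> list[frozenset[str]]:
    """All n(n-1)/2 splits whose sides are contiguous arcs of the ordering."""
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(order[i : j + 1]))
    return out


def neighbor_net(dm: pd.DataFrame, weight_threshold: float = 1e-8) -> SplitSystem:
    """Circular split system with NNLS-estimated non-negative split weights.

    Splits below ``weight_threshold`` are dropped except trivial (singleton)
    splits, which are always retained.
    """
    taxa = list(dm.index)
    D = np.asarray(dm, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise NetworkError("distance matrix must be square and symmetric")
    if (D < 0).any():
        raise NetworkError("negative distances")
    if len(taxa) < 3:
        raise NetworkError("need >= 3 taxa")
    order_idx = _nn_ordering(D)
    order = [taxa[i] for i in order_idx]
    cand = _circular_splits(order)
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    A = np.zeros((len(pairs), len(cand)))
    for s_idx, side in enumerate(cand):
        for p_idx, (i, j) in enumerate(pairs):
            if (taxa[i] in side) != (taxa[j] in side):
                A[p_idx, s_idx] = 1.0
    dvec = np.array([D[i, j] for i, j in pairs])
    w, _ = nnls(A, dvec)
    splits = []
    for side, weight in zip(cand, w):
        canon = _canonical_side(side, taxa)
        trivial = len(canon) in (1, len(taxa) - 1)
        if weight >= weight_threshold or trivial:
            splits.append(Split(side=canon, weight=float(weight)))
    splits.sort(key=lambda s: (len(s.side), sorted(s.side)))
    return SplitSystem(ordering=order, splits=splits)


def split_bootstrap(
    inc: IncidenceMatrix,
    n_replicates: int = 2000,
    seed: int | None = 0,
    weight_threshold: float = 1e-8,
) -> SplitSystem:
    """Column bootstrap: support of a split = fraction of replicates whose
    retained splits include the identical bipartition."""
    base = neighbor_net(uncorrected_p(inc), weight_threshold)
    rng = np.random.default_rng(seed)
    counts = {s.side: 0 for s in base.splits}
    n_feat = inc.data.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, n_feat, size=n_feat)
        data = inc.data[:, idx]
        keep = data.sum(axis=0) > 0
        rep = IncidenceMatrix(taxa=list(inc.taxa), data=data[:, keep])
        try:
            rep_sys = neighbor_net(uncorrected_p(rep), weight_threshold)
        except NetworkError:
            continue
        rep_sides = {s.side for s in rep_sys.splits}
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for s in base.splits:
        s.support = counts[s.side] / n_replicates
    return base
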