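"""Lundberg rooting with hypothetical extreme-state ancestors, node-distance
chronology, and linear clock calibration to geological time (Gya).

The root is found by scoring the attachment of a max- (or min-) state
ancestor on every edge of the unrooted tree and splitting the best edge; the
ancestor itself is not retained as a leaf.  Leaf ages are the edge counts
from root to leaf, normalized to nd in [0, 1] (0 = oldest), then optionally
mapped to Gya through user-set anchor points (default 0 -> 3.6 Gya, 1 -> 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import MISSING, CharacterMatrix
from .parsimony import ParsimonyScorer, leaf_cost_vector
from .trees import RNode, UnrootedTree, rooted_from_unrooted


class RootingError(ValueError):
    pass


@dataclass
class AncestorVector:
    states: np.ndarray  # per-character extreme state
    mode: str  # "max" | "min"


def make_ancestor(cm: CharacterMatrix, mode: str = "max") -> AncestorVector:
    """Per-character observed maximum (or minimum) state vector."""
    if mode not in ("max", "min"):
        raise RootingError(f"mode must be 'max' or 'min', got {mode!r}")
    states = np.empty(len(cm.characters), dtype=np.int64)
    for j in range(len(cm.characters)):
        col = cm.states[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            states[j] = 0
        else:
            states[j] = col.max() if mode == "max" else col.min()
    return AncestorVector(states=states, mode=mode)


def lundberg_root(
    tree: UnrootedTree, cm: CharacterMatrix, ancestor: AncestorVector
) -> RNode:
    """Root on the edge where attaching the ancestor is most parsimonious.

    Ties break toward the first edge in canonical order.
    """
    if not tree.is_binary() and len(tree.adj) > 2:
        raise RootingError("tree must be binary")
    scorer = ParsimonyScorer(cm)
    anc_cost = leaf_cost_vector(ancestor.states, cm.n_states)
    scores = scorer.attachment_scores(tree, anc_cost)
    best_edge = min(scores, key=lambda es: es[1])[0]
    return rooted_from_unrooted(tree, best_edge)


def node_distances(root: RNode) -> dict[str, int]:
    """Edge count from root to each leaf."""
    if not isinstance(root, RNode):
        raise RootingError("node_distances requires a rooted tree")
    out: dict[str, int] = {}

    def walk(n: RNode, depth: int):
        if n.is_leaf:
            out[n.label] = depth
            return
        for c in n.children:
            walk(c, depth + 1)

    walk(root, 0)
    return out


def normalize_nd(d: dict[str, int]) -> dict[str, float]:
    """nd = (d - min) / (max - min); all-equal depths collapse to 0."""
    if not d:
        raise RootingError("no leaves")
    lo, hi = min(d.values()), max(d.values())
    if hi == lo:
        warnings.warn("all node distances equal; nd set to 0 for every leaf")
        return {k: 0.0 for k in d}
    return {k: (v - lo) / (hi - lo) for k, v in d.items()}


@dataclass
class ClockCalibration:
    """Affine nd -> Gya map fit by least squares through anchor points."""

    anchors: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 3.6), (1.0, 0.0)]
    )

    def __post_init__(self):
        nds = [a for a, _ in self.anchors]
        if len(self.anchors) < 2 or len(set(nds)) < 2:
            raise RootingError("need >= 2 anchors with distinct nd")
        x = np.array(nds)
        y = np.array([g for _, g in self.anchors])
        A = np.vstack([x, np.ones_like(x)]).T
        (self.slope, self.intercept), *_ = np.linalg.lstsq(A, y, rcond=None)


def calibrate_time(nd, cal: ClockCalibration | None = None):
    """Map nd to Gya (clamped at >= 0); accepts scalars or dicts."""
    cal = cal or ClockCalibration()
    if isinstance(nd, dict):
        return {k: calibrate_time(v, cal) for k, v in nd.items()}
    return float(max(0.0, cal.slope * nd + cal.intercept))


@dataclass
class RootedChronology:
    tree: RNode
    d: dict[str, int]
    nd: dict[str, float]
    age_gya: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": k,
                "d": self.d[k],
                "nd": self.nd[k],
                "age_gya": (self.age_gya or {}).get(k, float("nan")),
            }
            for k in sorted(self.d, key=lambda k: (self.nd[k], k))
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_chronology(
    tree: UnrootedTree,
    cm: CharacterMatrix,
    mode: str = "max",
    calibration: ClockCalibration | None = None,
) -> RootedChronology:
    """Root, count node distances, normalize and calibrate in one step."""
    rooted = lundberg_root(tree, cm, make_ancestor(cm, mode))
    d = node_distances(rooted)
    nd = normalize_nd(d)
    age = calibrate_time(nd, calibration or ClockCalibration())
    return RootedChronology(tree=rooted, d=d, nd=nd, age_gya=age)
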