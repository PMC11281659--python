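"""Maximum parsimony for linearly ordered multistate (Wagner) characters.

Tree length is the Sankoff minimum over internal-node state assignments with
per-edge cost |i - j| on the linear state graph.  Because the cost is a
distance, the min-plus convolution against |i - j| reduces to a two-pass
distance transform over the state axis, giving O(S) per node and character.
Missing states ('?') initialize every state at cost zero.

The same "insert a pendant vertex on every edge" primitive drives stepwise
addition, SPR reattachment and Lundberg root placement: for an edge (p, v)
and an attachment with parent-view cost vector g,

    score = sum_chars min_t [ DT(down[v])(t) + g(t) + DT(out[p, v])(t) ]

where down/out are the inside/outside Sankoff vectors and DT the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import MISSING, CharacterMatrix
from .trees import UnrootedTree, enumerate_topologies, random_topology

INF = np.inf


class ParsimonyError(ValueError):
    pass


def _dt(m: np.ndarray) -> np.ndarray:
    """Distance transform: out[..., s] = min_t m[..., t] + |s - t|."""
    out = m.copy()
    S = out.shape[-1]
    for s in range(1, S):
        np.minimum(out[..., s], out[..., s - 1] + 1, out=out[..., s])
    for s in range(S - 2, -1, -1):
        np.minimum(out[..., s], out[..., s + 1] + 1, out=out[..., s])
    return out


def leaf_cost_vector(states: np.ndarray, n_states: int) -> np.ndarray:
    """(n_chars, S) Sankoff initialization for one taxon's state row."""
    n_chars = states.shape[0]
    cost = np.full((n_chars, n_states), INF)
    miss = states == MISSING
    cost[miss, :] = 0.0
    idx = np.nonzero(~miss)[0]
    cost[idx, states[idx]] = 0.0
    return cost


class ParsimonyScorer:
    """Scores trees against a fixed character matrix."""

    def __init__(self, cm: CharacterMatrix):
        self.cm = cm
        self.S = cm.n_states
        self.n_chars = len(cm.characters)
        self.leaf_cost = {
            t.id: leaf_cost_vector(cm.states[i], cm.n_states)
            for i, t in enumerate(cm.taxa)
        }

    def _check_taxa(self, tree: UnrootedTree) -> None:
        extra = set(tree.leaf_labels) - set(self.leaf_cost)
        if extra:
            raise ParsimonyError(f"tree leaves absent from matrix: {sorted(extra)}")

    def _down(self, tree: UnrootedTree, root: int) -> dict[int, np.ndarray]:
        """Inside vectors for the orientation rooted at ``root``."""
        down: dict[int, np.ndarray] = {}

        def walk(node: int, parent: int | None):
            kids = [nb for nb in sorted(tree.adj[node]) if nb != parent]
            if not kids:
                down[node] = self.leaf_cost[tree.labels[node]]
                return
            for k in kids:
                walk(k, node)
            down[node] = sum(_dt(down[k]) for k in kids)

        walk(root, None)
        return down

    def char_lengths(self, tree: UnrootedTree, root: int | None = None) -> np.ndarray:
        """Per-character minimum steps on the tree (root choice immaterial)."""
        self._check_taxa(tree)
        if len(tree.adj) == 2:
            a, b = tree.leaf_ids
            comb = _dt(self.leaf_cost[tree.labels[a]]) + self.leaf_cost[tree.labels[b]]
            return comb.min(axis=1)
        if root is None:
            root = next(n for n in sorted(tree.adj) if len(tree.adj[n]) > 1)
        down = self._down(tree, root)
        if len(tree.adj[root]) == 1:  # rooted at a leaf: fold its own cost in
            vec = _dt(down[tree.adj[root][0]]) + self.leaf_cost[tree.labels[root]]
            return vec.min(axis=1)
        return down[root].min(axis=1)

    def length(self, tree: UnrootedTree, root: int | None = None) -> int:
        return int(self.char_lengths(tree, root).sum())

    def attachment_scores(
        self, tree: UnrootedTree, attach_cost: np.ndarray
    ) -> list[tuple[tuple[int, int], int]]:
        """Total length after attaching a pendant with cost vector
        ``attach_cost`` ((n_chars, S), already the subtree-root vector) on
        each edge, in canonical edge order."""
        self._check_taxa(tree)
        g = _dt(attach_cost)
        if len(tree.adj) == 2:
            a, b = tree.leaf_ids
            comb = (
                _dt(self.leaf_cost[tree.labels[a]])
                + _dt(self.leaf_cost[tree.labels[b]])
                + g
            )
            return [((a, b), int(comb.min(axis=1).sum()))]
        root = next(n for n in sorted(tree.adj) if len(tree.adj[n]) > 1)
        down = self._down(tree, root)
        ddown = {v: _dt(d) for v, d in down.items()}
        out_above: dict[int, np.ndarray] = {root: np.zeros((self.n_chars, self.S))}
        out_edge: dict[tuple[int, int], np.ndarray] = {}

        def walk(node: int, parent: int | None):
            kids = [nb for nb in sorted(tree.adj[node]) if nb != parent]
            for v in kids:
                out = out_above[node].copy()
                for c in kids:
                    if c != v:
                        out += ddown[c]
                out_edge[(node, v)] = out
                out_above[v] = _dt(out)
                walk(v, node)

        walk(root, None)
        # enumerate edges in the same (root-oriented) parent->child direction
        edges: list[tuple[int, int]] = []

        def collect(node: int, parent: int | None):
            for nb in sorted(tree.adj[node]):
                if nb != parent:
                    edges.append((node, nb))
                    collect(nb, node)

        collect(root, None)
        scores = []
        for (p, v) in edges:
            vec = ddown[v] + g + _dt(out_edge[(p, v)])
            scores.append(((p, v), int(vec.min(axis=1).sum())))
        return scores

    def leaf_attachment_scores(self, tree: UnrootedTree, label: str):
        return self.attachment_scores(tree, self.leaf_cost[label])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ordered_char_length(tree: UnrootedTree, states: dict[str, int | str]) -> int:
    """Minimum Wagner steps of a single character on a tree.

    ``states`` maps each leaf label to an integer state or "any"/"?" for
    missing.
    """
    labels = tree.leaf_labels
    for lab in labels:
        if lab not in states:
            raise ParsimonyError(f"leaf {lab!r} has no state entry")
    numeric = [s for s in states.values() if not isinstance(s, str)]
    S = max(24, (max(numeric) + 1) if numeric else 1)
    from .census import DomainFamily, SupergroupLabel
    from .coding import CharacterMatrix

    col = np.array(
        [
            [MISSING if isinstance(states[lab], str) else int(states[lab])]
            for lab in labels
        ]
    )
    cm = CharacterMatrix(
        taxa=[DomainFamily(lab) for lab in labels],
        characters=[("c1", SupergroupLabel("A"))],
        states=col,
        n_states=S,
    )
    return ParsimonyScorer(cm).length(tree)


def tree_length(tree: UnrootedTree, cm: CharacterMatrix) -> int:
    """Total Sankoff length over all characters; invariant to rooting."""
    tl, ml = set(tree.leaf_labels), {t.id for t in cm.taxa}
    if tl != ml:
        raise ParsimonyError(
            f"taxon mismatch; tree-only={sorted(tl - ml)}, matrix-only={sorted(ml - tl)}"
        )
    return ParsimonyScorer(cm).length(tree)


def char_min_steps(states) -> int:
    """Lower bound on steps: the state range."""
    xs = _numeric_states(states)
    return int(max(xs) - min(xs))


def char_max_steps(states, n_states: int = 24) -> int:
    """Steps on the fully unresolved bush: min_z sum |x_i - z|."""
    xs = _numeric_states(states)
    lo, hi = min(min(xs), 0), max(max(xs) + 1, n_states)
    return int(min(sum(abs(x - z) for x in xs) for z in range(lo, hi)))


def _numeric_states(states) -> list[int]:
    vals = states.values() if isinstance(states, dict) else states
    xs = [int(s) for s in vals if not (isinstance(s, str) or s == MISSING)]
    if not xs:
        raise ParsimonyError("character has no non-missing states")
    return xs


def retention_index(tree: UnrootedTree, cm: CharacterMatrix) -> float:
    """RI = (G - S) / (G - M) summed over characters, clamped to [0, 1]."""
    scorer = ParsimonyScorer(cm)
    obs = scorer.char_lengths(tree)
    G = S_ = M = 0.0
    for j in range(len(cm.characters)):
        col = cm.states[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        g = char_max_steps(col, cm.n_states)
        m = char_min_steps(col)
        G += g
        M += m
        S_ += obs[j]
    if G == M:
        raise ParsimonyError("no retention signal (G == M for every character)")
    return float(min(1.0, max(0.0, (G - S_) / (G - M))))


def stepwise_addition(
    cm: CharacterMatrix, seed: int | None = None, addition_order: str = "as-is"
) -> UnrootedTree:
    """Greedy stepwise-addition tree; ties broken by lowest canonical edge index."""
    labels = cm.taxon_ids
    if len(labels) < 3:
        raise ParsimonyError("stepwise addition needs >= 3 taxa")
    if addition_order == "random":
        rng = np.random.default_rng(seed)
        labels = [labels[i] for i in rng.permutation(len(labels))]
    elif addition_order == "by-weight":
        # highest total state first: starts the tree at the taxa closest to
        # the maximum-state pole of the gradient
        mass = {
            t.id: int(np.where(cm.states[i] == MISSING, 0, cm.states[i]).sum())
            for i, t in enumerate(cm.taxa)
        }
        labels = sorted(labels, key=lambda l: (-mass[l], l))
    elif addition_order != "as-is":
        raise ParsimonyError(f"unknown addition_order {addition_order!r}")
    scorer = ParsimonyScorer(cm)
    tree = UnrootedTree.from_triplet(*labels[:3])
    for lab in labels[3:]:
        scores = scorer.leaf_attachment_scores(tree, lab)
        best_edge = min(scores, key=lambda es: es[1])[0]
        tree.insert_leaf(best_edge, lab)
    return tree


def _nni_candidates(tree: UnrootedTree):
    """Yield NNI rearrangements (copies) in deterministic order."""
    for (u, v) in tree.edges():
        if len(tree.adj[u]) != 3 or len(tree.adj[v]) != 3:
            continue
        b = [x for x in sorted(tree.adj[u]) if x != v][1]
        for c in [x for x in sorted(tree.adj[v]) if x != u]:
            t2 = tree.copy()
            t2._unlink(u, b)
            t2._unlink(v, c)
            t2._link(u, c)
            t2._link(v, b)
            yield t2


def _spr_candidates(tree: UnrootedTree, scorer: ParsimonyScorer):
    """Yield (length, tree) for all SPR rearrangements, deterministic order."""
    undirected = tree.edges()
    directed = [(p, v) for (p, v) in undirected] + [(v, p) for (p, v) in undirected]
    for (p, v) in directed:
        pruned = tree.copy()
        sub_leaves = pruned.split_of_edge(p, v)
        if len(pruned.leaf_labels) - len(sub_leaves) < 2:
            continue
        pruned.detach_subtree(p, v)
        # the detached subtree (rooted at v) and the remaining tree now form
        # two components of the same structure
        sub_nodes = _component(pruned, v)
        rem = UnrootedTree()
        rem.adj = {n: list(nb) for n, nb in pruned.adj.items() if n not in sub_nodes}
        rem.labels = {n: l for n, l in pruned.labels.items() if n not in sub_nodes}
        rem._next = pruned._next
        if len(rem.adj) < 2:
            continue
        sub_cost = _subtree_cost(pruned, v, sub_nodes, scorer)
        for edge, score in scorer.attachment_scores(rem, sub_cost):
            t2 = pruned.copy()
            t2.attach_node(edge, v)
            yield score, t2


def _component(tree: UnrootedTree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        n = stack.pop()
        for nb in tree.adj[n]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _subtree_cost(
    tree: UnrootedTree, root: int, nodes: set[int], scorer: ParsimonyScorer
) -> np.ndarray:
    def walk(node: int, parent: int | None) -> np.ndarray:
        kids = [nb for nb in sorted(tree.adj[node]) if nb != parent and nb in nodes]
        if not kids:
            return scorer.leaf_cost[tree.labels[node]]
        return sum(_dt(walk(k, node)) for k in kids)

    return walk(root, None)


def branch_swap_search(
    start: UnrootedTree,
    cm: CharacterMatrix,
    moves: str = "NNI",
    max_rounds: int | None = None,
) -> UnrootedTree:
    """First-improvement hill climbing over NNI or SPR neighborhoods.

    Runs until a full sweep yields no improvement (a local optimum) unless
    ``max_rounds`` caps the number of accepted rearrangements.
    """
    if not start.is_binary():
        raise ParsimonyError("branch swapping requires a binary start tree")
    scorer = ParsimonyScorer(cm)
    best = start.copy()
    best_len = scorer.length(best)
    rounds = 0
    while max_rounds is None or rounds < max_rounds:
        rounds += 1
        improved = False
        if moves == "NNI":
            for cand in _nni_candidates(best):
                L = scorer.length(cand)
                if L < best_len:
                    best, best_len, improved = cand, L, True
                    break
        elif moves == "SPR":
            for L, cand in _spr_candidates(best, scorer):
                if L < best_len:
                    best, best_len, improved = cand, L, True
                    break
        else:
            raise ParsimonyError(f"unknown move set {moves!r}")
        if not improved:
            break
    return best


@dataclass
class SearchResult:
    best_trees: list[UnrootedTree]
    length: int
    retention_index: float
    g1: float
    replicates: int
    seed: int | None


def mp_search(
    cm: CharacterMatrix,
    n_replicates: int = 10,
    seed: int | None = 0,
    moves: str = "NNI",
    n_random_trees_g1: int = 100,
) -> SearchResult:
    """Random-addition + branch-swapping search; returns all tying topologies."""
    rng = np.random.default_rng(seed)
    scorer = ParsimonyScorer(cm)
    best_len: int | None = None
    best: dict[frozenset, UnrootedTree] = {}
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        order = "by-weight" if rep == 0 else "random"
        t = stepwise_addition(cm, seed=rep_seed, addition_order=order)
        t = branch_swap_search(t, cm, moves=moves)
        L = scorer.length(t)
        if best_len is None or L < best_len:
            best_len, best = L, {t.topology_key(): t}
        elif L == best_len:
            best.setdefault(t.topology_key(), t)
    trees = list(best.values())
    try:
        ri = retention_index(trees[0], cm)
    except ParsimonyError:
        ri = float("nan")
    try:
        g1 = g1_statistic(cm, n_random_trees_g1, seed=int(rng.integers(2**31 - 1)))
    except ParsimonyError:
        g1 = float("nan")
    return SearchResult(
        best_trees=trees,
        length=int(best_len),
        retention_index=ri,
        g1=g1,
        replicates=n_replicates,
        seed=seed,
    )


def exhaustive_search(cm: CharacterMatrix) -> tuple[list[UnrootedTree], int]:
    """Enumerate every topology (small n only); independent oracle for mp_search."""
    scorer = ParsimonyScorer(cm)
    best_len: int | None = None
    best: dict[frozenset, UnrootedTree] = {}
    for t in enumerate_topologies(cm.taxon_ids):
        L = scorer.length(t)
        if best_len is None or L < best_len:
            best_len, best = L, {t.topology_key(): t}
        elif L == best_len:
            best.setdefault(t.topology_key(), t)
    return list(best.values()), int(best_len)


def sample_lengths(cm: CharacterMatrix, n_random_trees: int, seed=None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    scorer = ParsimonyScorer(cm)
    labels = cm.taxon_ids
    return np.array(
        [scorer.length(random_topology(labels, rng)) for _ in range(n_random_trees)],
        dtype=float,
    )


def skewness_g1(lengths) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) with population moments."""
    x = np.asarray(lengths, dtype=float)
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ParsimonyError("degenerate length distribution (zero variance)")
    m3 = np.mean((x - x.mean()) ** 3)
    return float(m3 / m2**1.5)


def g1_statistic(cm: CharacterMatrix, n_random_trees: int = 100, seed=None) -> float:
    """Skewness of tree lengths over random topologies (signal diagnostic)."""
    if n_random_trees < 3:
        raise ParsimonyError("need >= 3 random trees")
    return skewness_g1(sample_lengths(cm, n_random_trees, seed))


@dataclass
class BipartitionSupport:
    bipartition: frozenset[str]
    support: float
    n_replicates: int


def _resample_characters(cm: CharacterMatrix, rng) -> CharacterMatrix:
    n = len(cm.characters)
    idx = rng.integers(0, n, size=n)
    return CharacterMatrix(
        taxa=list(cm.taxa),
        characters=[cm.characters[j] for j in idx],
        states=cm.states[:, idx].copy(),
        n_states=cm.n_states,
    )


def bootstrap_support(
    cm: CharacterMatrix,
    n_replicates: int = 2000,
    seed: int | None = 0,
    search_replicates: int = 1,
    moves: str = "NNI",
) -> list[BipartitionSupport]:
    """Character-resampling bootstrap; a bipartition counts in a replicate when
    present in a strict majority of that replicate's tying best trees."""
    rng = np.random.default_rng(seed)
    tally: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        bcm = _resample_characters(cm, rng)
        res = mp_search(
            bcm,
            n_replicates=search_replicates,
            seed=int(rng.integers(2**31 - 1)),
            moves=moves,
            n_random_trees_g1=3,
        )
        counts: dict[frozenset, int] = {}
        for t in res.best_trees:
            for s in t.splits():
                counts[s] = counts.get(s, 0) + 1
        half = len(res.best_trees) / 2
        for s, c in counts.items():
            if c > half or len(res.best_trees) == 1:
                tally[s] = tally.get(s, 0) + 1
    out = [
        BipartitionSupport(bip, cnt / n_replicates, n_replicates)
        for bip, cnt in tally.items()
    ]
    out.sort(key=lambda b: (-b.support, sorted(b.bipartition)))
    return out
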