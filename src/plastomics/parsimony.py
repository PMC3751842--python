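"""Maximum parsimony: Fitch counting, tree search, bootstrap, homoplasy indices.

Trees are unrooted; internally they are held as nested pairs rooted on the
edge leading to taxon 0 (Fitch length is invariant to the rooting).  Gaps and
N are missing data (they match anything and add no steps).

Searches:

* ``exhaustive`` -- enumerate all (2n-5)!! topologies (n <= 9);
* ``branch_and_bound`` -- stepwise insertion with the partial-tree length as
  the pruning bound; provably returns every minimum-length tree;
* ``tbr_heuristic`` -- random-addition starts followed by
  tree-bisection-reconnection swapping, retaining all equally best trees.

The homoplasy indices use, per variable column i, m_i = states-1,
s_i = Fitch steps on the best tree, g_i = (taxa with a state) - (count of
the most frequent state); CI = sum(m)/sum(s), RI = (sum(g)-sum(s)) /
(sum(g)-sum(m)), RC = CI*RI; columns containing gaps are excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Union

import dendropy
import numpy as np

from .align import GAP
from .divergence import WholeGenomeAlignment

TreeT = Union[int, tuple]  # nested pairs of taxon indices

PARTITION_NAMES = ("complete", "coding_exons", "LSC", "SSC", "IR", "introns_spacers")


@dataclass
class CharacterMatrix:
    taxa: list[str]
    rows: np.ndarray  # n_taxa x columns, codes {0..3, 4=N, 5=gap}
    partition_name: str = "complete"
    outgroups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows.shape[0] != len(self.taxa):
            raise ValueError("row count != taxon count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.rows.shape[1]


@dataclass
class ParsimonyResult:
    best_trees: list[TreeT]
    length: int
    taxa: list[str]
    method: str
    CI: float | None = None
    RI: float | None = None
    RC: float | None = None
    n_parsimony_informative: int = 0
    supports: dict[frozenset[int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fitch machinery


def _masks(rows: np.ndarray) -> np.ndarray:
    out = np.where(rows < 4, np.left_shift(1, rows.astype(np.int64)), 15)
    return out.astype(np.uint8)


def _fitch_sets(tree: TreeT, masks: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, int]:
    """Bottom-up Fitch pass; returns (root state sets, weighted steps)."""
    steps = 0

    def rec(t: TreeT) -> np.ndarray:
        nonlocal steps
        if isinstance(t, int):
            return masks[t]
        l = rec(t[0])
        r = rec(t[1])
        inter = l & r
        empty = inter == 0
        if empty.any():
            steps += int(weights[empty].sum())
        return np.where(empty, l | r, inter)

    root = rec(tree)
    return root, steps


def fitch_length(tree: TreeT, matrix: CharacterMatrix) -> int:
    """Total Fitch parsimony steps of ``tree`` on ``matrix`` (gaps/N missing)."""
    leaves = set(_leaves(tree))
    if leaves != set(range(matrix.n_taxa)):
        raise ValueError("tree leaves do not match matrix taxa")
    masks = _masks(matrix.rows)
    _, steps = _fitch_sets(tree, masks, np.ones(matrix.length, dtype=np.int64))
    return steps


def _leaves(tree: TreeT) -> list[int]:
    if isinstance(tree, int):
        return [tree]
    return _leaves(tree[0]) + _leaves(tree[1])


def _column_steps(tree: TreeT, masks: np.ndarray) -> np.ndarray:
    """Per-column Fitch steps (vectorized over columns)."""
    P = masks.shape[1]
    steps = np.zeros(P, dtype=np.int64)

    def rec(t: TreeT) -> np.ndarray:
        nonlocal steps
        if isinstance(t, int):
            return masks[t]
        l, r = rec(t[0]), rec(t[1])
        inter = l & r
        empty = inter == 0
        steps[empty] += 1
        return np.where(empty, l | r, inter)

    rec(tree)
    return steps


def _compress(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Unique informative patterns + weights, and the tree-independent step
    count contributed by non-informative columns."""
    rows = matrix.rows
    counts = np.stack([(rows == b).sum(axis=0) for b in range(4)])
    n_states = (counts > 0).sum(axis=0)
    informative = (counts >= 2).sum(axis=0) >= 2
    constant_steps = int((n_states[~informative] - 1).clip(min=0).sum())
    pat = rows[:, informative]
    if pat.shape[1] == 0:
        return np.zeros((rows.shape[0], 0), dtype=np.uint8), np.zeros(0, dtype=np.int64), constant_steps
    uniq, inv, cnt = np.unique(pat, axis=1, return_inverse=True, return_counts=True)
    return _masks(uniq), cnt.astype(np.int64), constant_steps


def n_parsimony_informative(matrix: CharacterMatrix) -> int:
    rows = matrix.rows
    counts = np.stack([(rows == b).sum(axis=0) for b in range(4)])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


# ---------------------------------------------------------------------------
# Topology generation and rearrangement


def _insert_everywhere(tree: TreeT, new: int) -> Iterable[TreeT]:
    """All trees from inserting ``new`` on every edge (incl. the root edge)."""
    yield (tree, new)
    if not isinstance(tree, int):
        for sub in _insert_everywhere(tree[0], new):
            yield (sub, tree[1])
        for sub in _insert_everywhere(tree[1], new):
            yield (tree[0], sub)


def enumerate_topologies(n: int) -> Iterable[TreeT]:
    """All unrooted binary topologies over taxa 0..n-1, rooted at taxon 0's
    edge (full tree = (0, T))."""
    if n < 3:
        raise ValueError("need >= 3 taxa")

    def rec(k: int) -> Iterable[TreeT]:
        if k == 3:
            yield (1, 2)
            return
        for t in rec(k - 1):
            yield from _insert_everywhere(t, k - 1)

    for t in rec(n):
        yield (0, t)


def bipartitions(tree: TreeT, n: int) -> frozenset[frozenset[int]]:
    """Non-trivial bipartitions, each written as the side without taxon 0."""
    out: set[frozenset[int]] = set()

    def rec(t: TreeT) -> set[int]:
        if isinstance(t, int):
            return {t}
        s = rec(t[0]) | rec(t[1])
        if 1 < len(s) < n - 1 and 0 not in s:
            out.add(frozenset(s))
        elif 1 < len(n_minus := set(range(n)) - s) < n - 1 and 0 in s:
            out.add(frozenset(n_minus))
        return s

    rec(tree)
    return frozenset(out)


def topology_key(tree: TreeT, n: int) -> frozenset[frozenset[int]]:
    return bipartitions(tree, n)


def _subtrees_with_rebuild(tree: TreeT):
    """Yield (subtree, rebuild) pairs where rebuild(replacement) returns the
    full tree with the subtree replaced (replacement=None removes it)."""

    def rec(t: TreeT, build):
        yield t, build
        if isinstance(t, int):
            return
        a, b = t

        def build_a(x, _a=a, _b=b, _build=build):
            if x is None:
                return _build(_b)
            return _build((x, _b))

        def build_b(x, _a=a, _b=b, _build=build):
            if x is None:
                return _build(_a)
            return _build((_a, x))

        yield from rec(a, build_a)
        yield from rec(b, build_b)

    yield from rec(tree, lambda x: x)


def _reroot_all(tree: TreeT) -> list[TreeT]:
    """All rootings of an unrooted subtree along its edges (as nested pairs)."""
    if isinstance(tree, int) or (isinstance(tree[0], int) and isinstance(tree[1], int)):
        return [tree]
    out = {}

    def edges(t: TreeT, build):
        # reroot on the edge above t: new tree = (t, rest-rerooted)
        yield t, build
        if not isinstance(t, int):
            a, b = t
            yield from edges(a, lambda x, _b=b, _build=build: _build((x, _b)) if x is not None else _build(_b))
            yield from edges(b, lambda x, _a=a, _build=build: _build((_a, x)) if x is not None else _build(_a))

    n = len(_leaves(tree))
    for sub, build in _subtrees_with_rebuild(tree):
        if sub is tree:
            out[_canon(tree)] = tree
            continue
        rest = build(None)
        cand = (sub, rest)
        out[_canon(cand)] = cand
    return list(out.values())


def _canon(tree: TreeT):
    if isinstance(tree, int):
        return tree
    a, b = _canon(tree[0]), _canon(tree[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def tbr_neighbors(tree: TreeT) -> Iterable[TreeT]:
    """Tree-bisection-reconnection neighborhood of a full tree (0, T).

    Every edge is bisected; the detached part is rerooted in all ways and
    reattached on every edge of the remainder.
    """
    zero, T = tree
    seen: set = set()
    for sub, build in _subtrees_with_rebuild(T):
        if sub is T:
            continue
        rest = build(None)
        for rooted_sub in _reroot_all(sub):
            for attached in _insert_tree_everywhere(rest, rooted_sub):
                key = topology_key((0, attached), len(_leaves(tree)))
                if key not in seen:
                    seen.add(key)
                    yield (0, attached)


def _insert_tree_everywhere(tree: TreeT, new: TreeT) -> Iterable[TreeT]:
    yield (tree, new)
    if not isinstance(tree, int):
        for sub in _insert_tree_everywhere(tree[0], new):
            yield (sub, tree[1])
        for sub in _insert_tree_everywhere(tree[1], new):
            yield (tree[0], sub)


# ---------------------------------------------------------------------------
# Searches


class SearchError(ValueError):
    pass


def _score(tree: TreeT, masks: np.ndarray, weights: np.ndarray, const: int) -> int:
    _, s = _fitch_sets(tree, masks, weights)
    return s + const


def search_best_trees(
    matrix: CharacterMatrix,
    method: str = "branch_and_bound",
    n_random_addition: int = 10,
    seed: int = 0,
    keep_ties: bool = True,
) -> ParsimonyResult:
    """Find minimum-length tree(s) under the chosen strategy."""
    n = matrix.n_taxa
    if n < 4:
        raise SearchError("need >= 4 taxa")
    masks, weights, const = _compress(matrix)

    if method == "exhaustive":
        if n > 9:
            raise SearchError("exhaustive search limited to 9 taxa")
        best: list[TreeT] = []
        best_len = None
        for t in enumerate_topologies(n):
            s = _score(t, masks, weights, const)
            if best_len is None or s < best_len:
                best, best_len = [t], s
            elif s == best_len and keep_ties:
                best.append(t)
        trees, length = best, int(best_len)
    elif method == "branch_and_bound":
        trees, length = _branch_and_bound(n, masks, weights, const, keep_ties)
    elif method == "tbr_heuristic":
        trees, length = _tbr_search(
            n, masks, weights, const, n_random_addition, seed, keep_ties
        )
    else:
        raise SearchError(f"unknown method {method!r}")

    # deduplicate by unrooted topology
    uniq: dict = {}
    for t in trees:
        uniq.setdefault(topology_key(t, n), t)
    return ParsimonyResult(
        best_trees=list(uniq.values()),
        length=length,
        taxa=matrix.taxa,
        method=method,
        n_parsimony_informative=n_parsimony_informative(matrix),
    )


def _branch_and_bound(
    n: int, masks: np.ndarray, weights: np.ndarray, const: int, keep_ties: bool
) -> tuple[list[TreeT], int]:
    best_len: list[int | None] = [None]
    best: list[TreeT] = []

    def recurse(partial: TreeT, k: int) -> None:
        s = _score((0, partial), masks, weights, 0)
        if best_len[0] is not None and s > best_len[0]:
            return
        if k == n:
            total = s
            if best_len[0] is None or total < best_len[0]:
                best_len[0] = total
                best.clear()
                best.append((0, partial))
            elif total == best_len[0] and keep_ties:
                best.append((0, partial))
            return
        for t in _insert_everywhere(partial, k):
            recurse(t, k + 1)

    recurse((1, 2), 3)
    return best, int(best_len[0]) + const


def _stepwise_addition(
    order: list[int], masks: np.ndarray, weights: np.ndarray
) -> TreeT:
    """Greedy insertion following ``order`` (first three form the start)."""
    current: TreeT = (order[0], (order[1], order[2]))
    for k in order[3:]:
        cands = []
        zero, T = _as_zero_rooted(current)
        for t in _insert_everywhere(T, k):
            cand = (zero, t)
            cands.append((_score(cand, masks, weights, 0), cand))
        cands.sort(key=lambda x: x[0])
        current = cands[0][1]
    return _as_zero_rooted(current)


def _as_zero_rooted(tree: TreeT) -> tuple[int, TreeT]:
    """Normalize a full tree so it reads (0, rest)."""
    if isinstance(tree, tuple) and tree[0] == 0:
        return tree
    # reroot: find taxon 0 and pull it to the top
    n = len(_leaves(tree))
    for sub, build in _subtrees_with_rebuild(tree if isinstance(tree, tuple) else (tree,)):
        if sub == 0:
            rest = build(None)
            return (0, rest)
    raise ValueError("taxon 0 missing")


def _tbr_search(
    n: int,
    masks: np.ndarray,
    weights: np.ndarray,
    const: int,
    n_random_addition: int,
    seed: int,
    keep_ties: bool,
) -> tuple[list[TreeT], int]:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4057]))
    best_len: int | None = None
    best: dict = {}
    for rep in range(max(1, n_random_addition)):
        order = [0] + [int(x) for x in 1 + rng.permutation(n - 1)]
        tree = _stepwise_addition(order, masks, weights)
        score = _score(tree, masks, weights, 0)
        improved = True
        while improved:
            improved = False
            for nb in tbr_neighbors(tree):
                s = _score(nb, masks, weights, 0)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        if best_len is None or score < best_len:
            best_len = score
            best = {topology_key(tree, n): tree}
        elif score == best_len and keep_ties:
            best.setdefault(topology_key(tree, n), tree)
    # collect equally-best TBR neighbors of the winners
    if keep_ties:
        for t in list(best.values()):
            for nb in tbr_neighbors(t):
                if _score(nb, masks, weights, 0) == best_len:
                    best.setdefault(topology_key(nb, n), nb)
    return list(best.values()), int(best_len) + const


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    matrix: CharacterMatrix,
    n_replicates: int = 1000,
    method: str = "tbr_heuristic",
    seed: int = 0,
    n_random_addition: int = 1,
) -> ParsimonyResult:
    """Nonparametric bootstrap: resample columns with replacement, re-search,
    report the percentage of replicates containing each clade of the best
    tree from the full matrix."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    result = search_best_trees(matrix, method=method, seed=seed)
    n = matrix.n_taxa
    ref_tree = result.best_trees[0]
    ref_clades = bipartitions(ref_tree, n)

    counts = np.stack([(matrix.rows == b).sum(axis=0) for b in range(4)])
    any_variation = ((counts > 0).sum(axis=0) >= 2).any()
    if not any_variation:
        result.supports = {c: float("nan") for c in ref_clades}
        return result

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
    L = matrix.length
    clade_hits = {c: 0 for c in ref_clades}
    for rep in range(n_replicates):
        idx = rng.integers(0, L, L)
        rep_matrix = CharacterMatrix(
            matrix.taxa, matrix.rows[:, idx], matrix.partition_name, matrix.outgroups
        )
        masks, weights, const = _compress(rep_matrix)
        if masks.shape[1] == 0:
            continue
        trees, _ = _tbr_search(
            n, masks, weights, const, max(1, n_random_addition), seed + rep + 1,
            keep_ties=True,
        )
        # a clade counts when it appears in every equally best tree (strict)
        clades = None
        for t in trees:
            bp = bipartitions(t, n)
            clades = bp if clades is None else (clades & bp)
        for c in ref_clades & (clades or frozenset()):
            clade_hits[c] += 1
    result.supports = {
        c: 100.0 * clade_hits[c] / n_replicates for c in ref_clades
    }
    return result


# ---------------------------------------------------------------------------
# Homoplasy indices


def tree_indices(
    result: ParsimonyResult, matrix: CharacterMatrix
) -> tuple[float, float | None, float | None]:
    """(CI, RI, RC) on the first best tree; indel-containing columns excluded."""
    tree = result.best_trees[0]
    rows = matrix.rows
    no_gap = ~(rows == GAP).any(axis=0)
    counts = np.stack([(rows == b).sum(axis=0) for b in range(4)])
    n_states = (counts > 0).sum(axis=0)
    use = no_gap & (n_states >= 2)
    if not use.any():
        return float("nan"), None, None
    sub = rows[:, use]
    masks = _masks(sub)
    s = _column_steps(tree, masks)
    m = (n_states[use] - 1).astype(np.int64)
    with_state = (sub < 4).sum(axis=0)
    g = (with_state - counts[:, use].max(axis=0)).astype(np.int64)
    CI = float(m.sum() / s.sum()) if s.sum() else float("nan")
    denom = g.sum() - m.sum()
    if denom == 0:
        RI = None
        RC = None
    else:
        RI = float((g.sum() - s.sum()) / denom)
        RC = CI * RI
    result.CI, result.RI, result.RC = CI, RI, RC
    return CI, RI, RC


# ---------------------------------------------------------------------------
# Partitions


def build_partitions(
    wga: WholeGenomeAlignment,
    outgroups: list[str] | None = None,
    ambiguous_window: int = 5,
) -> dict[str, CharacterMatrix]:
    """The six analysis datasets from a whole-genome alignment.

    Columns within ``ambiguous_window`` of a gap opening in any row are
    treated as ambiguously aligned and excluded from every partition.
    """
    func, struct = wga.col_classes()
    rows = wga.rows
    gap = rows == GAP
    opening = np.zeros(wga.length, dtype=bool)
    opening[0] = gap[:, 0].any()
    if wga.length > 1:
        opening[1:] = (gap[:, 1:] & ~gap[:, :-1]).any(axis=0)
    excluded = np.zeros(wga.length, dtype=bool)
    for c in np.nonzero(opening)[0]:
        excluded[max(0, c - ambiguous_window) : c + ambiguous_window + 1] = True
    keep = ~excluded

    masks = {
        "complete": keep,
        "coding_exons": keep & (func == "coding"),
        "LSC": keep & (struct == "LSC"),
        "SSC": keep & (struct == "SSC"),
        "IR": keep & (struct == "IR"),
        "introns_spacers": keep & (func == "intron_spacer"),
    }
    out = {}
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"partition {name} is empty")
        out[name] = CharacterMatrix(
            taxa=list(wga.taxa),
            rows=rows[:, m],
            partition_name=name,
            outgroups=list(outgroups or []),
        )
    return out


# ---------------------------------------------------------------------------
# Export


def to_dendropy(
    tree: TreeT, taxa: list[str], supports: dict[frozenset[int], float] | None = None
) -> dendropy.Tree:
    """Convert a nested-pair tree to a dendropy tree with support labels."""
    ns = dendropy.TaxonNamespace(taxa)
    t = dendropy.Tree(taxon_namespace=ns)

    def build(sub: TreeT, parent: dendropy.Node) -> None:
        node = dendropy.Node()
        parent.add_child(node)
        if isinstance(sub, int):
            node.taxon = ns.get_taxon(taxa[sub])
        else:
            build(sub[0], node)
            build(sub[1], node)
            if supports:
                leafset = frozenset(_leaves(sub))
                if leafset in supports:
                    node.label = str(int(round(supports[leafset])))

    root = t.seed_node
    build(tree[0], root)
    build(tree[1], root)
    t.is_rooted = False
    return t
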