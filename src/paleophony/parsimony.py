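"""Parsimony scoring, character mapping and convergence counting.

Tree length is computed by generalized (Sankoff) dynamic programming with a
per-character cost matrix: unit costs off the diagonal for unordered
characters (Fitch counting) and ``|i − j|`` state-distance costs for ordered
(additive/Farris) characters.  The DP handles polytomies (soft-polytomy
semantics: a multifurcating node is scored as-is), polymorphic leaves (zero
cost for every admissible state) and missing data (zero cost everywhere, so
a missing cell never adds steps).

Ensemble indices follow the TNT conventions: for each character, ``m`` is
the minimum conceivable number of steps on *any* tree and ``g`` the number
of steps on a completely unresolved bush; summed over active characters
(weighted), they give CI = M/S and RI = (G − S)/(G − M).  All variable
characters are included by default, parsimony-uninformative ones too; an
``informative_only`` flag excludes them.

Trees are dendropy ``Tree`` objects throughout (rooted or with a
basal trifurcation standing in for an unrooted tree).
"""
from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .characters import CharacterMatrix
from .errors import ConfigError, TreeMatrixMismatchError

INF = math.inf


# ---------------------------------------------------------------------------
# Tree I/O helpers

def read_trees(path: str | Path, schema: str = "newick") -> list[dendropy.Tree]:
    """Read one or more trees (Newick by default; quoted labels and
    polytomies supported)."""
    tl = dendropy.TreeList.get(path=str(path), schema=schema,
                               preserve_underscores=True)
    return list(tl)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _check_labels(tree: dendropy.Tree, matrix: CharacterMatrix) -> dict[str, int]:
    labels = _leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeMatrixMismatchError("duplicate leaf labels in tree")
    index = {t: i for i, t in enumerate(matrix.taxa)}
    missing = [l for l in labels if l not in index]
    if missing:
        raise TreeMatrixMismatchError(
            f"tree leaves not in matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return index


# ---------------------------------------------------------------------------
# Core DP

def _cost_matrix(n_states: int, ordered: bool,
                 values: Sequence[int] | None = None) -> np.ndarray:
    if ordered:
        v = np.asarray(values if values is not None else range(n_states),
                       dtype=float)
        return np.abs(v[:, None] - v[None, :])
    return 1.0 - np.eye(n_states)


def _char_setup(matrix: CharacterMatrix, j: int):
    """(alphabet, per-taxon leaf cost rows, cost matrix) for character j."""
    alpha = matrix.alphabet(j)
    if len(alpha) < 2:
        return alpha, None, None
    pos = {s: i for i, s in enumerate(alpha)}
    values = [int(s) if s.isdigit() else i for i, s in enumerate(alpha)]
    cost = _cost_matrix(len(alpha), matrix.ordered[j], values)
    leaf_costs = np.full((matrix.n_taxa, len(alpha)), INF)
    for t, cell in enumerate(matrix.state_sets(j)):
        for s in cell:
            leaf_costs[t, pos[s]] = 0.0
    return alpha, leaf_costs, cost


def _down_pass(tree: dendropy.Tree, leaf_costs: np.ndarray,
               cost: np.ndarray, taxon_index: dict[str, int]
               ) -> dict[dendropy.Node, np.ndarray]:
    """Subtree cost vectors D[v][s] in postorder."""
    D: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            D[node] = leaf_costs[taxon_index[node.taxon.label]]
        else:
            total = np.zeros(cost.shape[0])
            for child in node.child_nodes():
                # min over child state t of D[c][t] + cost[s, t]
                total = total + np.min(D[child][None, :] + cost, axis=1)
            D[node] = total
    return D


def _char_length(tree: dendropy.Tree, matrix: CharacterMatrix, j: int,
                 taxon_index: dict[str, int]) -> float:
    alpha, leaf_costs, cost = _char_setup(matrix, j)
    if leaf_costs is None:
        return 0.0
    D = _down_pass(tree, leaf_costs, cost, taxon_index)
    return float(np.min(D[tree.seed_node]))


def tree_length(tree: dendropy.Tree, matrix: CharacterMatrix) -> int | float:
    """Weighted parsimony length of ``tree`` on ``matrix`` (active
    characters only)."""
    taxon_index = _check_labels(tree, matrix)
    S = 0.0
    for j in range(matrix.n_char):
        if not matrix.active[j]:
            continue
        S += matrix.weights[j] * _char_length(tree, matrix, j, taxon_index)
    return int(S) if float(S).is_integer() else S


# ---------------------------------------------------------------------------
# Ensemble indices

def _char_min_steps(matrix: CharacterMatrix, j: int) -> int:
    """Minimum conceivable steps for character j on any tree.

    Unordered: size of the smallest state subset hitting every cell, minus 1
    (so free polymorphic choices are exploited).  Ordered: the unavoidable
    span ``max(0, max_cell(min) − min_cell(max))``.
    """
    alpha = matrix.alphabet(j)
    if len(alpha) < 2:
        return 0
    cells = [c for c in matrix.state_sets(j)]
    if matrix.ordered[j]:
        val = {s: (int(s) if s.isdigit() else i) for i, s in enumerate(alpha)}
        lo = max(min(val[s] for s in c) for c in cells)
        hi = min(max(val[s] for s in c) for c in cells)
        return max(0, lo - hi)
    # smallest hitting set over a tiny alphabet: brute force by subset size
    universe = list(alpha)
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            cs = frozenset(combo)
            if all(c & cs for c in cells):
                return size - 1
    return len(universe) - 1  # unreachable

def _star_tree(taxa: Sequence[str]) -> dendropy.Tree:
    newick = "(" + ",".join(taxa) + ");"
    return tree_from_newick(newick)


def _char_max_steps(matrix: CharacterMatrix, j: int,
                    taxa: Sequence[str]) -> float:
    """Steps on the completely unresolved bush (the conceivable maximum)."""
    star = _star_tree(taxa)
    index = {t: i for i, t in enumerate(matrix.taxa)}
    return _char_length(star, matrix, j, index)


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length with ensemble consistency and retention indices.

    ``ci = M/S``; ``ri = (G − S)/(G − M)``, reported as ``None`` when
    ``G == M`` (no variable signal to retain).
    """

    S: float
    M: float
    G: float

    def __post_init__(self) -> None:
        if not self.M <= self.S <= self.G:
            raise ConfigError(
                f"parsimony bound violated: M={self.M} S={self.S} G={self.G}"
            )

    @property
    def ci(self) -> float | None:
        return None if self.S == 0 else self.M / self.S

    @property
    def ri(self) -> float | None:
        return None if self.G == self.M else (self.G - self.S) / (self.G - self.M)


def indices(matrix: CharacterMatrix, S: float | None = None,
            tree: dendropy.Tree | None = None,
            informative_only: bool = False) -> ParsimonyScore:
    """Ensemble M, G and the derived CI/RI for ``matrix``.

    Supply either a precomputed length ``S`` or the ``tree`` to score.
    With ``informative_only`` the sums skip parsimony-uninformative
    characters (S is then recomputed on the reduced matrix, so the tree is
    required).
    """
    if informative_only:
        keep = [j for j in range(matrix.n_char) if matrix.is_informative(j)]
        matrix = matrix.subset(keep)
        if tree is None:
            raise ConfigError("informative_only requires the tree")
        S = None
    if S is None:
        if tree is None:
            raise ConfigError("provide S or a tree to score")
        S = tree_length(tree, matrix)
    taxa = matrix.taxa
    M = G = 0.0
    for j in range(matrix.n_char):
        if not matrix.active[j]:
            continue
        M += matrix.weights[j] * _char_min_steps(matrix, j)
        G += matrix.weights[j] * _char_max_steps(matrix, j, taxa)
    return ParsimonyScore(S=float(S), M=float(M), G=float(G))


def score_report(trees: Iterable[dendropy.Tree], matrix: CharacterMatrix,
                 informative_only: bool = False) -> pd.DataFrame:
    """Score table ``tree_id,S,M,G,CI,RI`` (CI/RI rounded half-up to three
    decimals, matching how such indices are conventionally printed)."""
    rows = []
    for i, tree in enumerate(trees):
        S = tree_length(tree, matrix)
        sc = indices(matrix, S=S, tree=tree, informative_only=informative_only)
        rows.append([
            i, sc.S, sc.M, sc.G,
            None if sc.ci is None else _round3(sc.ci),
            None if sc.ri is None else _round3(sc.ri),
        ])
    return pd.DataFrame(rows, columns=["tree_id", "S", "M", "G", "CI", "RI"])


def _round3(x: float) -> float:
    """Round half-up to 3 decimals (report-time convention)."""
    return math.floor(x * 1000 + 0.5) / 1000


# ---------------------------------------------------------------------------
# Character mapping (ancestral state sets)

def map_character(tree: dendropy.Tree, matrix: CharacterMatrix,
                  j: int) -> dict[dendropy.Node, frozenset]:
    """Most-parsimonious ancestral state sets for character ``j``.

    Returns, for every node, the set of states that occur at that node in at
    least one most-parsimonious reconstruction (the MPR set).  For unordered
    characters on a binary tree this coincides with the classical
    downpass/uppass set assignment.  Leaf sets equal the observed cells
    (full alphabet for missing data).
    """
    taxon_index = _check_labels(tree, matrix)
    alpha, leaf_costs, cost = _char_setup(matrix, j)
    if leaf_costs is None:
        only = frozenset(alpha) if alpha else frozenset({"0"})
        return {node: only for node in tree.preorder_node_iter()}
    D = _down_pass(tree, leaf_costs, cost, taxon_index)
    root = tree.seed_node
    best = float(np.min(D[root]))
    # uppass: U[v][s] = optimal cost of the rest of the tree when v has s
    U: dict[dendropy.Node, np.ndarray] = {root: np.zeros(cost.shape[0])}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        # contribution of each child to its parent, per parent state
        contrib = {c: np.min(D[c][None, :] + cost, axis=1) for c in children}
        total = U[node] + sum(contrib.values())
        for c in children:
            parent_side = total - contrib[c]  # cost excluding child c
            U[c] = np.min(parent_side[:, None] + cost, axis=0)
    cells = matrix.state_sets(j)
    result: dict[dendropy.Node, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            result[node] = cells[taxon_index[node.taxon.label]]
            continue
        tot = D[node] + U[node]
        states = frozenset(alpha[i] for i in np.flatnonzero(
            np.isclose(tot, best)))
        result[node] = states
    return result


# ---------------------------------------------------------------------------
# Minimum independent origins

def count_origins(tree: dendropy.Tree, matrix: CharacterMatrix, j: int,
                  derived: str = "1") -> int:
    """Minimum number of independent gains of ``derived`` over all
    most-parsimonious reconstructions of binary character ``j``.

    Gains and losses cost one step each; among all reconstructions with the
    minimal total number of changes, the one with the fewest
    ancestral→derived transitions is found by a lexicographic
    (changes, gains) dynamic program on the rooted tree.  The root is held
    at the ancestral (non-derived) state — the natural convention when the
    tree is rooted on an outgroup that lacks the trait; if no reconstruction
    allows an ancestral root (every leaf fixed derived), the constraint is
    dropped.
    """
    alpha = matrix.alphabet(j)
    if derived not in alpha:
        return 0
    if len(alpha) > 2:
        raise ConfigError(
            f"count_origins needs a binary character, alphabet is {alpha}"
        )
    if len(alpha) == 1:
        return 0
    taxon_index = _check_labels(tree, matrix)
    pos = {s: i for i, s in enumerate(alpha)}
    d_idx = pos[derived]
    cells = matrix.state_sets(j)
    BIG = (INF, INF)
    # DP over (changes, gains) tuples, lexicographic order
    def add(a, b):
        return (a[0] + b[0], a[1] + b[1])

    D: dict[dendropy.Node, list[tuple[float, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cell = cells[taxon_index[node.taxon.label]]
            D[node] = [(0.0, 0.0) if alpha[s] in cell else BIG
                       for s in range(2)]
        else:
            vec = [(0.0, 0.0), (0.0, 0.0)]
            for child in node.child_nodes():
                cv = D[child]
                for s in range(2):
                    options = []
                    for t in range(2):
                        change = 1.0 if s != t else 0.0
                        gain = 1.0 if (s != t and t == d_idx) else 0.0
                        options.append(add(cv[t], (change, gain)))
                    vec[s] = add(vec[s], min(options))
            D[node] = vec
    root_vec = D[tree.seed_node]
    anc_idx = 1 - d_idx
    best = root_vec[anc_idx] if root_vec[anc_idx][0] < INF else min(root_vec)
    return int(best[1])


# ---------------------------------------------------------------------------
# Tree search

def _all_topologies(taxa: Sequence[str]):
    """Yield every unrooted binary topology as a Newick string with a basal
    trifurcation (3 × 5 × … × (2n−5) trees)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        yield "(" + ",".join(taxa) + ");"
        return

    def grow(tree, remaining):
        if not remaining:
            yield tree
            return
        leaf, rest = remaining[0], remaining[1:]
        for i in range(_n_edges(tree)):
            yield from grow(_insert_at_edge(tree, i, leaf), rest)

    # nested-tuple representation: leaves are strings, internals are 2-tuples;
    # the top level is a 3-tuple (unrooted basal trifurcation)
    base = (taxa[0], taxa[1], taxa[2])
    for t in grow(base, taxa[3:]):
        yield _to_newick(t) + ";"


def _n_edges(tree) -> int:
    if isinstance(tree, str):
        return 1
    return sum(_n_edges(c) for c in tree) + (0 if len(tree) == 3 else 1)


def _insert_at_edge(tree, i, leaf, top=True):
    """Attach ``leaf`` on the i-th edge (preorder count) of the nested tuple."""
    def walk(node, i, top=False):
        # returns (new_node, remaining_i or None when inserted)
        if not top:
            if i == 0:
                return (node, leaf), None
            i -= 1
        if isinstance(node, str):
            return node, i
        out = []
        for c in node:
            if i is None:
                out.append(c)
                continue
            nc, i = walk(c, i)
            out.append(nc)
        return tuple(out), i

    new, rem = walk(tree, i, top=True)
    assert rem is None
    return new


def _to_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(_to_newick(c) for c in tree) + ")"


def exhaustive_search(matrix: CharacterMatrix,
                      taxa: Sequence[str] | None = None
                      ) -> tuple[list[dendropy.Tree], float]:
    """Exact minimum over all unrooted binary topologies (practical to
    about 8 taxa)."""
    taxa = list(taxa or matrix.taxa)
    if len(taxa) > 9:
        raise ConfigError("exhaustive search is limited to ≤9 taxa")
    best: list[str] = []
    best_S = INF
    for newick in _all_topologies(taxa):
        tree = tree_from_newick(newick)
        S = tree_length(tree, matrix)
        if S < best_S - 1e-9:
            best, best_S = [newick], S
        elif abs(S - best_S) <= 1e-9:
            best.append(newick)
    return [tree_from_newick(n) for n in best], best_S


def _nni_neighbors(newick: str):
    """Yield Newick strings of all nearest-neighbor interchanges of an
    unrooted tree given with a basal trifurcation."""
    tree = tree_from_newick(newick)
    nodes = list(tree.preorder_node_iter())
    internal_edges = [
        n for n in nodes
        if (not n.is_leaf()) and n.parent_node is not None
    ]
    for idx, v in enumerate(internal_edges):
        parent = v.parent_node
        siblings = [c for c in parent.child_nodes() if c is not v]
        for child_i in range(len(v.child_nodes())):
            for sib_i in range(len(siblings)):
                t2 = tree_from_newick(newick)
                nodes2 = [
                    n for n in t2.preorder_node_iter()
                    if (not n.is_leaf()) and n.parent_node is not None
                ]
                v2 = nodes2[idx]
                p2 = v2.parent_node
                sibs2 = [c for c in p2.child_nodes() if c is not v2]
                child = v2.child_nodes()[child_i]
                sib = sibs2[sib_i]
                v2.remove_child(child)
                p2.remove_child(sib)
                v2.add_child(sib)
                p2.add_child(child)
                yield t2.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()


def naive_search(matrix: CharacterMatrix, seed: int = 0,
                 budget: int = 10) -> tuple[list[dendropy.Tree], float]:
    """Heuristic search: seeded random-addition starting trees, each
    hill-climbed to an NNI local optimum.

    ``budget`` is the number of random-addition replicates.  Deterministic
    under ``seed``; the returned length is never worse than the best
    starting tree.  Intended for small (≲30 taxa) matrices; it replicates
    no particular program's search trajectory.
    """
    if budget <= 0:
        raise ConfigError("search budget must be positive")
    rng = random.Random(seed)
    taxa = list(matrix.taxa)
    if len(taxa) < 4:
        tree = tree_from_newick("(" + ",".join(taxa) + ");")
        return [tree], tree_length(tree, matrix)

    def addition_tree() -> str:
        order = taxa[:]
        rng.shuffle(order)
        current = (order[0], order[1], order[2])
        for leaf in order[3:]:
            best_t, best_S = None, INF
            for i in range(_n_edges(current)):
                cand = _insert_at_edge(current, i, leaf)
                S = tree_length(tree_from_newick(_to_newick(cand) + ";"),
                                matrix)
                if S < best_S:
                    best_t, best_S = cand, S
            current = best_t
        return _to_newick(current) + ";"

    best_newicks: list[str] = []
    best_S = INF
    for _ in range(budget):
        newick = addition_tree()
        S = tree_length(tree_from_newick(newick), matrix)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(newick):
                S_c = tree_length(tree_from_newick(cand), matrix)
                if S_c < S - 1e-9:
                    newick, S = cand, S_c
                    improved = True
                    break
        if S < best_S - 1e-9:
            best_newicks, best_S = [newick], S
        elif abs(S - best_S) <= 1e-9:
            key = _topology_key(newick)
            if key not in {_topology_key(n) for n in best_newicks}:
                best_newicks.append(newick)
    return [tree_from_newick(n) for n in best_newicks], best_S


def _topology_key(newick: str) -> frozenset:
    """Unrooted topology fingerprint: the set of non-trivial leaf bipartitions."""
    tree = tree_from_newick(newick)
    all_leaves = frozenset(_leaf_labels(tree))
    parts = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            parts.add(frozenset({below, all_leaves - below}))
    return frozenset(parts)
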