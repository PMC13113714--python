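"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library's dynamic programs: tree length is
checked by exhaustive enumeration of internal-node state labelings, origin
counts by scanning every minimal labeling, and t-test p-values by full
enumeration of group relabelings.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def _edges(tree):
    """(parent, child) node pairs of a dendropy tree."""
    return [(n.parent_node, n) for n in tree.preorder_node_iter()
            if n.parent_node is not None]


def enumeration_tree_length(tree, matrix, j):
    """Minimal steps for character j by brute force over every assignment of
    a single state to every node (leaves restricted to their cells)."""
    alpha = matrix.alphabet(j)
    if len(alpha) < 2:
        return 0
    ordered = matrix.ordered[j]
    val = {s: (int(s) if s.isdigit() else i) for i, s in enumerate(alpha)}
    cells = dict(zip(matrix.taxa, matrix.state_sets(j)))
    nodes = list(tree.preorder_node_iter())
    choices = [
        sorted(cells[n.taxon.label]) if n.is_leaf() else list(alpha)
        for n in nodes
    ]
    index = {id(n): i for i, n in enumerate(nodes)}
    best = math.inf
    for assign in itertools.product(*choices):
        cost = 0
        for parent, child in _edges(tree):
            a, b = assign[index[id(parent)]], assign[index[id(child)]]
            cost += abs(val[a] - val[b]) if ordered else (a != b)
        best = min(best, cost)
    return best


def enumeration_min_gains(tree, matrix, j, derived="1"):
    """Minimum derived-state gains among all minimal-change labelings whose
    root carries the ancestral state (unconstrained if that is infeasible)."""
    alpha = matrix.alphabet(j)
    ancestral = [s for s in alpha if s != derived]
    cells = dict(zip(matrix.taxa, matrix.state_sets(j)))
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}

    def scan(root_choices):
        best = (math.inf, math.inf)
        choices = []
        for n in nodes:
            if n.is_leaf():
                choices.append(sorted(cells[n.taxon.label]))
            elif n is tree.seed_node:
                choices.append(root_choices)
            else:
                choices.append(list(alpha))
        for assign in itertools.product(*choices):
            changes = gains = 0
            for parent, child in _edges(tree):
                a, b = assign[index[id(parent)]], assign[index[id(child)]]
                if a != b:
                    changes += 1
                    if b == derived:
                        gains += 1
            best = min(best, (changes, gains))
        return best

    constrained = scan(ancestral) if ancestral else (math.inf, math.inf)
    if math.isinf(constrained[0]):
        constrained = scan(list(alpha))
    return constrained[1]


def pooled_t_statistic(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    na, nb = len(x), len(y)
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
    return (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_p_value(x, y):
    """Two-sided exact permutation p for the mean difference, enumerating
    every split of the pooled sample."""
    pooled = list(x) + list(y)
    na = len(x)
    obs = abs(np.mean(pooled[:na]) - np.mean(pooled[na:]))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        d = abs(np.mean(a) - np.mean(b))
        count += d >= obs - 1e-12
        total += 1
    return count / total
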