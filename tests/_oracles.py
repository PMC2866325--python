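"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
minimum step counts are found by enumerating every assignment of states to
internal nodes (and to missing leaves) and summing edge mismatches.
"""

from __future__ import annotations

import numpy as np
import dendropy


def min_steps_by_enumeration(tree: dendropy.Tree, character: dict) -> int:
    """True minimum changes via exhaustive internal-state enumeration.

    Optimal labelings only ever use observed states, so the enumeration
    alphabet is the set of non-missing leaf states.
    """
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    states = sorted({v for v in character.values() if v is not None}, key=repr)
    k = len(states)
    code = {s: i for i, s in enumerate(states)}
    free, fixed = [], {}
    for i, n in enumerate(nodes):
        if n.is_leaf() and character[n.taxon.label] is not None:
            fixed[i] = code[character[n.taxon.label]]
        else:
            free.append(i)
    edges = [
        (idx[id(n.parent_node)], idx[id(n)])
        for n in nodes if n.parent_node is not None
    ]
    n_assign = k ** len(free)
    # free nodes = internal vertices plus missing leaves; 7-leaf trees with
    # a few missing tips stay comfortably enumerable
    assert n_assign <= 4 ** 10, "instance too large for enumeration"
    grid = np.indices((k,) * len(free)).reshape(len(free), -1)
    full = np.zeros((len(nodes), n_assign), dtype=np.int8)
    for i, v in fixed.items():
        full[i] = v
    for j, i in enumerate(free):
        full[i] = grid[j]
    cost = np.zeros(n_assign, dtype=np.int32)
    for p, c in edges:
        cost += full[p] != full[c]
    return int(cost.min())


def pairwise_p_distances(seqs: list[str]) -> list[float]:
    """Naive per-pair uncorrected distances with pairwise deletion."""
    out = []
    n = len(seqs)
    for i in range(n - 1):
        for j in range(i + 1, n):
            comp = mism = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    mism += a != b
            if comp:
                out.append(mism / comp)
    return out


def column_census(column: str) -> dict:
    """Per-column distinct-state census over unambiguous cells."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch in "ACGT":
            counts[ch] = counts.get(ch, 0) + 1
    k = len(counts)
    return {
        "variable": k >= 2,
        "informative": sum(1 for c in counts.values() if c >= 2) >= 2,
        "min_changes": max(k - 1, 0),
    }


def random_tree(
    labels: list[str], rng: np.random.Generator, p_polytomy: float = 0.0
) -> dendropy.Tree:
    """Random topology by random pair joins; optional edge collapse."""
    import genegauge as gg

    shapes = list(labels)
    while len(shapes) > 1:
        i, j = sorted(rng.choice(len(shapes), size=2, replace=False))
        b = shapes.pop(j)
        a = shapes.pop(i)
        shapes.append(f"({a},{b})")
    tree = gg.tree_from_newick(shapes[0] + ";")
    if p_polytomy > 0.0:
        for node in list(tree.preorder_internal_node_iter()):
            if node.parent_node is None:
                continue
            if rng.random() < p_polytomy:
                node.edge.collapse()
    return tree
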