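"""Parsimony step counting and the ensemble character-congruence indices.

Minimum state changes of a character on a tree are counted with the Fitch
set rule on bifurcating nodes and Hartigan's frequency rule at polytomies
(polytomies are "soft": a multifurcation can be resolved at no cost).
Missing states carry the full state set through the dynamic program and
never force a change.  From the per-character step counts the ensemble
consistency index CI = M/S and retention index RI = (G-S)/(G-M) are
assembled, where per character m is the tree-independent minimum number of
changes (states - 1), s the minimum on the given tree, and g the greatest
number possible on any tree (non-missing leaves minus the modal state's
count, realised on the star tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

import dendropy
import numpy as np

from .io import Alignment, ValidationError, tree_from_newick

# Bitmask encoding of state sets over {A, C, G, T}.
_BITS = {b"A": 1, b"C": 2, b"G": 4, b"T": 8}
_FULL = 15  # missing / ambiguous: the full state set


def _encode(data: np.ndarray) -> np.ndarray:
    """Map an (n, A) byte matrix to state-set bitmasks; non-ACGT -> full set."""
    out = np.full(data.shape, _FULL, dtype=np.uint8)
    for sym, bit in _BITS.items():
        out[data == sym] = bit
    return out


def _leaf_masks_from_map(
    tree: dendropy.Tree, character: Mapping[str, object]
) -> dict[str, np.ndarray]:
    """One-column bitmask per leaf for a single generic character."""
    symbols = sorted(
        {v for v in character.values() if v is not None}, key=repr
    )
    if len(symbols) > 4:
        raise ValidationError("at most 4 distinct states are supported")
    code = {s: np.uint8(1 << i) for i, s in enumerate(symbols)}
    masks = {}
    for lf in tree.leaf_node_iter():
        label = lf.taxon.label
        if label not in character:
            raise ValidationError(f"leaf {label!r} has no state in the character")
        v = character[label]
        masks[label] = np.array(
            [_FULL if v is None else code[v]], dtype=np.uint8
        )
    if not any(v is not None for v in character.values()):
        raise ValidationError("character has no non-missing state")
    return masks


def _hartigan_steps(
    tree: dendropy.Tree, leaf_masks: Mapping[str, np.ndarray], ncols: int
) -> np.ndarray:
    """Vectorised bottom-up pass; returns per-column minimum change counts.

    At each internal node, for every state count the children whose state
    set contains it; keep the states attaining the maximum count k and add
    (number of children - k) changes.  With two children this is exactly
    the Fitch intersection/union rule.
    """
    steps = np.zeros(ncols, dtype=np.int64)
    sets: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            sets[node] = leaf_masks[node.taxon.label]
            continue
        counts = np.zeros((4, ncols), dtype=np.int32)
        for ch in children:
            m = sets.pop(ch)
            for b in range(4):
                counts[b] += (m >> b) & 1
        k = counts.max(axis=0)
        keep = counts == k
        mask = np.zeros(ncols, dtype=np.uint8)
        for b in range(4):
            mask |= keep[b].astype(np.uint8) << b
        sets[node] = mask
        steps += len(children) - k
    return steps


def steps_matrix(aln: Alignment, tree: dendropy.Tree) -> np.ndarray:
    """Per-column minimum changes (s_c) of an alignment on a tree."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if labels != set(aln.ids):
        raise ValidationError(
            "tree leaves and alignment terminals differ: "
            f"{sorted(labels ^ set(aln.ids))[:10]}"
        )
    enc = _encode(aln.data)
    row = {t: i for i, t in enumerate(aln.ids)}
    leaf_masks = {t: enc[row[t]] for t in aln.ids}
    return _hartigan_steps(tree, leaf_masks, aln.n_columns)


def steps_on_tree(tree: dendropy.Tree, character: Mapping[str, object]) -> int:
    """Minimum state changes of one character on the given tree.

    ``character`` maps each leaf label to a hashable state or None for
    missing.  At least one leaf must be non-missing.
    """
    masks = _leaf_masks_from_map(tree, character)
    return int(_hartigan_steps(tree, masks, 1)[0])


def min_changes_per_column(aln: Alignment) -> np.ndarray:
    """m_c = (distinct unambiguous states in column) - 1, floored at 0."""
    enc = _encode(aln.data)
    present = np.zeros(aln.n_columns, dtype=np.int64)
    for bit in (1, 2, 4, 8):
        unamb = enc != _FULL
        present += ((enc == bit) & unamb).any(axis=0)
    return np.maximum(present - 1, 0)


def max_steps_per_column(aln: Alignment) -> np.ndarray:
    """g_c = non-missing leaves minus the modal state's count, per column."""
    enc = _encode(aln.data)
    unamb = enc != _FULL
    n_obs = unamb.sum(axis=0)
    modal = np.zeros(aln.n_columns, dtype=np.int64)
    for bit in (1, 2, 4, 8):
        modal = np.maximum(modal, (enc == bit).sum(axis=0))
    return n_obs - modal


def max_steps(character: Mapping[str, object]) -> int:
    """Greatest number of changes of one character on any cladogram.

    Equals the number of non-missing leaves minus the count of the most
    frequent state; the bound is attained on the star tree.
    """
    observed = [v for v in character.values() if v is not None]
    if not observed:
        raise ValidationError("character has no non-missing state")
    counts: dict[object, int] = {}
    for v in observed:
        counts[v] = counts.get(v, 0) + 1
    return len(observed) - max(counts.values())


@dataclass
class CharacterFit:
    """Per-character step counts m <= s <= g over the columns of a matrix."""

    m: np.ndarray
    s: np.ndarray
    g: np.ndarray

    @property
    def variable(self) -> np.ndarray:
        return self.m >= 1


@dataclass
class CongruenceScores:
    """Ensemble sums and the CI/RI indices over the variable characters.

    ``ci`` is None when S = 0 (no variable characters) and ``ri`` is None
    when G = M (no potential synapomorphy).
    """

    S: int
    M: int
    G: int
    ci: float | None
    ri: float | None
    n_characters: int


def character_fits(aln: Alignment, tree: dendropy.Tree) -> CharacterFit:
    return CharacterFit(
        m=min_changes_per_column(aln),
        s=steps_matrix(aln, tree),
        g=max_steps_per_column(aln),
    )


def congruence(
    aln: Alignment, tree: dendropy.Tree, include_invariant: bool = False
) -> CongruenceScores:
    """Ensemble CI and RI of a matrix on a tree.

    Invariant characters (m_c = 0) contribute nothing to either index and
    are excluded unless ``include_invariant`` is set.
    """
    fit = character_fits(aln, tree)
    keep = np.ones(aln.n_columns, dtype=bool) if include_invariant else fit.variable
    S = int(fit.s[keep].sum())
    M = int(fit.m[keep].sum())
    G = int(fit.g[keep].sum())
    ci = M / S if S > 0 else None
    ri = (G - S) / (G - M) if G > M else None
    return CongruenceScores(S=S, M=M, G=G, ci=ci, ri=ri,
                            n_characters=int(keep.sum()))


def ensemble_ci(aln: Alignment, tree: dendropy.Tree) -> float | None:
    """CI = sum(m_c) / sum(s_c) over the variable characters."""
    return congruence(aln, tree).ci


def ensemble_ri(aln: Alignment, tree: dendropy.Tree) -> float | None:
    """RI = (G - S) / (G - M) over the variable characters."""
    return congruence(aln, tree).ri


# ---------------------------------------------------------------------------
# Exhaustive topology enumeration (small-n oracle; stands in for tree search)


def _enumerate_shapes(leaves: list[str]) -> Iterator[object]:
    """All unrooted binary shapes over the leaves as nested tuples.

    The top-level tuple has three children (an unrooted tree drawn as a
    basal trifurcation); every other internal vertex has two.  Grown by
    inserting each successive leaf on every edge of every smaller shape.
    """
    if len(leaves) < 3:
        yield tuple(leaves)
        return

    def insert(sub: object, leaf: str) -> Iterator[object]:
        # attach on the edge above `sub`
        yield (sub, leaf)
        if isinstance(sub, tuple):
            a, b = sub
            for new_a in insert(a, leaf):
                yield (new_a, b)
            for new_b in insert(b, leaf):
                yield (a, new_b)

    shapes: list[tuple] = [tuple(leaves[:3])]
    for leaf in leaves[3:]:
        grown: list[tuple] = []
        for shape in shapes:
            a, b, c = shape
            for new_a in insert(a, leaf):
                grown.append((new_a, b, c))
            for new_b in insert(b, leaf):
                grown.append((a, new_b, c))
            for new_c in insert(c, leaf):
                grown.append((a, b, new_c))
        shapes = grown
    yield from shapes


def _shape_to_newick(shape: object) -> str:
    if isinstance(shape, tuple):
        return "(" + ",".join(_shape_to_newick(s) for s in shape) + ")"
    return str(shape)


def n_unrooted_topologies(n_leaves: int) -> int:
    """(2n-5)!! for n >= 3; 1 otherwise."""
    if n_leaves < 3:
        return 1
    return math.prod(range(1, 2 * n_leaves - 4, 2))


def enumerate_topologies(leaves: list[str]) -> Iterator[dendropy.Tree]:
    """Yield every unrooted binary topology on the leaf set as a tree."""
    for shape in _enumerate_shapes(list(leaves)):
        yield tree_from_newick(_shape_to_newick(shape) + ";")


def exhaustive_min_steps(
    character: Mapping[str, object], max_leaves: int = 8
) -> tuple[int, list[dendropy.Tree]]:
    """Minimum of steps_on_tree over all unrooted binary topologies.

    A test oracle for small instances only; refuses more than ``max_leaves``
    (at most 8) leaves since the topology space grows as (2n-5)!!.
    """
    leaves = sorted(character, key=str)
    if len(leaves) > min(max_leaves, 8):
        raise ValidationError(
            f"exhaustive search limited to 8 leaves, got {len(leaves)}"
        )
    best = None
    best_trees: list[dendropy.Tree] = []
    for tree in enumerate_topologies(leaves):
        s = steps_on_tree(tree, character)
        if best is None or s < best:
            best, best_trees = s, [tree]
        elif s == best:
            best_trees.append(tree)
    assert best is not None
    return best, best_trees
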