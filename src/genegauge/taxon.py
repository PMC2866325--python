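"""Taxonomic-congruence signal: PMT, TCI and TRI.

Each named taxon (genus, subfamily, family, superfamily) is a concordance
group encoded as a binary membership character (1 = member, 0 =
non-member).  Scoring that character on a cladogram gives s_t, the minimum
number of clades the taxon resolves into on that tree (its parsimony step
count, clamped to >= 1 so the all-terminals group still exhibits one
clade).  With M_t test groups, S_t the summed s_t and G_t the number of
terminals in the matrix, the indices are

    PMT = (# monophyletic groups) / M_t
    TCI = M_t / S_t
    TRI = (G_t - S_t) / (G_t - M_t)

the taxon-level analogues of the character consistency and retention
indices; all three equal 1 exactly when every group is a clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import ConcordanceGroup, MembershipMatrix, ValidationError, leaf_labels
from .parsimony import steps_on_tree


@dataclass
class TaxonFit:
    """Per-group fit of one concordance group on one tree."""

    group: str
    members: int
    monophyletic: bool
    s_t: int


@dataclass
class TaxonCongruenceScores:
    """Ensemble taxon-congruence indices for one tree and one rank.

    ``tri`` is None when G_t = M_t (every group is a singleton relative to
    the matrix and the denominator vanishes).
    """

    rank: str
    M_t: int
    S_t: int
    G_t: int
    n_monophyletic: int
    pmt: float
    tci: float
    tri: float | None
    per_group: list[TaxonFit]


def _leafset_index(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= sets[ch]
            sets[node] = frozenset(s)
    return sets


def is_monophyletic(
    tree: dendropy.Tree, group: ConcordanceGroup, unrooted: bool = False
) -> bool:
    """True iff some node's leaf-descendant set equals the member set.

    Rooted convention by default: the complement of a group does not count
    as the group.  With ``unrooted=True`` a group is also accepted when its
    complement is a clade (the "clan" reading of an unrooted tree).
    """
    leaves = frozenset(leaf_labels(tree))
    if not group.members <= leaves:
        raise ValidationError(
            f"group {group.name!r} has members absent from the tree: "
            f"{sorted(group.members - leaves)[:5]}"
        )
    target = frozenset(group.members)
    complement = leaves - target
    for s in _leafset_index(tree).values():
        if s == target:
            return True
        if unrooted and complement and s == complement:
            return True
    return False


def clade_count(tree: dendropy.Tree, group: ConcordanceGroup) -> int:
    """s_t: minimum number of clades the group resolves into on the tree.

    Computed as the parsimony step count of the binary membership
    character, clamped to >= 1 (a taxon always exhibits at least one
    clade); equals 1 exactly when the group is monophyletic.
    """
    leaves = set(leaf_labels(tree))
    if not group.members <= leaves:
        raise ValidationError(
            f"group {group.name!r} has members absent from the tree"
        )
    character = {lf: (1 if lf in group.members else 0) for lf in leaves}
    return max(1, steps_on_tree(tree, character))


def taxon_congruence(
    tree: dendropy.Tree, groups: MembershipMatrix, unrooted: bool = False
) -> TaxonCongruenceScores:
    """Score every concordance group of one rank on one tree."""
    if not groups.groups:
        raise ValidationError("no concordance groups to score")
    leaves = leaf_labels(tree)
    G_t = len(leaves)
    fits = []
    for grp in groups.groups:
        fits.append(TaxonFit(
            group=grp.name,
            members=len(grp.members),
            monophyletic=is_monophyletic(tree, grp, unrooted=unrooted),
            s_t=clade_count(tree, grp),
        ))
    M_t = len(fits)
    S_t = sum(f.s_t for f in fits)
    n_mono = sum(f.monophyletic for f in fits)
    tri = (G_t - S_t) / (G_t - M_t) if G_t > M_t else None
    return TaxonCongruenceScores(
        rank=groups.rank, M_t=M_t, S_t=S_t, G_t=G_t,
        n_monophyletic=n_mono, pmt=n_mono / M_t, tci=M_t / S_t, tri=tri,
        per_group=fits,
    )


def strict_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Strict consensus of trees over an identical leaf set."""
    tl = dendropy.TreeList(trees)
    cons = tl.consensus(min_freq=1.0)
    cons.is_rooted = True
    return cons


def taxon_congruence_multi(
    trees: list[dendropy.Tree],
    groups: MembershipMatrix,
    unrooted: bool = False,
    consensus: bool = False,
) -> pd.DataFrame:
    """Score a rank's groups on several (equally parsimonious) trees.

    Returns one row per tree plus mean and range rows across trees; with
    ``consensus`` an additional row scores the strict consensus tree.
    Trees must share one leaf set.
    """
    if not trees:
        raise ValidationError("no trees supplied")
    leafsets = [frozenset(leaf_labels(t)) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValidationError("trees have differing leaf sets")
    rows = []
    for i, t in enumerate(trees):
        sc = taxon_congruence(t, groups, unrooted=unrooted)
        rows.append({"tree": str(i), "rank": sc.rank, "M_t": sc.M_t,
                     "S_t": sc.S_t, "G_t": sc.G_t, "pmt": sc.pmt,
                     "tci": sc.tci, "tri": sc.tri})
    df = pd.DataFrame(rows)
    summary = []
    for stat, fn in (("mean", np.mean), ("min", np.min), ("max", np.max)):
        rec = {"tree": f"__{stat}__", "rank": groups.rank}
        for col in ("M_t", "S_t", "G_t", "pmt", "tci", "tri"):
            vals = df[col].dropna()
            rec[col] = fn(vals) if len(vals) else None
        summary.append(rec)
    out = pd.concat([df, pd.DataFrame(summary)], ignore_index=True)
    if consensus:
        sc = taxon_congruence(strict_consensus(trees), groups,
                              unrooted=unrooted)
        out = pd.concat([out, pd.DataFrame([{
            "tree": "__consensus__", "rank": sc.rank, "M_t": sc.M_t,
            "S_t": sc.S_t, "G_t": sc.G_t, "pmt": sc.pmt, "tci": sc.tci,
            "tri": sc.tri}])], ignore_index=True)
    return out
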