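"""Matrix-intrinsic phylogenetic-utility statistics.

These are properties of an aligned matrix measured before any tree is
inferred: the aligned length A, the number of variable columns V, the
number of parsimony-informative columns PI (variable columns that are not
autapomorphies), the tree-independent minimum number of state changes M,
the character-taxon ratio A / n_terminals, and the mean uncorrected
pairwise p-distance.  Ambiguity codes, gaps and 'N'/'?' never count as
states nor as mismatches.

Group-structured profiles restrict the matrix to each taxon (genus,
subfamily, ...) with enough species, recompute V/PI/M there, and average
the proportions across groups; proportions are always relative to the
global aligned length A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Alignment, ValidationError, build_membership_matrix
from .parsimony import _FULL, _encode, min_changes_per_column

logger = logging.getLogger(__name__)


def aligned_length(aln: Alignment) -> int:
    """A: the number of columns in the aligned matrix."""
    return aln.n_columns


def _state_counts(aln: Alignment) -> np.ndarray:
    """(4, A) counts of unambiguous A/C/G/T per column."""
    enc = _encode(aln.data)
    return np.stack([(enc == bit).sum(axis=0) for bit in (1, 2, 4, 8)])


def count_variable(aln: Alignment) -> int:
    """V: columns with >= 2 distinct unambiguous states."""
    counts = _state_counts(aln)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_parsimony_informative(aln: Alignment) -> int:
    """PI: columns with >= 2 unambiguous states each in >= 2 terminals."""
    counts = _state_counts(aln)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def min_changes(aln: Alignment) -> int:
    """M: sum over columns of (distinct unambiguous states - 1).

    The tree-independent lower bound on parsimony steps of the matrix.
    """
    return int(min_changes_per_column(aln).sum())


def char_taxon_ratio(aln: Alignment) -> float:
    return aln.n_columns / aln.n_terminals


def mean_p_distance(aln: Alignment) -> float:
    """Mean uncorrected pairwise distance with pairwise deletion.

    For each unordered pair of terminals, mismatches / compared sites over
    the columns where both cells are unambiguous; pairs with no comparable
    site are excluded with a warning.
    """
    if aln.n_terminals < 2:
        raise ValidationError("p-distance needs at least 2 terminals")
    enc = _encode(aln.data)
    ok = enc != _FULL
    dists = []
    skipped = 0
    n = aln.n_terminals
    for i in range(n - 1):
        both = ok[i] & ok[i + 1:]
        comp = both.sum(axis=1)
        mism = ((enc[i] != enc[i + 1:]) & both).sum(axis=1)
        for c, m in zip(comp, mism):
            if c == 0:
                skipped += 1
            else:
                dists.append(m / c)
    if skipped:
        logger.warning("%d pair(s) had no comparable sites and were skipped",
                       skipped)
    if not dists:
        raise ValidationError("no terminal pair has comparable sites")
    return float(np.mean(dists))


@dataclass
class UtilityScores:
    """The full utility panel for one matrix."""

    A: int
    V: int
    PI: int
    M: int
    n_terminals: int
    char_taxon_ratio: float
    p_mean: float | None

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "UtilityScores":
        return cls(
            A=aligned_length(aln),
            V=count_variable(aln),
            PI=count_parsimony_informative(aln),
            M=min_changes(aln),
            n_terminals=aln.n_terminals,
            char_taxon_ratio=char_taxon_ratio(aln),
            p_mean=mean_p_distance(aln) if aln.n_terminals >= 2 else None,
        )


def utility_profile(
    aln: Alignment,
    tax: pd.DataFrame,
    rank: str,
    min_species: int = 3,
) -> pd.DataFrame:
    """Per-group V/PI/M at one rank, plus the across-group mean proportions.

    Groups at ``rank`` with at least ``min_species`` members are scored on
    their restricted sub-matrices.  Proportions V/A, PI/A, M/A use the
    global A.  The returned frame has one row per group and a final
    ``__mean__`` row with the unweighted mean of the proportions (the mean
    is of proportions across groups, not a pooled count).
    """
    A = aln.n_columns
    mm = build_membership_matrix(tax, rank, aln.ids, min_size=min_species)
    rows = []
    for grp in mm.groups:
        sub = aln.subset(sorted(grp.members))
        v = count_variable(sub)
        pi = count_parsimony_informative(sub)
        m = min_changes(sub)
        rows.append({
            "rank": rank, "group": grp.name, "n_species": len(grp.members),
            "V": v, "PI": pi, "M": m,
            "V_prop": v / A, "PI_prop": pi / A, "M_prop": m / A,
        })
    if not rows:
        logger.warning("no group at rank %r has >= %d species", rank,
                       min_species)
        return pd.DataFrame(
            columns=["rank", "group", "n_species", "V", "PI", "M",
                     "V_prop", "PI_prop", "M_prop"]
        )
    df = pd.DataFrame(rows)
    mean = {
        "rank": rank, "group": "__mean__", "n_species": df["n_species"].mean(),
        "V": df["V"].mean(), "PI": df["PI"].mean(), "M": df["M"].mean(),
        "V_prop": df["V_prop"].mean(), "PI_prop": df["PI_prop"].mean(),
        "M_prop": df["M_prop"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
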