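"""Rank-structured censuses and side-by-side gene comparisons.

Aggregates the per-matrix utility panel, the character-congruence indices
(CI/RI, scored per taxon on induced subtrees and averaged), and the
taxon-congruence indices (PMT/TCI/TRI) into one report per gene, and lines
up several genes over a shared taxonomy with a dense per-measure ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import (
    RANKS,
    Alignment,
    ValidationError,
    build_membership_matrix,
    restrict,
)
from .parsimony import congruence
from .taxon import taxon_congruence_multi
from .utility import UtilityScores, utility_profile

logger = logging.getLogger(__name__)


def census(tax: pd.DataFrame, terminals: list[str]) -> pd.DataFrame:
    """Per-rank taxon counts over the analysed terminals.

    For each rank: the number of distinct taxa, the number of concordance
    groups (taxa containing more than one species) and the number of taxa
    containing more than two species.
    """
    absent = [t for t in terminals if t not in tax.index]
    if absent:
        raise ValidationError(f"terminals absent from taxonomy: {absent[:10]}")
    sub = tax.loc[list(terminals)]
    rows = [{
        "rank": "species", "n_taxa": len(terminals),
        "n_groups_gt1": None, "n_groups_gt2": None,
    }]
    for rank in [r for r in RANKS if r in tax.columns]:
        sizes = sub[rank].dropna().value_counts()
        rows.append({
            "rank": rank,
            "n_taxa": int(len(sizes)),
            "n_groups_gt1": int((sizes > 1).sum()),
            "n_groups_gt2": int((sizes > 2).sum()),
        })
    return pd.DataFrame(rows)


def congruence_profile(
    aln: Alignment,
    trees: list[dendropy.Tree],
    tax: pd.DataFrame,
    rank: str,
    min_species: int = 3,
) -> pd.DataFrame:
    """Within-taxon ensemble CI/RI at a rank, averaged across groups.

    Each qualifying group is scored on its own sub-matrix and the induced
    subtree of each input tree; per-group values are the mean across trees
    and the rank summary row is the unweighted mean across groups.
    Undefined indices (no variable character, or G = M) stay missing and
    are dropped from means.
    """
    mm = build_membership_matrix(tax, rank, aln.ids, min_size=min_species)
    rows = []
    for grp in mm.groups:
        members = sorted(grp.members)
        cis, ris = [], []
        for tree in trees:
            sub_aln, sub_tree = restrict(aln, tree, members)
            sc = congruence(sub_aln, sub_tree)
            cis.append(sc.ci)
            ris.append(sc.ri)
        rows.append({
            "rank": rank, "group": grp.name, "n_species": len(members),
            "ci": np.mean([c for c in cis if c is not None]) if any(
                c is not None for c in cis) else None,
            "ri": np.mean([r for r in ris if r is not None]) if any(
                r is not None for r in ris) else None,
        })
    if not rows:
        return pd.DataFrame(columns=["rank", "group", "n_species", "ci", "ri"])
    df = pd.DataFrame(rows)
    mean = {
        "rank": rank, "group": "__mean__",
        "n_species": df["n_species"].mean(),
        "ci": df["ci"].dropna().mean() if df["ci"].notna().any() else None,
        "ri": df["ri"].dropna().mean() if df["ri"].notna().any() else None,
    }
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


@dataclass
class GeneReport:
    """All measures for one gene over the shared taxonomy."""

    name: str
    overall: UtilityScores
    utility: dict[str, pd.DataFrame] = field(default_factory=dict)
    char_congruence: dict[str, pd.DataFrame] = field(default_factory=dict)
    taxon_congruence: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """One row per rank with the headline per-rank means."""
        rows = []
        for rank in self.utility:
            rec: dict[str, object] = {"gene": self.name, "rank": rank}
            rec.update({m: np.nan for m in _RANKED_MEASURES})
            ut = self.utility.get(rank)
            if ut is not None and len(ut):
                m = ut[ut["group"] == "__mean__"].iloc[0]
                rec.update(V_prop=m["V_prop"], PI_prop=m["PI_prop"],
                           M_prop=m["M_prop"])
            cc = self.char_congruence.get(rank)
            if cc is not None and len(cc):
                m = cc[cc["group"] == "__mean__"].iloc[0]
                rec.update(ci=m["ci"], ri=m["ri"])
            tc = self.taxon_congruence.get(rank)
            if tc is not None and len(tc):
                m = tc[tc["tree"] == "__mean__"].iloc[0]
                rec.update(pmt=m["pmt"], tci=m["tci"], tri=m["tri"])
            rows.append(rec)
        df = pd.DataFrame(rows)
        # undefined indices surface as None; keep the columns numeric
        for m in _RANKED_MEASURES:
            if m in df.columns:
                df[m] = pd.to_numeric(df[m], errors="coerce")
        return df


def build_gene_report(
    name: str,
    aln: Alignment,
    trees: list[dendropy.Tree],
    tax: pd.DataFrame,
    ranks: list[str] | None = None,
    min_species: int = 3,
) -> GeneReport:
    ranks = [r for r in (ranks or RANKS) if r in tax.columns]
    report = GeneReport(name=name, overall=UtilityScores.from_alignment(aln))
    for rank in ranks:
        report.utility[rank] = utility_profile(
            aln, tax, rank, min_species=min_species
        )
        report.char_congruence[rank] = congruence_profile(
            aln, trees, tax, rank, min_species=min_species
        )
        mm = build_membership_matrix(tax, rank, aln.ids, min_size=min_species)
        if len(mm):
            report.taxon_congruence[rank] = taxon_congruence_multi(trees, mm)
        else:
            logger.warning("no concordance group at rank %r", rank)
            report.taxon_congruence[rank] = pd.DataFrame(
                columns=["tree", "rank", "M_t", "S_t", "G_t",
                         "pmt", "tci", "tri"]
            )
    return report


#: Measures where a larger value ranks first in gene comparisons.
_RANKED_MEASURES = ("V_prop", "PI_prop", "M_prop", "ci", "ri",
                    "pmt", "tci", "tri")


def compare_genes(reports: list[GeneReport]) -> pd.DataFrame:
    """Side-by-side per-rank table with dense per-measure gene rankings.

    Requires >= 2 reports over the same rank set.  For every measure a
    ``rank_<measure>`` column gives the dense ranking (1 = best, ties
    share a rank); missing values stay missing and are unranked.
    """
    if len(reports) < 2:
        raise ValidationError("need at least two gene reports to compare")
    rank_sets = [tuple(r.utility.keys()) for r in reports]
    if len(set(rank_sets)) != 1:
        raise ValidationError(f"gene reports cover different ranks: {rank_sets}")
    table = pd.concat([r.summary() for r in reports], ignore_index=True)
    for measure in _RANKED_MEASURES:
        if measure not in table.columns:
            continue
        table[f"rank_{measure}"] = (
            table.groupby("rank")[measure]
            .rank(method="dense", ascending=False)
        )
    return table
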