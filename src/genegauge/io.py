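"""Readers, writers and cross-referenced data structures.

The package works on three coupled inputs: an aligned DNA matrix (FASTA),
one or more trees over the same terminals (Newick), and a taxonomy table
mapping each terminal to a named group at each rank (TSV).  This module
owns the containers, the format round-trips, the validation between them,
and the derived structures every scorer consumes: binary group-membership
matrices and induced (alignment, tree) subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical rank order, shallowest first.
RANKS = ("genus", "subfamily", "family", "superfamily")

#: Unambiguous nucleotide states.  Everything else -- IUPAC ambiguity codes,
#: the gap '-' and 'N'/'?' -- is treated as missing by every scorer.
UNAMBIGUOUS = frozenset(b"ACGT")

#: Symbols accepted on input without a warning.
_KNOWN = frozenset(b"ACGTRYSWKMBDHVN-?")


class ValidationError(ValueError):
    """Raised when inputs violate a structural precondition."""


@dataclass
class Alignment:
    """An aligned character matrix: rows are terminals, columns are sites.

    ``data`` is an (n_terminals, n_columns) byte array of single uppercase
    symbols.  Column count is the measure *A*; it is a property of the full
    matrix and is never recomputed when rows are subset.
    """

    ids: list[str]
    data: np.ndarray  # dtype 'S1', shape (n, A)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="S1")
        if self.data.ndim != 2:
            raise ValidationError("alignment data must be 2-dimensional")
        if len(self.ids) != self.data.shape[0]:
            raise ValidationError("id count does not match row count")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("terminal ids must be unique")
        if self.data.shape[1] < 1:
            raise ValidationError("alignment must have at least one column")

    @property
    def n_terminals(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def sequence(self, terminal: str) -> str:
        row = self.data[self.ids.index(terminal)]
        return row.tobytes().decode("ascii")

    def subset(self, keep: list[str]) -> "Alignment":
        """Row subset in the order given; columns untouched."""
        if not keep:
            raise ValidationError("cannot subset to an empty terminal set")
        index = {t: i for i, t in enumerate(self.ids)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise ValidationError(f"terminals not in alignment: {missing}")
        rows = [index[t] for t in keep]
        return Alignment(list(keep), self.data[rows])


@dataclass
class ConcordanceGroup:
    """A named taxon expected to form a clade, as a set of member terminals."""

    rank: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"group {self.name!r} has no members")


@dataclass
class MembershipMatrix:
    """One binary character per concordance group at a single rank.

    State 1 = member, 0 = non-member, over a fixed ordered terminal set.
    """

    rank: str
    terminals: list[str]
    groups: list[ConcordanceGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        term_set = set(self.terminals)
        for g in self.groups:
            if not g.members <= term_set:
                raise ValidationError(
                    f"group {g.name!r} has members outside the terminal set"
                )

    def __len__(self) -> int:
        return len(self.groups)

    def to_array(self) -> np.ndarray:
        """(n_groups, n_terminals) 0/1 matrix in terminal order."""
        idx = {t: i for i, t in enumerate(self.terminals)}
        out = np.zeros((len(self.groups), len(self.terminals)), dtype=np.int8)
        for gi, g in enumerate(self.groups):
            for t in g.members:
                out[gi, idx[t]] = 1
        return out


# ---------------------------------------------------------------------------
# Alignment I/O


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Symbols are uppercased; anything outside the DNA alphabet plus IUPAC
    codes, '-' and '?' is mapped to '?' with a warning.  Records of unequal
    length are a hard error naming the offending record.
    """
    if format != "fasta":
        raise ValidationError(f"unsupported alignment format: {format}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no sequences found in {path}")
    ids = [r.id.strip() for r in records]
    length = len(records[0].seq)
    for r in records:
        if len(r.seq) != length:
            raise ValidationError(
                f"record {r.id!r} has length {len(r.seq)}, expected {length}"
            )
    data = np.frombuffer(
        "".join(str(r.seq).upper() for r in records).encode("ascii"), dtype="S1"
    ).reshape(len(records), length)
    data = data.copy()
    unknown = ~np.isin(data, np.frombuffer(bytes(_KNOWN), dtype="S1"))
    if unknown.any():
        bad = sorted({s.decode() for s in data[unknown]})
        logger.warning(
            "mapped %d unknown symbol(s) %s to '?'", int(unknown.sum()), bad
        )
        data[unknown] = b"?"
    return Alignment(ids, data)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.data[i].tobytes().decode("ascii")), id=t, description="")
        for i, t in enumerate(aln.ids)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tree I/O


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    for nd in tree.preorder_internal_node_iter():
        if len(nd.child_nodes()) < 2 and nd is not tree.seed_node:
            raise ValidationError("tree contains a degree-2 internal node")
    return tree


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more Newick trees from a file.

    A trifurcating Newick root is kept as a rooted basal polytomy; all
    scoring is done on the tree as read unless rerooted explicitly.
    """
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValidationError(f"could not parse Newick file {path}: {exc}") from exc
    if not trees:
        raise ValidationError(f"no trees found in {path}")
    out = []
    for t in trees:
        t.is_rooted = True
        out.append(_validate_tree(t))
    return out


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read exactly the first tree from a Newick file."""
    return read_trees(path)[0]


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return _validate_tree(tree)


def write_trees(trees: list[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(
                t.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
            )


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def reroot_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Reroot on the pendant edge of the named leaf (in place; returns tree)."""
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            node = lf
            break
    if node is None:
        raise ValidationError(f"outgroup {outgroup!r} is not a leaf of the tree")
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV keyed by terminal id.

    Expected header: ``terminal`` followed by rank columns.  Values are
    stripped of surrounding whitespace; empty cells become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "terminal" not in df.columns:
        raise ValidationError("taxonomy table must have a 'terminal' column")
    df["terminal"] = df["terminal"].str.strip()
    if df["terminal"].duplicated().any():
        dupes = df.loc[df["terminal"].duplicated(), "terminal"].tolist()
        raise ValidationError(f"duplicate terminals in taxonomy: {dupes}")
    df = df.set_index("terminal")
    for col in df.columns:
        df[col] = df[col].str.strip().replace({"": None})
    return df


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index_label="terminal")


def check_cross_references(
    aln: Alignment | None,
    trees: list[dendropy.Tree] | None,
    tax: pd.DataFrame | None,
) -> set[str]:
    """Validate that every supplied input covers the same terminal set.

    Returns the shared terminal set; raises if alignment and tree disagree
    or if the taxonomy is missing a terminal under analysis.
    """
    terminals: set[str] | None = None
    if aln is not None:
        terminals = set(aln.ids)
    if trees is not None:
        for t in trees:
            leaves = set(leaf_labels(t))
            if terminals is None:
                terminals = leaves
            elif leaves != terminals:
                raise ValidationError(
                    "tree leaf set does not match other inputs: "
                    f"only-in-tree={sorted(leaves - terminals)[:5]}, "
                    f"missing-from-tree={sorted(terminals - leaves)[:5]}"
                )
    if terminals is None:
        raise ValidationError("nothing to cross-reference")
    if tax is not None:
        absent = terminals - set(tax.index)
        if absent:
            raise ValidationError(
                f"terminals absent from taxonomy: {sorted(absent)[:10]}"
            )
    return terminals


# ---------------------------------------------------------------------------
# Derived structures


def build_membership_matrix(
    tax: pd.DataFrame,
    rank: str,
    terminals: list[str],
    min_size: int = 1,
) -> MembershipMatrix:
    """Binary group-membership characters (1 = member, 0 = non-member).

    One character per group at ``rank`` having at least ``min_size`` members
    among ``terminals``.  Terminals with a missing value at the rank are
    excluded from every group with a warning.
    """
    if rank not in tax.columns:
        raise ValidationError(f"rank {rank!r} not in taxonomy table")
    terminals = list(terminals)
    absent = [t for t in terminals if t not in tax.index]
    if absent:
        raise ValidationError(f"terminals absent from taxonomy: {absent[:10]}")
    values = tax.loc[terminals, rank]
    dropped = [t for t, v in values.items() if pd.isna(v)]
    if dropped:
        logger.warning(
            "%d terminal(s) have no %s assignment and join no group: %s",
            len(dropped), rank, dropped[:5],
        )
    if len(dropped) == len(terminals):
        raise ValidationError(f"no terminal has a value at rank {rank!r}")
    groups: dict[str, set[str]] = {}
    for t, v in values.items():
        if pd.isna(v):
            continue
        groups.setdefault(str(v), set()).add(t)
    kept = [
        ConcordanceGroup(rank, name, frozenset(members))
        for name, members in sorted(groups.items())
        if len(members) >= min_size
    ]
    return MembershipMatrix(rank, terminals, kept)


def restrict(
    aln: Alignment, tree: dendropy.Tree, ids: set[str] | list[str]
) -> tuple[Alignment, dendropy.Tree]:
    """Induce the sub-alignment and subtree over ``ids``.

    Columns are untouched (A is a property of the full matrix); degree-2
    nodes created by pruning are suppressed.
    """
    ids = list(dict.fromkeys(ids))
    if not ids:
        raise ValidationError("cannot restrict to an empty id set")
    sub_aln = aln.subset(ids)
    keep = set(ids)
    taxa = [t for t in tree.taxon_namespace if t.label in keep]
    if len(taxa) != len(keep):
        found = {t.label for t in taxa}
        raise ValidationError(f"ids not on tree: {sorted(keep - found)[:10]}")
    sub_tree = tree.extract_tree_with_taxa(
        taxa=taxa, suppress_unifurcations=True
    )
    sub_tree.is_rooted = True
    # extract_tree can leave a degree-1 seed node; collapse it.
    while len(sub_tree.seed_node.child_nodes()) == 1:
        only = sub_tree.seed_node.child_nodes()[0]
        if only.is_leaf():
            break
        sub_tree.seed_node = only
        only.parent_node = None
    return sub_aln, sub_tree
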