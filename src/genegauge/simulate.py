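"""Coherent synthetic (tree, alignment, taxonomy) bundles with ground truth.

The generator plays the role of a curated multi-gene dataset: a pure-birth
(Yule) species tree, DNA evolved along it under JC69 or K2P with optional
gamma rate heterogeneity, and a four-rank taxonomy obtained by cutting the
ultrametric tree at increasing heights so that, before any perturbation,
every taxonomic group is exactly a clade of the generating tree.  A
controlled fraction of tips can then have their labels swapped pairwise
between genera to create known amounts of taxonomic incongruence, and
cells can be masked to missing.  Everything is reproducible from a single
seed, and the truth object records the generating tree, the unperturbed
taxonomy, the realised per-column substitution counts, and exactly which
tips were swapped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import (
    RANKS,
    Alignment,
    ValidationError,
    write_alignment,
    write_taxonomy,
    write_trees,
)

logger = logging.getLogger(__name__)

_NUC = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
# K2P transition partner of each state (A<->G, C<->T), as indices into _NUC
_TRANSITION = np.array([2, 3, 0, 1])


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    rank_depths are cut heights as fractions of total tree height measured
    from the tips: a small fraction cuts near the tips (many small genera),
    a large one near the root (few superfamilies); they must increase from
    genus to superfamily.  subst_rate is the expected number of
    substitutions per site per unit time on the Yule time scale.
    """

    n_species: int = 64
    seq_length: int = 600
    tree_model: str = "yule"
    birth_rate: float = 1.0
    subst_model: str = "JC69"
    subst_rate: float = 0.01
    kappa: float = 2.0
    gamma_shape: float | None = None
    homoplasy_free: bool = False
    rank_depths: dict[str, float] = field(default_factory=lambda: {
        "genus": 0.15, "subfamily": 0.35, "family": 0.55, "superfamily": 0.75,
    })
    perturb_fraction: float = 0.0
    missing_fraction: float = 0.0
    # block-missing: a contiguous run of columns masked for a random taxon
    # subset, emulating genes sequenced as non-overlapping fragments
    block_missing_fraction: float = 0.0
    block_missing_taxon_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValidationError("n_species must be >= 4")
        if self.seq_length < 1:
            raise ValidationError("seq_length must be >= 1")
        if self.tree_model != "yule":
            raise ValidationError(f"unknown tree model {self.tree_model!r}")
        if self.subst_model not in ("JC69", "K2P"):
            raise ValidationError(f"unknown model {self.subst_model!r}")
        if not 0.0 <= self.perturb_fraction <= 1.0:
            raise ValidationError("perturb_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValidationError("missing_fraction must be in [0, 1]")
        if not 0.0 <= self.block_missing_fraction <= 1.0:
            raise ValidationError("block_missing_fraction must be in [0, 1]")
        if not 0.0 <= self.block_missing_taxon_fraction <= 1.0:
            raise ValidationError(
                "block_missing_taxon_fraction must be in [0, 1]")
        depths = [self.rank_depths[r] for r in RANKS if r in self.rank_depths]
        if len(depths) != len(self.rank_depths) or any(
            b <= a for a, b in zip(depths, depths[1:])
        ):
            raise ValidationError(
                "rank_depths must cover known ranks with strictly increasing "
                "cut heights from genus to superfamily"
            )

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent streams per stage, all derived from the one seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("tree", "sequence", "perturb", "missing")
        return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


@dataclass
class ScenarioTruth:
    """Ground truth recorded alongside a generated bundle."""

    newick: str
    taxonomy_true: pd.DataFrame
    column_changes: np.ndarray
    perturbed_tips: list[str]


@dataclass
class Bundle:
    config: ScenarioConfig
    tree: dendropy.Tree
    alignment: Alignment
    taxonomy: pd.DataFrame
    truth: ScenarioTruth


def simulate_tree(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Pure-birth tree with n_species leaves, stopped at the last split.

    All tips are contemporaneous; each node carries a ``depth`` annotation
    (time from the root) used for rank assignment.  Tips are labelled
    t0001, t0002, ... in birth order.
    """
    rng = cfg.rngs()["tree"] if rng is None else rng
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    active = [root]
    t = 0.0
    while len(active) < cfg.n_species:
        t += rng.exponential(1.0 / (cfg.birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    height = t if cfg.n_species > 1 else 0.0
    # assign edge lengths and tip labels
    i = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        start = parent.split_time if parent is not None else 0.0
        end = getattr(node, "split_time", height)
        node.edge.length = end - start if parent is not None else None
        node.birth_time = start
        node.end_time = end
        if node.is_leaf():
            i += 1
            taxon = tns.new_taxon(label=f"t{i:04d}")
            node.taxon = taxon
    tree.height = height
    return tree


def _tree_height(tree: dendropy.Tree) -> float:
    h = getattr(tree, "height", None)
    if h is not None:
        return h
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def assign_taxonomy(tree: dendropy.Tree, cfg: ScenarioConfig) -> pd.DataFrame:
    """Clade-based taxonomy: cut the ultrametric tree at each rank's height.

    At cut height h above the tips, the groups are the subtrees hanging
    from the edges that span time (height - h); their leaf sets partition
    the tips and are clades of the tree by construction.  Cuts are nested,
    so genera nest within subfamilies and so on.
    """
    height = _tree_height(tree)
    ranks = [r for r in RANKS if r in cfg.rank_depths]
    records: dict[str, dict[str, str]] = {
        lf.taxon.label: {} for lf in tree.leaf_node_iter()
    }
    prefix = {"genus": "G", "subfamily": "SF", "family": "F",
              "superfamily": "SUF"}
    for rank in ranks:
        cut = height * (1.0 - cfg.rank_depths[rank])  # time from the root
        n_groups = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            # the path root->tip partitions [0, height); each tip's path
            # crosses the cut on exactly one edge
            if node.birth_time <= cut < node.end_time:
                n_groups += 1
                name = f"{prefix.get(rank, rank[:3].upper())}{n_groups:03d}"
                for lf in node.leaf_iter():
                    records[lf.taxon.label][rank] = name
        if n_groups == 0:
            # cut at or above the root: everything is one group
            n_groups = 1
            name = f"{prefix.get(rank, rank[:3].upper())}001"
            for lf in tree.leaf_node_iter():
                records[lf.taxon.label][rank] = name
        if n_groups == 1 and rank == "genus":
            logger.warning("genus-level cut yields a single group (degenerate)")
    df = pd.DataFrame.from_dict(records, orient="index")[ranks]
    df.index.name = "terminal"
    return df.sort_index()


def _gamma_multipliers(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.gamma_shape is None:
        return np.ones(cfg.seq_length)
    a = cfg.gamma_shape
    return rng.gamma(shape=a, scale=1.0 / a, size=cfg.seq_length)


def evolve_alignment(
    tree: dendropy.Tree,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, np.ndarray]:
    """Evolve sequences down the tree; returns (alignment, per-column counts).

    The root sequence is uniform over {A,C,G,T}.  Substitution events are
    placed as a Poisson process along each branch (rate subst_rate x
    optional per-column gamma multiplier); each event replaces the state by
    a different one (uniformly for JC69, transition-biased kappa:1:1 for
    K2P), so every counted event is a real change and the per-column event
    counts upper-bound the parsimony steps on the generating tree.

    In homoplasy-free mode each column instead changes exactly once, on a
    random internal edge subtending 2..n-2 tips, to a distinct state.
    """
    rngs = cfg.rngs()
    rng = rngs["sequence"] if rng is None else rng
    L = cfg.seq_length
    if L < 1:
        raise ValidationError("zero-length alignment requested")
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)

    changes = np.zeros(L, dtype=np.int64)
    seqs: dict[dendropy.Node, np.ndarray] = {}

    if cfg.homoplasy_free:
        root_states = rng.integers(4, size=L)
        eligible = [
            nd for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
            and 2 <= sum(1 for _ in nd.leaf_iter()) <= n - 2
        ]
        if not eligible:
            raise ValidationError("tree too small for homoplasy-free mode")
        rows = {lab: root_states.copy() for lab in labels}
        edge_pick = rng.integers(len(eligible), size=L)
        for c in range(L):
            node = eligible[edge_pick[c]]
            new = (root_states[c] + 1 + rng.integers(3)) % 4
            for lf in node.leaf_iter():
                rows[lf.taxon.label][c] = new
            changes[c] = 1
        data = np.stack([_NUC[rows[lab]] for lab in labels])
        aln = Alignment(labels, data)
    else:
        gamma = _gamma_multipliers(cfg, rng)
        seqs[tree.seed_node] = rng.integers(4, size=L)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            states = seqs[node.parent_node].copy()
            blen = node.edge.length or 0.0
            n_events = rng.poisson(cfg.subst_rate * blen * gamma)
            hit = np.nonzero(n_events)[0]
            for c in hit:
                for _ in range(int(n_events[c])):
                    cur = states[c]
                    if cfg.subst_model == "JC69":
                        states[c] = (cur + 1 + rng.integers(3)) % 4
                    else:  # K2P: transition with prob kappa/(kappa+2)
                        if rng.random() < cfg.kappa / (cfg.kappa + 2.0):
                            states[c] = _TRANSITION[cur]
                        else:
                            # one of the two transversion partners
                            tv = [s for s in range(4)
                                  if s != cur and s != _TRANSITION[cur]]
                            states[c] = tv[rng.integers(2)]
                changes[c] += int(n_events[c])
            seqs[node] = states
        data = np.stack([_NUC[seqs[lf]] for lf in leaves])
        aln = Alignment(labels, data)

    if cfg.missing_fraction > 0.0 or cfg.block_missing_fraction > 0.0:
        mrng = rngs["missing"]
        masked = aln.data.copy()
        if cfg.missing_fraction > 0.0:
            masked[mrng.random(aln.data.shape) < cfg.missing_fraction] = b"N"
        if cfg.block_missing_fraction > 0.0:
            width = int(np.floor(cfg.block_missing_fraction * L))
            n_taxa = int(np.floor(cfg.block_missing_taxon_fraction * n))
            if width and n_taxa:
                start = int(mrng.integers(L - width + 1))
                rows = mrng.choice(n, size=n_taxa, replace=False)
                masked[np.ix_(rows, np.arange(start, start + width))] = b"N"
        aln = Alignment(aln.ids, masked)
    return aln, changes


def perturb_taxonomy(
    tax: pd.DataFrame,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Swap taxonomy rows pairwise between tips of distinct genera.

    floor(perturb_fraction * n) tips are perturbed (rounded down to an
    even count); each swapped pair exchanges its full label row, so group
    sizes and the rank census are preserved exactly.
    """
    rng = cfg.rngs()["perturb"] if rng is None else rng
    k = int(np.floor(cfg.perturb_fraction * len(tax)))
    if k % 2 == 1:
        logger.info("perturbation count %d rounded down to %d", k, k - 1)
        k -= 1
    out = tax.copy()
    if k < 2:
        return out, []
    genus_col = out.columns[0]
    tips = np.array(out.index)
    order = rng.permutation(len(tips))
    chosen: list[str] = []
    pairs: list[tuple[str, str]] = []
    # greedy pairing of shuffled tips, skipping same-genus partners
    pool = list(order)
    while len(pairs) < k // 2 and pool:
        a = pool.pop(0)
        partner = None
        for j, b in enumerate(pool):
            if out.iloc[a][genus_col] != out.iloc[b][genus_col]:
                partner = pool.pop(j)
                break
        if partner is None:
            break
        pairs.append((tips[a], tips[partner]))
    for ta, tb in pairs:
        ra, rb = out.loc[ta].copy(), out.loc[tb].copy()
        out.loc[ta], out.loc[tb] = rb, ra
        chosen += [ta, tb]
    return out, sorted(chosen)


def simulate_bundle(cfg: ScenarioConfig) -> Bundle:
    """Generate a coherent (tree, alignment, taxonomy, truth) bundle."""
    rngs = cfg.rngs()
    tree = simulate_tree(cfg, rngs["tree"])
    aln, changes = evolve_alignment(tree, cfg, rngs["sequence"])
    tax_true = assign_taxonomy(tree, cfg)
    tax, perturbed = perturb_taxonomy(tax_true, cfg, rngs["perturb"])
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    truth = ScenarioTruth(
        newick=newick,
        taxonomy_true=tax_true,
        column_changes=changes,
        perturbed_tips=perturbed,
    )
    return Bundle(config=cfg, tree=tree, alignment=aln, taxonomy=tax,
                  truth=truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write alignment.fasta, tree.nwk, taxonomy.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "tree": outdir / "tree.nwk",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(bundle.alignment, paths["alignment"])
    write_trees([bundle.tree], paths["tree"])
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    cfg = asdict(bundle.config)
    truth = {
        "config": cfg,
        "newick": bundle.truth.newick,
        "taxonomy_true": bundle.truth.taxonomy_true.to_dict(orient="index"),
        "column_changes": bundle.truth.column_changes.tolist(),
        "perturbed_tips": bundle.truth.perturbed_tips,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
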