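# genegauge

Tools for deciding which gene regions are worth sequencing for molecular
phylogenetics. Given an aligned matrix, one or more cladograms over the
same terminals, and a reference taxonomy, `genegauge` quantifies a gene's
value on two axes:

- **Phylogenetic utility** — intrinsic properties of the matrix measured
  before any tree is inferred: aligned length *A*, variable characters
  *V*, parsimony-informative characters *PI*, the minimum number of
  character-state changes *M*, the character–taxon ratio *A/Gᵗ*, and the
  mean uncorrected pairwise distance *p*, all reportable per genus,
  subfamily, family and superfamily.
- **Phylogenetic signal** — measured after inference.
  *Character congruence*: the ensemble consistency and retention indices
  CI = *M/S* and RI = (*G−S*)/(*G−M*), where *S* is the tree length
  (minimum changes on the cladogram, Fitch/Hartigan counting) and *G* the
  greatest possible number of changes on any cladogram.
  *Taxonomic congruence*: named taxa become *concordance groups*, encoded
  as binary membership characters (1 = member, 0 = non-member) and scored
  on the tree; with *Mᵗ* test groups, *Sᵗ* the summed minimum number of
  clades each taxon exhibits, and *Gᵗ* terminals, the indices are the
  proportion of monophyletic taxa PMT, the taxon consistency index
  TCI = *Mᵗ/Sᵗ*, and the taxon retention index TRI = (*Gᵗ−Sᵗ*)/(*Gᵗ−Mᵗ*).
  All three equal 1 exactly when every taxon is recovered as a clade.

A synthetic-data module generates coherent (tree, alignment, taxonomy)
bundles — Yule trees, JC69/K2P sequence evolution, clade-derived nested
taxonomies, controlled label perturbation — with full ground truth, so
every measure is testable without downloading anything. See
`docs/methods.md` for the statistics, algorithms and their assumptions.

## Worked example

Simulate a 64-species bundle at moderate divergence in which 10% of tips
have had their taxonomy labels swapped between genera, then score it:

```python
import genegauge as gg

cfg = gg.ScenarioConfig(n_species=64, seq_length=600, subst_rate=0.016,
                        perturb_fraction=0.1, seed=42)
bundle = gg.simulate_bundle(cfg)

scores = gg.UtilityScores.from_alignment(bundle.alignment)
print(f"A={scores.A}  V={scores.V}  PI={scores.PI}  M={scores.M}  "
      f"A/Gt={scores.char_taxon_ratio:.2f}  p={scores.p_mean:.3f}")

for rank in gg.RANKS:
    mm = gg.build_membership_matrix(bundle.taxonomy, rank,
                                    sorted(bundle.taxonomy.index), min_size=3)
    sc = gg.taxon_congruence(bundle.tree, mm)
    print(f"{rank:12s} M_t={sc.M_t:2d}  S_t={sc.S_t:3d}  "
          f"PMT={sc.pmt:.3f}  TCI={sc.tci:.3f}  TRI={sc.tri:.3f}")
```

prints

```
A=600  V=313  PI=213  M=401  A/Gt=9.38  p=0.072
genus        M_t=10  S_t= 14  PMT=0.800  TCI=0.714  TRI=0.926
subfamily    M_t= 6  S_t= 14  PMT=0.500  TCI=0.429  TRI=0.862
family       M_t= 3  S_t=  3  PMT=1.000  TCI=1.000  TRI=1.000
superfamily  M_t= 2  S_t=  2  PMT=1.000  TCI=1.000  TRI=1.000
```

Reading it: 213 of 600 sites (36%) are parsimony-informative and the mean
pairwise divergence is 7.2%. Of the ten genera with ≥ 3 species, eight
are recovered as clades; the two broken genera account for the four extra
clades (*Sᵗ* = 14 vs *Mᵗ* = 10), giving TCI = 10/14 ≈ 0.71. The swaps
happen to fall within families here, so the two deepest ranks still score
a perfect 1. On an unperturbed bundle every index is exactly 1 at every
rank.

The same analyses are available from the shell:

```sh
genegauge simulate --config scenario.yaml --out bundle/
genegauge utility    --alignment bundle/alignment.fasta --taxonomy bundle/taxonomy.tsv --out utility.tsv
genegauge congruence --alignment bundle/alignment.fasta --tree bundle/tree.nwk --out ci_ri.tsv
genegauge signal     --tree bundle/tree.nwk --taxonomy bundle/taxonomy.tsv --out signal.tsv
genegauge census     --taxonomy bundle/taxonomy.tsv --out census.tsv
genegauge report     --config run.yaml --out report/
```

Every table is written as TSV with a JSON mirror; undefined indices are
reported as missing, never as zeros.

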