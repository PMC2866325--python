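# Methods

`genegauge` scores aligned gene regions on two axes: **phylogenetic
utility**, intrinsic properties of the aligned matrix measured before any
tree is inferred, and **phylogenetic signal**, measured after inference by
scoring characters — the matrix's own columns, or binary taxon-membership
characters derived from a reference classification — on cladograms. This
note describes the statistics, the algorithms behind them, the synthetic
data generator used for validation, and the numerical and design choices
that were genuinely open.

## Utility statistics

For an aligned matrix with `A` columns over `Gᵗ` terminals:

- `A` — aligned length (column count). A property of the whole matrix; it
  is never recomputed when rows are subset, and all proportions below are
  relative to this global `A`.
- `V` — number of variable columns: columns with at least two distinct
  unambiguous states.
- `PI` — parsimony-informative columns: at least two unambiguous states
  each carried by at least two terminals (variable columns that are not
  autapomorphies).
- `M` — tree-independent minimum number of character-state changes,
  `Σ_c max(0, k_c − 1)` with `k_c` the distinct unambiguous states in
  column `c`. For any tree `T`, `M ≤ length(T)`, and `PI ≤ V ≤ M ≤ 3A`.
- character–taxon ratio `A/Gᵗ`.
- `p̄` — mean uncorrected p-distance over all unordered pairs with
  pairwise deletion: only sites where both cells are unambiguous are
  compared; a pair with no comparable site is dropped with a warning.

**Missing-data convention.** Gaps (`-`), `N`, `?` and every IUPAC
ambiguity code are treated as missing for *all* statistics — they
contribute no state, no mismatch, and carry the full state set in
parsimony scoring. This matches common parsimony-software defaults and
keeps `V`, `PI`, `M` and `p̄` mutually consistent; the alternative
(crediting partial ambiguity matches) would make `PI` incomparable with
the step-count bound `M`.

**Rank-structured profiles.** Utility is also measured *within* taxa:
for every group at a rank (genus, subfamily, family, superfamily) with at
least `min_species` members (default 3), `V`, `PI`, `M` are recomputed on
the row-restricted sub-matrix and the per-rank summary is the unweighted
mean of the per-group proportions. The mean is across groups, not pooled
across species — pooling would weight large genera and is a different
statistic.

## Parsimony engine

Minimum changes of a character on a tree are computed by a single
bottom-up dynamic program: Hartigan's frequency rule. At a node with `d`
children, each state is scored by the number of child state-sets that
contain it; the states attaining the maximum count `k` form the node's
set and `d − k` changes are added. For bifurcating nodes this reduces
exactly to the Fitch intersection/union rule. Missing leaves carry the
full state alphabet and can never force a change. The pass is vectorised
across alignment columns with 4-bit state-set masks, so scoring a
600-column matrix on a 64-tip tree is a single sweep of small numpy
operations per node.

**Polytomies are scored as given.** Hartigan's rule yields the minimum
number of changes on the multifurcating tree itself: a star tree with
tip states 0,0,1,1 costs 2, whereas any resolved tree carrying the same
split costs 1. This is the semantics checked by the exhaustive
internal-state enumeration oracle in the test suite. The alternative —
minimising over all binary resolutions of each polytomy ("resolve for
free") — is *not* what the engine computes; when trees come from a
search that collapses unsupported branches, scores on a polytomous
consensus are therefore conservative (never smaller than on any
resolution's best case, and possibly larger).

**Step counting is rooting-invariant** (re-rooting an unrooted topology
never changes the count), so CI/RI and the clade counts below do not
depend on where a basal trifurcation was rooted; only the explicit
monophyly flag does (see below).

Per character three counts are kept: `m` (minimum on any tree, =
states − 1), `s` (minimum on the given tree), and `g` (maximum on any
tree, = non-missing leaves minus the modal state's count, attained on the
star). The ensemble indices over the variable characters are

    CI = Σm / Σs        RI = (G − S) / (G − M)

with `S = Σs`, `M = Σm`, `G = Σg`. Invariant characters are excluded by
default (each contributes 0/0); `include_invariant` exposes the
alternative. `CI` is undefined (reported missing, never zero) when
`S = 0` and `RI` when `G = M`.

A small exhaustive tree search (`exhaustive_min_steps`, all `(2n−5)!!`
unrooted binary topologies, `n ≤ 8`) is provided purely as a desk-scale
oracle; the package performs no heuristic tree search.

## Taxonomic congruence

Each named taxon with enough species is a *concordance group*, encoded as
a binary membership character (1 = member, 0 = non-member). On a tree:

- `sᵗ` (clade count) = `max(1, steps of the membership character)`: the
  minimum number of clades the taxon resolves into. The clamp handles
  the degenerate all-terminals group, whose character is invariant.
- monophyly flag: some node's exact leaf-descendant set equals the member
  set. Rooted convention by default — a group's complement is not
  accepted as the group; the unrooted "clan" reading is behind a flag.

With `Mᵗ` test groups, `Sᵗ = Σsᵗ`, and `Gᵗ` terminals in the matrix:

    PMT = #monophyletic / Mᵗ     TCI = Mᵗ / Sᵗ     TRI = (Gᵗ − Sᵗ) / (Gᵗ − Mᵗ)

All three equal 1 exactly when every group is a clade; `TRI` is undefined
when `Gᵗ = Mᵗ`. `Gᵗ` is the terminal count of the scored tree, not the
sum of group sizes (they coincide when the rank partitions the
terminals).

**A consistency caveat.** `TCI = 1 ⟺ PMT = 1` holds whenever every
group is smaller than half the leaf set — which every realistic
concordance group is. A *majority* group whose complement is a buried
clade has `sᵗ = 1` (the character fits the unrooted tree in one split)
while failing the rooted monophyly test; the per-group output reports
both quantities so such cases are visible. Similarly, `sᵗ` is the
character's parsimony length, which can be smaller than the count of
maximal member-only subtrees when a member-dominated region contains a
non-member island (a reversal is cheaper than separate origins); the
parsimony reading is the one the index formulas are built on.

With several equally parsimonious input trees the default report is the
across-tree mean, with per-tree rows and min/max always retained; a
strict-consensus row is optional. Per-taxon CI/RI profiles are computed
on induced subtrees of the supplied tree (leaf restriction with
degree-two suppression), since separately inferred subtrees are not
available to a scorer.

## Synthetic data generator

The generator emulates a curated multi-rank, single-gene datamatrix:

- **Tree**: pure-birth (Yule) with `n_species` tips (default 64, birth
  rate 1/time-unit), stopped at the last speciation, so tips are
  contemporaneous and node depths are meaningful. Extinction is omitted:
  tree-shape realism adds parameters no measure here exploits.
- **Taxonomy**: the ultrametric tree is cut at four heights (fractions of
  total height above the tips, defaults genus 0.15 < subfamily 0.35 <
  family 0.55 < superfamily 0.75); the subtrees hanging below each cut
  are the groups. Every group is therefore exactly a clade of the
  generating tree, cuts are nested, and group sizes partition the tips.
- **Sequences**: root drawn uniformly; substitution events placed as a
  Poisson process along each branch at `subst_rate` per site per time
  unit (default 0.01), each event an actual state change (JC69 uniform,
  or K2P with transition probability κ/(κ+2)); optional per-column gamma
  rate multipliers and uniform or block missing-data masking. The truth
  object records realised per-column event counts, which upper-bound the
  parsimony steps on the generating tree. A homoplasy-free mode instead
  changes each column exactly once on a random internal edge (clade size
  2..n−2), making `CI = RI = 1` on the generating tree by construction.
- **Perturbation**: `⌊perturb_fraction·n⌋` tips (rounded down to an even
  count) swap their entire taxonomy rows pairwise between distinct
  genera. Swapping rather than reassigning preserves every group size
  and the rank census, isolating congruence degradation from census
  change.
- **Determinism**: all four stages draw from independent streams spawned
  from the single scenario seed; identical configs give byte-identical
  FASTA/Newick/TSV output.

What the generator does *not* emulate: gene-tree/species-tree
discordance, indels and alignment error, rate variation across lineages,
non-clade (paraphyletic) named taxa, and the uneven taxon sampling of
mined databases. Passing recovery tests therefore shows the measures are
computed correctly and respond to controlled incongruence — not that any
particular real gene will score well.

## Problem sizes and numerical choices

- Validation uses 16–64-tip trees and 10–600-column matrices; the
  exhaustive oracles run at ≤ 7–8 leaves where the enumeration spaces
  (internal labelings, `(2n−5)!!` topologies) are trivial.
- The moderate-divergence demonstration uses the 64-tip default with
  `subst_rate = 0.016`: the expected Yule total tree length is
  `Σ_{k=2..64} k · E[epoch_k] = 63` time units, roughly half of it on
  internal edges, so the expected informative-substitution load per
  column is ≈ 0.016·63/2 = 0.50 and the predicted informative fraction
  `PI/A ≈ 1 − e^{−0.50} ≈ 0.40`, the middle of the 0.30–0.50 range
  reported for moderately divergent genes. The registered check is the
  10-seed mean within ±0.06 of that prediction.
- Undefined ratios (CI with `S = 0`, RI with `G = M`, TRI with
  `Gᵗ = Mᵗ`) propagate as missing values, never as zeros; means are
  taken over defined values only.
- Identifier matching between files is exact string equality after
  whitespace trimming; silent fuzzy matching would corrupt congruence
  scores.
- Trees are scored as read. A trifurcating Newick root is kept as a
  rooted basal polytomy; an outgroup flag reroots on a named leaf's
  pendant edge. Step counts are unaffected by the choice; only the
  rooted monophyly flags can differ.

## Known limitations

- No NEXUS/PHYLIP input, no alignment, no database fetching, no
  heuristic tree search at scale, no branch support, no model-corrected
  distances, no plotting: reports are tables.
- Single-character soft-polytomy scoring (minimising over resolutions)
  is not implemented; see the polytomy note above.
- `sᵗ` on trees with polytomies inherits the as-given scoring: a group
  scattered across an unresolved node counts each origin, which is the
  conservative reading.
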