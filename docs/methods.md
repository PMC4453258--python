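# Methods

## The problem

Fossil-rich clades such as Crocodyliformes accumulate their diversity in
bursts: a handful of subclades radiate in restricted time intervals
rather than the whole group diversifying continuously. Detecting those
bursts from a dated taxon phylogeny — without branch lengths, using only
tree shape and stratigraphic first appearances — is what this package
implements: nested-growth time slicing with ghost-lineage inference,
per-branch shift detection against the equal-rates Markov (ERM / Yule)
null, and a rule separating genuine radiations from extinction
artefacts. An MRP supertree stage assembles the input topology from
overlapping source trees when no single published tree covers the group.

## Nested-growth time slicing

Taxa are binned into an ordered series of stratigraphic intervals
(default: the ten composite intervals Carnian–Aalenian … Pliocene–Recent,
oldest first; bins are categorical, no numeric ages are used). A taxon
recorded in several intervals, or of uncertain age, is scored by its
oldest record (FAD = minimum bin index).

For each bin *t* the slice tree contains every taxon with FAD ≤ *t*;
each maximal clade of the full tree whose members all have FAD > *t* is
collapsed to a single **ghost leaf** — one inferred lineage, regardless
of the clade's later diversity, labeled by its lexicographically
smallest member so identity is stable across bins. Because taxa are
added and never removed, the series simulates speciation but not
extinction; the final slice is the full tree. A classic (non-nested)
variant that drops taxa whose range [FAD, LAD] does not overlap the bin
is provided for comparison.

Slices with fewer than two non-ghost taxa are skipped with a warning;
the series starts at the first bin with at least two occurring taxa.

Representing a collapsed clade as a single leaf (rather than its full
membership) prevents future diversity from leaking into an earlier
bin's tree shape; this is the package's resolution of an ambiguity in
the method's published descriptions and is deliberately conservative.

## The shift statistics

Under the ERM null every lineage splits at the same rate, so the size of
a designated daughter of an *n*-tip clade is uniform: P(i | n) = 1/(n−1).
The two-rate alternative treats the focal clade and its sibling as
independent pure-birth processes with rate ratio ρ; conditional on the
parent's tip count *m*, the focal size *k* then follows the tilted
geometric P(k | m, ρ) = ρ^(k−1) / Σ_{j=1..m−1} ρ^(j−1), which recovers
the ERM value at ρ = 1. With L1(k|m) = sup_ρ P(k | m, ρ):

- Δ₁(b) = log L1(k|m) + log(m−1) ≥ 0 — support for a rate shift on
  branch *b* from the parent-node diversity partition alone;
- Δ₂(b) = Δ₁(k|m) − Δ₁(max(l,r)|k), where l, r are the focal clade's
  daughter sizes — support for a *stem* shift over the rival hypothesis
  of a nested shift inside the focal clade.

The ML tilt ρ̂ solves E_ρ[J] = k−1 (J tilted on 0..m−2), a monotone
one-dimensional root found by bracketed bisection; the balanced split
gives ρ̂ = 1 exactly by symmetry. At the boundary (k ∈ {1, m−1}) the
supremum log L1 = 0 is used exactly, with no regularization. Pendant
branches (k = 1) have Δ₂ = 0 by convention; the scan scores internal
branches only.

## Monte-Carlo significance

Soft polytomies are resolved by ERM-style sequential random joins
(uniform over pairs; each rooted resolution of a trichotomy has
probability 1/3), and Δ₁/Δ₂ are averaged over a sample of resolutions
(100 by default; already-bifurcating trees need none and are seed
invariant). Null trees are ERM topologies of the same tip count, built
by uniform random joins; ghost leaves count as ordinary tips.

- `p_tree` — fraction of null trees whose *maximum* Δ₂ anywhere meets or
  exceeds the branch's Δ₂ (familywise control; the headline criterion,
  default α = 0.05).
- `p_local` — the same with the maximum restricted to branches whose
  focal clade falls in the same log2 size class (diagnostic).

Both use the (1 + exceedances)/(1 + N) estimator, so no p-value is ever
exactly zero. Defaults are desk scale (1 000 null trees, 100
resolutions); production budgets are configuration options. All
randomness flows from one seed, with documented per-bin stream
splitting, so reruns are byte-identical.

### Known limitation: localization and power

Calibration is nominal (the tree-wide test rejects at ≈ α on pure Yule
trees; the suite asserts the exact binomial 95% CI at n = 64). Power
and localization against a single planted two-rate shift are, however,
intrinsically weak at desk scale: a boundary split (k = m−1) hands any
branch Δ₁ = log(m−1), so the null maximum grows like log n; the shifted
clade is internally ERM, so its own top split is uniform and the
nested-shift discount often moves support one level down; and ancestors
of the stem with small sibling clades carry comparable statistics,
smearing the signal along the path to the root. In measured simulations
(n = 128, ×5 shift, shifted clade ≈ half the tips), the minimal-p branch
is the true stem or an adjacent branch in roughly a quarter of
replicates, and familywise power at α = 0.05 is below 0.2 even at ×10 —
though power is monotone in the rate ratio. Deterministic detection is
achievable when the shifted clade is internally balanced (Δ₂ ≈ log(m−1)),
which is how the worked examples and integration tests are constructed.
Real-data results based on this statistic should therefore be read as
conservative: reported shifts are strongly supported; absence of a shift
is weak evidence of absence.

## Tracking and the artefact rule

Every slice tree is a collapse of one full tree, so a significant slice
clade (ghost representatives expanded to the clades they collapse) maps
to a unique stem node of the full tree; detections at different bins
sharing that stem are one shift record. Records may be punctual
(detected then lost in later bins).

A record first detected at bin *t* is **genuine** iff its older-taxon
fraction — members with FAD < *t* over members with FAD ≤ *t*, ghosts
excluded from both counts — does not exceed the threshold (default 10%,
boundary counts genuine). The denominator is the shift clade's own
occurring richness, not the whole tree's: the rule is applied
clade-by-clade. A high older-taxon fraction means the apparent
imbalance is better explained by extinction of lineages outside the
clade than by elevated speciation within it. The genuine set is monotone
in the threshold. The rule is quantitative only; it does not attempt the
qualitative fossil-record judgments a practitioner may add.

## MRP supertree stage (optional)

Source trees are coded Baum–Ragan style (one binary column per non-root
internal node: members 1, other taxa present 0, absent taxa missing;
constant columns dropped; duplicate trees act as weights). The matrix is
searched by random-addition + branch-swapping parsimony (NNI, SPR, or
TBR = SPR with rerooting of the pruned clade; first-improvement,
deterministic neighbor order, ties keep earlier trees). Missing states
are the full state set and never add length. Columns are polarized by
their source tree's rooting: the search scores Fitch length with the
root constrained to state 0, which is equivalent to the classic
hypothetical all-zero outgroup; the plain (rooting-invariant) Fitch
score is also exposed, and an explicit all-zero outgroup taxon is a
config switch. Defaults are desk scale (100 replicates, hold 5, TBR);
production-scale settings (10 000 replicates, hold 20) are reachable by
configuration, but the search is stochastic and not a general-purpose
engine.

Rogue taxa are pruned greedily: repeatedly delete the taxon whose
removal most increases the number of resolved nodes in the strict
consensus of the leaf-pruned tree set, reporting each removed taxon's
alternative attachment positions. This is a reduced-consensus
re-implementation of the iterative positional-congruence approach, not
a line-for-line port: the observable contract (identify taxa whose
floating positions destroy resolution) is what is reproduced. Finally,
a resolved crown-group subtree can be grafted over its placeholder
terminal in the backbone (combined leaf count = backbone − 1 + crown).

## The synthetic generator

The generator produces exactly the structures the analysis assumes, so
every stage is testable without literature-compiled data:

- **Yule chronograms** — Gillespie pure birth at rate λ (default 1.0 per
  lineage-time), stopped at `n_tips` total tips and extended by one
  further exponential waiting time so the present falls strictly inside
  the n-tip interval. Root daughter sizes verify against the uniform
  ERM law.
- **Planted shifts** — when the growing tree reaches `select_at_tips`
  extant lineages, the node whose extant-descendant count is closest to
  `tip_fraction` of the standing diversity is selected; descendants
  thereafter speciate at `multiplier × λ` (and die at a clade-restricted
  death rate if set, the feedstock for extinction-artefact scenarios).
  Choosing `tip_fraction` small selects a single lineage, which places
  the rate change exactly on the stem branch of the final shifted
  clade. For the n = 128 power study the settings (selection at 28
  tips, single lineage, ×5) follow from the pure-birth growth
  arithmetic that makes the expected final share of the shifted clade
  about half the tips. Extinct lineages are retained as fossil tips.
- **Fossil sampling** — finds are a Poisson process (rate ψ, default 2.0
  per lineage-time) along each taxon's terminal branch (whole
  root-to-tip path as a flag); FAD/LAD are the bins of the oldest and
  youngest find. Unsampled taxa fall back to the bin of their tip time
  and are flagged (or dropped on request) so tree and age table always
  align. Lower ψ lengthens ghost lineages and skews FADs young, as it
  should.
- **Source trees** — induced subtrees on random leaf subsets
  (`coverage` fraction) perturbed by random NNI moves, for supertree
  tests.

What the generator does **not** emulate: rock-record sampling bias
through time (no correction exists within this framework), correlated
fossilization across taxa, taxonomic error in tip identity, and
morphological character evolution. Passing tests on synthetic data
therefore demonstrate internal correctness of the machinery and its
statistical calibration, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale study sizes
chosen as this package's own defaults: calibration at n = 64 with 200
trees and 1 000 null trees per scan; power/recovery at n = 128 with 100
replicates per rate multiplier, sharing one 1 000-tree null sample per
multiplier across equal-sized replicates; oracle equivalences at ≤ 8
taxa (exhaustive parsimony) and ≤ 12 leaves (subset-scan ghost oracle).
The tilted-ML root is solved to 1e-12 bracket tolerance and matches a
200 001-point grid search to 1e-6. Ties in maximum Δ₂ break toward the
larger focal clade, then lexicographic clade order. Degenerate slices,
empty bins, and star source trees warn or error as documented rather
than silently proceeding.
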