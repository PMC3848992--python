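# Methods

This note documents the models implemented in `phyloniche`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user auditing results will want to
know.

## Single-threshold mixed Yule–coalescent delimitation

**Model.**  The input is a rooted, binary, ultrametric specimen tree with
node ages measured as height above the tip plane (units are taken as given
— substitutions/site for a clock tree with mean rate fixed, or relative
time; no rescaling is attempted).  A threshold age *T* classifies each
internal node: nodes older than *T* are between-species diversification
events, nodes at or below *T* are within-species coalescences.  Every
branch crossing *T* defines one delimited entity; the subtree below it is a
coalescent cluster (entities with a single specimen are singletons).  A
branch that crosses *T* remains a species-level lineage until its first
coalescence, so un-coalesced entity stems and singleton branches continue
to contribute to the diversification process below the threshold.

Between successive node ages, the census of the tree is constant and the
waiting time is modelled as exponential with total rate

    b_i = lam_div * k_i^p_div  +  lam_coal * sum_j n_ij * (n_ij - 1)^p_coal

(`k` = species-level lineages, `n_j` = lineages in cluster `j`).  The
scaling exponents generalize the two canonical processes: `p_div = 1` is a
Yule process, `p_coal = 1` a neutral coalescent, and departures capture
rate acceleration or deceleration.  The log-likelihood is the density of
the pooled inter-event waiting times,

    logL(T) = sum_i [ log b_i  -  b_i * x_i ],

with every slice paired with the branching event at its older end.  Two
useful collapses fix the conventions: a tree with no clusters reduces to
the Yule likelihood `sum [log(lam k) - lam k x]`, and a two-specimen
cluster of depth *t* contributes `log(2 lam_coal) - 2 lam_coal t` at
`p_coal = 1`.  Slices of zero duration (tied node ages) contribute only
their event term, processed in fixed node order.

Formulating the likelihood on the pooled waiting times (the total rate in
the event term, not the per-component rate) is essential for fair model
comparison: per-component event terms either mix a forward-time and a
backward-time reading (which structurally favours the coalescent
classification) or compare densities over different outcome spaces (a
per-cluster model is a density of event times *and* their allocation to
clusters; the single-process null is a density of pooled times only).
Either defect makes the no-structure model spuriously win even on strongly
separated data.  With the pooled form, all thresholds and the null live on
the same outcome space.

**Fitting.**  Candidate thresholds are the midpoints between successive
distinct node ages plus both boundaries (all-diversification at `T = 0`;
all-coalescent above the root).  At each candidate the four parameters are
maximized by L-BFGS-B on `(log lam_div, log lam_coal, p_div, p_coal)` with
analytic gradients, bounds `log lam in [-25, 25]`, `p in [-3, 3]`, and five
deterministic exponent starts `(1,1), (0.5,1.5), (1.5,0.5), (0,2), (2,0)`
with method-of-moments rate initialization (events / exposure).  The fit is
deterministic; candidates on which the optimizer fails are excluded with a
warning.

**Inference outputs.**  The confidence set collects candidates within 2
log-likelihood units of the maximum and is summarized as the [min, max]
range of entity counts.  The null model — a single uniform coalescent-type
branching process for the whole tree — equals the mixed model at the
above-root boundary candidate, so `LR = 2(logL_max - logL_null) >= 0` by
construction; its p-value is read from chi-square with `df = 3` by default
(one extra rate, one extra exponent, the profiled threshold), configurable.

**Known limitation (measured).**  Because the LR maximizes over ~n−1
candidate thresholds and *T* is not a regular parameter, the null
distribution of the statistic is stochastically larger than chi-square(3):
on 300 simulated single-population coalescent trees of 40 tips the test at
nominal 5% rejected 14% of the time (null 95th percentile ≈ 9.8 vs 7.8 for
chi-square(3)).  The df is reported rather than claimed exact; users who
need a calibrated test should simulate their own null reference.  On
structured data the test is decisive regardless (LR in the hundreds on the
default fixture), and entity recovery is unaffected: on 50 simulated
20-species × 4-specimen trees with an enforced separation factor of 5, the
true species count fell in the 2-logL confidence set in 100% of replicates
and the ML threshold inside the true gap in ≥ 94%.

## Parsimony, resolutions and phylotypes

Fitch parsimony is computed by the classic bottom-up set pass (score =
number of union events), with unit-cost Sankoff dynamic programming behind
the ACCTRAN/DELTRAN resolutions: top-down, each node may take any state
that keeps the subtree cost minimal given its parent; ACCTRAN takes a
non-parent state whenever one is free (changes accelerate toward the root),
DELTRAN keeps the parent state whenever it is optimal (changes delay toward
the tips).  Both therefore realize exactly the Fitch minimum.  Ties among
equally optimal states are broken toward the state most frequent among the
node's subtree tips, then by vocabulary order — a pure vocabulary-order
tie-break would make reconstructions (and phylotype null distributions)
depend on the arbitrary ordering of state labels.  Tips with missing states
are pruned for that character's reconstruction rather than treated as a
state.  Transition counting defaults to ACCTRAN.

A **phylotype** rooted at internal node *v* with state *s* is the set of
tips whose entire path to *v* (tip included) carries *s*.  Scores:

- **Size** — number of members;
- **Different** — number of maximal embedded subtrees whose root carries
  another state;
- **Persistence** — number of consecutive internal-node generations below
  *v* in which *every* internal node retains *s*; counting stops at the
  first generation containing no internal nodes, and a lineage that simply
  runs out of internal nodes does not cap its ancestors.  (The original
  phylotype software does not publish its exact semantics; this definition
  is fixed here for testability and reproduces the structure of published
  tables, e.g. a monophyletic 4-tip clade has Persistence 1.)
- **coverage** — percent of all tips bearing *s* that are members.

Default selection criteria: Size ≥ 3 (mandatory), Size/Different ≥ 1
(Different = 0 passes), Persistence ≥ 1, and a support mask admitting only
phylotype roots with support ≥ 80 (nodes without a support value pass).
Retained phylotypes are maximal: a candidate whose root lies inside a
retained phylotype of the same state is absorbed.

**Shuffle significance.**  Tip states are permuted (state frequencies
fixed), reconstruction and phylotype search are re-run with identical
criteria, and two p-values are reported with both the raw fraction and the
`(count+1)/(n+1)` correction: per state, the fraction of shuffles
containing a criteria-passing same-state phylotype at least as large as the
observed one; and for the parsimony score, the fraction of null scores at
or below (conservatism) or at or above the observed count.  All
reconstruction paths — observed and null — run through one vectorized
engine that processes hundreds of permutations at once, so 1000 iterations
on a ~60-species tree take well under a second.  Nested same-state
candidates never exceed their enclosing candidate's size, so the null
existence check can skip the absorption step.

One behaviour worth knowing: a state near 50% frequency whose phylotype
spans the root is weakly discriminating — ACCTRAN backbones connect
scattered same-state tips through the root in a nontrivial fraction of
shuffles, so such phylotypes earn honestly large p-values even when the
observed configuration is perfectly clustered.  Clustered *minority* states
are detected sharply (p ≈ 0.004 for a monophyletic 8-of-20 state), and the
parsimony-score conservatism test is sensitive in both situations.  The
permutation machinery is valid by construction: under tree-independent
labels the corrected p-values rejected at 5% in ≤ 2% of 100 replicates
(phylotype and score tests alike).

## Niche coding and shift statistics

An ecological niche is the combination of a species' host-plant species set
and feeding-site set (shoot / branch / trunk).  Two species overlap only
when both components intersect simultaneously; niche ids are the connected
components of that overlap graph.  Species whose removal disconnects their
component (articulation points) are *bridges* — one species joining two
otherwise disjoint niches — and are handled by policy: `components`
(default, one id per component), `split` (the bridge receives one id per
part it connects), or `sister` (the bridge adopts the part containing its
cherry partner, when one exists).  Species with empty host or feeding-site
data are excluded with a warning.

The proportion of lineage splits accompanied by a niche shift is the
parsimony transition count of the niche character divided by the number of
internal nodes (tips − 1); sister-pair statistics count cherries whose two
species share no niche id.

## Range overlap versus divergence time

For every internal node the two daughter clades' present-day zone sets
(unions over member species, eight-zone vocabulary by default) either
intersect (overlap = 1) or not.  Cosmopolitan species expand to the full
vocabulary under the default `expand` policy, or keep a private token /
user-supplied area of origin under `origin`.  The binary overlap is
regressed on node age by maximum-likelihood logistic regression
(statsmodels IRLS) with a Wald test on the slope.  All internal nodes enter
by default (a support filter is available, off by default).  Complete or
quasi-complete separation on the single covariate is detected directly
(non-interleaved age ranges of the two response classes) and flagged, with
no p-value reported; an optional hand-rolled Firth (Jeffreys-penalized)
fit, off by default, yields finite estimates under separation.  All-0 or
all-1 responses return a degenerate result with flags rather than an
exception.

**Calibration caveat.**  Tree-independent *tip* ranges do not make the
node-level overlap response independent of node age: older nodes subtend
larger clades whose zone unions almost surely intersect, so even "random"
ranges produce a genuinely positive overlap–age association at clade level
(slope > 0 in 100/100 replicates).  The size of the slope test is therefore
assessed under an explicitly enforced independence null — overlap values
permuted across nodes — where it rejected 3.5% of 200 replicates at
nominal 5%; the allopatric-with-expansion scenario yielded a positive slope
in ≥ 99% of 200 replicates at ~40 internal nodes.  Interpreting the
clade-level regression on real data carries the same confound; the usual
reading (overlap increases with time since divergence) is directional, not
causal.

## Synthetic-data generators

The generators reproduce the statistical structure the analyses assume, at
the scale of a medium-sized insect radiation study:

- **Species tree**: Yule with birth rate 1.0 (time units are arbitrary;
  all analyses are scale-equivariant), default 56 species.
- **Specimens**: zero-truncated geometric with mean 4 clipped at 18
  specimens per species — a typical "1 to many colonies per species"
  sampling profile.
- **Within-species genealogies**: single-population coalescents with
  expected pairwise time `coalescent_depth_scale`, grafted so the tree
  stays ultrametric.  Heights are resampled until the deepest within-species
  node is below `min_speciation_age / separation_factor` (default factor 5
  in the fixture; scale auto-set to 5% of that limit), which makes the
  single-threshold model identifiable and gives every recovery test an
  unambiguous truth.  Real data need not have such a gap; passing recovery
  tests demonstrate correctness of the machinery under the model's own
  assumptions, not robustness to gene flow, varying population sizes, or
  rate heterogeneity, none of which are simulated.
- **Characters**: symmetric k-state Markov jumps along branches; the
  realized number of change events is recorded as ground truth (parsimony
  can only undercount it).  Fixture rates are set so the *expected*
  transition counts on the species tree are ~10 for the conservative
  7-state host-genus character and ~17 for the labile 3-state feeding-site
  character — the conserved-vs-labile contrast that drives the
  phylotype analyses.  Host species are drawn from per-genus pools (6 per
  genus, 1–3 per species) so niches show realistic partial overlaps.
- **Ranges**: allopatric mode partitions the parent's zone set disjointly
  at every split, sized in proportion to descendant tip counts (so
  daughters never run short of zones while the vocabulary can cover their
  tips; with too few zones, daughters share the parent set and are flagged
  sympatric at birth), then expands each lineage at `expansion_rate` per
  unit time (fixture default 1.0).  Random mode draws each tip's zone set
  independently (inclusion probability 0.25 — a mean range of two of eight
  zones, typical of range-restricted taxa).

All randomness derives from a single master seed through named substreams
(`seed`, CRC32 of the stage name), so stages are independently reproducible
and fixture outputs are byte-identical under a fixed seed.

## Pipeline

`phyloniche all` executes delimit → prune (one random representative per
entity, seeded) → character/phylotype analyses → niche coding → overlap
regression, writing per-stage TSV/JSON, a machine-readable `report.json`, a
human summary, and a MANIFEST with SHA-256 checksums of every file.  Stage
failures abort with the stage name; completed stages and their outputs
remain recorded.  Species-level states are aggregated from specimen
annotations per delimited entity (set-valued fields by union, scalar fields
by majority).  Defaults mirror standard practice for this analysis family:
Size = 3, Size/Different = 1, Persistence = 1, support > 80 mask, 1000
shuffles, 2-logL confidence sets, chi-square df = 3.

## Problem sizes used in the shipped experiments

The acceptance experiments use 50 replicates for delimitation recovery
(20 species × 4 specimens), 100 single-population trees of 40 tips for LR
calibration, 500 random instances (≤ 8 tips, ≤ 3 states) for the exhaustive
parsimony cross-check, 100 replicates × 1000 shuffles for permutation
validity, 200 replicates for overlap size and power, and the 56-species
fixture (~220 specimens) for the end-to-end run — sizes chosen to keep
Monte-Carlo error a few percentage points while the whole battery completes
in about a minute on one CPU.
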