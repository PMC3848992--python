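# phyloniche

**Is speciation in a clade driven by ecology or by geography?**  `phyloniche`
is a post-phylogeny analysis pipeline for answering that question from an
ultrametric specimen tree plus per-specimen ecological and geographic
annotations — the situation of a host-specialised insect radiation (e.g.
conifer-feeding aphids) sampled with several colonies per morphospecies.  It
chains four analyses that are usually run with separate, hard-to-script
tools, and ships a simulation module that generates complete synthetic
studies with known truth, so every stage is testable end to end.

## What it computes

1. **Species delimitation** (`phyloniche.gmyc`) — the single-threshold
   generalized mixed Yule-coalescent (GMYC) model.  Branching events on the
   ultrametric tree are classified as between-species diversification or
   within-species coalescence on either side of an age threshold *T*.  Each
   inter-event slice *i* of the tree waits an exponential time with total
   rate

   *b<sub>i</sub>* = λ<sub>div</sub>·k<sub>i</sub><sup>p<sub>div</sub></sup> +
   λ<sub>coal</sub>·Σ<sub>j</sub> n<sub>ij</sub>(n<sub>ij</sub>−1)<sup>p<sub>coal</sub></sup>,

   where *k* counts species-level lineages and *n<sub>j</sub>* the lineages
   inside coalescent cluster *j*; log L = Σ<sub>i</sub> [log *b<sub>i</sub>* −
   *b<sub>i</sub>x<sub>i</sub>*].  The threshold is profiled over midpoints
   between distinct node ages; the fit reports the delimited entities
   (clusters + singletons), a 2-logL confidence range of entity counts, and
   a likelihood-ratio test against the single-process coalescent null.
2. **Character history and phylotypes** (`phyloniche.charevo`) — Fitch
   parsimony with ACCTRAN/DELTRAN resolution; transition counts per
   character; *phylotypes* (sets of taxa sharing one state along every path
   to a common root node) scored by Size, Persistence, Different and
   coverage, with significance from shuffling tip states (1000 iterations)
   and a parsimony-score conservatism test against the same null.
3. **Niche coding** (`phyloniche.charevo.code_niches`) — ecological niches
   as connected components of the simultaneous-overlap graph (species share
   a niche only when host-plant species *and* feeding sites both intersect),
   bridge-species policies, the proportion of lineage splits accompanied by
   a niche shift, and sister-pair niche overlap counts.
4. **Geographic overlap vs divergence time** (`phyloniche.geodiverge`) —
   per-node binary overlap of the daughter clades' zone sets against node
   age, fitted by logistic regression (Wald test on the slope, separation
   detection, optional Firth penalization).  Under prevalent allopatric
   speciation the slope is positive: young splits are allopatric, old ones
   have re-expanded into sympatry.
5. **Synthetic studies** (`phyloniche.simulate`) — Yule species trees with
   per-species coalescent tip clusters and an enforced separation gap,
   Markov characters with recorded realized transition counts, allopatric
   or tree-independent geographic ranges, and a complete 56-species fixture
   profile.

## Worked example

Simulate a 56-species study (≈220 specimens) and run the whole chain:

```bash
cat > study.toml <<EOF
[simulate]
enabled = true
n_species = 56
EOF
phyloniche all --config study.toml --out results --seed 7
```

which prints:

```
phyloniche pipeline summary
===========================
delimitation: 56 entities (40 clusters, 16 singletons), CI [56, 56], threshold age 0.004816, LR p = 1.04e-247
character host_genus: 10 transitions, 5 phylotypes, score p_low = 0.000999
character feeding_site: 12 transitions, 4 phylotypes, score p_low = 0.000999
character continent: 24 transitions, 3 phylotypes, score p_low = 0.208
niches: 17 niches, 25 transitions, 45% of splits with a shift, 9/20 sister pairs with non-overlapping niches
overlap ~ age: slope 2.82 (p = 0.00999), 10/20 sister pairs with non-overlapping ranges
```

Reading the numbers: the delimitation recovers exactly the 56 simulated
species (40 multi-specimen genetic clusters plus 16 singletons) with a
decisive rejection of the one-species null; the host-genus character is
strongly conserved (10 transitions across 55 splits, fewer than any of 1000
shuffles — `score p_low ≈ 0.001` — with high-coverage phylotypes such as

```
state        coverage_pct  size  p_value  persistence  different  size/different
Pseudotsuga  100.0         35    0.358    2            7          5.0
Picea        66.7          4     0.011    1            0          inf
```

); only 45% of lineage splits are accompanied by an ecological-niche shift;
and range overlap between daughter clades increases significantly with node
age (positive slope, p ≈ 0.01), the signature of geography-driven
speciation with secondary range expansion.  Per-stage outputs (entity
table, fit JSON, phylotype tables, null-score histograms, overlap records,
MANIFEST with checksums) land in `results/`.

The same analyses are available as library calls
(`gmyc.fit_single_threshold`, `charevo.shuffle_test`, `charevo.code_niches`,
`geodiverge.fit_overlap_logistic`, ...) and as per-stage subcommands
(`simulate`, `delimit`, `characters`, `niches`, `overlap`, `report`).

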