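# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions and the open design choices behind `spnkit`.

## Hot/cold spot model

For marker *m* in compartment *c*, let *k* be its LOH/AI count among *n*
informative calls, and let the background rate *b* be the pooled LOH/AI
fraction of all **other** eligible markers on the same chromosome in the same
compartment (leave-one-out pooling, not an average of per-marker
frequencies — pooling weights each sibling marker by its informativeness).
The spot test is the two-sided exact binomial test of (k, n) against *b*:
hot when the frequency exceeds *b* with p < α, cold when below with p < α
(α = 0.05 per marker, no multiplicity correction by default; a
Benjamini–Hochberg mode could be layered on the returned raw p-values).
The detector sits behind a single function (`spots.exact_binomial_p`) so an
alternative model can be swapped in.

Markers with fewer than `min_informative` (default 10) informative calls are
excluded and reported; a chromosome with a single eligible marker has no
contrast, so its marker is classed `none` with p = NaN. Because *b* is
estimated from siblings rather than known, the test is only approximately
calibrated; with ~16 sibling markers × ~85 informative samples the background
estimate is precise enough that the empirical per-marker false-call rate
stays at the nominal level (checked by simulation in the acceptance suite).
A strong genuine hot spot inflates its chromosome's pooled background and can
make quiet neighbors look cold; this is inherent to any same-chromosome
contrast and is visible in end-to-end runs.

Sharing bookkeeping: a marker is *shared* when it receives the same hot/cold
class in both compartments; a marker hot in one compartment and cold in the
other is counted in both compartment-only cells and logged as a conflict.
CPF (clinicopathological-feature) markers are an external input; one that is
also hot/cold is flagged both but counted once, under its hot/cold cell.

## Marker→gene windows

Gene intervals are BED-convention 0-based half-open; marker positions are
0-based points. A gene maps to a marker when its interval overlaps the
closed window [pos − w, pos + w] (w = 250 kb by default, clipped at zero).
Overlap — rather than gene-midpoint or TSS distance — is the most inclusive
defensible reading and keeps the mapping monotone in w. The implementation
is a per-chromosome sorted sweep (searchsorted over gene starts, bounded by
the maximum gene length); an O(n·m) double loop is kept in the test suite as
the oracle. Genes mapping to several markers stay duplicated in the map for
marker-level traceability and are de-duplicated only when seed sets are
formed.

## Weighted network and segment search

Edge weight: `w = β₁·reliability + β₂·|r| + β₃·J` with β = (0.4, 0.4, 0.2)
by default; *r* is the Pearson coexpression of the two genes across all
samples (computed only for requested edges) and *J* the Jaccard index of
annotation-term sets (0 when either set is empty). When *r* is undefined
(missing gene, < 3 shared samples, zero variance) the remaining weights are
renormalized — a missing measurement is not a penalty. Edges between
localization-incompatible proteins (no shared compartment and not adjacent in
the order extracellular–membrane–cytoplasm–nucleus) are removed.

A pathway segment is a simple path of ≤ `max_segment_length` (default 6)
edges whose endpoints are seed genes, whose first node can sit at the
membrane (or extracellular space), whose last node can sit in the nucleus,
and whose compartment assignment is nondecreasing along the path. Validity
is decided by a greedy minimal assignment (take the lowest feasible
compartment at each step), which is exact: keeping the assignment minimal
preserves every continuation any other assignment would allow. Scores are
the geometric mean of edge weights — length-normalized so longer chains are
not penalized multiplicatively — and invariant to path reversal; a path and
its reversal count once.

Significance: the null for a k-edge segment is the score distribution of B
(default 1000) random localization-valid simple walks of k edges started at
random membrane-capable nodes, seed status ignored; p = (1 + #{null ≥
observed}) / (B + 1), so p is never 0 and bottoms out at 1/(B+1). Ties count
against the observed score; in the degenerate all-equal-weights network every
null ties and nothing is retained. Segments with p < α (default 0.01) are
merged into the compartment's signaling pathway network: nodes red when
inside a hot-spot window, blue when cold, pink for recruited intermediaries
(a gene in both a hot and a cold window is colored red and logged); edges red
for r > 0, green for r < 0, gray when r is undefined; dashed style marks
predicted interactions.

Under exchangeability the retention probability of a null segment at α = 0.01
with B = 999 is exactly 9/1000 (the add-one rule's discreteness); the
acceptance suite checks this on i.i.d.-weight graphs with randomly assigned
seeds.

## Global test

For an n-samples × m-genes matrix X (genes centered across samples) and a
binary outcome y with mean μ and residual e = y − μ:

    Q = e′ (X X′ / m) e / (μ(1 − μ))

i.e. the average over genes of the squared covariance between gene expression
and the outcome residual, on a scale where gene count cancels (duplicating
every gene leaves Q unchanged). Q is invariant to gene order and to adding a
constant to any gene. Inference is by permuting y (B default 999, add-one
rule); the report carries the observed Q, the permutation mean (Expected Q)
and sd (sd of Q), the group size (Genes) and the number of genes actually
present in the matrix (Tested). The classical formulation of this statistic
is written in terms of generalized-linear-model residuals; for a binary
outcome the quadratic form above is that score statistic, and it is exactly
testable against a brute-force double loop, which the test suite does.

Seven standard gene groups are assembled per run: the two compartments'
window genes, the two SPN gene sets, the SPN intersection, and the
hot/cold-window subset of each SPN.

## Clustering and coherence

Expression is z-normalized per sample (mean 0, population sd 1; a constant
sample is an error). Both axes are clustered by average-linkage
agglomeration on 1 − Pearson r; the linkage method is configurable since the
original procedure's choice is not documented. *Coherence* is the adjusted
Rand index between the sample dendrogram cut at k = number of distinct
labels and the labels themselves; "disarray" of a gene set is thus 1 −
coherence. `coherence_vs_random` compares a group's coherence against
n_random size-matched gene sets sampled without replacement from the
interaction universe, with an add-one empirical p.

## Synthetic-data generator

The generator emulates the bicompartmental study design the pipeline
targets, and its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 122 | patients, each with epithelium + stroma samples |
| n_chromosomes × markers_per_chromosome | 22 × 17 | ≈374 microsatellite markers |
| intermarker_cM / bp_per_cM | 9 / 1e6 | ~9 cM (~9 Mb) marker spacing |
| informative_prob | 0.7 | germline heterozygosity per (patient, marker) |
| background_loh_rate | 0.15 | LOH/AI rate away from planted spots |
| hot_rate / cold_rate | 0.5 / 0.02 | planted spot rates |
| gene_density_per_100kb | 1.0 | homogeneous Poisson gene placement |
| ppi_nodes / ppi_mean_degree | 300 / 4 | preferential-attachment background graph |
| background_reliability | 0.3 | background edge reliability (planted: 0.9) |
| r_path | 0.7 | planted coexpression magnitude along paths |
| normal_fraction / label_shift | 0.2 / 1.0 | tumor-panel class mix and factor shift |
| n_samples | 60 | expression panel size |
| outcome_effect | 2.0 | log-odds of sensitivity per unit pathway activity |

Informativeness is a free parameter (the emulated study reports none), not an
estimate. Genotype draws are independent across patients and compartments; a
"shared" planted spot raises the rate in both compartments but never couples
the draws, keeping the null clean for calibration tests.

Expression uses a latent factor per planted path. Each path gene loads with
magnitude √r_path and a random per-gene sign, so planted-edge correlations
are ±r_path — mirroring real signaling chains, where activating and
inhibitory interactions give both positively and negatively coexpressed
edges. The signs are essential, not cosmetic: with equal positive loadings
the factor is constant across the gene axis and per-sample Pearson centering
removes it exactly, making the planted structure invisible to 1 − r sample
clustering. In the tumor panel the factor is shifted between tumor and
normal samples by `label_shift` and renormalized to unit variance (so |r|
stays exactly r_path); planted genes therefore carry gene-specific signed
tumor-vs-normal shifts — most down, some up — and the labels are recoverable
from the planted structure. In the cell-line panel the factor is unshifted
and the sensitive/resistant outcome is drawn per sample by a logistic model
on the first path's factor (the pathway's latent activity);
`outcome_effect = 0` yields labels independent of expression, the type-I
null.

What the generator does **not** emulate: linkage disequilibrium or spatial
correlation between markers, informativeness varying by marker or
compartment, copy-number-driven expression dosage at hot spots, batch
effects, heavy-tailed expression noise, or interaction false
positives/negatives structured by study bias. Passing tests therefore show
the machinery is correct and calibrated under a clean factor model, not that
effect sizes on real arrays would match.

## Determinism and seeds

One root seed fans out per stage through numpy `SeedSequence.spawn`, so
stages are independently reproducible; every stochastic routine takes an
explicit `Generator` or seed. Identical (config, params, seed) reproduce
every output file hash; the run manifest records config, per-stage seeds,
artifact SHA-256 digests, timings and library versions. Tie-breaks are
lexicographic on gene/marker ids everywhere (segment ordering: score
descending, then node ids), so outputs are independent of input order.

## Problem sizes in the validation suites

The acceptance checks use, as the package's own choices: 200 background-only
seeds for spot-caller calibration and 100 for power (one 17-marker
chromosome, 122 patients); 1000-gene random instances for window-mapping
equivalence and 20 Poisson tracks for growth linearity; 100 random graphs of
≤ 30 nodes for search/enumeration identity, 50 replicates (120-node
networks, 200-sample panels, B = 999) for planted-path retention and 30
i.i.d.-weight graphs for null calibration; 200 null panels and 100 panels
per effect size (40 samples, B = 199) for the global test; 20 seeds × 30
random sets for clustering coherence; and two full pipeline runs for
determinism. The acceptance script scales a few counts down (30 retention
replicates, 100 calibration seeds) while keeping the same conditions.

## Known limitations

- The spot test conditions on an estimated background; its exactness is
  marginal, not conditional, and neighboring markers of a strong hot spot
  can be shadowed cold.
- The segment null (random walks from membrane-capable starts) ignores the
  endpoint-seed and nucleus-end constraints of observed segments; scores are
  exchangeable only because weights are independent of topology, which is an
  assumption about the inputs, not a theorem about real networks.
- Whether the original segment threshold was per-segment or family-wise is
  unknown; p-values here are per-segment and uncorrected.
- The global test here is the binary-outcome quadratic form; survival
  outcomes (the statistic's other classical use) are out of scope.
- Known-pathway edges are modeled as reliability-1 inputs rather than a
  trained interaction scorer; homology-based edge prediction is out of scope
  (predicted edges are carried through as dashed annotations only).
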