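# Methods

`soilfungnet` analyses sample × OTU read-count matrices collected across a
soil depth profile: a grid of depth classes × horizontal positions ×
replicate cores, sequenced with uneven per-sample effort. This note
documents the models, the numerical choices, and what the synthetic-data
experiments do and do not establish.

## Preprocessing chain

Raw replicate-level counts pass through a fixed chain:

1. **Replicate merging** — replicate cores of the same (depth class,
   horizontal position) are summed cellwise. Replicates are treated as
   poolable technical draws from one position's community; no
   replicate-level effect is modelled. Positions with a missing replicate
   keep whatever exists, with a logged warning.
2. **Low-count OTU filtering** — OTUs with fewer than 10 reads in total
   are removed (likely PCR/sequencing artefacts). The boundary is
   inclusive: a column total of exactly 10 survives.
3. **Negative-control OTU removal** — any OTU with ≥ 1 read in a
   negative-control sample is removed from every sample, then the control
   rows are dropped. This runs *after* the low-count filter; the order is
   configurable in principle but fixed in the pipeline driver so that the
   reported OTU counts are comparable across runs.
4. **Rarefaction** (diversity branch only) — each position is subsampled
   without replacement to exactly 1000 reads (one multivariate
   hypergeometric draw per row, one seed per run recorded in the report);
   positions with fewer than 1000 reads are dropped, as are OTUs left
   with zero reads everywhere.
5. **Per-depth prevalence filtering** (network branch only) — at each
   depth, OTUs present (≥ 1 read) at one-third or more of the retained
   positions are kept. The fraction is compared as an exact rational:
   with 47 positions the threshold 47/3 = 15.67 means 16 occurrences.

Routing is deliberate and runtime-asserted: richness, habitat preference
and all distance-based tests consume the **rarefied** matrix; network
inference consumes the **unrarefied** merged counts, because equalising
totals by subsampling distorts the count-magnitude information that
compositional correlation estimators rely on. Network inference defaults
to the three shallowest depth classes, where enough positions retain
adequate sequencing depth.

## Habitat preference (HP)

For depth class *i* and OTU *j*, N_obs(i, j) is the number of depth-*i*
samples in which the OTU occurs (presence/absence, not read counts). The
null shuffles the depth-label vector over samples uniformly; then

HP(i, j) = [N_obs(i, j) − mean(N_rand(i, j))] / sd(N_rand(i, j)).

Positive HP is preference, negative is avoidance. Cells invariant under
relabelling (OTU present everywhere or nowhere) have sd = 0 and are
defined as HP = 0, p = 1. p-values are two-sided by default (both
preference and avoidance are of interest), with the add-one convention
(1 + exceedances)/(1 + permutations) and ties counted as exceedances;
q-values are Benjamini–Hochberg over the pooled depth × OTU family.

Two numerical points:

* Under uniform shuffles each cell's null is exactly hypergeometric, so
  the null *mean* is n_i·K_j/n in closed form. The two-sided exceedance
  comparison centres deviations on this analytic mean rather than on the
  Monte-Carlo mean: occurrence counts are integers, the analytic mean
  frequently falls exactly midway between two integers, and centring on
  a noisy mean estimate would flip entire probability atoms in or out of
  the rejection region. Reported null means and sds remain the
  Monte-Carlo ones.
* `exact_habitat_preference` enumerates every distinct assignment of the
  depth-label multiset (refusing instances beyond 10⁶ assignments) and
  reports exact proportions as p-values (the observed assignment is part
  of the enumeration, so no add-one correction applies). It is the
  oracle against which the sampler is tested, and its moments are
  cross-checked against the hypergeometric closed form.

## Beta-diversity and distance-based tests

**Raup–Crick dissimilarity.** Each null replicate rebuilds every sample
by drawing its observed richness from the OTU pool without replacement,
with selection probabilities proportional to OTU occupancy. The
dissimilarity for a pair is P(null shared > observed) + ½·P(tie),
estimated over `n_null` replicates: 0 means far more shared than chance,
1 far less. Weighted sampling without replacement uses exponential sort
keys, vectorised across samples; zero-richness samples get the
uninformative value 0.5 with a logged warning. A signed [−1, 1] variant
(2p − 1) is available by flag. The randomisation estimator is tested
against exhaustive enumeration of weighted assemblages on a 4-sample,
6-OTU toy.

**PERMANOVA.** Anderson's distance-based pseudo-F via the Gower-centred
inner-product matrix G: F = [tr(HG)/m] / [tr((I−H)G)/(n−m−1)] with H the
hat matrix of the predictor design. Depth enters as a single numeric
predictor by default (model df = 1, matching the convention of treating
the profile as a gradient); categorical coding is a flag. p-values
permute predictor values over samples. The statistic is verified against
a raw sums-of-squared-distances oracle, against exhaustive relabelling
on 6 samples, and against scikit-bio's implementation (categorical
mode); type-I error is checked over 200 null simulations.

**PERMDISP.** Samples are embedded by principal-coordinates analysis;
axes with negative eigenvalues are retained as imaginary components
whose squared contributions are subtracted from squared distances to the
group centroid (clamped at zero) — standard practice for non-Euclidean
dissimilarities like Raup–Crick. The one-way F on centroid distances is
permuted over group labels with the distances held fixed. Groups of size
1 are excluded with a warning; k groups give (k−1, n−k) df.

**Mantel correlogram.** Pairwise horizontal distances are binned into
equal-width classes (Sturges' rule on the pair count unless a class
width or count is given). Per class, the Mantel r between community
dissimilarity and class membership is permuted (sample-order
permutations of the community matrix); classes with < 2 pairs are
omitted. Reported p-values carry a progressive Holm correction (class k
corrected within classes 1..k), the conventional correlogram treatment.
Progressive correction controls the familywise rate only approximately;
the calibration test bounds the observed null familywise rate
accordingly rather than at the nominal level.

## Co-occurrence estimators

**Log-ratio basis correlations (SparCC-style).** For each Dirichlet
resample (posterior draw with a +1 pseudocount per cell), pairwise
log-ratio variances t_ij = Var(log x_i/x_j) are computed; basis
variances ω solve the linear system Σ_{j∈J_i} t_ij = |J_i|·ω_i +
Σ_{j∈J_i} ω_j implied by the sparsity assumption; basis correlations are
ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j)). Each resample iteratively
excludes the single strongest pair with |ρ| above the exclusion
threshold (default 0.1, up to 10 iterations) from the averaging and
re-solves. The final estimate is the elementwise median over 20
resamples, clamped to [−1, 1]. Signed networks take edges at
|ρ| ≥ 0.4 (boundary inclusive).

**Neighbourhood selection (MB-style).** Counts are CLR-transformed
(log(count+1) minus the row's mean log); each OTU is lasso-regressed on
all others over a log-spaced penalty grid (10⁻³…1, 30 points). The
penalty is chosen by StARS-style stability selection: edge-selection
frequencies over random subsamples give a mean instability 2θ(1−θ) per
penalty; after monotonisation from the sparse end, the weakest penalty
with instability ≤ 0.05 is used and the model refitted on all samples.
The subsample size follows the stability-selection convention — 80% of
samples for n ≤ 144, 10√n for larger n — so that subsamples remain
genuinely perturbing as n grows. Edges follow the OR rule by default
(AND available); signs come from the averaged coefficients.

Two caveats established empirically and reflected in the test design:

* CLR values of OTUs that are absent from most samples collapse onto the
  (negated) sample mean log, creating spurious conditional-dependence
  hubs among rare OTUs. This is why the estimators' input contract is a
  prevalence-filtered matrix and why the network benchmark uses deep,
  even sequencing (20 000 ± lognormal-0.5 reads), isolating estimator
  behaviour from count noise.
* A planted truth consisting only of direct strong pairs makes the
  marginal-correlation graph minimal, so the conditional graph cannot be
  sparser. The benchmark therefore plants *triads* A–B–C with adjacent
  correlation 0.8 and the indirect 0.64 that positive-definiteness
  requires: the 0.4-cutoff correlation graph contains all nine planted
  links while neighbourhood selection prunes the indirect ones —
  reproducing the observation that the conditional method is the more
  conservative and further compartmentalises modules.

## Modules

A module is a connected component of the positive network with ≥ 2
induced edges. Components with exactly one edge and isolated nodes are
reported as non-module residue. This is an edge-count reading of
"sub-communities with two or more positive links": the alternative
per-node-degree reading would exclude open triads that are visibly
clusters. No statistical modularity optimisation is attempted — these
networks are too fragmented for it. Summaries count guild and
lowest-rank taxonomy labels from user-supplied annotations
("unassigned"/"unidentified" when missing).

## Synthetic data generator

Each sampling position carries a latent basis abundance vector
exp(b_j + e_{d(p),j} + ε_p) with per-OTU baselines b_j ~ N(0, σ_base),
depth-preference offsets e, and per-position fluctuations ε_p that are
multivariate normal with unit-free scale σ_sample and a correlation
matrix encoding planted association pairs (validated positive definite
at build time). Observed counts are independent multinomial draws per
replicate from the position's basis composition, with per-replicate
totals lognormal(log 3000, 1.2); a configured fraction of positions
(default 40%) is forced below the 1000-read rarefaction threshold to
exercise sample dropping — the emulated design retains roughly 300 of
500 positions.

Defaults σ_base = 3.0, σ_sample = 2.0 were chosen to reproduce realistic
summaries of depth-profile fungal data at the emulated scale: ~90 OTUs
per 1000-read position (of ~1000 total), a long rare tail, and one to a
few hundred OTUs passing the per-depth prevalence filter. Estimator
benchmarks deliberately use tamer spreads (σ_base = 1.5, σ_sample = 1.0)
and plant effects on prevalent OTUs: association recovery is only
meaningful for taxa that survive the prevalence filter, and planted
pairs on effectively-absent OTUs measure count noise, not the estimator.
The generator adds `sample_log_sd` as an explicit field because a
correlation between per-sample fluctuations is undefined without a
dispersion scale.

What the generator does *not* emulate: spatial autocorrelation along the
horizontal axis beyond depth structure, replicate-level effects,
taxonomy-correlated abundance structure, and sequence-level artefacts
(chimeras, index hopping). Tests passing on this generator therefore
validate the statistical machinery, not field-data robustness.

## Problem sizes and determinism

The default full-pipeline configuration mirrors the emulated design
(10 depths × 50 positions × 2 replicates, ~1000–1200 OTUs). Permutation
counts are configurable; the bundled end-to-end test runs the
study-shaped pipeline with 300 permutations per test, 150 Raup–Crick
nulls, 10 SparCC resamples and 8 stability repetitions, completing in
about two minutes on one CPU, and verifies byte-identical reruns. Every
stochastic stage receives a child seed spawned from one master seed via
`numpy.random.SeedSequence`, all recorded in the run manifest; outputs
contain no timestamps, so a rerun with the same manifest reproduces all
output bytes.

## Known limitations

* The SparCC-style estimator's null distribution inherits plain sampling
  noise: with D OTUs and n samples the largest absolute null estimate
  concentrates near √(2 ln(D(D−1)/2))/√n (~0.15 for 50 OTUs at n = 500).
  The 0.4 edge cutoff sits far above this, but individual null estimates
  above 0.1 are expected, not a defect.
* Progressive Holm correction in the correlogram is conventional, not
  exact familywise control (see above).
* The exact HP enumerator is exponential in sample count and refuses
  instances beyond 10⁶ assignments; it exists as an oracle, not an
  analysis path.
* p-values can never fall below 1/(n_perm + 1); significance claims at
  very small q require raising `n_perm` accordingly.
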