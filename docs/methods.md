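# Methods

This note documents the models behind `islandrad`, the choices made where
the design was genuinely open, and what the synthetic-data generators do
and do not emulate.

## Time axis and tree model

All ages are in Ma before present (0 = present, increasing into the past).
Trees are rooted, binary and ultrametric with an absolute tolerance of
1e-6 Ma on root-to-tip depths; dating software emits rounding jitter well
below this, and an optional `stretch_tips` flag absorbs slightly larger
jitter by extending terminal branches to the maximum depth. Trees failing
the tolerance are rejected rather than silently repaired.

## Benthic δ18O → temperature

Deep-ocean temperature is reconstructed pointwise from benthic δ18O. The
default conversion is the linear ice-free deep-ocean form **T = 12 −
4·δ18O** (°C per ‰). Published calibrations differ (linear, quadratic and
piecewise forms are all in use), so the conversion is a `ConversionSpec`
value recorded in the provenance of every converted series and swappable
without touching downstream code. Downstream statistics depend on the
curve only through its shape, so the default mainly fixes scale and sign.

Smoothing is non-overlapping bin averaging anchored at age 0 (a 1-Ma
window yields one point per Ma at bin midpoints), not a running mean;
this reads a "smoothed in 20-kyr / 1-Ma windows" record as interval
aggregation and keeps the operation idempotent and order-independent.
Interpolation onto analysis grids is linear, and extrapolation beyond the
record's span is an error rather than a guess.

## Time-varying birth–death likelihood

Three nested models of the speciation rate λ(t) on a dated tree:
constant; `time_exp`, λ(t) = λ0·e^(αt); and `temp_exp`,
λ(t) = λ0·e^(α·T(t)) for a paleotemperature curve T. Extinction is μ0
(optionally also exponential in the driver via β; off by default, since
the variable-speciation model is the scientific focus). A single global
sampling fraction f enters as ρ-sampling; the default f = 24/36 mirrors a
radiation with 24 of 36 putative species sampled. Clade-specific sampling
fractions are intentionally not supported — a documented simplification.

The reconstructed-tree likelihood is conditioned on the crown age and on
both crown lineages being represented in the sample (no conditioning on
tip count). Writing r(t) = ∫₀ᵗ(λ−μ)ds and A(t) = 1/f + ∫₀ᵗ e^(r(s))λ(s)ds,
the probability that a lineage alive at age t leaves no sampled
descendant is E(t) = 1 − e^(r(t))/A(t) — the exact solution of the usual
Riccati ODE — and each observed branch (t_c, t_p) contributes

    r(t_p) − r(t_c) + 2[log A(t_c) − log A(t_p)],

plus log λ at each non-root internal node, n·log f at the tips, and
−2·log(1−E(T)) for the conditioning. Everything therefore reduces to two
cumulative trapezoid integrals evaluated once per likelihood call on a
dense grid; the trapezoid rule is kept deliberately — higher-order rules
are unstable on the near-duplicate knots the piecewise shift model
inserts at the jump. Node ages, and the shift age for the piecewise
model, are added to the grid so kinks are integrated exactly. Grid
resolution is the accuracy knob; the test suite verifies
the implementation against closed forms (Yule, constant birth–death) to
1e-8 on a dense grid and against a 100× finer grid for the time-varying
case.

ML fitting is bounded L-BFGS-B over (log λ0, α, log μ0[, β]) with
multi-start (one Yule-heuristic start plus seeded random starts); ties
are broken toward the smaller parameter-vector norm. AICc uses
k = number of free parameters and n = number of tips. Akaike weights are
the usual softmax of −ΔAICc/2.

### Posterior sampling

A deliberately simple single-regime random-walk Metropolis sampler over
(log λ0, α, log μ0) replaces multi-regime reversible-jump machinery; the
rate-shift question is answered separately by an explicit 0-vs-1-shift ML
comparison. Priors are wide and documented: log λ0 ~ N(log 0.1, 1.5²),
α ~ N(0, 1²), log μ0 ~ N(log 0.05, 1.5²). Four chains, 10% burn-in,
proposal-scale adaptation during burn-in only (so the chain is Markovian
afterwards), thinned to at least 9,000 retained draws by default. Split-R̂
and a positive-sequence ESS are reported; low ESS warns rather than
fails. Each retained draw carries λ(t) on a shared age grid.

### Single-shift test

The shift model is piecewise-constant speciation with constant extinction;
the shift age is profiled over a uniform grid of candidates (default 24
between 5% and 95% of the crown age) with the two rates and μ re-optimised
at each candidate. The shift is called significant when ΔAICc > 2 in its
favour (k = 4 vs k = 2, the shift age counted as a parameter). This is an
explicit, reproducible stand-in for posterior-odds-based shift detection.
On simulated trees with λ jumping 0.1→0.4 at 10 Ma (40–130 tips) the
shift is detected within ±3 Ma in ≥70% of replicates, with ≤~10% false
positives on Yule trees — at the cost that the pre-shift rate is often
biased low, a known pathology of reconstructed-tree inference.

## Rate–paleoclimate correlation

For every posterior draw, the λ(t) trajectory is correlated with
paleotemperature resampled onto the draw grid, both series oriented
past→present. Besides Pearson's r, the detrended cross-correlation
coefficient ρ_DCCA(n) handles nonstationarity: both demeaned series are
integrated into profiles; overlapping boxes of length n (step 1) are
linearly detrended; ρ_DCCA is the ratio of summed residual cross-products
to the geometric mean of summed residual squares. It is exactly 1 (−1)
for y = ax + b with a > 0 (a < 0). Box sizes default to a geometric grid
of six sizes from 4 to len/4; the per-draw headline coefficient is the
median over box sizes, with per-size values also reported. Draws with
flat trajectories (zero variance) have no defined coefficient and are
excluded with a logged count.

A two-sided one-sample Student's t test asks whether the mean coefficient
across draws differs from zero. Posterior draws are not independent, so
this p-value is anti-conservative by construction; the sampler's ESS is
reported alongside so readers can judge the effective replication. This
mirrors the common practice the pipeline supports and is documented
rather than "fixed".

## DEC(+J)(+X) historical biogeography

Ranges are non-empty subsets of the ordered area list (bitmasks); the
default state space keeps all 2⁴−1 = 15 subsets of the four archipelagos.
Anagenetic evolution: range R expands into area b at rate
Σ_{a∈R} d·m_ab with m_ab = (dist_ab/dist_ref)^(−x), and loses one area at
rate e — only multi-area ranges may contract, so there is no absorbing
null range. This differs from the classical formulation that includes an
empty range reachable from single-area states; the consequence here is
exact conservation of probability over tip-range datasets (handy for
validation) at the cost of a slightly lower effective extirpation
pressure on single-area ranges. dist_ref is the geometric mean
off-diagonal distance, which makes d's scale distance-free and x
identifiable.

Cladogenesis enumerates, per ancestor: sympatry (single-area ancestors),
subset sympatry and single-area vicariance (multi-area ancestors), all
with equal base weight 1, plus founder events (+J) in which one daughter
jumps to an available single area b outside the range with weight
j·(Σ_{a∈R} m_ab)/|R| — the distance kernel deliberately applies to
founder dispersal as well as anagenetic dispersal, as one consistent
convention. Probabilities are normalised per ancestor.

Island emergence stratifies time: HIMI at 22 Ma and the PEI at 0.475 Ma
by default. No state containing an island may exist before its
emergence. Branches are segmented at stratum boundaries; per-stratum
transition matrices (eigendecomposition of the ≤15×15 rate matrix, with
an `expm` fallback when the eigenbasis is ill-conditioned) are composed
oldest→youngest. Because emergence only ever adds areas forward in time,
every state valid in an older stratum remains valid in younger ones; a
projection rule (renormalising mass from a newly invalid state onto its
largest valid subsets) is implemented for completeness but can only fire
if an area were ever to submerge.

The likelihood uses Felsenstein pruning with cladogenetic mixing at
nodes and a uniform root prior over root-stratum states (switchable). ML
fitting is bounded multi-start L-BFGS-B with d, e ∈ [1e-6, 5],
j ∈ [0, 2.9], x ∈ [0, 5]. Likelihoods of DEC, DEC+J, DEC+X and DEC+J+X
are reported side by side without a cross-model statistical test.
Marginal ancestral-range probabilities come from an exact outside/inside
(down/up) pass, verified against constrained enumeration.

### Stochastic mapping

Each iteration samples the root state from its posterior, a cladogenetic
event per node from its exact conditional, branch endpoint states per
stratum segment from the conditional transition kernels, and the
anagenetic path within each segment by endpoint-conditioned
uniformization (jump count from the conditioned Poisson mixture, then a
discrete bridge). Events are tallied as anagenetic dispersals
(source→destination; the source area within a multi-area range is
attributed proportionally to the distance kernel), founder dispersals,
extirpations, and cladogenetic types; "total dispersal" is anagenetic
plus founder. Node-state frequencies over 5,000 maps agree with the
pruning marginals to within 3 Monte-Carlo standard errors, and a
single-branch expected-count check validates the path sampler.

## SNP population structure

All statistics use alternate-allele counts of biallelic diploid loci with
per-locus pairwise deletion of missing genotypes (a locus needs ≥2
non-missing genotypes in every population involved).

* **Diversity**: H_o is the observed heterozygote fraction; H_e is the
  small-sample unbiased 2p(1−p)·2n/(2n−1); F_IS = 1 − mean(H_o)/mean(H_e)
  over polymorphic loci (ratio of averages); monomorphic-only populations
  have undefined F_IS, reported as missing.
* **F_ST**: Weir–Cockerham θ (default) and Hudson, both multilocus
  ratio-of-averages; negative multilocus values are truncated to 0 in
  headline matrices with raw values retained. The two estimators agree to
  < 0.02 on balanced simulations, and recover a Balding–Nichols target of
  F = 0.3 to within ±0.03.
* **Fixed differences**: loci at which the observed allele sets of two
  populations are disjoint (missing genotypes ignored) — evidence of zero
  contemporary gene flow.
* **HWE**: the conditional exact test (probability of the heterozygote
  count given allele counts, summing outcomes no more probable than
  observed), Bonferroni-corrected within each population over its
  testable loci; loci flagged in ≥2 populations are reported separately.
  The test is super-uniform under the null (≤6% rejections at α = 0.05).
* **PCoA**: Gower double-centering and eigendecomposition; percent
  variance uses positive eigenvalues only, with negative eigenvalues
  reported. The default individual distance is 1 − proportion of shared
  alleles over non-missing loci.
* **Mantel / partial Mantel**: Pearson correlation over upper-triangle
  entries; p = (1 + #{|r*| ≥ |r|})/(perms + 1) under joint row/column
  permutation (default 9,999 permutations, seed mandatory). The partial
  test correlates residuals of both matrices regressed on the covariate,
  permuting the first matrix. Type-I error is within (0.03, 0.07) at
  α = 0.05 for i.i.d. random symmetric matrices; for distances embedded
  in a low-dimensional space the permutation test is conservative, which
  is the known behaviour of Mantel tests, not a defect.
* **Outlier/ancestry analyses are not reimplemented**; the pipeline
  accepts an optional locus-exclusion list instead.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of parameters + seed (byte-identical
reruns; child seeds derived from the given seed).

* **Climate**: a piecewise-linear Cenozoic-shaped cooling trend (steep
  early drop, a mid-span warm bump, a sharp mid-Miocene-like transition),
  endpoints 12→1 °C over 50→0 Ma by default, plus a 0.04-Ma-period
  sinusoid over the last 5 Ma (glacial cycles) and white noise. The
  nonlinear shape matters: a straight-line trend would make temperature
  an affine function of time and the `temp_exp` and `time_exp` models
  statistically indistinguishable, a degeneracy the real benthic record
  does not have. Orbital-band structure beyond one sinusoid, ice-volume
  vs temperature mixing in δ18O, and dating error are not emulated.
* **Trees**: time-inhomogeneous birth–death via thinning from the two
  crown lineages, conditioned by rejection on both crown lineages
  surviving into the sample; ρ-sampling removes tips uniformly.
  Power analysis drove two scale choices stated here once: the distance-
  exponent recovery check uses 30 trees of 30–50 tips (matching the
  empirical clade's scale), while the model-selection power check uses 50
  trees of 120–600 tips under strong forcing (α = −0.3 /°C, λ spanning
  ~27× across the cooling range) — at the empirical clade's own size
  (tens of tips) reconstructed-tree likelihoods genuinely cannot separate
  temperature- from time-dependence in most replicates, so passing that
  check at large n shows method correctness, not small-sample power.
* **Range histories**: forward Gillespie simulation per branch with
  stratum-aware rates and cladogenesis sampled from the same event menu
  the likelihood uses, with the full true event log returned for
  validating stochastic mapping.
* **Genotypes**: Balding–Nichols — per-locus ancestral frequency,
  per-population Beta-distributed frequencies at divergence F, binomial
  diploid genotypes; a hierarchical variant first draws per-cluster
  frequencies at a deeper divergence (emulating a west/east archipelago
  split that dominates a PCoA). Linkage, allele-frequency spectra from
  real ascertainment, and genotyping error are not emulated, so passing
  calibrations show estimator correctness under the island model, not
  robustness to real SNP-chip artefacts.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
trees of 3–600 tips, 100–9,000 posterior draws, 5,000 stochastic maps on
a 3-tip tree, 500–2,000 loci, 500 replicates for calibration rates.
These sizes were chosen to bound every Monte-Carlo standard error well
inside the asserted tolerance while keeping a full run on one CPU in
minutes.

## Known limitations

* The t test over posterior draws inherits their autocorrelation (see
  above); p-values are descriptive.
* The piecewise shift fit profiles the shift age on a grid, so reported
  shift times are grid-quantised (default resolution ≈ 4% of crown age).
* DEC state spaces are dense; more than ~10 areas would need sparse
  methods and is out of scope.
* The likelihood treats the sampling fraction as global; strongly
  clade-biased sampling will bias α.
* No null-range state: see the DEC section for the behavioural
  consequence.
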