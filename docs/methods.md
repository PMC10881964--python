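# Methods

This note records the model assumptions, estimator conventions, numerical
choices, and the design decisions made where more than one reasonable
implementation existed. Units: fitness and drift rates are per day unless
stated otherwise; logarithms are natural throughout (thresholds appear as
ln 10, ln 5, ln 3).

## Evolutionary model

Lineage frequencies `f_ℓ,m(t)` within a host m follow a well-mixed
continuous-time model

    ∂f/∂t = [s_ℓ,m(t) − X̄_m(t)] f + sqrt(Λ_m(t) f) · η(t),

where `X̄ = Σ s f` is the frequency-weighted mean fitness of the retained
lineages and `Λ = 1/(Ne·τe)` is the strength of genetic drift (`Ne` effective
population size, `τe` effective generation time). All inference works with
the *relative* fitness `x = s − X̄` and its time average χ over an interval;
absolute fitness and mean fitness are never estimated separately, because
without a trusted neutral reference class the decomposition is not
identifiable.

Sequencing adds a second branching process: given a true frequency f, read
counts have mean `D·f` and variance `κ·D·f`, with `κ` the noise Fano factor
(κ = 2 for the two-stage Poisson model used throughout). Combining the two
processes gives the moment formulas implemented in
`simulate.branching_moments` (adaptive quadrature over arbitrary x(t), Λ(t)
paths; closed forms exist for constant rates and are used as test oracles).

## Estimator conventions

- **Pooling** is always by read sums (`Σ reads / Σ depth`), never by averaging
  per-sample frequencies, so deeper replicates weigh more and coarse-grained
  groups can be formed by summing pooled frequencies.
- **Pseudocount structure**: the max/min floors in the χ estimator engage only
  when an endpoint frequency is zero; they are conservatively biased toward
  χ = 0 (a lineage with f(t₀) < 1/D(t₁) that disappears scores exactly zero).
  Lineages absent at both endpoints are *undefined* (0/0) and excluded from
  all rank and correlation computations rather than imputed.
- **Intervals without a duration** (in vitro passages, the library-creation
  pseudo-environment with uniform founding frequency 1/L) use Δt := 1, so χ
  is per passage there.
- **Gene assignment**: 1-based inclusive gene intervals; "upstream" is
  strand-aware. The fitness-determinant preprocessing filter uses
  distance ≤ 100 bp upstream (boundary inclusive); gene-complement assignment
  uses < 100 bp (boundary exclusive); both windows are arguments. An insertion
  claimed by overlapping genes goes to the gene with the nearest start
  (deterministic, tie broken by gene id, logged).
- **Correlations** between environments or replicates are computed on χ
  values restricted to lineages observed at non-zero frequency at both
  timepoints (optionally both environments), because the pseudocount floors
  otherwise attenuate correlations; this mirrors the estimator's own bias
  structure rather than patching it post hoc.

## Synthetic data generator

`simulate.simulate_experiment` emulates: a founding library (lognormal
frequency spread, default log-SD 1.0, representing differential growth during
library creation), pre-existing fitness variation (default 90% neutral +
10% exponential tail with mean 0.3/day; effects coupled across
condition × interval environments by a Gaussian copula on ranks and either
shared across hosts — pre-existing variation — or drawn independently per
host), Wright–Fisher propagation (selection via multiplicative weights
e^{s·τ} per generation, 10 generations/day by default so 4 days ≈ 40
generations; exact multinomial resampling for Ne ≤ 10⁷ and a per-lineage
Poisson approximation above, with O(1/√Ne) error, negligible at Ne = 10⁸),
optional single injected de novo sweeps (extra fitness in one lineage of one
host from an origin day onward), and two-stage Poisson sequencing. Every
host/sample draws from a named RNG substream derived from the master seed, so
runs are reproducible component-wise.

What the generator does *not* emulate: within-host spatial structure,
horizontal transfer, continuous de novo mutation accumulation, PCR jackpot
tails beyond the κ-fold Poisson overdispersion, inter-species interactions,
and depth variation across samples. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
every artifact of real sequencing data.

## Study-condition scenarios (`tnlineage.scenarios`)

- **Discrimination** (cross-validation contract): 2×10⁴ lineages, 8 hosts,
  40 WF generations at Ne = 10⁸, depth 10⁶, all-neutral vs 10% adaptive
  (Exp(0.3/day)). The null envelope is a pointwise mean ± z·SD band over 20
  replicate neutral simulations; a pointwise 95% band is expected to be
  exceeded by ≈5% of windows of a fresh null curve. With an exponential
  effect-size tail the mean fitness rises substantially within 4 days, so the
  bulk of the curve sits at −X̄ < 0 and the adaptive signal is the strongly
  positive top ranks plus KDE mass above 0.1/day — the neutral scenario shows
  neither.
- **Drift**: libraries of 5×10⁴ lineages with log-uniform initial frequencies
  over ~3 decades, per-lineage fitness Normal(0, 0.5/day) shared across 4
  hosts, t = 4 days, depth 10⁶, drift via multinomial WF at Ne·τe = 10⁵.
  Analysis windows: final frequency (5×10⁻⁵, 10⁻⁴), initial frequency
  (10⁻⁵, 5×10⁻⁴), 6 log-spaced initial-frequency bins (occupancy a few
  hundred per bin, the same order as real-data analyses). The windows keep
  the analysis in the diffusion regime — at much smaller final frequencies
  drift extinguishes lineages outright (variance becomes bimodal with a
  point mass at zero) and the second-moment model no longer applies.
- **De novo**: 3×10⁴ lineages, 5 hosts, days 0/4/10/16, neutral background,
  Ne·τe = 10⁵, depth 5×10⁵, library log-SD 1.5. Calibration draws the focal
  set i.i.d. from the control process (lineages measured at day 16 in ≥2
  hosts) and checks KS-indistinguishability from the matched null; detection
  injects one s = 0.5/day sweep at day 4 and requires its Δ to exceed the
  null's 99th percentile. A neutral background is used because a 16-day run
  of the exponential adaptive tail drives the population near-monoclonal,
  which is a property of that fitness distribution rather than of the
  divergence statistic under test.
- **Clustering**: 3 planted profile archetypes × 200 lineages over 10
  environments, component noise SD 0.5; agreement measured by adjusted Rand
  index over clustered lineages.

## Drift inference: numerical choices

- X (mean final frequency) and Y (unbiased, n−1 variance) always come from
  disjoint host cohorts; all (near-)equal unordered partitions are
  enumerated, records concatenated, then downsampled to one random partition
  per lineage to remove cross-partition correlations.
- The permutation statistic Ω̂ uses per-bin decile-trimmed means of (W, X, Y)
  (trimming by the Y order) and weighted least squares of ⟨Y⟩/⟨X⟩ on ln⟨W⟩
  with weights (⟨X⟩/σ_Y)², σ_Y from 1000 bootstrap resamples of the trimmed
  mean. Permutations shuffle the (X, Y) pairs against the fixed W values
  inside the window (equivalent to permuting initial frequencies), preserving
  bin occupancy and the W marginal; bin weights are held at their observed
  values across permutations. p is the one-sided fraction of permuted slopes
  ≤ the observed slope.
- **The Ne·τe fit uses untrimmed bin means.** The model g_α(w, x) =
  α₁x + α₂·x(x/w−1)/ln(x/w) predicts the *expectation* of the sample
  variance; with |M₂| = 2 replicates that variance is χ²(1)-skewed and its
  within-bin distribution is a scale mixture, so a decile-trimmed mean
  underestimates it by a factor that grows with the drift contribution and
  propagates multiplicatively into Ne·τe (factor ~3–7 in pilot simulations).
  Trimmed means are therefore reserved for the robust test statistic, where
  only the slope's sign and its permutation null matter, and the quantitative
  inversion uses plain means with bootstrap uncertainties.
- g_α has a removable singularity at x = w; a series guard
  (x·(1 + δ/2 − δ²/12), δ = x/w − 1) is used for |ln(x/w)| < 10⁻⁶.
- α is unconstrained in the fit; estimates are flagged reportable only when
  α₂ > 0, |σ_{Nτ}/N̂τ| < 1 and |σ_{Deff}/D̂eff| < 0.25. In drift-dominated
  simulations the sequencing term α₁ is dwarfed and its relative uncertainty
  usually fails the D_eff filter even when Ne·τe itself is accurate — the
  point estimate is still returned with its flag.
- κ is never estimated separately; it is absorbed into D_eff = 1/α₁.

## Clustering details

- Lineage and gene profiles are measured against the *whole* library
  (fitness-determinant lineages included), since beneficial knockouts are
  themselves of interest there. Profiles with any unmeasured environment are
  excluded from clustering; distances over partial masks are allowed only in
  the pairwise `profile_distance` utility.
- Knockout curation: stage 1 keeps genes with fold change > 10 in ≥1
  environment or > 5 in ≥2; stage 2 requires *every* leave-one-out profile to
  retain > 5 in one or > 3 in two. Before computing split-averaged gene
  profiles, a 2-means partition of the leave-one-out set that isolates a
  single outlying profile triggers removal of the corresponding lineage
  (fixed-seed k-means, n_init = 10).
- Novel-cluster search: seeds are fully measured lineages with max_k W >
  ln 10; average-linkage agglomerative clustering with merge cutoff ε = 4;
  a single remapping pass adds any fully measured lineage within ε of its
  nearest cluster mean, then means are recomputed once (no iteration — the
  remap is an augmentation step, not a k-means loop). Clusters of size 1 are
  dropped, as are clusters of size k in which any gene contributes more than
  max{1, ⌊log₁₀ k⌋} members. Novelty threshold on the minimum
  split-averaged-gene-profile distance D defaults to 4 (= d* + ε/2, with the
  lineage-to-gene match threshold d* = 2); no canonical value exists, so it
  is a configurable parameter.
- Genomic distance between an insertion and a gene is the minimum absolute
  coordinate difference to the interval (0 inside), same contig only;
  different contigs count as infinitely far, which *passes* the >100 kb
  off-target requirement.
- The multiply-hit-gene null: for clusters of ≤ ~10 members placed uniformly
  on a genome with a realistic gene-length distribution (~4,500 genes,
  mean ~1.1 kb), the chance of a doubly-hit gene is below ~1%; it grows
  roughly as k²/2 per extra member, which the max{1, ⌊log₁₀ k⌋} allowance
  tracks.

## De novo divergence details

Δ ranks final-timepoint frequencies per lineage across hosts with ties broken
by host id. A zero second-largest frequency is replaced by one read at the
second-ranked host's depth (1/D), keeping Δ finite and conservative. The
matched null stratifies controls into 20 log-spaced day-0-frequency bins
spanning the focal set's range, sampling per bin to match focal counts
(with replacement when a bin is short; empty bins fall back to the nearest
populated bin, logged).

## Problem sizes

Test-suite and acceptance-script simulations use the scenario sizes above
(2×10⁴–5×10⁴ lineages, 4–8 hosts, depth 10⁶), with 200 noise-only datasets
for type-I calibration, 50 (40 in the script) drift datasets for power, 25
(20) runs for Ne·τe recovery, and 500 permutations per dataset in the
replicated calibration studies (the single-dataset analysis driver uses the
full 10⁴ permutations and 10³ bootstraps). These sizes give binomial error
bars comfortably inside the asserted bands.

## Known limitations

- The discrimination and KDE analyses characterize the *distribution* of
  adaptive fitness effects; no per-lineage significance calls or
  multiple-testing control are attempted.
- Tradeoff labels are raw sign classifications of point estimates with no
  significance filter — descriptive, not inferential.
- The Ne·τe estimator assumes constant χ and Λ within the interval and
  breaks down outside the diffusion regime (final frequencies ≲ Λt), where
  lineage extinction dominates; window choice is part of the analysis.
- Cluster novelty depends on a threshold with no canonical value; clusters
  near the threshold should be treated as candidates either way.
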