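# tnlineage

Lineage-tracking inference for genome-wide transposon-insertion (Tn-Seq/InSeq)
libraries colonizing a host. Every unique insertion site defines a clonal
lineage whose relative frequency can be followed through sequencing; the
collective behavior of 10⁴–10⁵ such lineages encodes the evolutionary forces
acting in vivo. `tnlineage` turns lineage × sample read-count tables into
quantitative statements about those forces:

- **Relative fitness estimation** — the time-averaged growth rate of a lineage
  relative to the population mean,
  `χ = (1/Δt) · ln[ max{f(t₁), min(1/D₁, f(t₀))} / max{f(t₀), min(1/D₀, f(t₁))} ]`,
  a log-ratio estimator on cohort-pooled (read-sum) frequencies with a
  conservative pseudocount structure for lineages at the detection limit.
- **Cross-validated discovery of adaptive lineages** — hosts are split into
  discovery and validation cohorts; lineages are ranked by discovery fold
  change and sliding windows of 100 ranks are coarse-grained (frequencies
  summed) in the validation cohort, so genuine pre-existing fitness variation
  separates from sampling noise. Gene-complement tracks (all *other* lineages
  in the same gene) distinguish knockout effects from secondary mutations.
- **Pleiotropy and tradeoffs** — joint fitness across diets / time intervals /
  in vitro media from disjoint host cohorts, replicate-pair correlations, and
  sign-based tradeoff labels.
- **Phenotypic clustering** — multi-environment fitness profiles
  `W = (ln f̄₁/f̄₀ per environment)` compared by Euclidean distance;
  agglomerative clustering with leave-one-out-validated gene knockout profiles
  classifies recurrent adaptive phenotypes as knockout-like or novel.
- **De novo mutation signatures** — the divergence score
  `Δ = f₍₁₎/f₍₂₎` (largest over second-largest final frequency across
  replicate hosts) against a day-0-frequency-matched control null.
- **Genetic drift strength** — the across-replicate variance of final
  frequency decomposes as
  `Var(f̂) = κ⟨f⟩/D + (t/Neτe) · ⟨f⟩(⟨f⟩/f₀ − 1)/ln(⟨f⟩/f₀)`;
  a permutation test on the Fano-factor-vs-ln f₀ slope detects drift, and
  weighted least squares inverts the two-term model into an effective
  population size `Neτe`.

A first-class synthetic-data generator (`tnlineage.simulate`) emulates the
assumed data-generating process — heterogeneous pre-existing fitness (point
mass at zero + exponential beneficial tail, coupled across environments by a
Gaussian copula), Wright–Fisher drift at configurable Ne, environment-specific
selection, injected de novo sweeps, and two-stage Poisson sequencing (read
Fano factor κ = number of stages) — and returns full ground truth, so every
inference stage is validated end to end.

## Layout

- `src/tnlineage/` — the library: `count_io` (tables, annotations, filters,
  pooling), `simulate`, `fitness`, `discovery`, `tradeoffs`, `profiles`,
  `denovo`, `drift`, `scenarios` (end-to-end study conditions), `pipeline`
  and a thin `tnlineage` CLI (`simulate`, `preprocess`, `fitness`,
  `discover`, `denovo`, `drift`, `diagnose`, `run-all`, …).
- `analysis/01…07_*.py` — numbered drivers that run the full story on
  synthetic data and write tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_experiment.py
python analysis/03_adaptive_discovery.py
```

```
simulated 20000 lineages x 12 samples
2049 lineages (10.2%) carry pre-existing beneficial effects
19653 eligible lineages; discovery cohort ('HFHS_m2', 'HFHS_m4', 'HFHS_m6', 'HFHS_m8'), validation ('HFHS_m1', 'HFHS_m3', 'HFHS_m5', 'HFHS_m7')
top-500-window validation fitness: 0.194/day
339 windows exceed +0.05/day in validation (1.7% of windows)
KDE mass above 0.1/day: 0.015
```

The fittest discovery ranks validate at ≈0.2/day in held-out hosts — fitness
benefits that replicate across animals and are therefore carried by variants
present in the input library, not sampling noise. The kernel density estimate
over window fitnesses (bandwidth 0.3 × SD) puts measurable mass above
0.1/day, the strong-selection regime. Drift inference
(`python analysis/07_drift_inference.py`) prints, for a simulation at
`Neτe = 1e5`:

```
drift_Netau_1e5: n=2188 Omega=-7.68e-06 p=0.0000
  Ne*tau_e estimate 9.44e+04 (truth 1e+05), reported=False
noise_only: n=1456 Omega=2.55e-08 p=0.5799
```

— a significantly negative variance-vs-initial-frequency slope under drift
(and none under pure sequencing noise), with the inverted estimate within
6% of the true bottleneck size.

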