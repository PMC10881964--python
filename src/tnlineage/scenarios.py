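"""End-to-end validation scenarios: the study conditions under which the
inference pipeline is exercised against ground truth.

Each function simulates a complete experiment with the synthetic generator and
runs the corresponding inference stage from scratch.  The scenarios mirror the
experimental design the pipeline targets: libraries of tens of thousands of
Tn lineages, a handful of replicate gnotobiotic hosts per diet, 40 Wright--
Fisher generations (~4 days) per interval, and two-stage Poisson sequencing at
depth ~1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import denovo as dn
from . import discovery, drift, profiles
from .count_io import INPUT_KIND, pool_samples
from .simulate import (DeNovoEvent, FitnessModel, SimulationConfig,
                       simulate_drift_dataset, simulate_experiment)

# --- cross-validation discrimination -------------------------------------

CV_N_LINEAGES = 20_000
CV_HOSTS = 8
CV_DEPTH = 1_000_000


def discrimination_curve(fraction_adaptive: float, seed: int,
                         n_lineages: int = CV_N_LINEAGES, hosts: int = CV_HOSTS,
                         depth: int = CV_DEPTH) -> discovery.RankOrderCurve:
    """One discovery/validation rank-order curve: 40 Wright--Fisher
    generations at Ne = 1e8 with the given adaptive fraction (effects
    Exp(0.3/day), shared across hosts), two-stage Poisson sequencing."""
    cfg = SimulationConfig(n_lineages=n_lineages, conditions={"HF/HS": hosts},
                           timepoints=(0.0, 4.0), Ne=1e8, depth=depth, seed=seed,
                           fitness=FitnessModel(fraction_adaptive, 0.3))
    table, _ = simulate_experiment(cfg)
    host_ids = sorted(table.samples.loc[table.samples["kind"] == "fecal",
                                        "host_id"].unique())
    inp = sorted(table.samples.index[table.samples["kind"] == INPUT_KIND])
    split = discovery.split_cohorts(host_ids, "HF/HS", seed, inp)
    return discovery.rank_and_curve(table, split, 0.0, 4.0)


@dataclass
class DiscriminationResult:
    null_exceedance: float       #: fraction of null windows outside the envelope
    null_mean_abs: float
    null_kde_mass: float         #: null KDE mass above 0.1/day
    top_window_chi: float        #: adaptive scenario: mean of the top 500 windows
    top_decile_above_envelope: float
    kde_mass: float              #: adaptive KDE mass above 0.1/day


def discrimination_scenario(seed: int, n_null: int = 20) -> DiscriminationResult:
    """All-neutral vs 10%-adaptive discrimination with a Monte-Carlo null
    envelope from ``n_null`` replicate neutral simulations."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_null + 2)
    null_curves = [discrimination_curve(0.0, int(s)) for s in seeds[:n_null]]
    lo, hi = discovery.null_envelope(null_curves)
    obs = discrimination_curve(0.0, int(seeds[n_null]))
    m = min(len(obs.chi_window), len(lo))
    exceed = float(np.mean((obs.chi_window[:m] < lo[:m])
                           | (obs.chi_window[:m] > hi[:m])))
    null_kde = discovery.infer_fitness_distribution(obs)
    null_mass = _mass_above(null_kde, 0.1)

    adapt = discrimination_curve(0.1, int(seeds[n_null + 1]))
    k = min(len(adapt.chi_window), len(hi))
    n_top = max(1, k // 10)
    top_above = float(np.mean(adapt.chi_window[:n_top] > hi[:n_top]))
    kde = discovery.infer_fitness_distribution(adapt)
    return DiscriminationResult(
        null_exceedance=exceed,
        null_mean_abs=float(np.nanmean(np.abs(obs.chi_window))),
        null_kde_mass=null_mass,
        top_window_chi=float(np.nanmean(adapt.chi_window[:500])),
        top_decile_above_envelope=top_above,
        kde_mass=_mass_above(kde, 0.1),
    )


def _mass_above(dist: discovery.FitnessDistribution, x: float) -> float:
    if len(dist.grid) < 2:
        return float(dist.grid[0] > x)
    sel = dist.grid > x
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(dist.density[sel], dist.grid[sel]))


# --- drift test and Ne*tau_e inference ------------------------------------

DRIFT_N_LINEAGES = 50_000
DRIFT_HOSTS = 4
DRIFT_DEPTH = 1_000_000
DRIFT_NETAU = 1e5
DRIFT_T = 4.0
FINAL_WINDOW = (5e-5, 1e-4)
INITIAL_WINDOW = (1e-5, 5e-4)
DRIFT_BINS = 6


def drift_run(netau: float | None, seed: int, n_perm: int = 500,
              with_fit: bool = False):
    """One replicate-host drift dataset plus permutation test (and optional
    Ne*tau_e fit).  Returns ``(p_value, fit_or_None)``."""
    f0, fhat, _ = simulate_drift_dataset(DRIFT_N_LINEAGES, DRIFT_HOSTS,
                                         DRIFT_DEPTH, netau, seed=seed, t=DRIFT_T)
    regset = drift.build_regression_set(f0, fhat, FINAL_WINDOW, INITIAL_WINDOW,
                                        seed=seed + 1, t=DRIFT_T)
    res = drift.drift_test(regset, n_bins=DRIFT_BINS, n_perm=n_perm,
                           n_boot=300, seed=seed + 2)
    fit = drift.fit_Ne_tau(regset, t=DRIFT_T, n_bins=DRIFT_BINS,
                           n_boot=300, seed=seed + 3) if with_fit else None
    return res.p_value, fit


def drift_calibration(seed: int, n_datasets: int = 200) -> np.ndarray:
    """Type-I calibration: p-values over noise-only (no drift) datasets."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 10, size=n_datasets)
    return np.array([drift_run(None, int(s))[0] for s in seeds])


def drift_power(seed: int, n_datasets: int = 50) -> np.ndarray:
    """Power: p-values over drift-dominated datasets (Ne*tau_e = 1e5)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 10, size=n_datasets)
    return np.array([drift_run(DRIFT_NETAU, int(s))[0] for s in seeds])


def netau_recovery(seed: int, n_runs: int = 25) -> np.ndarray:
    """End-to-end Ne*tau_e estimates divided by the true value (1e5)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 10, size=n_runs)
    ratios = []
    for s in seeds:
        _, fit = drift_run(DRIFT_NETAU, int(s), n_perm=10, with_fit=True)
        ratios.append(fit.netau / DRIFT_NETAU if fit.converged else np.inf)
    return np.array(ratios)


def alpha_selfconsistency(seed: int) -> float:
    """Max relative error recovering alpha = (1e-6, 4e-6) from bins generated
    exactly by the two-term variance model plus tiny noise."""
    rng = np.random.default_rng(seed)
    alpha = (1e-6, 4e-6)
    w = np.logspace(-5, -3.3, 8)
    x = np.full(8, 7.5e-5)
    y = drift.g_alpha(w, x, *alpha) * (1 + rng.normal(0, 1e-4, 8))
    (a1, a2), _, ok = drift.fit_alpha(w, x, y, sigma_y=y * 1e-3)
    if not ok:
        return float("inf")
    return float(max(abs(a1 / alpha[0] - 1), abs(a2 / alpha[1] - 1)))


# --- de novo divergence ----------------------------------------------------

DENOVO_N_LINEAGES = 30_000
DENOVO_HOSTS = 5
DENOVO_DEPTH = 500_000


def _denovo_experiment(seed: int, de_novo: DeNovoEvent | None = None):
    cfg = SimulationConfig(n_lineages=DENOVO_N_LINEAGES,
                           conditions={"HF/HS": DENOVO_HOSTS},
                           timepoints=(0.0, 4.0, 10.0, 16.0), Ne=1e6,
                           depth=DENOVO_DEPTH, seed=seed, input_log_sd=1.5,
                           fitness=FitnessModel(0.0), de_novo=de_novo)
    table, _ = simulate_experiment(cfg)
    freqs, depths = dn.final_frequency_table(table, 16.0)
    scores = dn.divergence_scores(freqs, depths)
    inp = sorted(table.samples.index[table.samples["kind"] == INPUT_KIND])
    f0 = pool_samples(table, inp).freqs
    measured2 = (freqs > 0).sum(axis=1) >= 2
    eligible = scores[measured2.reindex(scores.index).fillna(False)]
    return table, scores, eligible, f0


def denovo_null_calibration(seed: int, n_focal: int = 1000) -> float:
    """Neutral host-exchangeable simulation: a focal set drawn i.i.d. from
    the control process must be indistinguishable from the matched null
    (KS p-value returned)."""
    _, _, eligible, f0 = _denovo_experiment(seed)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=min(n_focal, len(eligible) // 2),
                      replace=False)
    focal = eligible.iloc[pick]
    controls = eligible.drop(index=focal.index)
    null = dn.matched_null(f0.loc[focal.index], f0.loc[controls.index],
                           controls["delta"], seed=seed)
    return float(stats.ks_2samp(np.log(focal["delta"]), np.log(null)).pvalue)


def denovo_sweep_detection(seed: int) -> tuple[float, float]:
    """Inject one s = 0.5/day sweep at day 4 in host 1; return the swept
    lineage's divergence score and the matched null's 99th percentile."""
    _, _, _, f0 = _denovo_experiment(seed)
    idx = int(np.argsort(f0.to_numpy())[int(0.97 * len(f0))])
    event = DeNovoEvent(host_id="HFHS_m1", lineage_index=idx,
                        effect=0.5, origin_day=4.0)
    table, scores, eligible, f0 = _denovo_experiment(seed, de_novo=event)
    lid = table.counts.index[idx]
    focal = scores[scores["passed_threshold"]]
    controls = eligible.drop(index=focal.index, errors="ignore")
    null = dn.matched_null(f0.loc[focal.index], f0.loc[controls.index],
                           controls["delta"], seed=seed)
    return float(scores.loc[lid, "delta"]), float(np.percentile(null, 99))


# --- phenotypic clustering -------------------------------------------------


def planted_profiles(seed: int, n_per_cluster: int = 200, noise_sd: float = 0.5,
                     n_env: int = 10):
    """600 lineages in 3 planted profile archetypes with per-component noise."""
    rng = np.random.default_rng(seed)
    arch = np.zeros((3, n_env))
    arch[0, :3] = 3.0
    arch[1, 3:6] = 3.0
    arch[2, 6:9] = 3.0
    rows, labels = [], []
    for a in range(3):
        for _ in range(n_per_cluster):
            rows.append(arch[a] + rng.normal(0, noise_sd, n_env))
            labels.append(a)
    W = pd.DataFrame(rows, index=[f"l{i}" for i in range(len(rows))],
                     columns=[f"e{k}" for k in range(n_env)])
    return W, np.array(labels), arch


def cluster_recovery(seed: int) -> tuple[float, float, dict]:
    """Planted-archetype recovery.

    Returns ``(ari, coverage, kinds)``: co-clustering agreement (adjusted
    Rand index over clustered lineages), the fraction of lineages clustered,
    and archetype -> (kind, distance) labels against a gene profile matching
    archetype 0.
    """
    from sklearn.metrics import adjusted_rand_score
    W, labels, arch = planted_profiles(seed)
    gene_map = pd.Series(np.nan, index=W.index)
    clusters = profiles.find_novel_clusters(W, gene_map,
                                            gene_profiles={"geneA": arch[0]})
    pred = {m: i for i, c in enumerate(clusters) for m in c.members}
    common = [l for l in W.index if l in pred]
    ari = adjusted_rand_score(labels[[int(l[1:]) for l in common]],
                              [pred[l] for l in common])
    kinds = {}
    for c in clusters:
        lab = int(labels[int(c.members[0][1:])])
        kinds[lab] = (c.kind, float(c.distance))
    return float(ari), len(common) / len(W), kinds
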