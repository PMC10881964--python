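"""Cross-validated discovery of adaptive lineages.

Replicate hosts in one environment are split into discovery and validation
cohorts (input technical replicates are split too, so the cohorts share no
sample).  Lineages are ranked by their fold change in the discovery cohort;
because the validation cohort has independent biological and technical noise,
systematically positive validation fitness among top-ranked lineages is
evidence of genuine (pre-existing) fitness variation rather than sampling
fluctuations.

Per-lineage validation estimates are noisy, so ranks are coarse-grained:
sliding windows of consecutive ranks are merged by summing their pooled
frequencies, and the group estimator is applied to the window sums.  The
distribution of the window-level coarse-grained fitnesses approximates the
underlying fitness distribution of the adaptive lineages and is smoothed by
Gaussian KDE with bandwidth 0.3 x SD of the window values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .count_io import CohortPooledFrequencies, CountTable, INPUT_KIND, pool_cohort, pool_samples
from .fitness import _chi_arrays, relative_fitness, gene_complement_fitness_all

logger = logging.getLogger(__name__)

INPUT_FREQ_THRESHOLD = 10 ** -6.5
MIN_EXPECTED_VALIDATION_READS = 5.0


@dataclass
class CohortSplit:
    """Disjoint discovery/validation host cohorts plus the input-replicate split."""

    environment: str
    discovery_hosts: tuple
    validation_hosts: tuple
    discovery_input: tuple = ()
    validation_input: tuple = ()

    def __post_init__(self):
        if set(self.discovery_hosts) & set(self.validation_hosts):
            raise ValueError("discovery and validation cohorts overlap")
        if not 0 <= len(self.discovery_hosts) - len(self.validation_hosts) <= 1:
            raise ValueError("cohorts must be equal sized (discovery may have one extra)")


@dataclass
class RankOrderCurve:
    """Sliding-window validation fitness as a function of discovery rank."""

    eligible: list              #: lineage ids, ordered by discovery rank (1 = fittest)
    chi_discovery: np.ndarray   #: per-lineage discovery fitness, rank order
    window: int
    window_start: np.ndarray    #: first rank (1-based) of each window
    chi_window: np.ndarray      #: validation coarse-grained fitness per window
    chi_complement: np.ndarray  #: sliding average of gene-complement fitness (NaN if no map)
    t0: float = 0.0
    t1: float = 4.0


@dataclass
class FitnessDistribution:
    grid: np.ndarray
    density: np.ndarray
    values: np.ndarray  #: source coarse-grained fitness values
    bandwidth: float


def split_cohorts(hosts, environment: str, seed: int,
                  input_samples=()) -> CohortSplit:
    """Random equal split of hosts into discovery/validation cohorts.

    With an odd host count the discovery cohort receives the extra host
    (e.g. 9 hosts -> 5 discovery / 4 validation).  Input technical replicates
    are split the same way.
    """
    hosts = sorted(hosts)
    if len(hosts) < 2:
        raise ValueError("need at least 2 hosts to split")
    rng = np.random.default_rng(seed)
    perm = [hosts[i] for i in rng.permutation(len(hosts))]
    n_disc = (len(hosts) + 1) // 2
    inp = sorted(input_samples)
    iperm = [inp[i] for i in rng.permutation(len(inp))]
    n_disc_inp = (len(inp) + 1) // 2
    return CohortSplit(environment,
                       tuple(sorted(perm[:n_disc])), tuple(sorted(perm[n_disc:])),
                       tuple(sorted(iperm[:n_disc_inp])), tuple(sorted(iperm[n_disc_inp:])))


def eligibility_filter(input_freqs: pd.Series,
                       disc0: CohortPooledFrequencies, disc1: CohortPooledFrequencies,
                       val0: CohortPooledFrequencies, val1: CohortPooledFrequencies,
                       input_threshold: float = INPUT_FREQ_THRESHOLD,
                       min_reads: float = MIN_EXPECTED_VALIDATION_READS) -> pd.Index:
    """Lineages resolvable in the validation cohort.

    Keep lineages whose pooled input frequency exceeds ``input_threshold``
    (default 10^-6.5, ~10 reads in a typical pooled input) and whose expected
    validation reads min{D_V(t0), D_V(t1)} * max{f_D(t0), f_D(t1)} exceed
    ``min_reads``.
    """
    fmax = np.maximum(disc0.freqs, disc1.freqs)
    dmin = min(val0.depth, val1.depth)
    keep = (input_freqs > input_threshold) & (dmin * fmax > min_reads)
    logger.info("eligibility filter: %d / %d lineages retained",
                int(keep.sum()), len(keep))
    return keep.index[keep]


def _pool_at(table: CountTable, hosts, input_samples, day) -> CohortPooledFrequencies:
    if day == 0 and len(input_samples):
        return pool_samples(table, input_samples)
    return pool_cohort(table, hosts, day, kind=None)


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[w:] - c[:-w]


def rank_and_curve(table: CountTable, split: CohortSplit, t0: float, t1: float,
                   window: int = 100, gene_map: pd.Series | None = None,
                   eligible: pd.Index | None = None,
                   input_freqs: pd.Series | None = None) -> RankOrderCurve:
    """Rank eligible lineages by discovery fold change and compute sliding
    validation coarse-grained fitness (plus the gene-complement control track).

    Ranking uses the pseudocounted log-ratio estimator on the discovery pool,
    which is monotone in fold change for a fixed interval; ties are broken by
    lineage id so ranks are deterministic.  Windows are contiguous with
    stride 1; tail windows shorter than ``window`` are dropped.
    """
    disc0 = _pool_at(table, split.discovery_hosts, split.discovery_input, t0)
    disc1 = _pool_at(table, split.discovery_hosts, (), t1)
    val0 = _pool_at(table, split.validation_hosts, split.validation_input, t0)
    val1 = _pool_at(table, split.validation_hosts, (), t1)

    if eligible is None:
        if input_freqs is None:
            inp = table.samples.index[table.samples["kind"] == INPUT_KIND]
            input_freqs = pool_samples(table, inp).freqs if len(inp) else disc0.freqs
        eligible = eligibility_filter(input_freqs, disc0, disc1, val0, val1)

    chi_d = relative_fitness(disc0, disc1, t0, t1).loc[eligible]
    chi_d = chi_d[chi_d["defined"]]
    # stable mergesort on chi after an id sort -> ties broken by lineage id
    order = chi_d.loc[chi_d.sort_index().sort_values("chi", ascending=False,
                                                     kind="mergesort").index]
    ranked = order.index.to_list()
    n = len(ranked)
    w = min(window, n)
    if window > n:
        logger.info("window %d exceeds %d eligible lineages; using one window", window, n)

    v0 = val0.freqs.reindex(ranked).to_numpy()
    v1 = val1.freqs.reindex(ranked).to_numpy()
    s0 = _sliding_sum(v0, w)
    s1 = _sliding_sum(v1, w)
    chi_win, _, defined = _chi_arrays(s0, s1, val0.depth, val1.depth, t1 - t0)
    chi_win = np.where(defined, chi_win, np.nan)

    if gene_map is not None:
        comp = gene_complement_fitness_all(gene_map, val0, val1, t0, t1)
        comp = comp.reindex(ranked).to_numpy()
        vals = np.nan_to_num(comp)
        cnts = np.isfinite(comp).astype(float)
        with np.errstate(invalid="ignore"):
            comp_win = _sliding_sum(vals, w) / np.where(_sliding_sum(cnts, w) > 0,
                                                        _sliding_sum(cnts, w), np.nan)
    else:
        comp_win = np.full(n - w + 1, np.nan)

    return RankOrderCurve(ranked, order["chi"].to_numpy(), w,
                          np.arange(1, n - w + 2), chi_win, comp_win, t0, t1)


def infer_fitness_distribution(curve: RankOrderCurve, grid=None) -> FitnessDistribution:
    """Gaussian KDE over the window coarse-grained fitnesses.

    Bandwidth is 0.3 x the standard deviation of the source values (via the
    ``bw_method`` factor of :func:`scipy.stats.gaussian_kde`).  A zero-variance
    source degenerates to a point mass, returned as a single-point grid.
    """
    values = curve.chi_window[np.isfinite(curve.chi_window)]
    if len(values) < 2:
        raise ValueError("need at least 2 windows for a distribution")
    sd = values.std()
    if sd == 0:
        logger.info("zero-variance window fitnesses; returning point mass at %.3g", values[0])
        return FitnessDistribution(np.array([values[0]]), np.array([1.0]), values, 0.0)
    kde = stats.gaussian_kde(values, bw_method=0.3)
    bw = 0.3 * sd
    if grid is None:
        grid = np.linspace(values.min() - 4 * bw, values.max() + 4 * bw, 512)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return FitnessDistribution(grid, density, values, bw)


def null_envelope(null_curves, level: float = 0.95, method: str = "normal"):
    """Pointwise Monte-Carlo envelope of the window fitness under replicate
    null simulations, truncated to the shortest curve.

    ``method="normal"`` (default) uses mean +- z*SD per window, which is well
    calibrated from a modest number of replicate simulations; ``"percentile"``
    uses empirical quantiles (needs many replicates to reach the tails).
    """
    if not null_curves:
        raise ValueError("no null curves")
    m = min(len(c.chi_window) for c in null_curves)
    mat = np.vstack([c.chi_window[:m] for c in null_curves])
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        mu = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
        return mu - z * sd, mu + z * sd
    alpha = (1.0 - level) / 2 * 100
    return np.nanpercentile(mat, alpha, axis=0), np.nanpercentile(mat, 100 - alpha, axis=0)
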