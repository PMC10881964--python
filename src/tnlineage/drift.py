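"""Quantifying genetic drift amid widespread fitness variation.

Sequencing noise and genetic drift both inflate the variance of a lineage's
final frequency across replicate hosts, but they scale differently: given the
same expected final frequency <f(t)>, lineages that started *smaller* (hence
grew faster) accumulated more drift because they spent more time at small
size, while the sampling-noise term depends on the final frequency alone.
Under constant relative fitness and drift strength Lambda = 1/(Ne*tau_e),

    Var(f_hat(t)) = kappa/D * <f(t)>                      (technical noise)
                  + t/(Ne*tau_e) * <f(t)>[<f(t)>/f0 - 1] / ln(<f(t)>/f0).

The machinery below builds a per-lineage regression set (initial frequency W,
cross-cohort mean final frequency X, cross-cohort variance Y, estimated from
disjoint host cohorts so the moments are independent), tests for drift via
the sign of the Fano-factor-vs-ln(W) slope under a within-window permutation
null, and inverts the two-term variance model by weighted least squares to
estimate Ne*tau_e (and an effective depth D_eff = 1/alpha_1 that absorbs
kappa).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


def replicate_variance(freqs) -> np.ndarray:
    """Unbiased (n-1 denominator) across-replicate variance per lineage.

    ``freqs`` is lineage x host (array or DataFrame) with >=2 hosts.
    """
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a lineage x host matrix with >=2 hosts")
    return arr.var(axis=1, ddof=1)


def equal_partitions(hosts) -> list[tuple[tuple, tuple]]:
    """All unordered (near-)equal partitions of the host set into (M1, M2).

    For an even count each unordered split appears once, with M1 the half
    containing the lexicographically smallest host (4 hosts -> 3 partitions).
    For an odd count M1 takes the smaller half, so the variance cohort M2
    keeps at least as many replicates.
    """
    hosts = sorted(hosts)
    if len(hosts) < 4:
        raise ValueError("need >=4 hosts (>=2 per cohort)")
    k = len(hosts) // 2
    out = []
    if len(hosts) % 2 == 0:
        rest = hosts[1:]
        for combo in itertools.combinations(rest, k - 1):
            m1 = (hosts[0],) + combo
            m2 = tuple(h for h in hosts if h not in m1)
            out.append((m1, m2))
    else:
        for combo in itertools.combinations(hosts, k):
            m2 = tuple(h for h in hosts if h not in combo)
            out.append((tuple(combo), m2))
    return out


@dataclass
class DriftRegressionSet:
    """Per-lineage (W, X, Y) vectors after partition concatenation and
    one-record-per-lineage downsampling."""

    lineage_ids: list
    W: np.ndarray   #: initial frequencies
    X: np.ndarray   #: mean final frequency (cohort M1 of the retained record)
    Y: np.ndarray   #: across-replicate variance (cohort M2, n-1 denominator)
    final_window: tuple
    initial_window: tuple
    t: float = 4.0


def build_regression_set(f0: pd.Series, final_freqs: pd.DataFrame,
                         final_window: tuple, initial_window: tuple,
                         seed: int, t: float = 4.0) -> DriftRegressionSet:
    """Assemble the drift regression set from per-host final frequencies.

    For every equal partition (M1, M2) of the hosts, X is the mean final
    frequency over M1 and Y the unbiased variance over M2; lineages pass a
    partition if X lies in ``final_window`` and f0 in ``initial_window``.
    Records are concatenated over partitions, then each lineage keeps the
    record of a single random partition among those it passed, which removes
    the correlations induced by re-using hosts across partitions.
    """
    parts = equal_partitions(final_freqs.columns)
    if len(parts) < 2:
        logger.info("only %d partition(s) available; proceeding", len(parts))
    rng = np.random.default_rng(seed)
    w = f0.reindex(final_freqs.index).to_numpy(dtype=float)
    records: dict = {}
    for m1, m2 in parts:
        X = final_freqs[list(m1)].mean(axis=1).to_numpy()
        Y = replicate_variance(final_freqs[list(m2)])
        mask = ((X >= final_window[0]) & (X <= final_window[1])
                & (w >= initial_window[0]) & (w <= initial_window[1]))
        for i in np.nonzero(mask)[0]:
            records.setdefault(final_freqs.index[i], []).append((X[i], Y[i]))
    if not records:
        raise ValueError("no lineage passes the frequency windows in any partition")
    lids = sorted(records)
    Xs, Ys = [], []
    for lid in lids:
        recs = records[lid]
        x, y = recs[rng.integers(len(recs))]
        Xs.append(x)
        Ys.append(y)
    keep = f0.reindex(lids).to_numpy(dtype=float)
    return DriftRegressionSet(lids, keep, np.array(Xs), np.array(Ys),
                              tuple(final_window), tuple(initial_window), t)


# ---------------------------------------------------------------------------
# Binned statistics and the permutation test


@dataclass
class BinnedSet:
    edges: np.ndarray
    slices: list            #: per-bin index slices into the W-sorted arrays
    W: np.ndarray           #: W-sorted copies
    X: np.ndarray
    Y: np.ndarray
    w_mean: np.ndarray      #: per-bin decile-trimmed means (observed)
    x_mean: np.ndarray
    y_mean: np.ndarray
    sigma_y: np.ndarray     #: bootstrap SE of the trimmed mean of Y per bin
    occupancy: np.ndarray


def _trim_counts(k: int, trim: bool) -> int:
    return k // 10 if trim else 0


def _bin_set(regset: DriftRegressionSet, n_bins: int, n_boot: int,
             rng: np.random.Generator, trim: bool = True) -> BinnedSet:
    order = np.argsort(regset.W, kind="mergesort")
    W, X, Y = regset.W[order], regset.X[order], regset.Y[order]
    lo, hi = regset.initial_window
    if not np.isfinite(lo) or lo <= 0:
        lo = W.min()
    if not np.isfinite(hi) or hi <= 0:
        hi = W.max()
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.searchsorted(W, edges)
    slices, occ = [], []
    for b in range(n_bins):
        s = slice(idx[b], idx[b + 1])
        if s.stop - s.start > 0:
            slices.append(s)
            occ.append(s.stop - s.start)
    occ = np.array(occ)
    if len(slices) < 3:
        raise ValueError(f"degenerate binning: occupancy {occ.tolist()} "
                         f"across {n_bins} bins; need >=3 non-empty bins")

    w_mean = np.empty(len(slices))
    x_mean = np.empty(len(slices))
    y_mean = np.empty(len(slices))
    sigma_y = np.empty(len(slices))
    for j, s in enumerate(slices):
        Wb, Xb, Yb = W[s], X[s], Y[s]
        k = len(Yb)
        cut = _trim_counts(k, trim)
        o = np.argsort(Yb, kind="mergesort")[cut: k - cut if k - 2 * cut >= 1 else k]
        w_mean[j], x_mean[j], y_mean[j] = Wb[o].mean(), Xb[o].mean(), Yb[o].mean()
        # bootstrap the trimmed mean of Y
        samp = Yb[rng.integers(0, k, size=(n_boot, k))]
        samp.sort(axis=1)
        tm = samp[:, cut: k - cut if k - 2 * cut >= 1 else k].mean(axis=1)
        sigma_y[j] = tm.std(ddof=1)
    sigma_y = np.where(sigma_y > 0, sigma_y, np.nanmin(sigma_y[sigma_y > 0])
                       if (sigma_y > 0).any() else 1.0)
    return BinnedSet(edges, slices, W, X, Y, w_mean, x_mean, y_mean, sigma_y, occ)


def _weighted_slope(x, y, weights):
    wsum = weights.sum()
    xb = (weights * x).sum() / wsum
    yb = (weights * y).sum() / wsum
    return ((weights * (x - xb) * (y - yb)).sum()
            / (weights * (x - xb) ** 2).sum())


@dataclass
class DriftTestResult:
    omega: float
    p_value: float
    binned: BinnedSet
    n_perm: int


def drift_test(regset: DriftRegressionSet, n_bins: int = 8, n_perm: int = 10_000,
               n_boot: int = 1_000, seed: int = 0,
               chunk: int = 256) -> DriftTestResult:
    """Permutation test for genetic drift.

    The statistic Omega is the weighted-least-squares slope of the per-bin
    Fano factor <Y>/<X> against ln<W>, with per-bin decile-trimmed means and
    bootstrap-based weights (<X>/sigma_Y)^2.  The null permutes the initial
    frequencies across lineages within the final-frequency window, which
    preserves each bin's occupancy and W values while shuffling the (X, Y)
    pairs; the same trimmed-mean statistic is recomputed per permutation with
    the observed weights.  p is the one-sided fraction of permutations with
    a slope at least as negative as the observed one.
    """
    rng = np.random.default_rng(seed)
    binned = _bin_set(regset, n_bins, n_boot, rng)
    weights = (binned.x_mean / binned.sigma_y) ** 2
    lnw = np.log(binned.w_mean)
    omega = _weighted_slope(lnw, binned.y_mean / binned.x_mean, weights)

    n = len(binned.W)
    count = 0
    done = 0
    while done < n_perm:
        P = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((P, n)), axis=1)
        Xp = binned.X[idx]
        Yp = binned.Y[idx]
        fano = np.empty((P, len(binned.slices)))
        lnw_p = np.empty((P, len(binned.slices)))
        for j, s in enumerate(binned.slices):
            k = s.stop - s.start
            cut = _trim_counts(k, True)
            keep = slice(cut, k - cut if k - 2 * cut >= 1 else k)
            o = np.argsort(Yp[:, s], axis=1, kind="mergesort")[:, keep]
            Yb = np.take_along_axis(Yp[:, s], o, axis=1).mean(axis=1)
            Xb = np.take_along_axis(Xp[:, s], o, axis=1).mean(axis=1)
            Wb = binned.W[s][o].mean(axis=1)
            fano[:, j] = Yb / Xb
            lnw_p[:, j] = np.log(Wb)
        for p_i in range(P):
            om = _weighted_slope(lnw_p[p_i], fano[p_i], weights)
            if om <= omega:
                count += 1
        done += P
    return DriftTestResult(float(omega), count / n_perm, binned, n_perm)


# ---------------------------------------------------------------------------
# Ne*tau_e estimation


def g_alpha(w, x, alpha1, alpha2):
    """Two-term variance model alpha1*x + alpha2*x(x/w-1)/ln(x/w).

    The drift factor has a removable singularity at x = w; a series guard
    evaluates the analytic limit x*(1 + delta/2 - delta^2/12) for
    |ln(x/w)| < 1e-6.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    r = x / w
    lr = np.log(r)
    delta = r - 1.0
    small = np.abs(lr) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(small, x * (1.0 + delta / 2.0 - delta ** 2 / 12.0),
                          x * delta / np.where(small, 1.0, lr))
    return alpha1 * x + alpha2 * factor


@dataclass
class DriftFit:
    alpha: tuple
    alpha_sigma: tuple
    netau: float
    deff: float
    sigma_netau: float
    sigma_deff: float
    t: float
    reported: bool          #: passes the relative-uncertainty filters
    converged: bool = True


def fit_alpha(w_mean, x_mean, y_mean, sigma_y, p0=None):
    """Weighted nonlinear least squares of binned <Y> on g_alpha(<W>, <X>).

    Returns ``(alpha, alpha_sigma, converged)`` with uncertainties from the
    diagonal of the fit covariance (absolute sigma).
    """
    w_mean = np.asarray(w_mean, dtype=float)
    x_mean = np.asarray(x_mean, dtype=float)
    y_mean = np.asarray(y_mean, dtype=float)
    if p0 is None:
        fano = float(np.median(y_mean / x_mean))
        p0 = [max(fano, 1e-12), max(fano, 1e-12)]

    def _model(wx, a1, a2):
        return g_alpha(wx[0], wx[1], a1, a2)

    try:
        popt, pcov = curve_fit(_model, (w_mean, x_mean), y_mean, p0=p0,
                               sigma=np.asarray(sigma_y, dtype=float),
                               absolute_sigma=True, maxfev=20_000)
    except RuntimeError:
        nan = float("nan")
        return (nan, nan), (nan, nan), False
    s = np.sqrt(np.diag(pcov))
    return (float(popt[0]), float(popt[1])), (float(s[0]), float(s[1])), True


def fit_Ne_tau(regset: DriftRegressionSet, t: float | None = None,
               n_bins: int = 8, n_boot: int = 1_000, seed: int = 0) -> DriftFit:
    """Invert the binned variance regression to estimate Ne*tau_e.

    Bin means here are *untrimmed*: g_alpha predicts the expectation of the
    across-replicate sample variance, and with few replicates that sample
    variance is chi-square-skewed, so a decile-trimmed mean underestimates
    it by a factor that grows with the drift contribution and would bias
    Ne*tau_e upward; the trimmed means are reserved for the robust
    permutation statistic in :func:`drift_test`.

    Ne*tau_e = t/alpha2* and D_eff = 1/alpha1* (kappa is absorbed into
    D_eff rather than estimated separately); uncertainties come from the
    diagonal of the fit covariance by the delta method.  The estimate is only
    flagged ``reported`` when |sigma_Ntau/Ntau| < 1 and
    |sigma_Deff/Deff| < 0.25; alpha is unconstrained, and a negative alpha2
    (anti-drift sign) in practice always fails the filter.
    """
    if t is None:
        t = regset.t
    rng = np.random.default_rng(seed)
    binned = _bin_set(regset, n_bins, n_boot, rng, trim=False)
    (a1, a2), (s1, s2), converged = fit_alpha(binned.w_mean, binned.x_mean,
                                              binned.y_mean, binned.sigma_y)
    if not converged:
        logger.info("fit_Ne_tau: curve_fit failed to converge")
        nan = float("nan")
        return DriftFit((nan, nan), (nan, nan), nan, nan, nan, nan, t,
                        reported=False, converged=False)
    netau = t / a2 if a2 != 0 else float("inf")
    deff = 1.0 / a1 if a1 != 0 else float("inf")
    sigma_netau = abs(t * s2 / a2 ** 2) if a2 != 0 else float("inf")
    sigma_deff = abs(s1 / a1 ** 2) if a1 != 0 else float("inf")
    reported = (np.isfinite(netau) and np.isfinite(deff) and a2 > 0
                and abs(sigma_netau / netau) < 1.0
                and abs(sigma_deff / deff) < 0.25)
    return DriftFit((float(a1), float(a2)), (float(s1), float(s2)),
                    float(netau), float(deff), float(sigma_netau),
                    float(sigma_deff), t, bool(reported))
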