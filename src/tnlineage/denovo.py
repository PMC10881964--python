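"""Signatures of within-host de novo mutations via cross-host divergence.

A beneficial mutation arising de novo inside one host sweeps through its Tn
lineage in that host only, so the lineage's final frequency diverges from the
other biological replicates.  The divergence score of a lineage is the ratio
of its largest to second-largest final-timepoint frequency across hosts,

    Delta = f_(1) / f_(2) >= 1.

Large Delta can also be produced by sampling noise at low frequency, so scores
are only computed for lineages reaching >0.1% frequency in some host, and the
observed distribution is compared against a control set matched on the
day-0 frequency distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FREQ_THRESHOLD = 1e-3
N_MATCH_BINS = 20


@dataclass
class DivergenceResult:
    lineage_id: str
    focal_host: str
    delta: float
    sorted_freqs: np.ndarray
    passed_threshold: bool


def divergence_scores(final_freqs: pd.DataFrame, depths: pd.Series,
                      threshold: float = FREQ_THRESHOLD) -> pd.DataFrame:
    """Divergence score per lineage from final-timepoint frequencies.

    ``final_freqs`` is lineage x host; ``depths`` gives each host's pooled
    depth at the final timepoint.  A zero second-largest frequency is replaced
    by one read at the second-ranked host's depth (1/D), which keeps Delta
    finite and conservative.  Host-frequency ties are broken by host id, so
    the result is invariant to relabeling the non-focal hosts.
    """
    if final_freqs.shape[1] < 2:
        raise ValueError("need final-timepoint samples from at least 2 hosts")
    hosts = list(final_freqs.columns)
    F = final_freqs.to_numpy(dtype=float)
    # sort per row: primary key frequency desc, tie-break host id asc
    host_order = np.argsort(hosts)
    rows = []
    for i, lid in enumerate(final_freqs.index):
        f = F[i]
        order = sorted(range(len(hosts)), key=lambda j: (-f[j], hosts[j]))
        f_sorted = f[order]
        focal = hosts[order[0]]
        f2 = f_sorted[1]
        if f2 == 0:
            f2 = 1.0 / float(depths[hosts[order[1]]])
        delta = f_sorted[0] / f2 if f_sorted[0] > 0 else np.nan
        rows.append((lid, focal, delta, f_sorted[0] > threshold))
    out = pd.DataFrame(rows, columns=["lineage_id", "focal_host", "delta",
                                      "passed_threshold"]).set_index("lineage_id")
    return out


def matched_null(focal_f0: pd.Series, control_f0: pd.Series,
                 control_delta: pd.Series, seed: int,
                 n_bins: int = N_MATCH_BINS) -> pd.Series:
    """Null divergence scores from controls matched on day-0 frequency.

    Controls (lineages measured at the final day in >=2 hosts, with
    precomputed Delta) are sampled per log-spaced day-0 frequency bin to match
    the focal set's histogram; an empty control bin falls back to the nearest
    populated bin (logged).  Sampling is with replacement when a bin has
    fewer controls than focal lineages.
    """
    rng = np.random.default_rng(seed)
    focal_f0 = focal_f0[focal_f0 > 0]
    control_f0 = control_f0[control_f0 > 0]
    control_f0 = control_f0[control_f0.index.isin(control_delta.index)]
    if focal_f0.empty or control_f0.empty:
        raise ValueError("no positive day-0 frequencies to match on")
    lo, hi = focal_f0.min(), focal_f0.max()
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[0] *= 1 - 1e-9
    edges[-1] *= 1 + 1e-9
    fbin = np.clip(np.digitize(focal_f0.to_numpy(), edges) - 1, 0, n_bins - 1)
    cbin = np.clip(np.digitize(control_f0.to_numpy(), edges) - 1, 0, n_bins - 1)
    picks = []
    populated = np.unique(cbin)
    for b in range(n_bins):
        need = int((fbin == b).sum())
        if need == 0:
            continue
        use_bin = b
        if not (cbin == b).any():
            use_bin = populated[np.argmin(np.abs(populated - b))]
            logger.info("matched_null: bin %d empty, using nearest bin %d", b, use_bin)
        pool = control_f0.index[cbin == use_bin]
        replace = len(pool) < need
        picks.extend(rng.choice(pool, size=need, replace=replace))
    # index = picked control lineage ids (repeats possible with replacement)
    return pd.Series(control_delta.loc[picks].to_numpy(), index=picks)


def final_frequency_table(table, day: float, kind: str = "fecal"):
    """Per-host pooled frequencies and depths at the final timepoint.

    Returns ``(freqs, depths)`` with one column/entry per host that has a
    sample at ``day``.
    """
    from .count_io import pool_samples
    meta = table.samples
    mask = (meta["day"] == day) & (meta["kind"] == kind)
    freqs = {}
    depths = {}
    for host, grp in meta[mask].groupby("host_id"):
        pooled = pool_samples(table, grp.index)
        freqs[host] = pooled.freqs
        depths[host] = pooled.depth
    if len(freqs) < 2:
        raise ValueError(f"need >=2 hosts with samples at day {day}")
    return pd.DataFrame(freqs), pd.Series(depths)
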