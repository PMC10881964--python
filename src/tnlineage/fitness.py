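"""Time-averaged relative fitness estimation from pooled lineage frequencies.

The relative fitness chi of a lineage over an interval [t0, t1] is the
time-average of its instantaneous growth rate relative to the population mean,
estimated from cohort-pooled frequencies with a conservative pseudocount
structure:

    chi = (1/(t1-t0)) * ln( max{f(t1), min{1/D(t1), f(t0)}}
                          / max{f(t0), min{1/D(t0), f(t1)}} )

When both frequencies are positive this is the standard log-ratio estimator;
when one endpoint is zero the min{.} floor acts as an effective pseudocount
that is conservatively biased towards zero relative fitness for lineages that
are too rare to resolve (e.g. f(t0) < 1/D(t1) gives chi = 0 exactly).  When
both endpoints are zero the estimator is 0/0 and the lineage is flagged
undefined; undefined lineages are excluded from downstream rank and
correlation computations rather than imputed at zero.

Natural logarithms are used throughout; chi is per day (per passage for the
in vitro and library-creation pseudo-environments, where t1 - t0 := 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .count_io import CohortPooledFrequencies, CountTable, INPUT_KIND, pool_samples


def _chi_arrays(f0, f1, D0, D1, dt):
    f0 = np.asarray(f0, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    floor1 = np.minimum(1.0 / D1, f0)
    floor0 = np.minimum(1.0 / D0, f1)
    num = np.maximum(f1, floor1)
    den = np.maximum(f0, floor0)
    defined = ~((f0 == 0) & (f1 == 0))
    clamped = defined & ((num != f1) | (den != f0))
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.log(num / den) / dt
    chi = np.where(defined, chi, np.nan)
    return chi, clamped, defined


def relative_fitness(pooled0: CohortPooledFrequencies, pooled1: CohortPooledFrequencies,
                     t0: float, t1: float) -> pd.DataFrame:
    """Per-lineage relative fitness between two pooled timepoints.

    Returns a DataFrame indexed by lineage with columns ``chi`` (per day),
    ``clamped`` (a pseudocount floor was active) and ``defined`` (False iff
    both pooled frequencies are zero, in which case ``chi`` is NaN).
    """
    if t1 <= t0:
        raise ValueError(f"t1 ({t1}) must exceed t0 ({t0})")
    f0, f1 = pooled0.freqs.align(pooled1.freqs, join="inner")
    chi, clamped, defined = _chi_arrays(
        f0.to_numpy(), f1.to_numpy(), pooled0.depth, pooled1.depth, t1 - t0)
    return pd.DataFrame({"chi": chi, "clamped": clamped, "defined": defined},
                        index=f0.index)


def chi_scalar(f0: float, f1: float, D0: float, D1: float, dt: float) -> float:
    """Scalar convenience wrapper for the pseudocounted log-ratio estimator."""
    chi, _, defined = _chi_arrays([f0], [f1], D0, D1, dt)
    return float(chi[0]) if defined[0] else float("nan")


def library_creation_fitness(input_table: CountTable) -> pd.DataFrame:
    """Fitness in the library-creation pseudo-environment.

    All lineages are assumed to be founded by single cells, so the input
    frequency spread reflects differential growth during library creation.
    Applies the standard estimator with a uniform initial frequency 1/L and an
    arbitrary interval t1 - t0 = 1 (chi is per passage).
    """
    inp = input_table.samples.index[input_table.samples["kind"] == INPUT_KIND]
    pooled = pool_samples(input_table, inp)
    L = len(pooled.freqs)
    f0 = np.full(L, 1.0 / L)
    chi, clamped, defined = _chi_arrays(f0, pooled.freqs.to_numpy(),
                                        pooled.depth, pooled.depth, 1.0)
    return pd.DataFrame({"chi": chi, "clamped": clamped, "defined": defined},
                        index=pooled.freqs.index)


def coarse_grained_fitness(members, pooled0: CohortPooledFrequencies,
                           pooled1: CohortPooledFrequencies,
                           t0: float, t1: float) -> float:
    """Relative fitness of a lineage group, via its summed pooled frequency.

    Equivalent (when every member is observed) to the frequency-weighted
    log-mean-exponential of the members' individual fitnesses, so the group
    value always lies within [min, max] of the member values.  Returns NaN
    if the group has zero total frequency at both timepoints.
    """
    members = list(members)
    if not members:
        raise ValueError("empty lineage group")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    f0 = float(pooled0.freqs.loc[members].sum())
    f1 = float(pooled1.freqs.loc[members].sum())
    return chi_scalar(f0, f1, pooled0.depth, pooled1.depth, t1 - t0)


def gene_complement_fitness(lineage, gene_map: pd.Series,
                            pooled0: CohortPooledFrequencies,
                            pooled1: CohortPooledFrequencies,
                            t0: float, t1: float) -> float:
    """Coarse-grained fitness of all *other* lineages in the focal lineage's
    gene.  NaN when the focal lineage is unassigned or the complement is
    empty (singleton gene)."""
    gene = gene_map.get(lineage)
    if gene is None or (isinstance(gene, float) and np.isnan(gene)):
        return float("nan")
    others = gene_map.index[(gene_map == gene) & (gene_map.index != lineage)]
    if not len(others):
        return float("nan")
    return coarse_grained_fitness(others, pooled0, pooled1, t0, t1)


def gene_complement_fitness_all(gene_map: pd.Series,
                                pooled0: CohortPooledFrequencies,
                                pooled1: CohortPooledFrequencies,
                                t0: float, t1: float) -> pd.Series:
    """Vectorized gene-complement fitness for every assigned lineage.

    For each gene, the complement frequency of member l is the gene total
    minus l's own frequency at each endpoint; the estimator is then applied
    to those complement frequencies.
    """
    assigned = gene_map.dropna()
    f0 = pooled0.freqs.reindex(assigned.index).to_numpy()
    f1 = pooled1.freqs.reindex(assigned.index).to_numpy()
    gene_f0 = pd.Series(f0, index=assigned.index).groupby(assigned).transform("sum").to_numpy()
    gene_f1 = pd.Series(f1, index=assigned.index).groupby(assigned).transform("sum").to_numpy()
    sizes = assigned.groupby(assigned).transform("size").to_numpy()
    c0 = gene_f0 - f0
    c1 = gene_f1 - f1
    chi, _, defined = _chi_arrays(c0, c1, pooled0.depth, pooled1.depth, t1 - t0)
    chi = np.where(sizes > 1, chi, np.nan)  # singleton gene: empty complement
    chi = np.where(defined, chi, np.nan)
    return pd.Series(chi, index=assigned.index).reindex(gene_map.index)
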