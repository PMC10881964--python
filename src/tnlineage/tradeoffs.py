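"""Pleiotropy across environments: joint fitness estimation and tradeoffs.

Fitness in a pair of environments (diet x time-interval combinations, or in
vitro media) is always estimated from *non-overlapping* host cohorts, so that
sampling fluctuations in one environment cannot leak into the other; this is
what makes near-diagonal scatter across a split of the same environment an
honest signal of shared fitness.

Tradeoff labels are purely descriptive sign classifications of the point
estimates (opposite signs = tradeoff, both positive = "generalist", etc.);
no significance machinery is attached to them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .count_io import CountTable, INPUT_KIND, pool_cohort, pool_samples
from .discovery import INPUT_FREQ_THRESHOLD, MIN_EXPECTED_VALIDATION_READS
from .fitness import relative_fitness

logger = logging.getLogger(__name__)

#: diet of each canonical condition during interval k (0-based); alternating
#: diets are grouped with the matching constant diet per interval.
_INTERVAL_DIET = {
    ("LF/HPP", 0): "L", ("LF/HPP", 1): "L", ("LF/HPP", 2): "L",
    ("HF/HS", 0): "H", ("HF/HS", 1): "H", ("HF/HS", 2): "H",
    ("LHL", 0): "L", ("LHL", 1): "H", ("LHL", 2): "L",
    ("HLH", 0): "H", ("HLH", 1): "L", ("HLH", 2): "H",
}

INTERVAL_INDEX = {(0.0, 4.0): 0, (4.0, 10.0): 1, (10.0, 16.0): 2}


@dataclass(frozen=True)
class EnvSpec:
    """An environment: a condition (diet or medium) over a time interval."""

    label: str
    diet: str       #: diet/medium label the cohort must experience in the interval
    t0: float
    t1: float


@dataclass
class EnvFitnessMatrix:
    chi: pd.DataFrame        #: lineage x environment relative fitnesses
    defined: pd.DataFrame    #: per-entry defined mask
    cohorts: dict            #: env label -> tuple of host ids (disjoint)


def hosts_for_environment(table: CountTable, env: EnvSpec,
                          group_alternating: bool = True) -> list[str]:
    """Hosts whose condition exposes them to ``env.diet`` during [t0, t1].

    With ``group_alternating`` (default), mice on alternating diets are
    grouped with the matching constant diet in each interval; otherwise only
    exact condition-label matches count.
    """
    meta = table.samples
    fecal = meta[meta["kind"] != INPUT_KIND]
    out = []
    k = INTERVAL_INDEX.get((env.t0, env.t1))
    for host, grp in fecal.groupby("host_id"):
        cond = grp["condition"].iloc[0]
        if cond == env.diet:
            out.append(host)
        elif group_alternating and k is not None and _INTERVAL_DIET.get((cond, k)) == env.diet:
            out.append(host)
    return sorted(out)


def _pool_env(table: CountTable, hosts, day, input_samples):
    if day == 0:
        return pool_samples(table, input_samples)
    return pool_cohort(table, hosts, day)


def env_fitness_pair(table: CountTable, env1: EnvSpec, env2: EnvSpec, seed: int,
                     hosts1=None, hosts2=None, group_alternating: bool = True,
                     nonzero_only: bool = False) -> EnvFitnessMatrix:
    """Joint per-lineage fitness in two environments from disjoint cohorts.

    Hosts eligible for both environments are split between them at random
    (seeded); explicitly requested overlapping host sets are an error.
    Lineages must clear the expected-read filter in at least one of the two
    environments (with the other environment's depths playing the validation
    role).  With ``nonzero_only`` the matrix is further restricted to lineages
    observed at non-zero pooled frequency at both timepoints in both
    environments, which removes the pseudocount floors that otherwise
    attenuate cross-environment correlations.
    """
    inp = sorted(table.samples.index[table.samples["kind"] == INPUT_KIND])
    if hosts1 is not None and hosts2 is not None:
        if set(hosts1) & set(hosts2):
            raise ValueError("explicit cohorts overlap")
        hosts1, hosts2 = sorted(hosts1), sorted(hosts2)
        rng = np.random.default_rng(seed)
    else:
        cand1 = hosts_for_environment(table, env1, group_alternating)
        cand2 = hosts_for_environment(table, env2, group_alternating)
        shared = sorted(set(cand1) & set(cand2))
        rng = np.random.default_rng(seed)
        perm = [shared[i] for i in rng.permutation(len(shared))]
        half = len(perm) // 2
        to1, to2 = set(perm[:half]), set(perm[half:])
        hosts1 = sorted((set(cand1) - set(shared)) | to1)
        hosts2 = sorted((set(cand2) - set(shared)) | to2)
    if not hosts1 or not hosts2:
        raise ValueError("need at least one host per environment")

    iperm = [inp[i] for i in rng.permutation(len(inp))] if inp else []
    inp1, inp2 = iperm[: (len(iperm) + 1) // 2], iperm[(len(iperm) + 1) // 2:]

    res = {}
    pools = {}
    for env, hosts, isplit in ((env1, hosts1, inp1), (env2, hosts2, inp2)):
        p0 = _pool_env(table, hosts, env.t0, isplit)
        p1 = _pool_env(table, hosts, env.t1, isplit)
        res[env.label] = relative_fitness(p0, p1, env.t0, env.t1)
        pools[env.label] = (p0, p1)

    # expected-read eligibility in >=1 of the two environments
    (a0, a1), (b0, b1) = pools[env1.label], pools[env2.label]
    ok = pd.Series(False, index=res[env1.label].index)
    for (d0, d1), (o0, o1) in (((a0, a1), (b0, b1)), ((b0, b1), (a0, a1))):
        fmax = np.maximum(d0.freqs, d1.freqs)
        ok |= min(o0.depth, o1.depth) * fmax > MIN_EXPECTED_VALIDATION_READS
    if inp:
        ok &= pool_samples(table, inp).freqs > INPUT_FREQ_THRESHOLD
    if nonzero_only:
        for p0, p1 in pools.values():
            ok &= (p0.freqs > 0) & (p1.freqs > 0)

    chi = pd.DataFrame({env1.label: res[env1.label]["chi"],
                        env2.label: res[env2.label]["chi"]})[ok]
    defined = pd.DataFrame({env1.label: res[env1.label]["defined"],
                            env2.label: res[env2.label]["defined"]})[ok]
    return EnvFitnessMatrix(chi, defined,
                            {env1.label: tuple(hosts1), env2.label: tuple(hosts2)})


def replicate_pair_correlation(table: CountTable, env1: EnvSpec, env2: EnvSpec,
                               group_alternating: bool = True,
                               min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation of chi between single-host biological replicates.

    For every ordered pair (one host per environment, distinct hosts) chi is
    estimated from that host alone; to avoid pseudocount bias only lineages
    observed at non-zero frequency at both timepoints in both replicates enter
    the correlation.  Pairs with fewer than ``min_shared`` such lineages are
    reported with r = NaN.
    """
    inp = sorted(table.samples.index[table.samples["kind"] == INPUT_KIND])
    rows = []
    hosts1 = hosts_for_environment(table, env1, group_alternating)
    hosts2 = hosts_for_environment(table, env2, group_alternating)

    def single_host_chi(host, env):
        p0 = _pool_env(table, [host], env.t0, inp)
        p1 = _pool_env(table, [host], env.t1, inp)
        df = relative_fitness(p0, p1, env.t0, env.t1)
        nz = (p0.freqs > 0) & (p1.freqs > 0)
        return df["chi"], nz

    cache = {}
    for h1, h2 in itertools.product(hosts1, hosts2):
        if h1 == h2 and env1.label == env2.label:
            continue
        if (h1, env1.label) not in cache:
            cache[(h1, env1.label)] = single_host_chi(h1, env1)
        if (h2, env2.label) not in cache:
            cache[(h2, env2.label)] = single_host_chi(h2, env2)
        c1, nz1 = cache[(h1, env1.label)]
        c2, nz2 = cache[(h2, env2.label)]
        shared = nz1 & nz2
        n = int(shared.sum())
        if n < min_shared:
            logger.info("pair (%s, %s): only %d shared lineages; correlation undefined",
                        h1, h2, n)
            r = np.nan
        else:
            a, b = c1[shared], c2[shared]
            if a.std() == 0 or b.std() == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(a, b).statistic)
        rows.append((env1.label, env2.label, h1, h2, r, n))
    return pd.DataFrame(rows, columns=["env1", "env2", "host1", "host2", "r", "n_lineages"])


def classify_tradeoffs(chi1: pd.Series, chi2: pd.Series) -> pd.Series:
    """Sign-based pleiotropy labels for paired fitness estimates.

    opposite signs -> ``tradeoff``; both > 0 -> ``concordant-beneficial``;
    both < 0 -> ``concordant-deleterious``; any exact zero -> ``mixed-null``;
    any NaN -> ``missing``.
    """
    c1, c2 = chi1.align(chi2, join="inner")
    out = pd.Series("mixed-null", index=c1.index, dtype=object)
    out[(c1 > 0) & (c2 > 0)] = "concordant-beneficial"
    out[(c1 < 0) & (c2 < 0)] = "concordant-deleterious"
    out[((c1 > 0) & (c2 < 0)) | ((c1 < 0) & (c2 > 0))] = "tradeoff"
    out[c1.isna() | c2.isna()] = "missing"
    return out
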