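"""Multi-environment fitness profiles and phenotypic clustering.

A fitness profile W is the vector of natural-log fold changes of a lineage
(or of the summed frequency of a set of lineages) across a panel of
environments, with frequencies measured against the *whole* library
(fitness-determinant genes included).  Profiles are compared by Euclidean
distance.  Two complementary searches are supported:

* knockout-like lineages: adaptive lineages, far (>100 kb) from a curated
  strongly-beneficial gene, whose profile falls within distance d* of that
  gene's knockout profile -- candidates for secondary loss-of-function
  mutations in the gene or its pathway;
* novel clusters: agglomerative (average-linkage) clustering of highly fit
  lineages with merge cutoff epsilon, followed by remapping of all fully
  measured lineages, size/multi-hit filters, and comparison against
  split-averaged gene profiles; clusters far from every gene profile are
  candidates for phenotypes with no knockout counterpart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .count_io import CountTable, GeneAnnotation, INPUT_KIND, pool_cohort, pool_samples
from .tradeoffs import EnvSpec, hosts_for_environment

logger = logging.getLogger(__name__)

D_STAR = 2.0          #: lineage-to-gene-profile match threshold
EPSILON = 4.0         #: agglomerative merge cutoff / remap radius
MIN_DISTANCE_BP = 100_000
NOVELTY_THRESHOLD = 4.0  #: min over genes of D above which a cluster is "novel"


# ---------------------------------------------------------------------------
# Environments


def build_environments(conditions, timepoints=(0.0, 4.0, 10.0, 16.0),
                       history_map=None, invitro_media=()) -> list[EnvSpec]:
    """Environment panel: one entry per (interval, diet-history-so-far).

    Conditions sharing the same diet history up to an interval's end are
    merged into one environment (e.g. constant-LF and LHL mice are the same
    environment during days 0-4).  With the four canonical diet histories and
    three intervals this yields the 10 in vivo environments; in vitro media
    are appended as single-passage environments (t1 - t0 := 1).
    """
    from .simulate import DIET_HISTORIES
    history_map = dict(DIET_HISTORIES if history_map is None else history_map)
    tps = list(timepoints)
    intervals = list(zip(tps[:-1], tps[1:]))
    envs = []
    seen = set()
    for k, (a, b) in enumerate(intervals):
        for cond in conditions:
            hist = history_map.get(cond, (cond,) * len(intervals))
            key = (k, tuple(hist[: k + 1]))
            if key in seen:
                continue
            seen.add(key)
            label = f"d{int(a)}-{int(b)}:{'' .join(hist[:k + 1])}"
            envs.append(EnvSpec(label, hist[k], float(a), float(b)))
    for medium in invitro_media:
        envs.append(EnvSpec(f"invitro:{medium}", medium, 0.0, 1.0))
    return envs


@dataclass
class EnvPools:
    """Pooled whole-library frequencies at both endpoints of each environment."""

    envs: list
    f0: pd.DataFrame  #: lineage x env pooled frequency at t0
    f1: pd.DataFrame  #: lineage x env pooled frequency at t1


def environment_pools(table: CountTable, envs, hosts_by_env=None,
                      group_alternating: bool = True) -> EnvPools:
    """Compute cohort-pooled endpoint frequencies for every environment.

    ``hosts_by_env`` optionally overrides the cohort per environment label
    (used for replicate-half splits); day-0 endpoints pool the input
    technical replicates.
    """
    inp = sorted(table.samples.index[table.samples["kind"] == INPUT_KIND])
    f0, f1 = {}, {}
    for env in envs:
        hosts = (hosts_by_env or {}).get(env.label)
        if hosts is None:
            hosts = hosts_for_environment(table, env, group_alternating)
        if env.t0 == 0 and inp:
            p0 = pool_samples(table, inp)
        else:
            p0 = pool_cohort(table, hosts, env.t0)
        p1 = pool_cohort(table, hosts, env.t1)
        f0[env.label] = p0.freqs
        f1[env.label] = p1.freqs
    return EnvPools(list(envs), pd.DataFrame(f0), pd.DataFrame(f1))


# ---------------------------------------------------------------------------
# Profiles and distances


def lineage_profiles(pools: EnvPools) -> pd.DataFrame:
    """Per-lineage profile matrix W = ln(f1/f0); NaN where either endpoint is 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.log(pools.f1.to_numpy() / pools.f0.to_numpy())
    W[~np.isfinite(W)] = np.nan
    return pd.DataFrame(W, index=pools.f0.index, columns=pools.f0.columns)


def set_profile(members, pools: EnvPools) -> np.ndarray:
    """Coarse-grained profile of a lineage set: log fold change of the summed
    frequency per environment (NaN where an endpoint sum is zero)."""
    members = list(members)
    s0 = pools.f0.loc[members].sum(axis=0).to_numpy()
    s1 = pools.f1.loc[members].sum(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.log(s1 / s0)
    W[~np.isfinite(W)] = np.nan
    return W


def profile_distance(w: np.ndarray, w2: np.ndarray) -> float:
    """Euclidean distance over the shared unmasked components (NaN if none)."""
    w = np.asarray(w, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    ok = np.isfinite(w) & np.isfinite(w2)
    if not ok.any():
        return float("nan")
    return float(np.sqrt(((w[ok] - w2[ok]) ** 2).sum()))


def genomic_distance(position: int, contig: str, gene: GeneAnnotation) -> float:
    """Distance from an insertion point to a gene interval (0 if inside);
    infinite across contigs."""
    if contig != gene.contig:
        return float("inf")
    if gene.start <= position <= gene.end:
        return 0.0
    return float(min(abs(position - gene.start), abs(position - gene.end)))


# ---------------------------------------------------------------------------
# Knockout curation


@dataclass
class KnockoutProfile:
    gene_id: str
    members: list
    profile: np.ndarray            #: full coarse-grained profile (no exclusions)
    leave_one_out: pd.DataFrame    #: one profile per excluded member
    split_profiles: tuple | None = None  #: (W1, W2) from a random two-part split


def _passes(W, strong: float, weak: float) -> bool:
    W = np.asarray(W, dtype=float)
    ok = np.isfinite(W)
    return bool((W[ok] > strong).any() or (W[ok] > weak).sum() >= 2)


def curate_beneficial_knockouts(gene_map: pd.Series, pools: EnvPools) -> dict:
    """Curate strongly beneficial gene knockouts robust to single lineages.

    Stage 1 keeps genes whose full knockout profile shows fold change >10 in
    at least one environment, or >5 in at least two.  Stage 2 requires every
    leave-one-out profile (each excluding a single member lineage) to retain
    fold change >5 in one environment or >3 in two -- genes whose signal
    collapses when one lineage is removed are driven by a secondary mutation
    in that lineage, not by the knockout.  Genes with <2 lineages cannot pass.
    """
    out = {}
    assigned = gene_map.dropna()
    for gene, members in assigned.groupby(assigned).groups.items():
        members = list(members)
        full = set_profile(members, pools)
        if not _passes(full, np.log(10), np.log(5)):
            continue
        if len(members) < 2:
            continue
        s0 = pools.f0.loc[members].to_numpy()
        s1 = pools.f1.loc[members].to_numpy()
        tot0, tot1 = s0.sum(axis=0), s1.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            loo = np.log((tot1 - s1) / (tot0 - s0))
        loo[~np.isfinite(loo)] = np.nan
        loo_df = pd.DataFrame(loo, index=members, columns=pools.f0.columns)
        if all(_passes(loo_df.loc[m].to_numpy(), np.log(5), np.log(3)) for m in members):
            out[gene] = KnockoutProfile(gene, members, full, loo_df)
    logger.info("curated %d strongly beneficial gene knockouts", len(out))
    return out


def screen_loo_outlier(ko: KnockoutProfile, pools: EnvPools, seed: int = 0) -> KnockoutProfile:
    """Drop a single outlying member detected by 2-means on the leave-one-out
    profiles, then recompute the gene profile.  A lone strongly adaptive
    lineage makes exactly one leave-one-out profile (the one excluding it)
    stand apart from all the others."""
    loo = ko.leave_one_out.dropna(axis=1)
    if len(ko.members) < 3 or loo.shape[1] == 0:
        return ko
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(loo.to_numpy())
    sizes = np.bincount(km.labels_, minlength=2)
    if sizes.min() != 1:
        return ko
    outlier_profile_idx = int(np.argmax(km.labels_ == np.argmin(sizes)))
    dropped = ko.members[outlier_profile_idx]
    members = [m for m in ko.members if m != dropped]
    logger.info("gene %s: removed outlying lineage %s before split profiles",
                ko.gene_id, dropped)
    return KnockoutProfile(ko.gene_id, members, set_profile(members, pools),
                           ko.leave_one_out.drop(index=dropped))


def gene_split_profiles(gene_map: pd.Series, pools: EnvPools, seed: int = 0,
                        min_members: int = 2, screen_outliers: bool = True) -> dict:
    """Random two-part split profiles (W1, W2) per gene.

    Members are first screened for a single strongly-outlying lineage (2-means
    on the leave-one-out set), then partitioned into two equal-sized halves
    (+-1); genes with an unmeasured component in either half are skipped.
    Returns gene -> KnockoutProfile with ``split_profiles`` populated.
    """
    rng = np.random.default_rng(seed)
    out = {}
    assigned = gene_map.dropna()
    for gene, members in assigned.groupby(assigned).groups.items():
        members = list(members)
        if len(members) < min_members:
            continue
        full = set_profile(members, pools)
        s0 = pools.f0.loc[members].to_numpy()
        s1 = pools.f1.loc[members].to_numpy()
        tot0, tot1 = s0.sum(axis=0), s1.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            loo = np.log((tot1 - s1) / (tot0 - s0))
        loo[~np.isfinite(loo)] = np.nan
        ko = KnockoutProfile(gene, members, full,
                             pd.DataFrame(loo, index=members, columns=pools.f0.columns))
        if screen_outliers:
            ko = screen_loo_outlier(ko, pools, seed=seed)
        mem = list(ko.members)
        if len(mem) < 2:
            continue
        perm = [mem[i] for i in rng.permutation(len(mem))]
        half = (len(perm) + 1) // 2
        w1 = set_profile(perm[:half], pools)
        w2 = set_profile(perm[half:], pools)
        if not (np.isfinite(w1).all() and np.isfinite(w2).all()):
            continue
        out[gene] = KnockoutProfile(gene, mem, ko.profile, ko.leave_one_out, (w1, w2))
    return out


# ---------------------------------------------------------------------------
# Clusters


@dataclass
class PhenotypeCluster:
    cluster_id: str
    members: list
    mean_profile: np.ndarray
    kind: str                      #: "knockout_like" | "novel" | "candidate"
    target_gene: str | None = None  #: target (knockout-like) or nearest gene
    distance: float = float("nan")  #: d to target / min D over genes


def assign_knockout_like(profiles: pd.DataFrame, ko: KnockoutProfile,
                         lineage_coords: pd.DataFrame, gene: GeneAnnotation,
                         gene_map: pd.Series | None = None,
                         d_star: float = D_STAR,
                         min_distance_bp: int = MIN_DISTANCE_BP) -> PhenotypeCluster:
    """Cluster of lineages resembling a curated beneficial knockout.

    Candidates must be measured in every environment, lie within ``d_star``
    of the gene's full knockout profile and be located more than
    ``min_distance_bp`` from the target gene (another contig counts as far).
    Any off-target gene represented by >=2 members has those members removed,
    since they could reflect a direct insertion effect in a related gene.
    """
    full = profiles.dropna(axis=0)
    members = []
    for lid, w in zip(full.index, full.to_numpy()):
        d = profile_distance(w, ko.profile)
        if not np.isfinite(d) or d >= d_star:
            continue
        row = lineage_coords.loc[lid]
        if genomic_distance(int(row["position"]), row["contig"], gene) <= min_distance_bp:
            continue
        members.append(lid)
    if gene_map is not None and members:
        genes = gene_map.reindex(members)
        counts = genes.value_counts()
        multi = set(counts.index[counts >= 2]) - {ko.gene_id}
        removed = [m for m in members if genes.get(m) in multi]
        if removed:
            logger.info("knockout-like cluster %s: removed %d multiply-represented "
                        "off-target lineages", ko.gene_id, len(removed))
        members = [m for m in members if m not in set(removed)]
    if not members:
        logger.info("knockout-like cluster for %s is empty", ko.gene_id)
        mean = np.full(profiles.shape[1], np.nan)
    else:
        mean = profiles.loc[members].mean(axis=0).to_numpy()
    return PhenotypeCluster(f"ko:{ko.gene_id}", members, mean, "knockout_like",
                            ko.gene_id,
                            profile_distance(mean, ko.profile) if members else float("nan"))


def _max_multiplicity(k: int) -> int:
    return max(1, int(np.floor(np.log10(k))))


def find_novel_clusters(profiles: pd.DataFrame, gene_map: pd.Series,
                        gene_profiles: dict | pd.DataFrame | None = None,
                        epsilon: float = EPSILON,
                        novelty_threshold: float = NOVELTY_THRESHOLD,
                        seed_min_w: float = float(np.log(10)),
                        min_size: int = 2) -> list[PhenotypeCluster]:
    """Discover recurrent phenotypes by clustering lineage fitness profiles.

    Steps: (i) seed set = fully measured lineages with max_k W > ``seed_min_w``;
    (ii) bottom-up average-linkage clustering with merge cutoff ``epsilon``;
    (iii) single-pass remap of every other fully measured lineage to its
    distance-minimizing cluster if d < epsilon, then recompute cluster means;
    (iv) drop singletons and clusters of size k where some gene contributes
    more than max{1, floor(log10 k)} members (multi-hit genes in a small
    cluster point to a shared insertion effect, not a shared secondary
    mutation); (v) compare survivors to the split-averaged gene profiles
    (shared lineages excluded on the gene side where possible) and label
    clusters whose minimum distance D exceeds ``novelty_threshold`` as novel.

    ``gene_profiles`` maps gene -> KnockoutProfile with split profiles (or a
    plain gene x environment DataFrame); pass None to skip step (v).
    """
    full = profiles.dropna(axis=0)
    seeds = full[(full.max(axis=1) > seed_min_w)]
    if seeds.empty:
        return []
    X = seeds.to_numpy()
    if len(seeds) == 1:
        labels = np.array([0])
    else:
        agg = AgglomerativeClustering(n_clusters=None, distance_threshold=epsilon,
                                      linkage="average", metric="euclidean")
        labels = agg.fit_predict(X)

    clusters: dict[int, list] = {}
    for lid, lab in zip(seeds.index, labels):
        clusters.setdefault(int(lab), []).append(lid)
    means = {lab: full.loc[mem].mean(axis=0).to_numpy() for lab, mem in clusters.items()}

    # (iii) single-pass remap of remaining fully measured lineages
    rest = full.drop(index=seeds.index)
    if len(rest) and clusters:
        labs = sorted(means)
        M = np.vstack([means[lab] for lab in labs])
        R = rest.to_numpy()
        d2 = ((R[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        bestd = np.sqrt(d2[np.arange(len(R)), best])
        for lid, j, d in zip(rest.index, best, bestd):
            if d < epsilon:
                clusters[labs[j]].append(lid)
        means = {lab: full.loc[mem].mean(axis=0).to_numpy()
                 for lab, mem in clusters.items()}

    out = []
    for lab in sorted(clusters):
        mem = sorted(clusters[lab])
        k = len(mem)
        if k < min_size:
            continue
        genes = gene_map.reindex(mem).dropna()
        if len(genes) and genes.value_counts().max() > _max_multiplicity(k):
            logger.info("cluster %d dropped: a gene is represented by %d/%d members",
                        lab, int(genes.value_counts().max()), k)
            continue
        mean = means[lab]
        nearest, min_d = None, float("inf")
        if gene_profiles is not None:
            items = (gene_profiles.items() if isinstance(gene_profiles, dict)
                     else gene_profiles.iterrows())
            for gid, gp in items:
                if isinstance(gp, KnockoutProfile):
                    if gp.split_profiles is not None:
                        w = 0.5 * (gp.split_profiles[0] + gp.split_profiles[1])
                    else:
                        w = gp.profile
                    shared = set(gp.members) & set(mem)
                    if shared and len(set(gp.members) - shared) >= 1:
                        w = None  # recompute excluding shared members below
                        gmem = [m for m in gp.members if m not in shared]
                        w = full.reindex(gmem).dropna().mean(axis=0).to_numpy() \
                            if gmem else gp.profile
                else:
                    w = np.asarray(gp, dtype=float)
                d = profile_distance(mean, w)
                if np.isfinite(d) and d < min_d:
                    nearest, min_d = gid, d
        kind = "novel" if (gene_profiles is not None and min_d > novelty_threshold) \
            else "candidate"
        out.append(PhenotypeCluster(f"c{lab}", mem, mean, kind, nearest,
                                    min_d if np.isfinite(min_d) else float("nan")))
    return out


# ---------------------------------------------------------------------------
# Replicate-split bands


def replicate_split_bands(members, table: CountTable, envs, seed: int = 0,
                          group_alternating: bool = True):
    """Replicate-averaged profiles and spread bands for a cluster.

    Biological replicates are split per environment into two halves; each
    lineage's band profile is the unweighted mean of its two half-cohort
    profiles (lineages unmeasured in either half are dropped).  The band is
    the per-environment interquartile range when the cluster has >=10
    usable lineages, the full range otherwise.

    Returns ``(per_lineage_profiles, lo, hi)``.
    """
    rng = np.random.default_rng(seed)
    halves = ({}, {})
    for env in envs:
        hosts = hosts_for_environment(table, env, group_alternating)
        if len(hosts) < 2:
            raise ValueError(f"environment {env.label} needs >=2 replicates to split")
        perm = [hosts[i] for i in rng.permutation(len(hosts))]
        half = (len(perm) + 1) // 2
        halves[0][env.label] = sorted(perm[:half])
        halves[1][env.label] = sorted(perm[half:])
    pools1 = environment_pools(table, envs, hosts_by_env=halves[0],
                               group_alternating=group_alternating)
    pools2 = environment_pools(table, envs, hosts_by_env=halves[1],
                               group_alternating=group_alternating)
    W1 = lineage_profiles(pools1).loc[list(members)]
    W2 = lineage_profiles(pools2).loc[list(members)]
    avg = 0.5 * (W1 + W2)
    avg = avg.dropna(axis=0)
    if avg.empty:
        raise ValueError("no cluster member measured in both replicate halves")
    if len(avg) >= 10:
        lo = avg.quantile(0.25)
        hi = avg.quantile(0.75)
    else:
        lo = avg.min()
        hi = avg.max()
    return avg, lo, hi
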