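"""End-to-end orchestration and Fig.-1-style frequency-shift diagnostics.

Stages communicate through plain tabular files so every stage can be re-run
independently; a run manifest records the configuration, seeds, and a
checksum for every output file, making runs byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import count_io, denovo, discovery, drift, simulate
from .count_io import CountTable, INPUT_KIND, pool_samples
from .fitness import relative_fitness

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "fitness", "discover", "tradeoffs", "cluster",
          "denovo", "drift", "diagnose")
#: stage -> stages it requires
DEPS = {
    "preprocess": ("simulate",),
    "fitness": ("preprocess",),
    "discover": ("preprocess",),
    "tradeoffs": ("preprocess",),
    "cluster": ("preprocess",),
    "denovo": ("preprocess",),
    "drift": ("preprocess",),
    "diagnose": ("preprocess",),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``counts_path``/``metadata_path`` point at an existing dataset, or
    ``simulation`` carries keyword arguments for
    :class:`tnlineage.simulate.SimulationConfig` and the data are generated.
    """

    seed: int = 0
    stages: tuple = STAGES
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    determinants_path: str | None = None
    simulation: dict = field(default_factory=dict)
    window: int = 100
    final_window: tuple = (7e-5, 8e-5)
    initial_window: tuple = (0.0, float("inf"))
    n_bins: int = 8
    n_perm: int = 10_000
    n_boot: int = 1_000

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Frequency-shift diagnostics


def frequency_shift_distribution(table: CountTable, host: str, day: float = 4.0,
                                 f0_window: tuple = (10.0, 15.0)):
    """Observed vs technical-null distribution of early read counts.

    Day-0 frequencies are estimated by pooling all but one of the input
    technical replicates; lineages whose pooled input frequency falls in
    ``[f0_window[0]/D, f0_window[1]/D]`` (D = the outcome sample's depth) are
    selected, and their read counts in the host's day-``day`` sample form the
    observed distribution.  The same selection applied to the held-out input
    replicate (with its own depth) gives a null showing technical noise alone.

    Returns ``(observed_counts, null_counts)``; the null is None (with a
    warning) when fewer than two input replicates exist.
    """
    meta = table.samples
    inp = sorted(meta.index[meta["kind"] == INPUT_KIND])
    if not inp:
        raise ValueError("no input technical replicates")
    held_out = inp[-1]
    pool_in = pool_samples(table, inp[:-1]) if len(inp) > 1 else pool_samples(table, inp)

    host_samples = meta.index[(meta["host_id"] == host) & (meta["day"] == day)]
    if not len(host_samples):
        raise ValueError(f"host {host} has no sample at day {day}")
    obs_sample = host_samples[0]
    D = float(table.counts[obs_sample].sum())
    sel = ((pool_in.freqs >= f0_window[0] / D) & (pool_in.freqs <= f0_window[1] / D))
    observed = table.counts.loc[sel, obs_sample].to_numpy()

    if len(inp) < 2:
        logger.warning("only one input replicate: no technical null available")
        return observed, None
    Dn = float(table.counts[held_out].sum())
    sel_null = ((pool_in.freqs >= f0_window[0] / Dn) & (pool_in.freqs <= f0_window[1] / Dn))
    null = table.counts.loc[sel_null, held_out].to_numpy()
    return observed, null


def joint_replicate_distribution(table: CountTable, host_pair, day: float = 4.0,
                                 f0_window: tuple = (2e-5, 3e-5), n_bins: int = 10):
    """Joint day-``day`` count histogram for two hosts plus a factorized null.

    Lineages are selected by pooled input frequency within ``f0_window``.
    Under host-independent dynamics the joint distribution factorizes,
    p(R1, R2) = p(R1) p(R2); the returned factorized null is the outer
    product of the marginal histograms, and ``spearman_r``/``p`` quantify the
    departure from independence.
    """
    from scipy import stats as sps
    meta = table.samples
    inp = sorted(meta.index[meta["kind"] == INPUT_KIND])
    pool_in = pool_samples(table, inp)
    sel = (pool_in.freqs > f0_window[0]) & (pool_in.freqs < f0_window[1])
    if not sel.any():
        raise ValueError("no lineage in the initial-frequency window")
    cols = []
    for host in host_pair:
        s = meta.index[(meta["host_id"] == host) & (meta["day"] == day)]
        if not len(s):
            raise ValueError(f"host {host} has no sample at day {day}")
        cols.append(s[0])
    r1 = table.counts.loc[sel, cols[0]].to_numpy()
    r2 = table.counts.loc[sel, cols[1]].to_numpy()
    if sel.sum() < 2:
        logger.info("joint_replicate_distribution: degenerate single-lineage histogram")
        rho, p = np.nan, np.nan
    else:
        rho, p = sps.spearmanr(r1, r2)
    edges = np.concatenate([[-0.5], np.logspace(0, np.log10(max(r1.max(), r2.max(), 10)),
                                                n_bins)])
    joint, _, _ = np.histogram2d(r1, r2, bins=[edges, edges])
    m1 = joint.sum(axis=1, keepdims=True)
    m2 = joint.sum(axis=0, keepdims=True)
    factorized = m1 * m2 / max(joint.sum(), 1)
    return {"joint": joint, "factorized": factorized, "edges": edges,
            "spearman_r": float(rho), "p": float(p), "n": int(sel.sum())}


# ---------------------------------------------------------------------------
# Orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the requested stages in dependency order.

    Writes every stage's outputs under ``outdir`` and a ``manifest.json``
    listing configuration, per-stage seeds, and a sha256 checksum per file.
    A stage failure aborts the stage's dependents with a structured error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in set(config.stages)]
    for s in requested:
        for dep in DEPS.get(s, ()):
            if dep not in requested:
                logger.info("stage %s skipped: dependency %s not requested", s, dep)
    active = []
    for s in requested:
        if all(d in active for d in DEPS.get(s, ())):
            active.append(s)
    manifest = {"seed": config.seed, "stages": active, "outputs": {},
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()}}
    table = None
    truth = None

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    try:
        if "simulate" in active:
            sim_kwargs = dict(config.simulation)
            fit_kwargs = sim_kwargs.pop("fitness", None)
            if fit_kwargs:
                sim_kwargs["fitness"] = simulate.FitnessModel(**fit_kwargs)
            sim_kwargs.setdefault("seed", config.seed)
            if "timepoints" in sim_kwargs:
                sim_kwargs["timepoints"] = tuple(sim_kwargs["timepoints"])
            sim_config = simulate.SimulationConfig(**sim_kwargs)
            table, truth = simulate.simulate_experiment(sim_config)
            emit("counts.tsv", lambda p: count_io.save_count_table(table, p))
            emit("metadata.tsv", lambda p: table.samples.rename_axis("sample_id")
                 .to_csv(p, sep="\t"))
            truth.save(outdir / "truth")
            for f in sorted((outdir / "truth").iterdir()):
                manifest["outputs"][f"truth/{f.name}"] = _sha256(f)
        elif config.counts_path:
            table = count_io.load_count_table(config.counts_path, config.metadata_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    if table is None:
        raise StageError("simulate", "no data source configured")

    if "preprocess" in active and config.annotation_path:
        try:
            genes = count_io.load_annotations(config.annotation_path,
                                              config.determinants_path)
            table = count_io.filter_fitness_determinants(table, genes)
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e

    meta = table.samples
    fecal_days = sorted(meta.loc[meta["kind"] == "fecal", "day"].unique())
    conditions = sorted(meta.loc[meta["kind"] == "fecal", "condition"].unique())
    t1 = fecal_days[0] if fecal_days else None

    if "fitness" in active and t1 is not None:
        try:
            frames = []
            inp = sorted(meta.index[meta["kind"] == INPUT_KIND])
            for cond in conditions:
                hosts = sorted(meta.loc[(meta["condition"] == cond)
                                        & (meta["kind"] == "fecal"), "host_id"].unique())
                p0 = pool_samples(table, inp)
                p1 = count_io.pool_cohort(table, hosts, t1)
                df = relative_fitness(p0, p1, 0.0, t1)
                df["environment"] = cond
                df["t0"], df["t1"] = 0.0, t1
                frames.append(df)
            fit = pd.concat(frames)
            emit("fitness.tsv", lambda p: fit.rename_axis("lineage_id")
                 .to_csv(p, sep="\t"))
        except Exception as e:  # noqa: BLE001
            raise StageError("fitness", e) from e

    if "discover" in active and t1 is not None:
        try:
            cond = conditions[0]
            hosts = sorted(meta.loc[(meta["condition"] == cond)
                                    & (meta["kind"] == "fecal"), "host_id"].unique())
            inp = sorted(meta.index[meta["kind"] == INPUT_KIND])
            split = discovery.split_cohorts(hosts, cond, config.seed, inp)
            curve = discovery.rank_and_curve(table, split, 0.0, t1,
                                             window=config.window)
            cdf = pd.DataFrame({"window_start": curve.window_start,
                                "chi_window": curve.chi_window,
                                "chi_complement": curve.chi_complement})
            emit("rank_curve.tsv", lambda p: cdf.to_csv(p, sep="\t", index=False))
            dist = discovery.infer_fitness_distribution(curve)
            ddf = pd.DataFrame({"chi": dist.grid, "density": dist.density})
            emit("fitness_distribution.tsv", lambda p: ddf.to_csv(p, sep="\t", index=False))
        except Exception as e:  # noqa: BLE001
            raise StageError("discover", e) from e

    if "tradeoffs" in active and t1 is not None and len(conditions) >= 2:
        try:
            from .tradeoffs import EnvSpec, classify_tradeoffs, env_fitness_pair
            e1 = EnvSpec(f"{conditions[0]}:d0-{int(t1)}", conditions[0], 0.0, t1)
            e2 = EnvSpec(f"{conditions[1]}:d0-{int(t1)}", conditions[1], 0.0, t1)
            mat = env_fitness_pair(table, e1, e2, config.seed,
                                   group_alternating=False)
            out = mat.chi.copy()
            out["label"] = classify_tradeoffs(mat.chi[e1.label], mat.chi[e2.label])
            emit("tradeoffs.tsv", lambda p: out.rename_axis("lineage_id")
                 .to_csv(p, sep="\t"))
        except Exception as e:  # noqa: BLE001
            raise StageError("tradeoffs", e) from e

    if "cluster" in active and len(fecal_days) >= 1:
        try:
            from . import profiles as prof
            envs = prof.build_environments(conditions,
                                           timepoints=[0.0] + list(fecal_days),
                                           history_map={c: (c,) * len(fecal_days)
                                                        for c in conditions})
            pools = prof.environment_pools(table, envs, group_alternating=False)
            W = prof.lineage_profiles(pools)
            gene_map = pd.Series(np.nan, index=W.index)
            clusters = prof.find_novel_clusters(W, gene_map, gene_profiles=None)
            rows = [(c.cluster_id, c.kind, len(c.members), ";".join(map(str, c.members)))
                    for c in clusters]
            cl = pd.DataFrame(rows, columns=["cluster_id", "kind", "size", "members"])
            emit("clusters.tsv", lambda p: cl.to_csv(p, sep="\t", index=False))
            emit("profiles.tsv", lambda p: W.rename_axis("lineage_id").to_csv(p, sep="\t"))
        except Exception as e:  # noqa: BLE001
            raise StageError("cluster", e) from e

    if "denovo" in active and fecal_days:
        try:
            final_day = fecal_days[-1]
            freqs, depths = denovo.final_frequency_table(table, final_day)
            scores = denovo.divergence_scores(freqs, depths)
            emit("denovo.tsv", lambda p: scores.to_csv(p, sep="\t"))
        except Exception as e:  # noqa: BLE001
            raise StageError("denovo", e) from e

    if "drift" in active and t1 is not None:
        try:
            cond = conditions[0]
            hosts = sorted(meta.loc[(meta["condition"] == cond)
                                    & (meta["kind"] == "fecal"), "host_id"].unique())
            freqs = {}
            for h in hosts:
                s = meta.index[(meta["host_id"] == h) & (meta["day"] == t1)]
                freqs[h] = table.counts[s[0]] / table.counts[s[0]].sum()
            fhat = pd.DataFrame(freqs)
            inp = sorted(meta.index[meta["kind"] == INPUT_KIND])
            f0 = pool_samples(table, inp).freqs
            regset = drift.build_regression_set(f0, fhat, config.final_window,
                                                config.initial_window,
                                                config.seed, t=float(t1))
            res = drift.drift_test(regset, n_bins=config.n_bins,
                                   n_perm=config.n_perm, n_boot=config.n_boot,
                                   seed=config.seed)
            fit = drift.fit_Ne_tau(regset, t=float(t1), n_bins=config.n_bins,
                                   n_boot=config.n_boot, seed=config.seed)
            report = {"omega": res.omega, "p": res.p_value,
                      "netau": fit.netau, "deff": fit.deff,
                      "sigma_netau": fit.sigma_netau, "sigma_deff": fit.sigma_deff,
                      "reported": fit.reported,
                      "final_window": list(config.final_window),
                      "occupancy": res.binned.occupancy.tolist()}
            emit("drift.json", lambda p: p.write_text(json.dumps(report, indent=2)))
            bins = pd.DataFrame({"w_mean": res.binned.w_mean, "x_mean": res.binned.x_mean,
                                 "y_mean": res.binned.y_mean, "sigma_y": res.binned.sigma_y})
            emit("drift_bins.tsv", lambda p: bins.to_csv(p, sep="\t", index=False))
        except Exception as e:  # noqa: BLE001
            raise StageError("drift", e) from e

    if "diagnose" in active and t1 is not None:
        try:
            host = sorted(meta.loc[meta["kind"] == "fecal", "host_id"].unique())[0]
            obs, null = frequency_shift_distribution(table, host, day=t1)
            diag = pd.DataFrame({"observed": pd.Series(obs),
                                 "null": pd.Series(null if null is not None else [])})
            emit("frequency_shifts.tsv", lambda p: diag.to_csv(p, sep="\t", index=False))
        except Exception as e:  # noqa: BLE001
            raise StageError("diagnose", e) from e

    cfg_json = json.dumps(manifest["config"], sort_keys=True, default=str)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
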