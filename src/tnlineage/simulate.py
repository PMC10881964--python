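"""Synthetic lineage-tracking experiments with known ground truth.

The generator emulates the statistical structure that the inference modules
assume: an input library of 1e4--1e5 lineages with heterogeneous pre-existing
fitness (a point mass at zero plus an exponential beneficial tail), replicate
hosts per condition, Wright--Fisher drift at configurable effective size Ne,
environment-specific selection that can shift between time intervals, optional
injected de novo sweeps, and a two-stage Poisson sequencing model whose read
counts have Fano factor kappa equal to the number of stages.

Continuous-time expectations of the read counts come from an effective
branching process: with x(t) the fitness of a lineage relative to the
population mean and Lambda(t) = 1/(Ne*tau_e) the strength of genetic drift,

    <R>      = D * a(t),      a(t) = f0 * exp(int x dt'),
    Var(R)   = D^2 * a(t) * [kappa/D + 2 b(t)],
    b(t)     = exp(int x) * int (Lambda/2) * exp(-int x) dt',

which :func:`branching_moments` evaluates by adaptive quadrature.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .count_io import CountTable, lineage_id

EXACT_MULTINOMIAL_MAX_NE = 10_000_000

#: canonical diet histories: condition label -> diet per interval
DIET_HISTORIES = {
    "LF/HPP": ("L", "L", "L"),
    "HF/HS": ("H", "H", "H"),
    "LHL": ("L", "H", "L"),
    "HLH": ("H", "L", "H"),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: every host/sample draws from its own reproducible
    generator derived from (seed, crc32(name))."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# Configuration and truth containers


@dataclass
class FitnessModel:
    """Pre-existing fitness variation of the input library.

    By default 90% of lineages are neutral and 10% carry beneficial effects
    drawn from an exponential tail with mean ``mean_effect`` per day.  Effects
    in different environments are coupled through a Gaussian copula on effect
    ranks with pairwise correlation ``env_correlation``; ``shared_across_hosts``
    toggles whether replicate hosts see the same draws (pre-existing variation)
    or independent ones (host-private noise).
    """

    fraction_adaptive: float = 0.1
    mean_effect: float = 0.3  # per day
    env_correlation: float = 1.0
    shared_across_hosts: bool = True


@dataclass
class DeNovoEvent:
    """A beneficial mutation injected into one lineage of one host."""

    host_id: str
    lineage_index: int
    effect: float = 0.5  # per day
    origin_day: float = 4.0


@dataclass
class SimulationConfig:
    n_lineages: int = 20_000
    conditions: dict = field(default_factory=lambda: {"HF/HS": 4})  # label -> n hosts
    timepoints: tuple = (0.0, 4.0)
    Ne: float = 1e8
    generations_per_day: float = 10.0
    depth: int = 1_000_000
    n_input_replicates: int = 4
    noise_stages: int = 2
    input_log_sd: float = 1.0
    fitness: FitnessModel = field(default_factory=FitnessModel)
    de_novo: DeNovoEvent | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_lineages < 2:
            raise ValueError("n_lineages must be >= 2")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted")
        if any(n <= 0 for n in self.conditions.values()) or not self.conditions:
            raise ValueError("every condition needs at least one host")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        tps = list(self.timepoints)
        return list(zip(tps[:-1], tps[1:]))

    @property
    def drift_strength(self) -> float:
        """Lambda = 1/(Ne * tau_e) per day, with tau_e = 1/generations_per_day."""
        if np.isinf(self.Ne):
            return 0.0
        return self.generations_per_day / self.Ne

    def host_ids(self, condition: str) -> list[str]:
        tag = condition.replace("/", "").replace(" ", "")
        return [f"{tag}_m{i + 1}" for i in range(self.conditions[condition])]


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated count table."""

    lineage_ids: list
    timepoints: list
    #: host -> (n_lineages, n_timepoints) true frequency trajectories
    trajectories: dict
    #: (condition, interval_index) -> per-lineage fitness per day; if fitness is
    #: host-specific the key is (host, interval_index)
    fitness: dict
    #: host -> mean fitness per stored timepoint
    mean_fitness: dict
    #: sample -> Fano factor of the sequencing noise
    kappa: dict
    config: SimulationConfig

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for host, traj in self.trajectories.items():
            for j, day in enumerate(self.timepoints):
                rows.append(pd.DataFrame({
                    "lineage_id": self.lineage_ids, "host_id": host,
                    "day": day, "freq": traj[:, j]}))
        pd.concat(rows).to_csv(outdir / "truth_trajectories.tsv", sep="\t", index=False)
        fit = pd.DataFrame({str(k): v for k, v in self.fitness.items()},
                           index=self.lineage_ids)
        fit.rename_axis("lineage_id").to_csv(outdir / "truth_fitness.tsv", sep="\t")
        cfg = asdict(self.config)
        cfg["fitness"] = asdict(self.config.fitness)
        if self.config.de_novo is not None:
            cfg["de_novo"] = asdict(self.config.de_novo)
        manifest = {
            "config": cfg,
            "mean_fitness": {h: list(map(float, v)) for h, v in self.mean_fitness.items()},
            "kappa": self.kappa,
            "timepoints": list(self.timepoints),
        }
        (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    @classmethod
    def load(cls, outdir) -> "SimulationTruth":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "truth_manifest.json").read_text())
        traj = pd.read_csv(outdir / "truth_trajectories.tsv", sep="\t")
        fit = pd.read_csv(outdir / "truth_fitness.tsv", sep="\t").set_index("lineage_id")
        tps = manifest["timepoints"]
        lids = fit.index.tolist()
        order = {l: i for i, l in enumerate(lids)}
        trajectories = {}
        for host, grp in traj.groupby("host_id"):
            arr = np.zeros((len(lids), len(tps)))
            for j, day in enumerate(tps):
                sub = grp[grp["day"] == day]
                idx = [order[l] for l in sub["lineage_id"]]
                arr[idx, j] = sub["freq"].to_numpy()
            trajectories[host] = arr
        cfgd = dict(manifest["config"])
        cfgd["fitness"] = FitnessModel(**cfgd["fitness"])
        if cfgd.get("de_novo"):
            cfgd["de_novo"] = DeNovoEvent(**cfgd["de_novo"])
        cfgd["conditions"] = dict(cfgd["conditions"])
        cfgd["timepoints"] = tuple(cfgd["timepoints"])
        config = SimulationConfig(**cfgd)
        return cls(lids, tps, trajectories,
                   {k: fit[k].to_numpy() for k in fit.columns},
                   manifest["mean_fitness"], manifest["kappa"], config)


# ---------------------------------------------------------------------------
# Branching-process moments


def branching_moments(x_path, lambda_path, f0: float, D: float, kappa: float,
                      t0: float, t: float) -> tuple[float, float]:
    """Mean and variance of read counts under the effective branching process.

    Parameters
    ----------
    x_path, lambda_path
        Callables of time: relative fitness x(t') and drift strength
        Lambda(t') on [t0, t].
    f0
        Frequency at t0.
    D, kappa
        Sequencing depth and noise Fano factor.
    """
    if f0 < 0 or D <= 0:
        raise ValueError("f0 must be >= 0 and D > 0")

    def cum_x(u):
        val, _ = integrate.quad(x_path, t0, u, limit=200)
        return val

    a = f0 * np.exp(cum_x(t))
    integrand = lambda u: 0.5 * lambda_path(u) * np.exp(-cum_x(u))
    inner, _ = integrate.quad(integrand, t0, t, limit=200)
    b = np.exp(cum_x(t)) * inner
    mean = D * a
    var = D ** 2 * a * (kappa / D + 2.0 * b)
    return mean, var


# ---------------------------------------------------------------------------
# Wright--Fisher propagation


def _wf_generation(freqs: np.ndarray, weights: np.ndarray, Ne: float,
                   rng: np.random.Generator) -> np.ndarray:
    p = freqs * weights
    p /= p.sum()
    if np.isinf(Ne):
        return p
    if Ne <= EXACT_MULTINOMIAL_MAX_NE:
        counts = rng.multinomial(int(Ne), p)
        return counts / Ne
    # Per-lineage Poisson approximation, error O(1/sqrt(Ne)): at the study's
    # Ne = 1e8 the multinomial constraint is negligible.
    counts = rng.poisson(Ne * p).astype(float)
    tot = counts.sum()
    if tot == 0:  # pragma: no cover - impossible at realistic Ne*f
        return p
    return counts / tot


def simulate_wright_fisher(f0: np.ndarray, s_per_day, config: SimulationConfig,
                           rng: np.random.Generator,
                           record_days=None) -> tuple[np.ndarray, np.ndarray]:
    """Propagate lineage frequencies over the configured timepoints.

    ``s_per_day`` is either an (n_lineages,) array used for every interval or
    an (n_lineages, n_intervals) array of per-interval fitnesses (per day).
    Selection acts through multiplicative weights exp(s * tau) per generation;
    drift through multinomial resampling of Ne individuals (Poisson
    approximation above ``EXACT_MULTINOMIAL_MAX_NE``).

    Returns ``(freqs, mean_fitness)`` where ``freqs`` is
    (n_lineages, n_record) at ``record_days`` (default: config.timepoints) and
    ``mean_fitness`` is the frequency-weighted mean fitness at those days.
    """
    f0 = np.asarray(f0, dtype=float)
    if not np.isclose(f0.sum(), 1.0):
        raise ValueError("initial frequencies must sum to 1")
    record_days = list(config.timepoints if record_days is None else record_days)
    s_per_day = np.asarray(s_per_day, dtype=float)
    if s_per_day.ndim == 1:
        s_per_day = np.repeat(s_per_day[:, None], max(len(config.intervals), 1), axis=1)

    gpd = config.generations_per_day
    tau = 1.0 / gpd
    out = np.zeros((len(f0), len(record_days)))
    xbar = np.zeros(len(record_days))
    f = f0.copy()
    day = config.timepoints[0]
    for j, d in enumerate(record_days):
        if np.isclose(d, day):
            out[:, j] = f
            xbar[j] = float((s_per_day[:, 0] * f).sum())

    for k, (a, b) in enumerate(config.intervals):
        s = s_per_day[:, k]
        weights = np.exp(s * tau)
        n_gen = int(round((b - a) * gpd))
        for g in range(n_gen):
            f = _wf_generation(f, weights, config.Ne, rng)
            day = a + (g + 1) * tau
            for j, d in enumerate(record_days):
                if np.isclose(d, day):
                    out[:, j] = f
                    xbar[j] = float((s * f).sum())
    if (f > 0).sum() == 1:
        import logging
        logging.getLogger(__name__).info("single surviving lineage in Wright-Fisher run")
    return out, xbar


def simulate_sequencing(freqs: np.ndarray, depth: int, stages: int = 2,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Two-stage (by default) Poisson sequencing of a frequency vector.

    Stage 1 draws Poisson(depth * f); each later stage resamples
    Poisson(previous count).  The resulting counts have mean depth*f and
    Fano factor equal to ``stages``.
    """
    if rng is None:
        rng = np.random.default_rng()
    freqs = np.asarray(freqs, dtype=float)
    if (freqs < 0).any():
        raise ValueError("negative frequencies")
    reads = rng.poisson(depth * freqs)
    for _ in range(stages - 1):
        reads = rng.poisson(reads)
    return reads


# ---------------------------------------------------------------------------
# Fitness draws


def draw_fitness(model: FitnessModel, n_lineages: int, n_envs: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw per-environment fitness effects (per day), shape (n, n_envs).

    Marginal per environment: point mass at 0 with weight 1-fraction_adaptive
    plus an Exp(mean_effect) beneficial tail.  Environments are coupled by a
    Gaussian copula with constant pairwise correlation ``env_correlation``.
    """
    rho = float(np.clip(model.env_correlation, -1.0 / max(n_envs - 1, 1) + 1e-9, 1.0))
    if n_envs == 1 or rho == 1.0:
        z = np.repeat(rng.standard_normal((n_lineages, 1)), n_envs, axis=1)
    else:
        cov = np.full((n_envs, n_envs), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(n_envs), cov, size=n_lineages)
    u = stats.norm.cdf(z)
    s = np.zeros_like(u)
    p0 = 1.0 - model.fraction_adaptive
    tail = u > p0
    if model.fraction_adaptive > 0:
        s[tail] = stats.expon.ppf((u[tail] - p0) / model.fraction_adaptive,
                                  scale=model.mean_effect)
    return s


# ---------------------------------------------------------------------------
# Replicate-host drift scenarios


def simulate_drift_dataset(n_lineages: int, n_hosts: int, depth: int,
                           netau: float | None, seed: int, t: float = 4.0,
                           fitness_sd: float = 0.5, generations_per_day: float = 10.0,
                           noise_stages: int = 2,
                           f0_range: tuple = (1e-6, 1e-3)):
    """Replicate-host dataset for drift inference: broad pre-existing fitness
    variation, optional Wright--Fisher drift, and two-stage Poisson sequencing.

    Initial frequencies are log-uniform over ``f0_range`` (normalized);
    per-lineage fitnesses are Normal(0, fitness_sd) per day and shared across
    hosts, so that with ``netau=None`` (no drift) all across-host variation in
    the final plug-in frequencies is sequencing noise, while a finite
    Ne*tau_e adds genuine drift variance.  Drift runs through multinomial
    Wright--Fisher resampling at Ne = netau * generations_per_day.

    Returns ``(f0, final_freq_hat, truth)`` with ``f0`` the true initial
    frequencies (Series), ``final_freq_hat`` the per-host plug-in final
    frequencies (DataFrame) and ``truth`` a dict with the fitness draws and
    true final frequencies.
    """
    rng = substream(seed, "drift-dataset")
    logf = rng.uniform(np.log(f0_range[0]), np.log(f0_range[1]), size=n_lineages)
    f0 = np.exp(logf)
    f0 /= f0.sum()
    s = rng.normal(0.0, fitness_sd, size=n_lineages)

    Ne = np.inf if netau is None else netau * generations_per_day
    config = SimulationConfig(
        n_lineages=n_lineages, conditions={"env": n_hosts}, timepoints=(0.0, t),
        Ne=Ne, generations_per_day=generations_per_day, depth=depth,
        n_input_replicates=1, noise_stages=noise_stages, seed=seed,
    )
    ids = pd.Index([f"l{i}" for i in range(n_lineages)], name="lineage_id")
    fhat = {}
    final_true = {}
    for h in range(n_hosts):
        host = f"m{h + 1}"
        if np.isinf(Ne):
            # deterministic selection: identical trajectories in every host
            if h == 0:
                f_final = f0 * np.exp(s * t)
                f_final /= f_final.sum()
            # else reuse f_final from host 0
        else:
            traj, _ = simulate_wright_fisher(f0, s, config,
                                             substream(seed, f"wf:{host}"))
            f_final = traj[:, -1]
        final_true[host] = f_final.copy()
        reads = simulate_sequencing(f_final, depth, noise_stages,
                                    substream(seed, f"seq:{host}"))
        tot = reads.sum()
        fhat[host] = reads / tot if tot > 0 else reads.astype(float)
    return (pd.Series(f0, index=ids),
            pd.DataFrame(fhat, index=ids),
            {"s": s, "final_true": final_true, "config": config})


# ---------------------------------------------------------------------------
# Full experiment


def simulate_experiment(config: SimulationConfig) -> tuple[CountTable, SimulationTruth]:
    """Generate a full synthetic experiment: input technical replicates plus
    per-host trajectories and sequenced fecal samples, with ground truth.

    Input-library frequencies carry a lognormal library-creation spread
    (sd ``input_log_sd`` in log space) around the uniform founding frequency,
    mimicking differential growth during library construction.
    """
    n = config.n_lineages
    rng_lib = substream(config.seed, "library")
    w_lib = rng_lib.normal(0.0, config.input_log_sd, size=n)
    f_input = np.exp(w_lib)
    f_input /= f_input.sum()

    n_int = max(len(config.intervals), 1)
    cond_fitness: dict = {}
    if config.fitness.shared_across_hosts:
        # joint draw over all (condition, interval) environments, so the
        # copula correlation couples diets as well as time intervals
        env_keys = [(cond, k) for cond in config.conditions for k in range(n_int)]
        s_all = draw_fitness(config.fitness, n, len(env_keys),
                             substream(config.seed, "fitness"))
        for j, key in enumerate(env_keys):
            cond_fitness[key] = s_all[:, j]

    counts = {}
    samples = []
    trajectories = {}
    mean_fitness = {}
    kappa = {}
    fitness_truth: dict = dict(cond_fitness)

    for r in range(config.n_input_replicates):
        sid = f"input_r{r + 1}"
        rng = substream(config.seed, f"seq:{sid}")
        counts[sid] = simulate_sequencing(f_input, config.depth, config.noise_stages, rng)
        samples.append((sid, "input", 0.0, "input", "input_technical_replicate"))
        kappa[sid] = config.noise_stages

    for cond in config.conditions:
        for host in config.host_ids(cond):
            if config.fitness.shared_across_hosts:
                s = np.stack([cond_fitness[(cond, k)] for k in range(n_int)], axis=1)
            else:
                s = draw_fitness(config.fitness, n, n_int,
                                 substream(config.seed, f"fitness:{host}"))
                for k in range(n_int):
                    fitness_truth[(host, k)] = s[:, k]
            if config.de_novo is not None and config.de_novo.host_id == host:
                s = s.copy()
                for k, (a, _b) in enumerate(config.intervals):
                    if a >= config.de_novo.origin_day - 1e-9:
                        s[config.de_novo.lineage_index, k] += config.de_novo.effect
            rng = substream(config.seed, f"wf:{host}")
            traj, xbar = simulate_wright_fisher(f_input, s, config, rng)
            trajectories[host] = traj
            mean_fitness[host] = xbar
            for j, day in enumerate(config.timepoints):
                if day == 0:
                    continue  # day 0 is covered by the input technical replicates
                sid = f"{host}_d{int(day)}"
                rng_s = substream(config.seed, f"seq:{sid}")
                counts[sid] = simulate_sequencing(traj[:, j], config.depth,
                                                  config.noise_stages, rng_s)
                samples.append((sid, host, float(day), cond, "fecal"))
                kappa[sid] = config.noise_stages

    lids = [lineage_id("chr1", 1000 + 10 * i, "+") for i in range(n)]
    lineage_df = pd.DataFrame({
        "contig": "chr1",
        "position": [1000 + 10 * i for i in range(n)],
        "strand": "+",
    }, index=pd.Index(lids, name="lineage_id"))
    count_df = pd.DataFrame(counts, index=lineage_df.index)
    sample_df = pd.DataFrame(
        samples, columns=["sample_id", "host_id", "day", "condition", "kind"]
    ).set_index("sample_id")
    sample_df["species_library"] = "synthetic"
    table = CountTable(count_df, lineage_df, sample_df).validate()

    truth = SimulationTruth(
        lineage_ids=lids,
        timepoints=list(config.timepoints),
        trajectories=trajectories,
        fitness=fitness_truth,
        mean_fitness=mean_fitness,
        kappa=kappa,
        config=config,
    )
    return table, truth
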