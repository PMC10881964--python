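import numpy as np
import pandas as pd
import pytest

import tnlineage as tl
from tnlineage.simulate import (DeNovoEvent, FitnessModel, SimulationConfig,
                                SimulationTruth, branching_moments, draw_fitness,
                                simulate_experiment, simulate_sequencing,
                                simulate_wright_fisher, substream)


class TestBranchingMoments:
    def test_neutral_no_drift(self):
        mean, var = branching_moments(lambda t: 0.0, lambda t: 0.0,
                                      f0=1e-4, D=1e6, kappa=2.0, t0=0.0, t=4.0)
        assert mean == pytest.approx(1e6 * 1e-4)
        assert var == pytest.approx(2.0 * 1e6 * 1e-4)

    def test_pure_sampling_fano(self):
        # Lambda = 0, constant x: Var/Mean = kappa exactly
        for kappa in (1.0, 2.0, 3.0):
            mean, var = branching_moments(lambda t: 0.05, lambda t: 0.0,
                                          1e-5, 1e6, kappa, 0.0, 4.0)
            assert var / mean == pytest.approx(kappa, rel=1e-10)

    def test_constant_rates_match_closed_form(self):
        # independent closed-form oracle for constant x and Lambda:
        # a = f0 e^{xt};  b = e^{xt} * (Lambda/2) * (1 - e^{-xt}) / x
        x, lam, t, f0, D, kappa = 0.2, 1e-4, 4.0, 1e-5, 1e6, 1.0
        a = f0 * np.exp(x * t)
        b = np.exp(x * t) * (lam / 2) * (1 - np.exp(-x * t)) / x
        mean_exp = D * a
        var_exp = D ** 2 * a * (kappa / D + 2 * b)
        mean, var = branching_moments(lambda u: x, lambda u: lam, f0, D, kappa, 0.0, t)
        assert mean == pytest.approx(mean_exp, rel=1e-8)
        assert var == pytest.approx(var_exp, rel=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            branching_moments(lambda t: 0, lambda t: 0, -1e-5, 1e6, 1, 0, 4)
        with pytest.raises(ValueError):
            branching_moments(lambda t: 0, lambda t: 0, 1e-5, 0, 1, 0, 4)


class TestWrightFisher:
    def cfg(self, **kw):
        base = dict(n_lineages=2, conditions={"e": 1}, timepoints=(0.0, 4.0),
                    Ne=np.inf, generations_per_day=10.0, depth=1000, seed=0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_equal_fitness_infinite_ne_is_constant(self):
        f0 = np.array([0.2, 0.3, 0.5])
        cfg = self.cfg(n_lineages=3)
        freqs, xbar = simulate_wright_fisher(f0, np.full(3, 0.7), cfg,
                                             np.random.default_rng(0))
        assert np.allclose(freqs[:, -1], f0)

    def test_logistic_closed_form_without_drift(self):
        # two lineages, fitness gap 0.1 per generation, no drift:
        # log-odds grows by 0.1 per generation (1/day at 10 gen/day)
        f0 = np.array([0.1, 0.9])
        s = np.array([1.0, 0.0])  # per day -> 0.1 per generation
        cfg = self.cfg()
        freqs, _ = simulate_wright_fisher(f0, s, cfg, np.random.default_rng(0))
        lo0 = np.log(f0[0] / f0[1])
        lo1 = np.log(freqs[0, -1] / freqs[1, -1])
        assert lo1 - lo0 == pytest.approx(1.0 * 4.0, rel=1e-9)

    def test_neutral_drift_variance_matches_diffusion(self):
        # Var[f_t] ~ f0 (1 - f0) * g / Ne across replicate runs
        Ne, f0, n_gen = 10_000, 0.3, 10
        cfg = self.cfg(Ne=Ne, timepoints=(0.0, 1.0))
        finals = []
        for i in range(300):
            freqs, _ = simulate_wright_fisher(np.array([f0, 1 - f0]), np.zeros(2),
                                              cfg, np.random.default_rng(100 + i))
            finals.append(freqs[0, -1])
        finals = np.array(finals)
        expected = f0 * (1 - f0) * n_gen / Ne
        se = expected * np.sqrt(2 / len(finals))  # chi-square SE of a variance
        assert abs(finals.var(ddof=1) - expected) < 4 * se

    def test_frequencies_sum_to_one(self):
        cfg = self.cfg(n_lineages=50, Ne=1e5)
        f0 = np.full(50, 1 / 50)
        freqs, _ = simulate_wright_fisher(f0, np.zeros(50), cfg,
                                          np.random.default_rng(1))
        assert np.allclose(freqs.sum(axis=0), 1.0)

    def test_unnormalized_start_rejected(self):
        with pytest.raises(ValueError):
            simulate_wright_fisher(np.array([0.2, 0.2]), np.zeros(2), self.cfg(),
                                   np.random.default_rng(0))


class TestSequencing:
    def test_single_stage_fano_one(self):
        rng = np.random.default_rng(0)
        reads = simulate_sequencing(np.full(10 ** 5, 1e-4), 10 ** 6, stages=1, rng=rng)
        fano = reads.var() / reads.mean()
        assert fano == pytest.approx(1.0, abs=0.05)

    def test_two_stage_fano_two(self):
        rng = np.random.default_rng(0)
        reads = simulate_sequencing(np.full(10 ** 5, 1e-4), 10 ** 6, stages=2, rng=rng)
        fano = reads.var() / reads.mean()
        assert fano == pytest.approx(2.0, abs=0.05)

    def test_zero_frequency_gives_zero_reads(self):
        reads = simulate_sequencing(np.zeros(1000), 10 ** 6, stages=2,
                                    rng=np.random.default_rng(0))
        assert (reads == 0).all()

    def test_mean_preserved_across_stages(self):
        rng = np.random.default_rng(1)
        reads = simulate_sequencing(np.full(10 ** 5, 1e-4), 10 ** 6, stages=3, rng=rng)
        assert reads.mean() == pytest.approx(100.0, rel=0.01)


class TestFitnessDraws:
    def test_marginal_structure(self):
        s = draw_fitness(FitnessModel(0.1, 0.3), 50_000, 1, np.random.default_rng(0))
        frac = (s > 0).mean()
        assert frac == pytest.approx(0.1, abs=0.01)
        assert s[s > 0].mean() == pytest.approx(0.3, rel=0.05)

    def test_full_copula_correlation_couples_environments(self):
        m = FitnessModel(0.5, 0.3, env_correlation=1.0)
        s = draw_fitness(m, 10_000, 3, np.random.default_rng(0))
        assert np.allclose(s[:, 0], s[:, 1])

    def test_zero_correlation_independent(self):
        m = FitnessModel(1.0, 0.3, env_correlation=0.0)
        s = draw_fitness(m, 20_000, 2, np.random.default_rng(0))
        assert abs(np.corrcoef(s.T)[0, 1]) < 0.03


class TestExperiment:
    def test_truth_frequencies_sum_to_one(self):
        cfg = SimulationConfig(n_lineages=500, conditions={"HF/HS": 2},
                               timepoints=(0.0, 4.0, 10.0), Ne=1e5, depth=50_000, seed=3)
        table, truth = simulate_experiment(cfg)
        for traj in truth.trajectories.values():
            assert np.allclose(traj.sum(axis=0), 1.0)

    def test_mean_fitness_matches_definition(self):
        cfg = SimulationConfig(n_lineages=500, conditions={"HF/HS": 1},
                               timepoints=(0.0, 4.0), Ne=np.inf, depth=50_000, seed=3,
                               fitness=FitnessModel(0.2, 0.3))
        table, truth = simulate_experiment(cfg)
        host = next(iter(truth.trajectories))
        s = truth.fitness[("HF/HS", 0)]
        f = truth.trajectories[host]
        for j in range(f.shape[1]):
            assert truth.mean_fitness[host][j] == pytest.approx((s * f[:, j]).sum())

    def test_infinite_ne_expected_frequency_conserved(self):
        cfg = SimulationConfig(n_lineages=200, conditions={"e": 2},
                               timepoints=(0.0, 4.0), Ne=np.inf, depth=10 ** 6, seed=1,
                               fitness=FitnessModel(0.0, 0.3))
        table, truth = simulate_experiment(cfg)
        f = tl.estimate_frequencies(table)
        inp = table.samples.index[table.samples.kind == "input_technical_replicate"]
        fec = table.samples.index[table.samples.kind == "fecal"]
        # per-lineage agreement within sampling error of the two means
        fi = f[inp].mean(axis=1).to_numpy()
        ff = f[fec].mean(axis=1).to_numpy()
        se = np.sqrt(2.0 * fi / 10 ** 6 * (1 / len(inp) + 1 / len(fec)))
        assert (np.abs(fi - ff) < 5 * se + 1e-9).all()

    def test_truth_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_lineages=100, conditions={"HF/HS": 2},
                               timepoints=(0.0, 4.0), Ne=1e5, depth=10_000, seed=7)
        table, truth = simulate_experiment(cfg)
        truth.save(tmp_path)
        loaded = SimulationTruth.load(tmp_path)
        for host in truth.trajectories:
            assert np.allclose(loaded.trajectories[host], truth.trajectories[host])
        assert loaded.config.seed == cfg.seed
        assert loaded.kappa == truth.kappa

    def test_shared_vs_independent_cross_host_correlation(self):
        def corr(shared):
            cfg = SimulationConfig(
                n_lineages=5000, conditions={"e": 2}, timepoints=(0.0, 4.0),
                Ne=np.inf, depth=200_000, seed=11,
                fitness=FitnessModel(0.2, 0.3, shared_across_hosts=shared))
            table, _ = simulate_experiment(cfg)
            fec = sorted(table.samples.index[table.samples.kind == "fecal"])
            inp = table.samples.index[table.samples.kind == "input_technical_replicate"]
            # condition on a narrow initial-frequency band, so the shared
            # library composition cannot induce cross-host correlation
            f0 = tl.pool_samples(table, inp).freqs
            band = (f0 > 1e-4) & (f0 < 3e-4)
            c = table.counts.loc[band, fec]
            keep = (c > 0).all(axis=1)
            logs = np.log(c[keep])
            return np.corrcoef(logs.iloc[:, 0], logs.iloc[:, 1])[0, 1]

        assert corr(True) > 0.5
        assert abs(corr(False)) < 0.25  # residual correlation via shared library

    def test_de_novo_sweep_is_host_private(self):
        idx = 5
        base = dict(n_lineages=300, conditions={"e": 3},
                    timepoints=(0.0, 4.0, 10.0, 16.0), Ne=np.inf, depth=10 ** 5,
                    seed=13, fitness=FitnessModel(0.0, 0.3))
        cfg = SimulationConfig(de_novo=DeNovoEvent("e_m1", idx, 0.5, 4.0), **base)
        table, truth = simulate_experiment(cfg)
        day16 = {h: truth.trajectories[h][idx, 3] for h in truth.trajectories}
        assert day16["e_m1"] > 50 * max(v for h, v in day16.items() if h != "e_m1")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_lineages=1)
        with pytest.raises(ValueError):
            SimulationConfig(timepoints=(4.0, 0.0))
        with pytest.raises(ValueError):
            SimulationConfig(conditions={"e": 0})

    def test_named_substreams_reproducible(self):
        a = substream(5, "wf:m1").standard_normal(3)
        b = substream(5, "wf:m1").standard_normal(3)
        c = substream(5, "wf:m2").standard_normal(3)
        assert np.allclose(a, b)
        assert not np.allclose(a, c)


class TestDriftDataset:
    def test_no_drift_hosts_identical_in_truth(self):
        f0, fhat, truth = tl.simulate_drift_dataset(2000, 4, 10 ** 5, None, seed=1)
        vals = list(truth["final_true"].values())
        for v in vals[1:]:
            assert np.allclose(v, vals[0])

    def test_moments_match_branching_prediction(self):
        """Across-host variance of read counts matches the branching-process
        moments for constant x and Lambda (Monte-Carlo check)."""
        netau, depth, t = 1e5, 10 ** 6, 4.0
        n_rep = 200
        f0 = 1e-4
        finals = []
        cfg = SimulationConfig(n_lineages=2, conditions={"e": 1},
                               timepoints=(0.0, t), Ne=netau * 10, depth=depth, seed=0)
        reads = []
        for i in range(n_rep):
            freqs, _ = simulate_wright_fisher(
                np.array([f0, 1 - f0]), np.zeros(2), cfg,
                np.random.default_rng(1000 + i))
            r = simulate_sequencing(freqs[:, -1], depth, 2,
                                    np.random.default_rng(5000 + i))
            reads.append(r[0])
        reads = np.array(reads, dtype=float)
        mean_pred, var_pred = branching_moments(
            lambda u: 0.0, lambda u: 1.0 / netau, f0, depth, 2.0, 0.0, t)
        assert reads.mean() == pytest.approx(mean_pred, rel=0.05)
        se = var_pred * np.sqrt(2 / n_rep)
        assert abs(reads.var(ddof=1) - var_pred) < 4 * se
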