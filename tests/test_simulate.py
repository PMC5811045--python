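import numpy as np
import pytest
from scipy import stats

from mstraj.simulate import TrajectoryConfig, profile_value, simulate_trajectory


class TestConfigValidation:
    def test_more_modules_than_genes_rejected(self):
        with pytest.raises(ValueError, match="n_modules"):
            TrajectoryConfig(n_cells=10, n_genes=3, n_modules=5)

    def test_wide_transition_rejected(self):
        with pytest.raises(ValueError, match="transition_width"):
            TrajectoryConfig(phase_boundaries=(0.45, 0.55), transition_width=0.2)

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            TrajectoryConfig(phase_boundaries=(0.6, 0.3))

    def test_boundaries_in_open_interval(self):
        with pytest.raises(ValueError, match="open interval"):
            TrajectoryConfig(phase_boundaries=(0.0, 0.5))

    def test_n_phases(self):
        assert TrajectoryConfig().n_phases == 3
        assert TrajectoryConfig(phase_boundaries=(0.25, 0.5, 0.75),
                                transition_width=0.05).n_phases == 4


class TestProfileValue:
    def test_plateau_constant(self):
        t = np.linspace(0, 1, 17)
        np.testing.assert_array_equal(profile_value(t, "plateau", {"level": 5.0}),
                                      np.full(17, 5.0))

    def test_sigmoid_step_limit(self):
        params = {"low": 0.0, "high": 10.0, "center": 0.5, "width": 1e-6}
        assert profile_value(0.49, "sigmoid", params) == pytest.approx(0.0, abs=1e-9)
        assert profile_value(0.51, "sigmoid", params) == pytest.approx(10.0, abs=1e-9)

    def test_sigmoid_monotone(self):
        t = np.linspace(0, 1, 101)
        v = profile_value(t, "sigmoid", {"low": 1, "high": 9, "center": 0.4,
                                         "width": 0.2})
        assert np.all(np.diff(v) >= 0)
        assert v.min() >= 1 and v.max() <= 9

    def test_pulse_unimodal(self):
        t = np.linspace(0, 1, 401)
        v = profile_value(t, "pulse", {"low": 0, "high": 5, "center": 0.5,
                                       "width": 0.2})
        peak = int(np.argmax(v))
        assert np.all(np.diff(v[:peak + 1]) >= 0)
        assert np.all(np.diff(v[peak:]) <= 0)

    def test_biphasic_argmax_between_rise_and_fall(self):
        # oracle: dense evaluation of the profile
        t = np.linspace(0, 1, 4001)
        v = profile_value(t, "biphasic", {"base": 5, "peak": 30, "rise": 0.6,
                                          "fall": 0.8, "width": 0.05})
        tmax = t[int(np.argmax(v))]
        assert 0.6 <= tmax <= 0.8
        # decays to ~0 after the fall, moderate plateau before the rise
        assert v[-1] < 0.5
        assert v[0] == pytest.approx(5.0, rel=0.05)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown profile kind"):
            profile_value(0.5, "sawtooth", {})

    def test_t_outside_unit_interval(self):
        with pytest.raises(ValueError, match="latent time"):
            profile_value(1.5, "plateau", {"level": 1})


class TestSimulateTrajectory:
    def test_shape_and_layer(self, default_sim):
        m, truth = default_sim
        assert m.shape == (300, 200)
        assert m.layer == "counts"
        assert np.allclose(m.values, np.round(m.values))

    def test_deterministic_from_seed(self):
        cfg = TrajectoryConfig(n_cells=40, n_genes=50, seed=123)
        m1, t1 = simulate_trajectory(cfg)
        m2, t2 = simulate_trajectory(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.cell_ids == m2.cell_ids
        np.testing.assert_array_equal(t1.cells["latent_time"].to_numpy(),
                                      t2.cells["latent_time"].to_numpy())

    def test_noise_free_limit_equals_profile_means(self):
        cfg = TrajectoryConfig(n_cells=30, n_genes=40, seed=5, noise=0.0,
                               dropout_rate=0.0, frac_offtrajectory=0.0,
                               library_sigma=0.0)
        m, truth = simulate_trajectory(cfg)
        t = truth.latent_time[m.cell_ids].to_numpy()
        for g in m.gene_ids:
            kind, params = truth.gene_profiles[g]
            expected = profile_value(t, kind, params)
            np.testing.assert_allclose(m.values[m.gene_index([g])[0]], expected)

    def test_three_metastable_phases_by_default(self, default_sim):
        _, truth = default_sim
        grid = np.linspace(0, 1, 501)
        assert truth.n_phases == 3
        assert set(truth.phase_of_time(grid).tolist()) == {0, 1, 2}

    def test_latent_time_and_flags(self, default_sim):
        _, truth = default_sim
        on = truth.cells["on_trajectory"]
        lat = truth.cells["latent_time"]
        assert lat[on].between(0, 1).all()
        assert lat[~on].isna().all()
        assert int((~on).sum()) == 20  # 10% of 200 off-trajectory

    def test_module_assignment_partitions_genes(self, default_sim):
        _, truth = default_sim
        mod = truth.module_of_gene
        n_module_genes = (mod != "noise").sum()
        assert n_module_genes > 0
        assert truth.biphasic_gene_id in truth.dynamic_genes()

    def test_monotone_module_rank_correlation_is_exact(self):
        # noise-free limit with a positive off-level floor: module profiles
        # are strictly monotone, so rank correlation with latent time is +-1
        cfg = TrajectoryConfig(n_cells=50, n_genes=60, seed=9, noise=0.0,
                               dropout_rate=0.0, frac_offtrajectory=0.0,
                               library_sigma=0.0, low_range=(0.2, 1.0))
        m, truth = simulate_trajectory(cfg)
        t = truth.latent_time[m.cell_ids].to_numpy()
        mod = truth.module_of_gene
        falling = [g for g in m.gene_ids if mod[g] == "0"][0]
        rising = [g for g in m.gene_ids if mod[g] == "2"][0]
        rho_f = stats.spearmanr(m.values[m.gene_index([falling])[0]], t).statistic
        rho_r = stats.spearmanr(m.values[m.gene_index([rising])[0]], t).statistic
        assert rho_f == pytest.approx(-1.0)
        assert rho_r == pytest.approx(1.0)

    def test_constant_gene_counts_follow_negative_binomial(self):
        # marginal law of a plateau gene at known mean and dispersion
        alpha = 0.3
        cfg = TrajectoryConfig(n_cells=10_000, n_genes=10, n_modules=2,
                               frac_noise_genes=0.5, noise=alpha,
                               dropout_rate=0.0, frac_offtrajectory=0.0,
                               library_sigma=0.0, seed=21)
        m, truth = simulate_trajectory(cfg)
        gene = next(g for g, (kind, _) in truth.gene_profiles.items()
                    if kind == "plateau")
        mu = truth.gene_profiles[gene][1]["level"]
        counts = m.values[m.gene_index([gene])[0]].astype(int)
        dist = stats.nbinom(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = dist.pmf(np.arange(kmax + 1)) * counts.size
        # pool sparse tail bins so the chi-square approximation is valid
        k, tail = kmax, expected[kmax]
        while k > 0 and tail < 5:
            k -= 1
            tail += expected[k]
        obs = np.append(observed[:k], observed[k:].sum())
        exp = np.append(expected[:k], expected[k:].sum())
        exp *= obs.sum() / exp.sum()
        p = stats.chisquare(obs, exp).pvalue
        assert p > 0.01

    def test_off_trajectory_cells_uncorrelated_with_modules(self, default_sim):
        m, truth = default_sim
        mod = truth.module_of_gene
        genes0 = [g for g in m.gene_ids if mod[g] == "0"][:15]
        off_cells = truth.cells.index[~truth.cells["on_trajectory"]].tolist()
        sub = m.subset_cells(off_cells).subset_genes(genes0).values
        rhos = []
        for i in range(len(genes0)):
            for j in range(i + 1, len(genes0)):
                r = stats.spearmanr(sub[i], sub[j]).statistic
                if not np.isnan(r):
                    rhos.append(r)
        assert abs(float(np.mean(rhos))) < 0.15

    def test_dropout_zeroes_entries(self):
        base = TrajectoryConfig(n_cells=50, n_genes=60, seed=3, dropout_rate=0.0,
                                low_range=(1.0, 2.0))
        heavy = TrajectoryConfig(n_cells=50, n_genes=60, seed=3, dropout_rate=0.6,
                                 low_range=(1.0, 2.0))
        m0, _ = simulate_trajectory(base)
        m1, _ = simulate_trajectory(heavy)
        assert (m1.values == 0).mean() > (m0.values == 0).mean()
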