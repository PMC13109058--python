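"""WF HMM transitions, trajectory posteriors, Z(t), model comparison."""

import numpy as np
import pandas as pd
import pytest

from polyhap.synthetic_data import simulate_wf_trajectories
from polyhap.wf_trajectory import (ConfigurationError, EpochSelectionModel,
                                   Trajectory, WFHMMConfig, estimate_epoch_s,
                                   generations_to_years, hmm_loglik,
                                   ps_model_comparison, ps_trajectory,
                                   selection_update, trajectory_posterior,
                                   wf_transition)


class TestTransition:
    @pytest.fixture
    def cfg(self):
        return WFHMMConfig(grid_size=101)

    def test_rows_sum_to_one(self, cfg):
        T = wf_transition(cfg, Ne=1000, s=0.02)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_boundaries_absorbing(self, cfg):
        T = wf_transition(cfg, Ne=500, s=0.05)
        assert T[0, 0] == 1.0 and T[0, 1:].sum() == 0.0
        assert T[-1, -1] == 1.0 and T[-1, :-1].sum() == 0.0

    def test_neutral_martingale_on_grid(self, cfg):
        T = wf_transition(cfg, Ne=2000, s=0.0)
        grid = cfg.grid
        expected = T @ grid
        # discretization error below half a grid cell
        assert np.max(np.abs(expected - grid)) < 1 / (2 * cfg.grid_size)

    def test_selection_update_hand_value(self):
        # p = 0.1, s = 0.013: p' = 0.1*1.013/1.0013
        assert selection_update(0.1, 0.013) == pytest.approx(0.101168, abs=1e-6)
        T = wf_transition(WFHMMConfig(101), Ne=5000, s=0.013)
        p_row = 10  # grid point 0.1
        assert T[p_row] @ np.linspace(0, 1, 101) == pytest.approx(0.101168,
                                                                  abs=5e-3)


class TestPosterior:
    def test_rows_normalized_and_mode_at_observation(self):
        model = EpochSelectionModel((0, 50, 100, 150), (0.0, 0.0, 0.0))
        traj = trajectory_posterior(k=20, n=44, model=model)
        assert traj.posterior.sum(axis=1) == pytest.approx(1.0, abs=1e-9)
        grid = traj.grid
        mode = grid[np.argmax(traj.posterior[0])]
        assert abs(mode - 20 / 44) <= 1 / 100 + 1e-12

    def test_fixation_under_recent_selection_rises_to_present(self):
        model = EpochSelectionModel((0, 50, 100, 150), (0.08, 0.0, 0.0),
                                    Ne=2000)
        traj = trajectory_posterior(k=44, n=44, model=model)
        recent = traj.freq[:51]
        assert recent[0] > recent[25] > recent[50]

    def test_invalid_count_rejected(self):
        model = EpochSelectionModel((0, 50), (0.0,))
        with pytest.raises(ValueError):
            trajectory_posterior(k=45, n=44, model=model, horizon=50)


class TestEstimateEpochS:
    def test_recovers_moderate_selection_from_path(self):
        rng = np.random.default_rng(1)
        freqs = simulate_wf_trajectories(0.1, 0.02, 80, 10_000, 1, rng)
        traj = Trajectory(times=np.arange(81), freq=freqs[0])
        s_hat, surf = estimate_epoch_s(traj, [0, 80], Ne=10_000)
        assert s_hat[0] == pytest.approx(0.02, abs=0.005)

    def test_monomorphic_path_flagged(self):
        traj = Trajectory(times=np.arange(21), freq=np.zeros(21))
        s_hat, _ = estimate_epoch_s(traj, [0, 20], Ne=1000)
        assert np.isnan(s_hat[0])

    def test_count_mode_prefers_positive_s_for_high_frequency(self):
        # a derived allele at 40/44 is better explained by recent positive
        # selection than by strong negative selection
        cfg = WFHMMConfig(grid_size=51)
        m_pos = EpochSelectionModel((0, 100), (0.05,), Ne=2000)
        m_neg = EpochSelectionModel((0, 100), (-0.05,), Ne=2000)
        ll_pos = hmm_loglik(40, 44, m_pos, cfg, 100)
        ll_neg = hmm_loglik(40, 44, m_neg, cfg, 100)
        assert ll_pos > ll_neg


class TestPSTrajectory:
    def traj(self, freq):
        return Trajectory(times=np.arange(len(freq)), freq=np.asarray(freq))

    def test_single_snp_identity(self):
        p = np.linspace(0.2, 0.6, 11)
        ps = ps_trajectory([self.traj(p)], [1.0])
        np.testing.assert_array_equal(ps.z, p)

    def test_cancellation(self):
        p = np.linspace(0.2, 0.6, 11)
        ps = ps_trajectory([self.traj(p), self.traj(p)], [0.5, -0.5])
        np.testing.assert_allclose(ps.z, 0.0, atol=1e-15)

    def test_linearity_over_union(self):
        rng = np.random.default_rng(4)
        ts = [self.traj(rng.uniform(size=8)) for _ in range(5)]
        betas = rng.normal(size=5)
        whole = ps_trajectory(ts, betas)
        part = (ps_trajectory(ts[:2], betas[:2]).z
                + ps_trajectory(ts[2:], betas[2:]).z)
        np.testing.assert_allclose(whole.z, part, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="time grid"):
            ps_trajectory([self.traj(np.ones(5) * 0.5),
                           self.traj(np.ones(6) * 0.5)], [1.0, 1.0])

    def test_individual_dosage_consistency(self):
        # sample mean of per-individual sum(beta_i * g_i) equals 2 * Z(0)
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(22, 10))  # diploid dosages
        betas = rng.normal(size=10)
        freq0 = geno.mean(axis=0) / 2
        z0 = float(betas @ freq0)
        indiv = geno @ betas
        assert indiv.mean() == pytest.approx(2 * z0, abs=1e-12)


class TestGenerationsToYears:
    @pytest.mark.parametrize("g,years", [(100, 2800), (50, 1400), (0, 0)])
    def test_published_conversions(self, g, years):
        assert generations_to_years(g) == years

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(-1)


class TestPSModelComparison:
    def test_perfectly_linear_ps_gives_r2_one(self):
        rng = np.random.default_rng(6)
        ps = rng.normal(size=22)
        age = rng.uniform(20, 70, size=22)
        bmi = 25 + 3 * ps
        table = ps_model_comparison(bmi, age, ps, age_cutoffs=(None,))
        row = table[table["model"] == "ps_only"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)

    def test_uninformative_ps_rarely_improves_aic(self):
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            age = rng.uniform(20, 70, size=22)
            bmi = 20 + 0.1 * age + rng.normal(scale=2.0, size=22)
            ps = rng.normal(size=22)  # independent of bmi
            t = ps_model_comparison(bmi, age, ps, age_cutoffs=(None,))
            aic = t.set_index("model")["aic"]
            wins += aic["age_and_ps"] < aic["age_only"]
        assert wins < 50

    def test_small_subsets_skipped_and_determinism(self):
        rng = np.random.default_rng(8)
        age = rng.uniform(40, 60, size=10)
        bmi = rng.normal(27, 3, size=10)
        ps = rng.normal(size=10)
        t1 = ps_model_comparison(bmi, age, ps, age_cutoffs=(None, 41))
        t2 = ps_model_comparison(bmi, age, ps, age_cutoffs=(None, 41))
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["subset"]) == {"all"} or (t1[t1.subset != "all"]["n"]
                                                >= 4).all()


class TestEpochModel:
    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ConfigurationError):
            EpochSelectionModel((10, 50), (0.0,))
        with pytest.raises(ConfigurationError):
            EpochSelectionModel((0, 50, 40), (0.0, 0.0))
        with pytest.raises(ConfigurationError):
            EpochSelectionModel((0, 50), (0.0, 0.1))

    def test_s_lookup_with_zero_beyond_last(self):
        m = EpochSelectionModel((0, 50, 100), (0.01, 0.02))
        assert m.s_at(0) == 0.01
        assert m.s_at(49) == 0.01
        assert m.s_at(50) == 0.02
        assert m.s_at(150) == 0.0
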