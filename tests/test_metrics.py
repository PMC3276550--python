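"""Readout layer: window statistics, fold changes, gradient fits, regression."""

import numpy as np
import pytest

from spinesim import metrics
from spinesim.metrics import (SpeciesGroup, activity_regression, fit_exponential_gradient,
                              fold_change, percent_phospho_GluA1, phospho_groups,
                              window_average)
from spinesim.trajectory import Trajectory


def _traj(times, values, species="X", region="all"):
    data = np.asarray(values, float)[:, None, None]
    return Trajectory(times=np.asarray(times, float), data=data,
                      regions=[region], species=[species],
                      region_volumes=np.array([1.0]))


GROUP_X = SpeciesGroup("x", {"X": 1})


class TestWindowAverage:
    def test_constant_trace(self):
        tr = _traj(np.linspace(0, 10, 11), np.full(11, 7.5))
        assert window_average(tr, GROUP_X, 2, 8) == pytest.approx(7.5)

    def test_linear_ramp_midpoint(self):
        t = np.linspace(0, 10, 101)
        tr = _traj(t, 10 * t)  # 0 -> 100 nM
        assert window_average(tr, GROUP_X, 0, 10) == pytest.approx(50.0)

    def test_matches_analytic_integral(self):
        t = np.linspace(0, 2 * np.pi, 20001)
        tr = _traj(t, np.sin(t) + 2)
        got = window_average(tr, GROUP_X, 0, 2 * np.pi, mode="sum")
        assert got == pytest.approx(4 * np.pi, abs=1e-9 * 4 * np.pi)

    def test_empty_window_rejected(self):
        tr = _traj([0, 1, 2], [1, 1, 1])
        with pytest.raises(ValueError):
            window_average(tr, GROUP_X, 5, 6)
        with pytest.raises(ValueError):
            window_average(tr, GROUP_X, 2, 1)


class TestFoldChange:
    def test_unchanged_trace_gives_one(self):
        tr = _traj(np.arange(11.0), np.full(11, 3.3))
        assert fold_change(tr, GROUP_X, (0, 2), (5, 10)) == pytest.approx(1.0)

    def test_reference_arithmetic(self):
        t = np.arange(0, 11.0)
        y = np.where(t < 2, 650.0, 3900.0)
        tr = _traj(t, y)
        assert fold_change(tr, GROUP_X, (0, 1.5), (2, 10)) == pytest.approx(6.0)

    def test_scale_invariance(self):
        t = np.arange(0, 30.0)
        rng = np.random.default_rng(0)
        y = 5 + rng.random(30)
        f1 = fold_change(_traj(t, y), GROUP_X, (0, 5), (10, 25))
        f2 = fold_change(_traj(t, 17.3 * y), GROUP_X, (0, 5), (10, 25))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_zero_baseline_rejected(self):
        tr = _traj(np.arange(5.0), [0, 0, 1, 2, 3])
        with pytest.raises(ValueError):
            fold_change(tr, GROUP_X, (0, 1), (2, 4))


class TestPercentPhosphoGluA1:
    def test_reference_fractions(self, network):
        species = [s.name for s in network.species]
        data = np.zeros((1, 1, len(species)))
        tr = Trajectory(times=np.array([0.0]), data=data, regions=["all"],
                        species=species, region_volumes=np.array([1.0]))
        i = {s: k for k, s in enumerate(species)}
        data[0, 0, i["GluA1"]] = 80.0
        assert percent_phospho_GluA1(tr, network)[0] == 0.0
        data[0, 0, i["pS845GluA1"]] = 10.0
        data[0, 0, i["pS845pS831GluA1"]] = 10.0
        # total moiety = 100
        assert percent_phospho_GluA1(tr, network)[0] == pytest.approx(20.0)

    def test_group_aggregation_conserves_darpp32(self, network, short_mesh):
        """Phospho groups plus unphosphorylated forms account for the whole
        DARPP-32 pool at every recorded time of a live run."""
        from spinesim import configuration as cfg
        from spinesim import deterministic as det
        conc0 = cfg.wellmixed_concentrations(network, short_mesh)
        traj = det.run_wellmixed(network, conc0, [], T=10.0, record_dt=2.0,
                                 total_volume=short_mesh.total_volume())
        g = phospho_groups(network)
        total = g["D32_total"].trace(traj)
        p34 = g["pThr34"].trace(traj)
        p75 = g["pThr75"].trace(traj)
        unphos = sum(traj.conc(n) for n in
                     ("D32", "D32_PKAc", "CDK5_D32"))
        assert np.allclose(p34 + p75 + unphos, total, rtol=1e-9)


class TestGradientFit:
    def test_noiseless_recovery_exact(self):
        x = np.linspace(0, 20, 20)
        y = 400 * np.exp(-x / 4.69) + 35.6
        fit = fit_exponential_gradient(x, y)
        assert fit.identifiable
        assert fit.decay_length == pytest.approx(4.69, rel=1e-6)
        assert fit.amplitude == pytest.approx(400, rel=1e-5)
        fit_b = fit_exponential_gradient(x, y, baseline=35.6)
        assert fit_b.decay_length == pytest.approx(4.69, rel=1e-6)

    def test_flat_profile_not_identifiable(self):
        x = np.linspace(0, 20, 30)
        fit = fit_exponential_gradient(x, np.full(30, 12.0))
        assert not fit.identifiable and fit.decay_length is None

    def test_noisy_recovery_median_within_5_percent(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 20, 40)
        lams = []
        for _ in range(100):
            y = (400 * np.exp(-x / 4.69) + 35.6) * (1 + 0.05 * rng.standard_normal(40))
            fit = fit_exponential_gradient(x, y)
            if fit.identifiable:
                lams.append(fit.decay_length)
        assert len(lams) >= 95
        assert np.median(lams) == pytest.approx(4.69, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_gradient(np.arange(4.0), np.arange(4.0))


class TestActivityRegression:
    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(2)
        camp = rng.uniform(50, 500, 16)
        coloc = np.tile([0, 1], 8)
        y = 3.0 * camp + 10
        res = activity_regression(camp, coloc, y)
        assert res["r2"] == pytest.approx(1.0)
        assert res["p_camp"] < 1e-10

    def test_pure_noise_not_significant(self):
        """Independent noise: p above 0.05, R^2 near zero, agreeing with a
        permutation-based significance oracle."""
        rng = np.random.default_rng(5)
        camp = rng.uniform(50, 500, 16)
        coloc = np.tile([0, 1], 8)
        y = rng.standard_normal(16)
        res = activity_regression(camp, coloc, y)
        assert res["r2"] < 0.3
        assert res["p_camp"] > 0.05
        # permutation oracle for the cAMP coefficient
        def coef(yy):
            X = np.column_stack([np.ones(16), camp, coloc])
            return np.linalg.lstsq(X, yy, rcond=None)[0][1]
        obs = abs(coef(y))
        perm = np.array([abs(coef(rng.permutation(y))) for _ in range(500)])
        p_perm = (perm >= obs).mean()
        assert p_perm > 0.05

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            activity_regression(np.arange(4.0), np.array([0, 1, 0, 1]),
                                np.arange(4.0))

    def test_rank_deficiency_rejected(self):
        camp = np.full(10, 100.0)
        coloc = np.zeros(10)
        with pytest.raises(ValueError):
            activity_regression(camp, coloc, np.arange(10.0))


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path):
        t = np.linspace(0, 5, 6)
        rng = np.random.default_rng(1)
        traj = Trajectory(times=t, data=rng.random((6, 2, 3)),
                          regions=["dendrite", "spine"], species=["A", "B", "C"],
                          region_volumes=np.array([1.0, 0.1]))
        p = tmp_path / "traj.csv"
        traj.save_csv(p)
        again = Trajectory.load_csv(p)
        assert again.species == traj.species and again.regions == traj.regions
        assert np.allclose(again.data, traj.data)
        assert np.allclose(again.times, traj.times)


class TestTrialStatistics:
    def test_trial_summary_mean_sem(self):
        v = [10.0, 12.0, 14.0, 16.0]
        s = metrics.trial_summary(v)
        assert s["mean"] == pytest.approx(13.0)
        assert s["sem"] == pytest.approx(np.std(v, ddof=1) / 2)
        assert s["n"] == 4

    def test_welch_distinguishes_separated_ensembles(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 8)
        b = rng.normal(14, 1, 8)
        assert metrics.welch_test(a, b)["p"] < 0.001
        assert metrics.welch_test(a, a)["p"] == pytest.approx(1.0)
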