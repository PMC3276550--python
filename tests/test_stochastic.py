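"""Tau-leap engine: analytic laws, diffusion statistics, conservation, seeds."""

import numpy as np
import pytest
from scipy.linalg import expm

from spinesim import configuration as cfg
from spinesim import geometry
from spinesim import stochastic as st
from spinesim.geometry import Coupling, Mesh, Subvolume
from spinesim.units import NM_UM3_TO_MOLECULES as F

from conftest import make_network


def _counts(net, mesh, species):
    c = np.zeros((mesh.n_subvolumes, net.n_species), np.int64)
    for (name, sub), n in species.items():
        c[sub, net.index[name]] = n
    return c


def _chain(n, volume=1.0):
    subs = [Subvolume(i, geometry.DEND_CYT, volume, float(i)) for i in range(n)]
    cpl = [Coupling(i, i + 1, 1.0, 1.0) for i in range(n - 1)]
    return Mesh(subs, cpl, {})


class TestReactionLeap:
    def test_no_propensity_leaves_state_unchanged(self):
        net = make_network("A + B -> C ; kf=1")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 50})  # no B -> nothing fires
        traj = st.run(net, mesh, c0, [], T=1.0,
                      engine=st.EngineConfig(dt=1e-3, record_dt=1.0, seed=1))
        assert np.array_equal(traj.final_counts, c0)

    def test_pure_decay_matches_exponential(self):
        """n0 e^{-kt}: ensemble mean at t=1 s within 3 SE of 1000/e."""
        net = make_network("A -> B ; kf=1")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 1000})
        finals = []
        for seed in range(100):
            traj = st.run(net, mesh, c0, [], T=1.0,
                          engine=st.EngineConfig(dt=1e-3, record_dt=1.0,
                                                 seed=seed))
            finals.append(traj.final_counts[0, net.index["A"]])
        finals = np.asarray(finals, float)
        expect = 1000 * np.exp(-1.0)
        se = finals.std(ddof=1) / 10
        assert abs(finals.mean() - expect) < 3 * se

    def test_reversible_pair_equilibrates_symmetrically(self):
        net = make_network("A <-> B ; kf=5 ; kb=5")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 2000})
        a_final = []
        for seed in range(40):
            traj = st.run(net, mesh, c0, [], T=2.0,
                          engine=st.EngineConfig(dt=5e-4, record_dt=2.0,
                                                 seed=seed))
            a_final.append(traj.final_counts[0, net.index["A"]])
        a_final = np.asarray(a_final, float)
        se = a_final.std(ddof=1) / np.sqrt(40)
        assert abs(a_final.mean() - 1000.0) < 3 * se

    def test_negativity_policy_protects_boundaries(self):
        """A fast sink on a handful of molecules never drives counts negative."""
        net = make_network("A -> B ; kf=500")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 3})
        for seed in range(30):
            traj = st.run(net, mesh, c0, [], T=0.1,
                          engine=st.EngineConfig(dt=2e-2, record_dt=0.1,
                                                 seed=seed))
            assert (traj.final_counts >= 0).all()
            assert traj.final_counts[0, net.index["B"]] == 3


class TestDiffusionLeap:
    def test_anchored_species_never_move(self):
        net = make_network("X -> Y ; kf=0", species={"X": 0.0, "Y": 0.0})
        mesh = _chain(2)
        c0 = _counts(net, mesh, {("X", 0): 500})
        traj = st.run(net, mesh, c0, [], T=1.0,
                      engine=st.EngineConfig(dt=1e-3, record_dt=1.0, seed=1),
                      regions={"a": [0], "b": [1]})
        assert traj.final_counts[1, 0] == 0

    def test_two_box_equilibration(self):
        net = make_network("X -> Y ; kf=0", species={"X": 10.0, "Y": 0.0})
        mesh = _chain(2)
        c0 = _counts(net, mesh, {("X", 0): 1000})
        finals = []
        for seed in range(30):
            traj = st.run(net, mesh, c0, [], T=1.0,
                          engine=st.EngineConfig(dt=2e-3, record_dt=1.0,
                                                 seed=seed))
            assert traj.final_counts[:, 0].sum() == 1000  # exact conservation
            finals.append(traj.final_counts[0, 0])
        finals = np.asarray(finals, float)
        # long-run occupancy Binomial(1000, 1/2)
        se = np.sqrt(1000 * 0.25 / 30)
        assert abs(finals.mean() - 500.0) < 3 * se

    def test_three_box_relaxation_matches_matrix_exponential(self):
        D = 1.5
        net = make_network("X -> Y ; kf=0", species={"X": D, "Y": 0.0})
        mesh = _chain(3)
        c0 = _counts(net, mesh, {("X", 0): 3000})
        t_obs = 0.3
        snapshots = []
        for seed in range(40):
            traj = st.run(net, mesh, c0, [], T=t_obs,
                          engine=st.EngineConfig(dt=2e-3, record_dt=t_obs,
                                                 seed=seed))
            snapshots.append(traj.final_counts[:, 0])
        snapshots = np.asarray(snapshots, float)
        L = D * np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        ref = expm(L * t_obs) @ np.array([3000.0, 0.0, 0.0])
        mean = snapshots.mean(axis=0)
        se = snapshots.std(axis=0, ddof=1) / np.sqrt(40)
        assert np.all(np.abs(mean - ref) < 3.5 * se)

    def test_hop_probability_cap_enforced(self):
        net = make_network("X -> Y ; kf=0", species={"X": 1000.0, "Y": 0.0})
        mesh = _chain(2)
        c0 = _counts(net, mesh, {("X", 0): 10})
        with pytest.raises(ValueError, match="hop probability"):
            st.run(net, mesh, c0, [], T=0.1,
                   engine=st.EngineConfig(dt=1e-3, record_dt=0.1, seed=1))


class TestRun:
    def test_zero_duration_returns_initial_record(self):
        net = make_network("A -> B ; kf=1")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 10})
        traj = st.run(net, mesh, c0, [], T=0.0,
                      engine=st.EngineConfig(dt=1e-3, record_dt=1.0, seed=1))
        assert len(traj.times) == 1 and traj.times[0] == 0.0

    def test_fixed_seed_reproducible(self):
        net = make_network("A <-> B ; kf=2 ; kb=1")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 500})
        eng = st.EngineConfig(dt=1e-3, record_dt=0.1, seed=42)
        t1 = st.run(net, mesh, c0, [], T=1.0, engine=eng)
        t2 = st.run(net, mesh, c0, [], T=1.0, engine=eng)
        assert np.array_equal(t1.data, t2.data)
        t3 = st.run(net, mesh, c0, [], T=1.0,
                    engine=st.EngineConfig(dt=1e-3, record_dt=0.1, seed=43))
        assert not np.array_equal(t1.data, t3.data)

    def test_seed_disjoint_means_agree(self):
        """Two disjoint seed sets give window means within 3 pooled SE."""
        net = make_network("A <-> B ; kf=3 ; kb=1")
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 800})
        def batch(seeds):
            return np.array([
                st.run(net, mesh, c0, [], T=1.0,
                       engine=st.EngineConfig(dt=1e-3, record_dt=1.0,
                                              seed=s)).final_counts[0, 0]
                for s in seeds], float)
        a = batch(range(30))
        b = batch(range(1000, 1030))
        pooled_se = np.sqrt(a.var(ddof=1) / 30 + b.var(ddof=1) / 30)
        assert abs(a.mean() - b.mean()) < 3 * pooled_se

    def test_clamp_holds_level_and_releases(self):
        net = make_network("A -> B ; kf=1", species={"A": 0.0, "B": 0.0})
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("A", 0): 0})
        level = 100.0 / F  # nM giving exactly 100 molecules in V=1
        clamp = cfg.StimulusTrain("A", (0,), "clamp", level, onset=0.0,
                                  duration=0.5, count=1)
        traj = st.run(net, mesh, c0, [clamp], T=1.0,
                      engine=st.EngineConfig(dt=1e-3, record_dt=0.25, seed=3))
        a = traj.conc("A") * F  # molecules
        assert a[1] == pytest.approx(100, abs=15)  # held near the clamp
        assert a[-1] < a[1]  # decays after release

    def test_injection_adds_expected_total(self):
        net = make_network("X -> Y ; kf=0", species={"X": 0.0, "Y": 0.0})
        mesh = st.single_compartment(1.0)
        c0 = _counts(net, mesh, {("X", 0): 0})
        inj = cfg.StimulusTrain("X", (0,), "injection", level=1000.0,
                                onset=0.0, duration=1.0, count=1)
        finals = [st.run(net, mesh, c0, [inj], T=1.0,
                         engine=st.EngineConfig(dt=1e-3, record_dt=1.0,
                                                seed=s)).final_counts[0, 0]
                  for s in range(30)]
        finals = np.asarray(finals, float)
        se = np.sqrt(1000 / 30)  # Poisson
        assert abs(finals.mean() - 1000) < 3 * se

    def test_moiety_conservation_exact_full_network(self, network, desk_mesh,
                                                    default_config):
        init = cfg.initialize(network, desk_mesh, default_config, seed=9)
        tot0 = {m: (init.counts @ w).sum()
                for m, w in network.conserved_moieties().items()}
        traj = st.run(network, desk_mesh, init, [], T=0.02,
                      engine=st.EngineConfig(dt=5e-6, record_dt=0.02, seed=9),
                      config=default_config)
        fc = traj.final_counts
        assert (fc >= 0).all()
        for m, w in network.conserved_moieties().items():
            assert (fc @ w).sum() == tot0[m], m

    def test_adaptive_mode_respects_diffusion_cap(self):
        net = make_network("X -> Y ; kf=0", species={"X": 100.0, "Y": 0.0})
        mesh = _chain(2)
        c0 = _counts(net, mesh, {("X", 0): 100000})
        traj = st.run(net, mesh, c0, [], T=0.05,
                      engine=st.EngineConfig(dt=1e-6, mode="adaptive",
                                             record_dt=0.05, seed=1))
        assert traj.final_counts[:, 0].sum() == 100000
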