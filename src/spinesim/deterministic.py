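"""Mass-action ODE engine: well-mixed and compartmental-spatial.

The deterministic engine serves two roles. It is the verification oracle for
the stochastic engine (for large copy numbers the tau-leap mean must converge
to the ODE solution), and it substitutes for multi-day stochastic runs in the
desk-scale presets, where trial-mean readouts (fold changes, window averages,
gradient decay lengths) are the quantities of interest.

The spatial variant integrates per-subvolume concentrations with finite-volume
diffusive fluxes (the continuum analog of the stochastic hop process) using a
stiff BDF integrator with an analytic sparse Jacobian. Stimulus pulse edges
are handled as integration segment boundaries; clamps hold species
algebraically; injections are square-wave source terms.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from . import geometry
from .configuration import (SpatialConfig, StimulusTrain, effective_diffusion,
                            effective_rate_constants)
from .geometry import Mesh
from .network import ReactionNetwork
from .trajectory import Trajectory, default_regions, region_matrix
from .units import NM_UM3_TO_MOLECULES as _F

__all__ = ["CompiledReactions", "run_wellmixed", "run_spatial", "settle_wellmixed"]

RTOL = 1e-6
ATOL = 1e-3  # nM; several species sit at single-molecule concentrations


class CompiledReactions:
    """Vectorized mass-action arrays for the elementary reaction list."""

    def __init__(self, network: ReactionNetwork, config: SpatialConfig | None = None):
        self.network = network
        n_r, n_s = network.n_reactions, network.n_species
        self.k = (effective_rate_constants(network, config)
                  if config is not None
                  else np.array([e.k for e in network.elementary]))
        self.r1 = np.empty(n_r, dtype=np.int64)
        self.r2 = np.full(n_r, -1, dtype=np.int64)
        self.identical = np.zeros(n_r, dtype=bool)
        for j, e in enumerate(network.elementary):
            names = [nm for nm, _ in e.reactants]
            self.r1[j] = network.index[names[0]]
            if len(names) == 2:
                self.r2[j] = network.index[names[1]]
            elif e.identical:
                self.identical[j] = True
        self.S = network.stoichiometry.astype(float)  # (n_r, n_s)
        self.has_r2 = self.r2 >= 0
        self.r2_safe = np.where(self.has_r2, self.r2, 0)

    def flux(self, C: np.ndarray) -> np.ndarray:
        """Mass-action flux per reaction; C is (..., n_species) in nM."""
        Cp = np.maximum(C, 0.0)
        f = self.k * Cp[..., self.r1]
        second = np.where(self.has_r2, Cp[..., self.r2_safe], 1.0)
        f = f * np.where(self.identical, Cp[..., self.r1], second)
        return f

    def rhs(self, C: np.ndarray) -> np.ndarray:
        return self.flux(C) @ self.S

    def jac_dense(self, c: np.ndarray) -> np.ndarray:
        """d(rhs)/dc for a single well-mixed state (n_s x n_s)."""
        n_r, n_s = self.S.shape
        cp = np.maximum(c, 0.0)
        df = np.zeros((n_r, n_s))
        rows = np.arange(n_r)
        second = np.where(self.has_r2, cp[self.r2_safe], 1.0)
        second = np.where(self.identical, cp[self.r1], second)
        dfl_dr1 = self.k * second
        np.add.at(df, (rows, self.r1), dfl_dr1)
        both = self.has_r2
        np.add.at(df, (rows[both], self.r2[both]), self.k[both] * cp[self.r1[both]])
        ident = self.identical
        np.add.at(df, (rows[ident], self.r1[ident]), self.k[ident] * cp[self.r1[ident]])
        return self.S.T @ df


# ---------------------------------------------------------------------------
# stimulus segmentation
# ---------------------------------------------------------------------------

def _segments(stimuli: list[StimulusTrain], T: float) -> list[float]:
    cuts = {0.0, float(T)}
    for st in stimuli:
        for b in st.boundaries():
            if 0.0 < b < T:
                cuts.add(float(b))
    return sorted(cuts)


def _active(stimuli: list[StimulusTrain], t_mid: float):
    clamps, injections = [], []
    for st in stimuli:
        if st.active_at(t_mid):
            (clamps if st.mode == "clamp" else injections).append(st)
    return clamps, injections


# ---------------------------------------------------------------------------
# well-mixed
# ---------------------------------------------------------------------------

def run_wellmixed(network: ReactionNetwork, init_conc: np.ndarray,
                  stimuli: list[StimulusTrain] | None = None, T: float = 100.0,
                  config: SpatialConfig | None = None, record_dt: float = 1.0,
                  total_volume: float | None = None,
                  rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the pooled network; returns a single-region trajectory.

    Stimulus targets are ignored (everything is one compartment); injection
    rates are converted with the total volume.
    """
    stimuli = stimuli or []
    if total_volume is None:
        total_volume = geometry.build_short_dendrite(0.3).total_volume()
    comp = CompiledReactions(network, config)
    c = np.asarray(init_conc, dtype=float).copy()
    times = [0.0]
    states = [c.copy()]
    record = np.arange(record_dt, T + record_dt / 2, record_dt)

    for t0, t1 in zip(_segments(stimuli, T)[:-1], _segments(stimuli, T)[1:]):
        clamps, injections = _active(stimuli, (t0 + t1) / 2)
        clamp_idx = np.array([network.index[st.species] for st in clamps], dtype=int)
        for st in clamps:
            c[network.index[st.species]] = st.level
        source = np.zeros(network.n_species)
        for st in injections:
            source[network.index[st.species]] += (st.level * len(st.targets)
                                                  / (total_volume * _F))

        def rhs(t, y):
            dy = comp.rhs(y) + source
            if len(clamp_idx):
                dy[clamp_idx] = 0.0
            return dy

        def jac(t, y):
            J = comp.jac_dense(y)
            if len(clamp_idx):
                J[clamp_idx, :] = 0.0
            return J

        t_eval = np.clip(record[(record > t0 + 1e-12) & (record <= t1 + 1e-12)],
                         t0, t1)
        sol = solve_ivp(rhs, (t0, t1), c, method="BDF", jac=jac,
                        rtol=rtol, atol=atol, t_eval=np.unique(np.append(t_eval, t1)))
        if not sol.success:
            worst = network.species[int(np.argmax(np.abs(comp.rhs(c))))].name
            raise RuntimeError(f"ODE solver failed at t={sol.t[-1]:.3f}s "
                               f"(fastest-changing species: {worst}): {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            if tt in t_eval:
                times.append(tt)
                states.append(yy.copy())
        c = sol.y[:, -1].copy()

    data = np.array(states)[:, None, :]
    return Trajectory(times=np.array(times), data=data, regions=["all"],
                      species=[s.name for s in network.species],
                      region_volumes=np.array([total_volume]),
                      meta={"engine": "deterministic-wellmixed"})


def settle_wellmixed(network: ReactionNetwork, init_conc: np.ndarray,
                     T: float = 2000.0, config: SpatialConfig | None = None,
                     total_volume: float | None = None) -> np.ndarray:
    """Relax the pooled network toward its basal steady state."""
    traj = run_wellmixed(network, init_conc, [], T=T, config=config,
                         record_dt=T, total_volume=total_volume)
    return traj.data[-1, 0, :]


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------

class _SpatialSystem:
    """Precompiled RHS/Jacobian of the compartmental reaction-diffusion ODEs."""

    def __init__(self, network: ReactionNetwork, mesh: Mesh,
                 config: SpatialConfig | None):
        self.network = network
        self.mesh = mesh
        self.comp = CompiledReactions(network, config)
        self.n_sub = mesh.n_subvolumes
        self.n_spec = network.n_species
        self.volumes = mesh.volumes()
        D = (effective_diffusion(network, config) if config is not None
             else network.diffusion_constants())
        self.D = D

        # symmetric conductances g = A/d; dc_i/dt += D_s/V_i * sum_j g_ij (c_j - c_i)
        n = self.n_sub
        G = sp.lil_matrix((n, n))
        for c in mesh.couplings:
            g = c.area / c.distance
            G[c.a, c.b] += g
            G[c.b, c.a] += g
            G[c.a, c.a] -= g
            G[c.b, c.b] -= g
        self.G = (sp.diags(1.0 / self.volumes) @ G.tocsr()).tocsr()

        # reaction Jacobian sparsity pattern within one subvolume
        S = self.comp.S
        entries = []  # (s_out, s_in, reaction, which-derivative)
        for j in range(S.shape[0]):
            outs = np.nonzero(S[j])[0]
            r1, r2 = self.comp.r1[j], self.comp.r2[j]
            for s_out in outs:
                entries.append((s_out, r1, j, 0))
                if r2 >= 0:
                    entries.append((s_out, r2, j, 1))
        self._jac_entries = np.array(entries, dtype=np.int64)

        # assemble the fixed diffusion Jacobian: kron(G, diag(D))
        self._J_diff = sp.kron(self.G, sp.diags(D), format="csr")

    def rhs_reaction(self, C: np.ndarray) -> np.ndarray:
        return self.comp.flux(C) @ self.comp.S

    def rhs(self, C: np.ndarray) -> np.ndarray:
        return self.rhs_reaction(C) + (self.G @ C) * self.D[None, :]

    def jac(self, C: np.ndarray) -> sp.csr_matrix:
        Cp = np.maximum(C, 0.0)
        e = self._jac_entries
        s_out, s_in, j, which = e[:, 0], e[:, 1], e[:, 2], e[:, 3]
        comp = self.comp
        # dflux_j/dc_{s_in} per subvolume
        second = np.where(comp.has_r2[j], Cp[:, comp.r2_safe[j]], 1.0)
        second = np.where(comp.identical[j], Cp[:, comp.r1[j]], second)
        d0 = comp.k[j] * second
        d0 = np.where(comp.identical[j], 2.0 * d0, d0)
        d1 = comp.k[j] * Cp[:, comp.r1[j]]
        dflux = np.where(which == 0, d0, d1)  # (n_sub, n_entries)
        vals = (comp.S[j, s_out] * dflux).ravel()
        sub = np.repeat(np.arange(self.n_sub), len(e)) * self.n_spec
        rows = sub + np.tile(s_out, self.n_sub)
        cols = sub + np.tile(s_in, self.n_sub)
        n = self.n_sub * self.n_spec
        J = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return J + self._J_diff


def run_spatial(network: ReactionNetwork, mesh: Mesh, init,
                stimuli: list[StimulusTrain] | None = None, T: float = 100.0,
                config: SpatialConfig | None = None, record_dt: float = 1.0,
                regions: dict[str, list[int]] | None = None,
                rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Compartmental ODE run on a mesh.

    ``init`` is either per-subvolume expected molecule counts (n_sub, n_spec)
    or an InitialState; it is converted to concentrations internally.
    """
    stimuli = stimuli or []
    if hasattr(init, "expected"):
        init = init.expected
    init = np.asarray(init, dtype=float)
    sys_ = _SpatialSystem(network, mesh, config)
    volumes = sys_.volumes
    C = init / (volumes[:, None] * _F)  # counts -> nM

    if regions is None:
        regions = default_regions(mesh)
    M = region_matrix(mesh, regions)
    region_vol = M @ volumes

    def to_region(Cstate: np.ndarray) -> np.ndarray:
        return (M @ (Cstate * volumes[:, None])) / (region_vol[:, None] * 1.0)

    times = [0.0]
    rec = [to_region(C)]
    record = np.arange(record_dt, T + record_dt / 2, record_dt)
    n_flat = sys_.n_sub * sys_.n_spec

    segs = _segments(stimuli, T)
    for t0, t1 in zip(segs[:-1], segs[1:]):
        clamps, injections = _active(stimuli, (t0 + t1) / 2)
        clamp_mask = np.zeros((sys_.n_sub, sys_.n_spec), dtype=bool)
        for st in clamps:
            j = network.index[st.species]
            C[list(st.targets), j] = st.level
            clamp_mask[list(st.targets), j] = True
        source = np.zeros((sys_.n_sub, sys_.n_spec))
        for st in injections:
            j = network.index[st.species]
            for i in st.targets:
                source[i, j] += st.level / (volumes[i] * _F)
        flat_mask = clamp_mask.ravel()
        keep = sp.diags((~flat_mask).astype(float), format="csr")

        def rhs(t, y):
            Cs = y.reshape(sys_.n_sub, sys_.n_spec)
            dy = (sys_.rhs(Cs) + source).ravel()
            dy[flat_mask] = 0.0
            return dy

        def jac(t, y):
            J = sys_.jac(y.reshape(sys_.n_sub, sys_.n_spec))
            return keep @ J

        t_eval = np.clip(record[(record > t0 + 1e-12) & (record <= t1 + 1e-12)],
                         t0, t1)
        sol = solve_ivp(rhs, (t0, t1), C.ravel(), method="BDF", jac=jac,
                        rtol=rtol, atol=atol,
                        t_eval=np.unique(np.append(t_eval, t1)))
        if not sol.success:
            raise RuntimeError(f"spatial ODE solver failed at t~{t0}-{t1}s: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            if tt in t_eval:
                times.append(tt)
                rec.append(to_region(yy.reshape(sys_.n_sub, sys_.n_spec)))
        C = sol.y[:, -1].reshape(sys_.n_sub, sys_.n_spec).copy()

    traj = Trajectory(times=np.array(times), data=np.array(rec),
                      regions=list(regions), species=[s.name for s in network.species],
                      region_volumes=region_vol,
                      meta={"engine": "deterministic-spatial", "mesh": mesh.name,
                            "n_subvolumes": sys_.n_sub})
    traj.final_conc = C  # per-subvolume nM, for chaining runs
    return traj
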