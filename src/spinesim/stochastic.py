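"""Mesoscopic tau-leap reaction-diffusion engine.

Each time step draws, per subvolume, a Poisson number of firings for every
elementary reaction (mean = propensity * dt) and applies the stoichiometry;
diffusion then moves molecules between coupled subvolumes with multinomially
partitioned binomial draws (n = current count, p = per-molecule hop rate * dt,
bounded below 0.1). Per-species totals are conserved exactly by diffusion, and
conserved moieties are invariant under the reaction update by construction.

If a leap would drive a count negative in some subvolume, the step is redrawn
locally with a halved dt (up to 5 times), then falls back to an exact SSA for
that subvolume and step — boundary accuracy without a global step penalty.

A fixed 5 us step reproduces the reference integration scheme; the adaptive
mode rescales the step from the propensity time-scales (bounded by the
diffusion-probability cap) for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import geometry
from .configuration import (InitialState, SpatialConfig, StimulusTrain,
                            effective_diffusion, effective_rate_constants)
from .geometry import Mesh
from .network import ReactionNetwork
from .trajectory import Trajectory, default_regions, region_matrix
from .units import NM_UM3_TO_MOLECULES as _F

__all__ = ["EngineConfig", "run", "compile_model", "single_compartment"]

MAX_HOP_P = 0.1


@dataclass(frozen=True)
class EngineConfig:
    dt: float = 5e-6           # s; the reference-fidelity step
    mode: str = "fixed"        # fixed | adaptive
    eps: float = 0.03          # adaptive leap tolerance
    record_dt: float = 0.1     # s
    seed: int = 1
    max_retry: int = 5

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown dt mode {self.mode!r}")
        if not (0 < self.eps <= 0.1):
            raise ValueError("adaptive tolerance must lie in (0, 0.1]")


def single_compartment(volume: float) -> Mesh:
    """A one-subvolume mesh (well-mixed stochastic runs)."""
    return Mesh([geometry.Subvolume(0, geometry.DEND_CYT, volume, 0.0)], [],
                {}, name="well-mixed")


# ---------------------------------------------------------------------------
# model compilation
# ---------------------------------------------------------------------------

class CompiledModel:
    """Flat arrays consumed by the numba kernels."""

    def __init__(self, network: ReactionNetwork, mesh: Mesh,
                 config: SpatialConfig | None):
        self.network, self.mesh = network, mesh
        n_sub, n_rxn = mesh.n_subvolumes, network.n_reactions
        volumes = mesh.volumes()
        k = (effective_rate_constants(network, config) if config is not None
             else np.array([e.k for e in network.elementary]))

        r1 = np.empty(n_rxn, np.int64)
        r2 = np.full(n_rxn, -1, np.int64)
        q1 = np.ones(n_rxn, np.int64)
        q2 = np.zeros(n_rxn, np.int64)
        identical = np.zeros(n_rxn, np.uint8)
        for j, e in enumerate(network.elementary):
            terms = list(e.reactants)
            r1[j] = network.index[terms[0][0]]
            q1[j] = terms[0][1]
            if len(terms) == 2:
                r2[j] = network.index[terms[1][0]]
                q2[j] = terms[1][1]
            identical[j] = 1 if e.identical else 0

        # per-subvolume propensity constants
        csub = np.empty((n_sub, n_rxn))
        for j, e in enumerate(network.elementary):
            if e.order == 1:
                csub[:, j] = k[j]
            else:
                csub[:, j] = k[j] / (_F * volumes)
                if identical[j]:
                    csub[:, j] *= 2.0  # a = c*n*(n-1)/2 matches flux k*[A]^2

        # stoichiometry in CSR layout
        S = network.stoichiometry
        ptr = [0]
        spec_idx, delta = [], []
        for j in range(n_rxn):
            nz = np.nonzero(S[j])[0]
            spec_idx.extend(nz.tolist())
            delta.extend(S[j, nz].tolist())
            ptr.append(len(spec_idx))
        self.rxn_ptr = np.array(ptr, np.int64)
        self.rxn_spec = np.array(spec_idx, np.int64)
        self.rxn_delta = np.array(delta, np.int64)
        self.r1, self.r2, self.q1, self.q2 = r1, r2, q1, q2
        self.identical = identical
        self.csub = csub

        # species -> reactions with that species as a reactant (for incremental
        # propensity cache updates)
        by_spec: list[list[int]] = [[] for _ in range(network.n_species)]
        for j in range(n_rxn):
            by_spec[r1[j]].append(j)
            if r2[j] >= 0 and r2[j] != r1[j]:
                by_spec[r2[j]].append(j)
        sptr = [0]
        srxn = []
        for s in range(network.n_species):
            srxn.extend(by_spec[s])
            sptr.append(len(srxn))
        self.sp_ptr = np.array(sptr, np.int64)
        self.sp_rxn = np.array(srxn, np.int64)

        # directed diffusion edges grouped by source subvolume
        D = (effective_diffusion(network, config) if config is not None
             else network.diffusion_constants())
        self.dspec = np.nonzero(D > 0)[0].astype(np.int64)
        self.dD = D[self.dspec]
        edges: list[list[tuple[int, float]]] = [[] for _ in range(n_sub)]
        for c in mesh.couplings:
            edges[c.a].append((c.b, c.area / (volumes[c.a] * c.distance)))
            edges[c.b].append((c.a, c.area / (volumes[c.b] * c.distance)))
        eptr = [0]
        eto, ekb = [], []
        for i in range(n_sub):
            for to, kb in edges[i]:
                eto.append(to)
                ekb.append(kb)
            eptr.append(len(eto))
        self.edge_ptr = np.array(eptr, np.int64)
        self.edge_to = np.array(eto, np.int64)
        self.edge_kbase = np.array(ekb, float)
        self.edge_ksum = np.array([sum(kb for _, kb in edges[i])
                                   for i in range(n_sub)])
        self.volumes = volumes

    def max_hop_probability(self, dt: float) -> tuple[float, str]:
        if len(self.edge_kbase) == 0 or len(self.dD) == 0:
            return 0.0, ""
        pmax, desc = 0.0, ""
        kmax = float(self.edge_kbase.max())
        e = int(np.argmax(self.edge_kbase))
        src = int(np.searchsorted(self.edge_ptr, e, side="right") - 1)
        for s, Ds in zip(self.dspec, self.dD):
            p = Ds * kmax * dt
            if p > pmax:
                pmax = p
                desc = (f"species {self.network.species[int(s)].name} on coupling "
                        f"{src}->{int(self.edge_to[e])} (k_hop={Ds * kmax:.3g}/s)")
        return pmax, desc

    def diffusion_dt_cap(self) -> float:
        if len(self.edge_kbase) == 0 or len(self.dD) == 0:
            return np.inf
        return MAX_HOP_P / (float(self.edge_kbase.max()) * float(self.dD.max()))


def compile_model(network: ReactionNetwork, mesh: Mesh,
                  config: SpatialConfig | None = None) -> CompiledModel:
    return CompiledModel(network, mesh, config)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _propensity(cnt, j, r1, r2, q1, q2, identical, c):
    n1 = cnt[r1[j]]
    if n1 < q1[j]:
        return 0.0
    if identical[j] == 1:
        return c * 0.5 * n1 * (n1 - 1)
    if r2[j] >= 0:
        n2 = cnt[r2[j]]
        if n2 < q2[j]:
            return 0.0
        return c * n1 * n2
    return c * n1


@njit(cache=True)
def _ssa_subvolume(cnt, crow, r1, r2, q1, q2, identical,
                   rxn_ptr, rxn_spec, rxn_delta, tmax):
    n_rxn = crow.shape[0]
    a = np.empty(n_rxn)
    t = 0.0
    while True:
        atot = 0.0
        for j in range(n_rxn):
            a[j] = _propensity(cnt, j, r1, r2, q1, q2, identical, crow[j])
            atot += a[j]
        if atot <= 0.0:
            return
        t += -np.log(np.random.random()) / atot
        if t > tmax:
            return
        u = np.random.random() * atot
        acc = 0.0
        jpick = n_rxn - 1
        for j in range(n_rxn):
            acc += a[j]
            if u <= acc:
                jpick = j
                break
        for m in range(rxn_ptr[jpick], rxn_ptr[jpick + 1]):
            cnt[rxn_spec[m]] += rxn_delta[m]


@njit(cache=True)
def _react_subvolume(cnt, scratch, crow, r1, r2, q1, q2, identical,
                     rxn_ptr, rxn_spec, rxn_delta, dt, max_retry):
    remaining = dt
    h = dt
    fails = 0
    n_spec = cnt.shape[0]
    n_rxn = crow.shape[0]
    while remaining > 1e-18:
        if h > remaining:
            h = remaining
        for s in range(n_spec):
            scratch[s] = cnt[s]
        ok = True
        for j in range(n_rxn):
            a = _propensity(cnt, j, r1, r2, q1, q2, identical, crow[j])
            if a <= 0.0:
                continue
            m = np.random.poisson(a * h)
            if m == 0:
                continue
            for e in range(rxn_ptr[j], rxn_ptr[j + 1]):
                scratch[rxn_spec[e]] += m * rxn_delta[e]
        for s in range(n_spec):
            if scratch[s] < 0:
                ok = False
                break
        if ok:
            for s in range(n_spec):
                cnt[s] = scratch[s]
            remaining -= h
        else:
            fails += 1
            if fails > max_retry:
                _ssa_subvolume(cnt, crow, r1, r2, q1, q2, identical,
                               rxn_ptr, rxn_spec, rxn_delta, remaining)
                return
            h *= 0.5


@njit(cache=True, inline="always")
def _refresh_species(counts, i, s, a_cache, A_tot, csub,
                     r1, r2, q1, q2, identical, sp_ptr, sp_rxn):
    """Update cached propensities of the reactions consuming species s."""
    for m in range(sp_ptr[s], sp_ptr[s + 1]):
        j = sp_rxn[m]
        a_new = _propensity(counts[i], j, r1, r2, q1, q2, identical, csub[i, j])
        A_tot[i] += a_new - a_cache[i, j]
        a_cache[i, j] = a_new


@njit(cache=True)
def _refresh_subvolume(counts, i, a_cache, A_tot, csub,
                       r1, r2, q1, q2, identical):
    tot = 0.0
    for j in range(csub.shape[1]):
        a = _propensity(counts[i], j, r1, r2, q1, q2, identical, csub[i, j])
        a_cache[i, j] = a
        tot += a
    A_tot[i] = tot


@njit(cache=True)
def _step_chunk(counts, scratch, delta, a_cache, A_tot,
                csub, r1, r2, q1, q2, identical,
                rxn_ptr, rxn_spec, rxn_delta, sp_ptr, sp_rxn,
                dspec, dD, edge_ptr, edge_to, edge_kbase, edge_ksum,
                clamp_sub, clamp_spec, clamp_n,
                inj_sub, inj_spec, inj_rate,
                n_steps, dt, max_retry):
    """Advance n_steps of tau-leap reactions + diffusion.

    Per subvolume the number of reaction firings is drawn once from a Poisson
    with the cached total propensity (exact, by superposition of the
    per-reaction Poisson processes) and attributed to individual reactions in
    proportion to their cached propensities; caches update incrementally as
    counts change, so quiescent subvolumes cost one draw per step.
    """
    n_sub = counts.shape[0]
    n_spec = counts.shape[1]
    n_rxn = csub.shape[1]
    changed = np.empty(128, np.int64)
    seen = np.zeros(n_spec, np.uint8)
    for i in range(n_sub):
        _refresh_subvolume(counts, i, a_cache, A_tot, csub, r1, r2, q1, q2,
                           identical)
    # scan reactions in decreasing total-propensity order so the categorical
    # selection of a firing terminates after a few comparisons
    colsum = np.zeros(n_rxn)
    for i in range(n_sub):
        for j in range(n_rxn):
            colsum[j] += a_cache[i, j]
    order = np.argsort(-colsum)
    for _ in range(n_steps):
        # clamps reset at the start of every step
        for c in range(clamp_sub.shape[0]):
            i, s = clamp_sub[c], clamp_spec[c]
            if counts[i, s] != clamp_n[c]:
                counts[i, s] = clamp_n[c]
                _refresh_species(counts, i, s, a_cache, A_tot, csub,
                                 r1, r2, q1, q2, identical, sp_ptr, sp_rxn)
        for c in range(inj_sub.shape[0]):
            lam = inj_rate[c] * dt
            if lam > 0.0:
                m = np.random.poisson(lam)
                if m > 0:
                    i, s = inj_sub[c], inj_spec[c]
                    counts[i, s] += m
                    _refresh_species(counts, i, s, a_cache, A_tot, csub,
                                     r1, r2, q1, q2, identical, sp_ptr, sp_rxn)
        # reactions
        for i in range(n_sub):
            Ai = A_tot[i]
            if Ai <= 0.0:
                continue
            mtot = np.random.poisson(Ai * dt)
            if mtot == 0:
                continue
            # snapshot for rollback, then apply mtot firings drawn from the
            # start-of-step propensities (batch tau-leap semantics)
            for s in range(n_spec):
                scratch[s] = counts[i, s]
            n_changed = 0
            overflow = False
            for _k in range(mtot):
                u = np.random.random() * Ai
                acc = 0.0
                jpick = -1
                for jj in range(n_rxn):
                    j = order[jj]
                    a = a_cache[i, j]
                    if a > 0.0:
                        acc += a
                        if u <= acc:
                            jpick = j
                            break
                if jpick < 0:
                    continue  # float round-off at the tail: no firing
                for e in range(rxn_ptr[jpick], rxn_ptr[jpick + 1]):
                    s = rxn_spec[e]
                    counts[i, s] += rxn_delta[e]
                    if seen[s] == 0:
                        if n_changed < 128:
                            seen[s] = 1
                            changed[n_changed] = s
                            n_changed += 1
                        else:
                            overflow = True
            negative = False
            if overflow:
                for s in range(n_spec):
                    if counts[i, s] < 0:
                        negative = True
                        break
            else:
                for m in range(n_changed):
                    if counts[i, changed[m]] < 0:
                        negative = True
                        break
            if negative or overflow:
                if negative:
                    # restore and redo this subvolume-step with local halving
                    for s in range(n_spec):
                        counts[i, s] = scratch[s]
                    _react_subvolume(counts[i], scratch, csub[i], r1, r2, q1,
                                     q2, identical, rxn_ptr, rxn_spec,
                                     rxn_delta, dt, max_retry)
                _refresh_subvolume(counts, i, a_cache, A_tot, csub, r1, r2,
                                   q1, q2, identical)
                for m in range(n_changed):
                    seen[changed[m]] = 0
            else:
                for m in range(n_changed):
                    s = changed[m]
                    seen[s] = 0
                    if counts[i, s] != scratch[s]:
                        _refresh_species(counts, i, s, a_cache, A_tot,
                                         csub, r1, r2, q1, q2, identical,
                                         sp_ptr, sp_rxn)
        # diffusion: one aggregate leave-draw per (subvolume, species), then a
        # multinomial split across edges; totals conserved exactly
        if dspec.shape[0] > 0:
            for si in range(dspec.shape[0]):
                for i in range(n_sub):
                    delta[i, si] = 0
            for si in range(dspec.shape[0]):
                s = dspec[si]
                Ds = dD[si]
                for i in range(n_sub):
                    n = counts[i, s]
                    if n == 0:
                        continue
                    ptot = Ds * edge_ksum[i] * dt
                    if ptot <= 0.0:
                        continue
                    mtot = np.random.binomial(n, ptot)
                    if mtot == 0:
                        continue
                    prem = ptot
                    for e in range(edge_ptr[i], edge_ptr[i + 1]):
                        p = Ds * edge_kbase[e] * dt
                        q = p / prem
                        if q > 1.0:
                            q = 1.0
                        m = np.random.binomial(mtot, q)
                        if m > 0:
                            delta[i, si] -= m
                            delta[edge_to[e], si] += m
                            mtot -= m
                        prem -= p
                        if mtot <= 0:
                            break
            for si in range(dspec.shape[0]):
                s = dspec[si]
                for i in range(n_sub):
                    d = delta[i, si]
                    if d != 0:
                        counts[i, s] += d
                        _refresh_species(counts, i, s, a_cache, A_tot, csub,
                                         r1, r2, q1, q2, identical,
                                         sp_ptr, sp_rxn)


@njit(cache=True)
def _tau_bound(counts, csub, r1, r2, q1, q2, identical,
               rxn_ptr, rxn_spec, rxn_delta, eps):
    """Largest dt keeping expected relative change per species below eps."""
    n_sub, n_spec = counts.shape
    n_rxn = csub.shape[1]
    best = 1e9
    mu = np.empty(n_spec)
    var = np.empty(n_spec)
    for i in range(n_sub):
        for s in range(n_spec):
            mu[s] = 0.0
            var[s] = 0.0
        for j in range(n_rxn):
            a = _propensity(counts[i], j, r1, r2, q1, q2, identical, csub[i, j])
            if a <= 0.0:
                continue
            for e in range(rxn_ptr[j], rxn_ptr[j + 1]):
                d = rxn_delta[e]
                mu[rxn_spec[e]] += d * a
                var[rxn_spec[e]] += d * d * a
        for s in range(n_spec):
            lim = eps * counts[i, s]
            if lim < 1.0:
                lim = 1.0
            if mu[s] != 0.0:
                b = lim / abs(mu[s])
                if b < best:
                    best = b
            if var[s] > 0.0:
                b = lim * lim / var[s]
                if b < best:
                    best = b
    return best


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _clamp_arrays(network, mesh, clamps):
    subs, specs, ns = [], [], []
    volumes = mesh.volumes()
    for st in clamps:
        j = network.index[st.species]
        for i in st.targets:
            subs.append(i)
            specs.append(j)
            ns.append(int(round(st.level * volumes[i] * _F)))
    return (np.array(subs, np.int64), np.array(specs, np.int64),
            np.array(ns, np.int64))


def _inj_arrays(network, injections):
    subs, specs, rates = [], [], []
    for st in injections:
        j = network.index[st.species]
        for i in st.targets:
            subs.append(i)
            specs.append(j)
            rates.append(st.level)
    return (np.array(subs, np.int64), np.array(specs, np.int64),
            np.array(rates, float))


def run(network: ReactionNetwork, mesh: Mesh, init,
        stimuli: list[StimulusTrain] | None = None, T: float = 1.0,
        engine: EngineConfig | None = None,
        config: SpatialConfig | None = None,
        regions: dict[str, list[int]] | None = None,
        model: CompiledModel | None = None) -> Trajectory:
    """Propagate molecule counts on the mesh; returns region concentrations.

    ``init`` is an InitialState or an int64 (n_sub, n_spec) count array.
    Bit-reproducible for a fixed EngineConfig.seed.
    """
    stimuli = stimuli or []
    engine = engine or EngineConfig()
    if model is None:
        model = compile_model(network, mesh, config)
    counts = (init.counts if isinstance(init, InitialState) else init)
    counts = np.array(counts, dtype=np.int64, copy=True)
    if counts.shape != (mesh.n_subvolumes, network.n_species):
        raise ValueError("count array shape does not match mesh/network")
    if np.any(counts < 0):
        raise ValueError("negative initial counts")

    dt_cap = model.diffusion_dt_cap()
    if engine.mode == "fixed":
        pmax, desc = model.max_hop_probability(engine.dt)
        if pmax >= MAX_HOP_P:
            raise ValueError(
                f"diffusion hop probability {pmax:.3f} >= {MAX_HOP_P} at "
                f"dt={engine.dt:g}s for {desc}; reduce dt below "
                f"{dt_cap:.3g}s")

    if regions is None:
        regions = default_regions(mesh) if mesh.spines else {"all": list(range(mesh.n_subvolumes))}
    M = region_matrix(mesh, regions)
    region_vol = M @ model.volumes

    _seed(engine.seed % 2**31)
    scratch = np.empty(network.n_species, np.int64)
    delta = np.zeros((mesh.n_subvolumes, max(1, len(model.dspec))), np.int64)
    a_cache = np.zeros((mesh.n_subvolumes, network.n_reactions))
    A_tot = np.zeros(mesh.n_subvolumes)

    rec_times = [0.0]
    rec_data = [(M @ counts) / (region_vol[:, None] * _F)]

    # timeline: union of record times and stimulus boundaries
    record_marks = np.arange(engine.record_dt, T + engine.record_dt / 2,
                             engine.record_dt)
    cuts = sorted(set([0.0, float(T)])
                  | {float(b) for st in stimuli for b in st.boundaries()
                     if 0 < b < T}
                  | {float(t) for t in record_marks if t < T})
    cuts.append(float(T)) if cuts[-1] != float(T) else None

    t_now = 0.0
    for t_next in cuts[1:]:
        span = t_next - t_now
        if span <= 1e-15:
            t_now = t_next
            continue
        t_mid = (t_now + t_next) / 2
        clamps = [st for st in stimuli if st.mode == "clamp" and st.active_at(t_mid)]
        injections = [st for st in stimuli if st.mode == "injection" and st.active_at(t_mid)]
        c_sub, c_spec, c_n = _clamp_arrays(network, mesh, clamps)
        i_sub, i_spec, i_rate = _inj_arrays(network, injections)

        if engine.mode == "adaptive":
            tau = _tau_bound(counts, model.csub, model.r1, model.r2, model.q1,
                             model.q2, model.identical, model.rxn_ptr,
                             model.rxn_spec, model.rxn_delta, engine.eps)
            dt = min(max(tau, engine.dt), dt_cap, span)
        else:
            dt = engine.dt
        n_steps = max(1, int(round(span / dt)))
        dt = span / n_steps
        _step_chunk(counts, scratch, delta, a_cache, A_tot,
                    model.csub, model.r1, model.r2,
                    model.q1, model.q2, model.identical, model.rxn_ptr,
                    model.rxn_spec, model.rxn_delta, model.sp_ptr, model.sp_rxn,
                    model.dspec, model.dD,
                    model.edge_ptr, model.edge_to, model.edge_kbase,
                    model.edge_ksum,
                    c_sub, c_spec, c_n, i_sub, i_spec, i_rate,
                    n_steps, dt, engine.max_retry)
        t_now = t_next
        if np.any(np.isclose(t_now, record_marks)) or t_now == float(T):
            rec_times.append(t_now)
            rec_data.append((M @ counts) / (region_vol[:, None] * _F))

    import hashlib
    config_hash = hashlib.sha1(
        repr((mesh.name, config, engine, sorted(st.species for st in stimuli))
             ).encode()).hexdigest()[:12]
    traj = Trajectory(times=np.array(rec_times), data=np.array(rec_data),
                      regions=list(regions),
                      species=[s.name for s in network.species],
                      region_volumes=region_vol,
                      meta={"engine": "stochastic-tau-leap", "seed": engine.seed,
                            "dt": engine.dt, "mode": engine.mode,
                            "mesh": mesh.name, "config_hash": config_hash})
    traj.final_counts = counts
    return traj
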