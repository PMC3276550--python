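"""Anchoring configurations, initial molecule counts, and stimulation inputs.

The model's experimental design varies *where* the anchored pools sit while
holding every total amount fixed:

* the D1R/G-protein/adenylate-cyclase complex is anchored either in the four
  spine heads or in a focal dendritic submembrane area (volume of one spine
  head, beneath the second spine);
* the PKA holoenzyme pool is anchored in the spine heads, the focal area, or
  distributed uniformly (the Ht31-peptide mimic);
* PDE10 occupies the submembrane + spine compartments or is uniform;
* dopamine diffuses fast (volume transmission, uniform 1 uM transients) or
  3x slower with release localized to one end (extracellular gradient mode).

Initial counts are drawn per subvolume by expectation-preserving stochastic
rounding of conc * volume * N_A. Cytosolic pools populate the entire
morphology (PSD included); anchored receptor/G-protein/cyclase pools are
excluded from the PSD, while PKA pools and the AMPA receptors occupy it.

Stimuli are pulse trains that either clamp a species' concentration in target
subvolumes or inject molecules at a constant rate during each pulse:

* phasic dopamine: five 1 s, 1 uM elevations, 20 s apart;
* calcium tetanus: 100 pulses x 3 ms x 125 molecules/ms into two PSDs
  (10 ms gaps; the ~100 Hz, 1 s LTP protocol);
* bath application: a sustained clamp at an agonist concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry
from .geometry import Mesh
from .network import ReactionNetwork
from .units import NM_UM3_TO_MOLECULES as _F

__all__ = [
    "SpatialConfig",
    "InitialState",
    "StimulusTrain",
    "initialize",
    "expected_counts",
    "wellmixed_concentrations",
    "effective_diffusion",
    "effective_rate_constants",
    "dopamine_phasic",
    "calcium_tetanus",
    "bath_clamp",
    "DEFAULT_STIM_ONSET",
]

SPINE = "spine-head"
FOCAL = "focal-dendrite"
UNIFORM = "uniform"
SPLIT = "split"  # half spine heads, half focal patches (validation runs)

# stimuli start after a basal settling period; analysis windows quoted from
# the experiments (50-350 s etc.) are measured from simulation start
DEFAULT_STIM_ONSET = 50.0

DOPAMINE_PULSE_NM = 1000.0
DOPAMINE_PULSE_S = 1.0
DOPAMINE_PULSE_GAP_S = 20.0
DOPAMINE_PULSES = 5

CA_PULSES = 100
CA_PULSE_S = 0.003
CA_PULSE_GAP_S = 0.010
CA_RATE_PER_MS = 125.0


@dataclass(frozen=True)
class SpatialConfig:
    """One anchoring/stimulation configuration of the model."""

    AC_location: str = SPINE          # spine-head | focal-dendrite
    PKA_location: str = SPINE         # spine-head | focal-dendrite | uniform
    PDE10_distribution: str = "submembrane+spine"  # | uniform
    dopamine_D: float = 150.0         # um^2/s; 50 = extracellular-gradient mode
    neck_length: float = 0.3          # um, for the short mesh
    DARPP32_diffusion_mode: str = "all-diffuse"  # | all-frozen | PKA-bound-frozen
    pT75_PKA_block: bool = False

    def __post_init__(self):
        if self.AC_location not in (SPINE, FOCAL, SPLIT):
            raise ValueError(f"bad AC_location {self.AC_location!r}")
        if self.PKA_location not in (SPINE, FOCAL, UNIFORM, SPLIT):
            raise ValueError(f"bad PKA_location {self.PKA_location!r}")
        if self.PDE10_distribution not in ("submembrane+spine", UNIFORM):
            raise ValueError(f"bad PDE10_distribution {self.PDE10_distribution!r}")
        if self.dopamine_D not in (150.0, 50.0):
            raise ValueError("dopamine_D must be 150 (volume transmission) or 50 (gradient)")
        if self.DARPP32_diffusion_mode not in ("all-diffuse", "all-frozen",
                                               "PKA-bound-frozen"):
            raise ValueError(f"bad DARPP32_diffusion_mode {self.DARPP32_diffusion_mode!r}")

    def with_(self, **kw) -> "SpatialConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# basal state tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("spinesim").joinpath("data", name))


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    header_skipped = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_skipped:
            header_skipped = True
            continue
        rows.append(line.split("\t"))
    return rows


def load_basal_tables() -> tuple[dict[str, tuple[str, float]], list[dict]]:
    """(species -> (pool, avg conc nM), anchored rows)."""
    basal = {}
    for name, pool, conc in _read_tsv(_data_path("initial_state.tsv")):
        basal[name] = (pool, float(conc))
    anchored = []
    for name, pool, spine_nm, focal_sd in _read_tsv(_data_path("anchored_state.tsv")):
        anchored.append({"species": name, "pool": pool,
                         "spine_nM": float(spine_nm),
                         "focal_picoSD": float(focal_sd)})
    return basal, anchored


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------

@dataclass
class InitialState:
    counts: np.ndarray    # int64 (n_subvolumes, n_species)
    expected: np.ndarray  # float (n_subvolumes, n_species)
    config: SpatialConfig


def _spread(expected: np.ndarray, j: int, total: float, ids: list[int],
            volumes: np.ndarray) -> None:
    """Distribute an expected total uniformly per volume over subvolumes."""
    if not ids:
        raise ValueError("empty target region for initialization")
    v = volumes[ids]
    expected[ids, j] += total * v / v.sum()


def expected_counts(network: ReactionNetwork, mesh: Mesh,
                    config: SpatialConfig) -> np.ndarray:
    """Expected molecule count per (subvolume, species) under a configuration.

    Anchored totals are identical across configurations by construction: each
    pool's total equals its per-spine amount (local conc x spine-head volume,
    plus the PSD slice for PKA species) times the number of spines, wherever
    it is placed.
    """
    basal, anchored = load_basal_tables()
    volumes = mesh.volumes()
    v_total = float(volumes.sum())
    expected = np.zeros((mesh.n_subvolumes, network.n_species))

    psd_ids = mesh.region_ids(geometry.PSD)
    all_ids = list(range(mesh.n_subvolumes))
    membrane_ids = mesh.membrane_ids()
    pde10_region = (membrane_ids if config.PDE10_distribution == "submembrane+spine"
                    else all_ids)
    focal_ids = mesh.region_ids(geometry.FOCAL)

    for name, (pool, conc) in basal.items():
        if name not in network.index:
            raise ValueError(f"basal species {name!r} not in network")
        j = network.index[name]
        if pool == "cytosol":
            # the general-cytosol pool populates the entire morphology,
            # PSD included (the PSD exclusion applies to the spine-anchored
            # receptor/G/cyclase pools only)
            _spread(expected, j, conc * v_total * _F, all_ids, volumes)
        elif pool == "pde10":
            _spread(expected, j, conc * v_total * _F, pde10_region, volumes)
        elif pool == "membrane":
            _spread(expected, j, conc * v_total * _F, membrane_ids, volumes)
        elif pool == "psd":
            # meshes whose spine heads absorb the PSD slice put the receptor
            # pool in the merged head
            targets = psd_ids or [mesh.spines[s]["psd"] for s in mesh.spines]
            for i in targets:
                expected[i, j] += conc * volumes[i] * _F
        elif pool == "pka_avg":
            continue  # morphology-averaged duplicate of the anchored pool
        else:
            raise ValueError(f"unknown pool {pool!r} for {name}")

    # anchored pools
    head_cyt_vol = sum(mesh.subvolumes[i].volume
                       for i in mesh.spine_head_ids(0, include_psd=False))
    head_psd_vol = sum(mesh.subvolumes[i].volume
                       for i in mesh.spine_head_ids(0, include_psd=True))
    n_spines = len(mesh.spines)
    for row in anchored:
        j = network.index[row["species"]]
        is_pka = row["pool"] == "pka"
        per_spine = row["spine_nM"] * (head_psd_vol if is_pka else head_cyt_vol) * _F
        loc = config.PKA_location if is_pka else config.AC_location
        if loc == SPINE:
            for s in mesh.spines:
                ids = mesh.spine_head_ids(s, include_psd=is_pka)
                _spread(expected, j, per_spine, ids, volumes)
        elif loc == FOCAL:
            # each spine's quota goes to the focal dendritic patch beneath it,
            # keeping local and global anchored concentrations identical to
            # the spine-anchored configuration
            for s in mesh.spines:
                patch = mesh.spines[s].get("focal") or focal_ids
                _spread(expected, j, per_spine, patch, volumes)
        elif loc == SPLIT:
            # equal amounts in spine and dendrite (the validation layout)
            for s in mesh.spines:
                ids = mesh.spine_head_ids(s, include_psd=is_pka)
                _spread(expected, j, per_spine / 2, ids, volumes)
                patch = mesh.spines[s].get("focal") or focal_ids
                _spread(expected, j, per_spine / 2, patch, volumes)
        elif loc == UNIFORM:
            _spread(expected, j, per_spine * n_spines, all_ids, volumes)
    return expected


def initialize(network: ReactionNetwork, mesh: Mesh, config: SpatialConfig,
               seed: int | np.random.Generator = 0) -> InitialState:
    """Draw integer molecule counts by expectation-preserving rounding."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = expected_counts(network, mesh, config)
    base = np.floor(expected)
    frac = expected - base
    counts = (base + (rng.random(expected.shape) < frac)).astype(np.int64)
    return InitialState(counts=counts, expected=expected, config=config)


def wellmixed_concentrations(network: ReactionNetwork, mesh: Mesh | None = None,
                             config: SpatialConfig | None = None) -> np.ndarray:
    """Pooled (whole-morphology) basal concentrations, nM per species.

    Used by the well-mixed validation runs. Cytosolic, membrane and PDE10
    pools are morphology averages as printed; the PKA pool uses the printed
    morphology-averaged values directly, and the receptor/G/cyclase pool is
    averaged from its per-spine amounts.
    """
    if mesh is None:
        mesh = geometry.build_short_dendrite(0.3)
    basal, anchored = load_basal_tables()
    v_total = mesh.total_volume()
    head_cyt_vol = sum(mesh.subvolumes[i].volume
                       for i in mesh.spine_head_ids(0, include_psd=False))
    psd_vol = mesh.subvolumes[mesh.spines[0]["psd"]].volume
    n_spines = len(mesh.spines)

    conc = np.zeros(network.n_species)
    for name, (pool, c) in basal.items():
        j = network.index[name]
        if pool == "psd":
            conc[j] += c * (n_spines * psd_vol) / v_total
        else:
            conc[j] += c  # every other pool is a whole-morphology average
    for row in anchored:
        if row["pool"] == "ac":
            j = network.index[row["species"]]
            conc[j] += row["spine_nM"] * (n_spines * head_cyt_vol) / v_total
    return conc


# ---------------------------------------------------------------------------
# configuration-dependent network adjustments
# ---------------------------------------------------------------------------

def effective_diffusion(network: ReactionNetwork, config: SpatialConfig) -> np.ndarray:
    """Per-species diffusion constants under a configuration."""
    D = network.diffusion_constants().copy()
    D[network.index["Da"]] = config.dopamine_D
    if config.DARPP32_diffusion_mode == "all-frozen":
        for i, s in enumerate(network.species):
            if s.composition.get("d32"):
                D[i] = 0.0
    elif config.DARPP32_diffusion_mode == "PKA-bound-frozen":
        D[network.index["D32_PKAc"]] = 0.0
        D[network.index["p75D32_PKAc"]] = 0.0
    return D


def effective_rate_constants(network: ReactionNetwork, config: SpatialConfig) -> np.ndarray:
    """Per-elementary-reaction rate constants under a configuration."""
    k = np.array([e.k for e in network.elementary])
    if config.pT75_PKA_block:
        for j, e in enumerate(network.elementary):
            if e.tag.startswith("p75_pka_inhib"):
                k[j] = 0.0
    return k


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """A train of timed clamps or injections targeted at subvolumes.

    mode "clamp": hold the species at `level` nM in each target subvolume for
    the pulse duration. mode "injection": add `level` molecules per second to
    each target subvolume for the pulse duration. Pulse onsets are spaced
    ``duration + gap`` apart.
    """

    species: str
    targets: tuple[int, ...]
    mode: str            # clamp | injection
    level: float         # nM (clamp) or molecules/s per target (injection)
    onset: float
    duration: float
    gap: float = 0.0
    count: int = 1

    def __post_init__(self):
        if self.mode not in ("clamp", "injection"):
            raise ValueError(f"bad stimulus mode {self.mode!r}")
        if self.count > 1 and self.gap < 0:
            raise ValueError("overlapping pulses")
        if self.duration <= 0 and self.count > 0:
            raise ValueError("pulse duration must be positive")

    def windows(self) -> list[tuple[float, float]]:
        period = self.duration + self.gap
        return [(self.onset + i * period, self.onset + i * period + self.duration)
                for i in range(self.count)]

    def boundaries(self) -> list[float]:
        out = []
        for t0, t1 in self.windows():
            out += [t0, t1]
        return out

    def active_at(self, t: float) -> bool:
        period = self.duration + self.gap
        if self.count == 0 or t < self.onset:
            return False
        rel = t - self.onset
        i = int(rel // period)
        return i < self.count and (rel - i * period) < self.duration

    @property
    def end(self) -> float:
        if self.count == 0:
            return self.onset
        return self.windows()[-1][1]


def bath_clamp(mesh: Mesh, species: str, level_nM: float,
               onset: float = DEFAULT_STIM_ONSET, duration: float = 1e9) -> StimulusTrain:
    """Clamp a species uniformly over the whole morphology (bath application)."""
    if level_nM < 0:
        raise ValueError("clamp level must be >= 0")
    return StimulusTrain(species=species, targets=tuple(range(mesh.n_subvolumes)),
                         mode="clamp", level=level_nM, onset=onset, duration=duration)


def calcium_tetanus(mesh: Mesh, spine_ids: tuple[int, int] | None = None,
                    onset: float = DEFAULT_STIM_ONSET,
                    pulses: int = CA_PULSES) -> StimulusTrain:
    """100 Hz calcium influx train into the PSDs of two spines.

    125 molecules/ms for 3 ms per pulse, 10 ms between pulses, 100 pulses:
    37,500 molecules per stimulated spine over ~1.3 s.
    """
    if spine_ids is None:
        n = len(mesh.spines)
        spine_ids = (n // 2 - 1, n // 2)  # the two central spines
    if len(spine_ids) != 2:
        raise ValueError("calcium tetanus targets exactly two spines")
    for s in spine_ids:
        if s not in mesh.spines:
            raise ValueError(f"spine {s} not in mesh")
    targets = tuple(mesh.spines[s]["psd"] for s in spine_ids)
    return StimulusTrain(species="Ca", targets=targets, mode="injection",
                         level=CA_RATE_PER_MS * 1000.0, onset=onset,
                         duration=CA_PULSE_S, gap=CA_PULSE_GAP_S, count=pulses)


def _dopamine_release_rate(network: ReactionNetwork, mesh: Mesh,
                           targets: list[int], dopamine_D: float,
                           peak_nM: float) -> float:
    """Release rate (molecules/s per target) giving `peak_nM` at the site.

    Free dopamine dynamics are linear (diffusion + first-order export to the
    extracellular reservoir), so the quasi-steady concentration during a pulse
    is proportional to the release rate; one sparse solve calibrates it.
    """
    volumes = mesh.volumes()
    n = mesh.n_subvolumes
    k_export = None
    for e in network.elementary:
        if e.tag == "da_ext.f":
            k_export = e.k
    if k_export is None:
        raise ValueError("network lacks the dopamine export reaction")
    A = sp.lil_matrix((n, n))
    for c in mesh.couplings:
        kab = geometry.hop_rate(dopamine_D, c.area, c.distance, volumes[c.a])
        kba = geometry.hop_rate(dopamine_D, c.area, c.distance, volumes[c.b])
        A[c.a, c.a] -= kab
        A[c.b, c.a] += kab
        A[c.b, c.b] -= kba
        A[c.a, c.b] += kba
    A = A.tocsc() - k_export * sp.identity(n, format="csc")
    r = np.zeros(n)
    r[targets] = 1.0  # unit rate per target
    n_ss = spla.spsolve(A, -r)
    peak_per_unit = float(np.max(n_ss[targets] / (volumes[targets] * _F)))
    return peak_nM / peak_per_unit


def dopamine_phasic(mesh: Mesh, config: SpatialConfig,
                    network: ReactionNetwork | None = None,
                    onset: float = DEFAULT_STIM_ONSET,
                    pulses: int = DOPAMINE_PULSES) -> StimulusTrain:
    """Phasic dopamine: five 1 s, 1 uM elevations, 20 s apart.

    Volume-transmission mode (dopamine_D = 150): a uniform clamp at 1 uM.
    Gradient mode (dopamine_D = 50): point release at the PSD of the first
    spine, with the release rate calibrated so the concentration at the
    release site itself still peaks at 1 uM.
    """
    if config.dopamine_D == 150.0:
        return StimulusTrain(species="Da", targets=tuple(range(mesh.n_subvolumes)),
                             mode="clamp", level=DOPAMINE_PULSE_NM, onset=onset,
                             duration=DOPAMINE_PULSE_S, gap=DOPAMINE_PULSE_GAP_S,
                             count=pulses)
    if network is None:
        raise ValueError("gradient-mode dopamine release needs the network "
                         "(export rate) for calibration")
    targets = [mesh.spines[0]["psd"]]
    rate = _dopamine_release_rate(network, mesh, targets, config.dopamine_D,
                                  DOPAMINE_PULSE_NM)
    return StimulusTrain(species="Da", targets=tuple(targets), mode="injection",
                         level=rate, onset=onset, duration=DOPAMINE_PULSE_S,
                         gap=DOPAMINE_PULSE_GAP_S, count=pulses)
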