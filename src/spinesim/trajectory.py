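"""Recorded time series of region-aggregated concentrations.

Both engines emit the same container, so every metric downstream is engine
agnostic. Data are nM, organized time x region x species; a region is any
named set of subvolumes (anatomical compartments by default, axial slices for
gradient profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .geometry import Mesh

__all__ = ["Trajectory", "default_regions", "axial_regions", "region_matrix"]


def default_regions(mesh: Mesh) -> dict[str, list[int]]:
    """Anatomical recording regions for a spiny-dendrite mesh."""
    regions = {
        "all": list(range(mesh.n_subvolumes)),
        "dendrite": mesh.dendrite_ids(),
        "submembrane": mesh.submembrane_ids(),
        "cytosol": mesh.region_ids(geometry.DEND_CYT),
        "focal": mesh.region_ids(geometry.FOCAL),
        "spineheads": [i for s in mesh.spines
                       for i in mesh.spine_head_ids(s, include_psd=False)],
        "psd": mesh.region_ids(geometry.PSD),
    }
    for s in sorted(mesh.spines):
        regions[f"spine{s}_head"] = mesh.spine_head_ids(s, include_psd=False)
        regions[f"spine{s}_psd"] = [mesh.spines[s]["psd"]]
    return {k: v for k, v in regions.items() if v}


def axial_regions(mesh: Mesh) -> tuple[dict[str, list[int]], np.ndarray]:
    """One region per dendritic axial slice; returns (regions, x positions)."""
    xs = sorted({sv.x for sv in mesh.subvolumes
                 if sv.region in (geometry.DEND_CYT, geometry.DEND_SUB, geometry.FOCAL)})
    regions = {}
    for x in xs:
        ids = [sv.id for sv in mesh.subvolumes
               if sv.region in (geometry.DEND_CYT, geometry.DEND_SUB, geometry.FOCAL)
               and np.isclose(sv.x, x)]
        regions[f"x={x:.4f}"] = ids
    return regions, np.array(xs)


def region_matrix(mesh: Mesh, regions: dict[str, list[int]]) -> np.ndarray:
    """0/1 membership matrix (n_region, n_subvolumes)."""
    M = np.zeros((len(regions), mesh.n_subvolumes))
    for r, ids in enumerate(regions.values()):
        M[r, ids] = 1.0
    return M


@dataclass
class Trajectory:
    times: np.ndarray          # (n_t,) s
    data: np.ndarray           # (n_t, n_region, n_species) nM
    regions: list[str]
    species: list[str]
    region_volumes: np.ndarray  # (n_region,) um^3
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._region_idx = {r: i for i, r in enumerate(self.regions)}
        self._species_idx = {s: i for i, s in enumerate(self.species)}

    def conc(self, species: str, region: str = "all") -> np.ndarray:
        return self.data[:, self._region_idx[region], self._species_idx[species]]

    def group_conc(self, weights: dict[str, float], region: str = "all") -> np.ndarray:
        out = np.zeros(len(self.times))
        for name, w in weights.items():
            out += w * self.conc(name, region)
        return out

    def region_index(self, region: str) -> int:
        return self._region_idx[region]

    # -- I/O ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n_t, n_r, n_s = self.data.shape
        idx = pd.MultiIndex.from_product([self.times, self.regions],
                                         names=["time", "region"])
        return pd.DataFrame(self.data.reshape(n_t * n_r, n_s), index=idx,
                            columns=self.species)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, region_volumes=None, meta=None) -> "Trajectory":
        times = df.index.get_level_values("time").unique().to_numpy(dtype=float)
        regions = list(df.index.get_level_values("region").unique())
        species = list(df.columns)
        data = df.to_numpy().reshape(len(times), len(regions), len(species))
        return cls(times=times, data=data, regions=regions, species=species,
                   region_volumes=(np.asarray(region_volumes)
                                   if region_volumes is not None
                                   else np.full(len(regions), np.nan)),
                   meta=meta or {})

    @classmethod
    def load_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path, index_col=[0, 1])
        df.index.names = ["time", "region"]
        return cls.from_frame(df)
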