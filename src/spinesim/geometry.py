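"""Subvolume meshes for spiny dendrites.

The reference morphology is a rectangular-cuboid dendrite carrying cylindrical
spines. The short mesh is a 7.75 um dendrite (0.6 um wide x 0.4 um deep) cut
into 310 cuboids of 0.12 x 0.125 x 0.4 um^3 (62 axial slices x 5 width lanes;
the two outer lanes are the submembrane shell, which reproduces the
submembrane:cytosol ratio of a cylinder with a 70 nm shell) with four spines.
The long mesh is a ~23 um dendrite of 342 cuboids (0.2 x 0.2 x 0.4 um^3, a
3 x 2 cross-section x 57 axial slices) with twelve spines at ~1/um density.

Each spine is a stack of 0.1 um cylindrical slices: three neck slices (0.2 um
diameter), two head slices and one PSD slice (0.6 um diameter). Diffusion is
two-dimensional in the dendrite sheet and one-dimensional up the spine.

Both builders accept a ``desk`` preset producing an axially coarsened variant
of the same morphology (identical total volumes and region structure, fewer
subvolumes) for desktop-scale deterministic and stochastic runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Subvolume",
    "Coupling",
    "Mesh",
    "build_short_dendrite",
    "build_long_dendrite",
    "hop_rate",
]

# region tags
DEND_CYT = "dendrite-cytosol"
DEND_SUB = "dendrite-submembrane"
FOCAL = "focal-dendrite-submembrane"
NECK = "spine-neck"
HEAD = "spine-head"
PSD = "PSD"

SPINE_HEAD_DIAMETER = 0.6
SPINE_NECK_DIAMETER = 0.2
SLICE = 0.1  # spine slice height, um

_HEAD_AREA = math.pi * (SPINE_HEAD_DIAMETER / 2) ** 2
_NECK_AREA = math.pi * (SPINE_NECK_DIAMETER / 2) ** 2


def hop_rate(D: float, area: float, distance: float, source_volume: float) -> float:
    """Per-molecule diffusive hop propensity (s^-1) across a coupling.

    Finite-volume coupling k = D*A/(V*d); detailed balance k_ab*V_a = k_ba*V_b
    holds by construction.
    """
    if D < 0 or area <= 0 or distance <= 0 or source_volume <= 0:
        raise ValueError("need D >= 0 and positive area, distance, volume")
    return D * area / (source_volume * distance)


@dataclass(frozen=True)
class Subvolume:
    id: int
    region: str
    volume: float  # um^3
    x: float  # axial position, um from the stimulated end


@dataclass(frozen=True)
class Coupling:
    a: int
    b: int
    area: float  # um^2
    distance: float  # um, center-to-center


@dataclass
class Mesh:
    """Subvolume list + diffusion couplings + spine registry."""

    subvolumes: list[Subvolume]
    couplings: list[Coupling]
    # spine id -> {"neck": [...], "head": [...], "psd": int, "base": int, "x": float}
    spines: dict[int, dict] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        ids = [sv.id for sv in self.subvolumes]
        if ids != list(range(len(ids))):
            raise ValueError("subvolume ids must be 0..n-1 in order")
        for c in self.couplings:
            if c.a == c.b:
                raise ValueError("self-coupling")

    # -- lookups ------------------------------------------------------------
    @property
    def n_subvolumes(self) -> int:
        return len(self.subvolumes)

    def volumes(self) -> np.ndarray:
        return np.array([sv.volume for sv in self.subvolumes])

    def positions(self) -> np.ndarray:
        return np.array([sv.x for sv in self.subvolumes])

    def region_ids(self, *regions: str) -> list[int]:
        want = set(regions)
        return [sv.id for sv in self.subvolumes if sv.region in want]

    def region_volume(self, *regions: str) -> float:
        return float(sum(sv.volume for sv in self.subvolumes if sv.region in set(regions)))

    def total_volume(self) -> float:
        return float(sum(sv.volume for sv in self.subvolumes))

    def spine_head_ids(self, spine: int, include_psd: bool = False) -> list[int]:
        entry = self.spines[spine]
        ids = list(entry["head"])
        if include_psd and entry["psd"] not in ids:
            ids.append(entry["psd"])
        return ids

    def dendrite_ids(self) -> list[int]:
        return self.region_ids(DEND_CYT, DEND_SUB, FOCAL)

    def submembrane_ids(self) -> list[int]:
        return self.region_ids(DEND_SUB, FOCAL)

    def membrane_ids(self) -> list[int]:
        """Subvolumes adjacent to plasma membrane (pumps live here).

        Meshes whose dendrite is not subdivided into submembrane/cytosol lanes
        (the long gradient mesh) treat every subvolume as membrane-adjacent.
        """
        spine_ids = [sv.id for sv in self.subvolumes
                     if sv.region in (NECK, HEAD, PSD)]
        if not self.region_ids(DEND_SUB):
            return list(range(self.n_subvolumes))
        return self.submembrane_ids() + spine_ids

    def adjacency(self) -> dict[int, list[Coupling]]:
        adj: dict[int, list[Coupling]] = {i: [] for i in range(self.n_subvolumes)}
        for c in self.couplings:
            adj[c.a].append(c)
            adj[c.b].append(c)
        return adj

    def is_connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for c in adj[i]:
                j = c.b if c.a == i else c.a
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_subvolumes

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "subvolumes": [[int(sv.id), sv.region, float(sv.volume), float(sv.x)]
                           for sv in self.subvolumes],
            "couplings": [[int(c.a), int(c.b), float(c.area), float(c.distance)]
                          for c in self.couplings],
            "spines": {
                str(k): {
                    "neck": [int(i) for i in v["neck"]],
                    "head": [int(i) for i in v["head"]],
                    "psd": int(v["psd"]),
                    "base": int(v["base"]),
                    "x": float(v["x"]),
                    "focal": [int(i) for i in v.get("focal", [])],
                }
                for k, v in self.spines.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Mesh":
        payload = json.loads(text)
        return cls(
            subvolumes=[Subvolume(i, r, v, x) for i, r, v, x in payload["subvolumes"]],
            couplings=[Coupling(a, b, ar, d) for a, b, ar, d in payload["couplings"]],
            spines={int(k): v for k, v in payload["spines"].items()},
            name=payload.get("name", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Mesh":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _attach_spine(subvolumes, couplings, spines, spine_id, base_id, neck_length,
                  x, base_half_thickness):
    """Stack neck/head/PSD slices onto a dendrite subvolume."""
    n_neck = int(round(neck_length / SLICE))
    neck_vol = _NECK_AREA * SLICE
    head_vol = _HEAD_AREA * SLICE
    entry = {"neck": [], "head": [], "psd": None, "base": base_id, "x": x}
    prev = base_id
    prev_half = base_half_thickness
    for _ in range(n_neck):
        sid = len(subvolumes)
        subvolumes.append(Subvolume(sid, NECK, neck_vol, x))
        couplings.append(Coupling(prev, sid, _NECK_AREA, prev_half + SLICE / 2))
        entry["neck"].append(sid)
        prev, prev_half = sid, SLICE / 2
    for j in range(2):
        sid = len(subvolumes)
        subvolumes.append(Subvolume(sid, HEAD, head_vol, x))
        # the junction between neck and head is constricted to the neck bore;
        # with no neck the head sits directly on the dendrite over its full base
        if entry["neck"] or j == 1:
            area = _HEAD_AREA if j == 1 else _NECK_AREA
        else:
            area = _HEAD_AREA
        couplings.append(Coupling(prev, sid, area, prev_half + SLICE / 2))
        entry["head"].append(sid)
        prev, prev_half = sid, SLICE / 2
    sid = len(subvolumes)
    subvolumes.append(Subvolume(sid, PSD, head_vol, x))
    couplings.append(Coupling(prev, sid, _HEAD_AREA, SLICE))
    entry["psd"] = sid
    spines[spine_id] = entry


def build_short_dendrite(neck_length: float = 0.3, preset: str = "paper",
                         n_spines: int = 4) -> Mesh:
    """The 7.75 um four-spine mesh (neck length 0, 0.3 or 1.0 um).

    ``preset="paper"``: 62 axial slices x 5 lanes = 310 dendrite cuboids of
    0.12 x 0.125 x 0.4 um^3. ``preset="desk"``: 31 slices x 3 lanes (outer
    lanes remain the 0.12 um submembrane shell), same dendrite volume.
    """
    if not any(math.isclose(neck_length, v) for v in (0.0, 0.3, 1.0)):
        raise ValueError(f"unsupported neck length {neck_length} (use 0, 0.3 or 1.0 um)")
    length, depth = 7.75, 0.4
    if preset == "paper":
        nx = 62
        lane_w = [0.12, 0.12, 0.12, 0.12, 0.12]
        sub_lanes = {0, 4}
    elif preset == "desk":
        nx = 31
        lane_w = [0.12, 0.36, 0.12]
        sub_lanes = {0, 2}
    else:
        raise ValueError(f"unknown preset {preset!r}")
    dx = length / nx
    n_lanes = len(lane_w)

    subvolumes: list[Subvolume] = []
    couplings: list[Coupling] = []
    grid = np.empty((nx, n_lanes), dtype=int)
    for ix in range(nx):
        for il in range(n_lanes):
            sid = len(subvolumes)
            region = DEND_SUB if il in sub_lanes else DEND_CYT
            subvolumes.append(Subvolume(sid, region, lane_w[il] * dx * depth,
                                        (ix + 0.5) * dx))
            grid[ix, il] = sid
    for ix in range(nx):
        for il in range(n_lanes):
            if ix + 1 < nx:  # axial coupling
                couplings.append(Coupling(grid[ix, il], grid[ix + 1, il],
                                          lane_w[il] * depth, dx))
            if il + 1 < n_lanes:  # lateral coupling
                couplings.append(Coupling(grid[ix, il], grid[ix, il + 1],
                                          dx * depth,
                                          (lane_w[il] + lane_w[il + 1]) / 2))

    spines: dict[int, dict] = {}
    for s in range(n_spines):
        x = (s + 0.5) * length / n_spines
        ix = min(int(x / dx), nx - 1)
        _attach_spine(subvolumes, couplings, spines, s, grid[ix, 0],
                      neck_length, x, lane_w[0] / 2)

    # focal dendritic submembrane areas: one contiguous block of top-lane
    # submembrane subvolumes beneath EACH spine, each block with the volume of
    # one spine head. Dendritic anchoring puts each spine's quota of the
    # anchored pools into its own block, which keeps both the local and the
    # global concentrations of the anchored molecules identical across all
    # anchoring configurations.
    head_vol = 2 * _HEAD_AREA * SLICE
    lane_vol = lane_w[0] * dx * depth
    n_focal = max(1, round(head_vol / lane_vol))
    for s, entry in spines.items():
        center_ix = min(int(entry["x"] / dx), nx - 1)
        start = max(0, min(center_ix - n_focal // 2, nx - n_focal))
        ids = [int(grid[ix, 0]) for ix in range(start, start + n_focal)]
        entry["focal"] = ids
        for sid in ids:
            sv = subvolumes[sid]
            subvolumes[sid] = Subvolume(sv.id, FOCAL, sv.volume, sv.x)

    return Mesh(subvolumes, couplings, spines,
                name=f"short-{preset}-neck{neck_length}")


def build_mini_dendrite(n_spines: int = 2, length: float = 4.0, nx: int = 8) -> Mesh:
    """A reduced two-spine mesh for ensemble stochastic runs.

    The dendrite is a single-lane chain (0.6 x 0.4 um^2 cross-section) and each
    spine collapses to one neck subvolume plus one head subvolume that includes
    the PSD volume. Diffusion couplings are gentle enough for ~40 us leap steps,
    so many-trial ensembles (the colocalization regression) stay desk-sized.
    Region totals follow the standard initializer; with no separate PSD
    subvolume, receptor and PKA pools occupy the merged head.
    """
    width, depth = 0.6, 0.4
    dx = length / nx
    subvolumes = [Subvolume(i, DEND_CYT, width * depth * dx, (i + 0.5) * dx)
                  for i in range(nx)]
    couplings = [Coupling(i, i + 1, width * depth, dx) for i in range(nx - 1)]
    spines: dict[int, dict] = {}
    neck_vol = _NECK_AREA * 0.3
    head_vol = 3 * _HEAD_AREA * SLICE  # two head slices + PSD slice
    for s in range(n_spines):
        x = (s + 0.5) * length / n_spines
        ix = min(int(x / dx), nx - 1)
        neck_id = len(subvolumes)
        subvolumes.append(Subvolume(neck_id, NECK, neck_vol, x))
        couplings.append(Coupling(ix, neck_id, _NECK_AREA, depth / 2 + 0.15))
        head_id = len(subvolumes)
        subvolumes.append(Subvolume(head_id, HEAD, head_vol, x))
        couplings.append(Coupling(neck_id, head_id, _NECK_AREA, 0.15 + 0.15))
        spines[s] = {"neck": [neck_id], "head": [head_id], "psd": head_id,
                     "base": ix, "x": x, "focal": [ix]}
    # focal areas: the dendritic subvolume under each spine
    for entry in spines.values():
        fid = entry["base"]
        sv = subvolumes[fid]
        subvolumes[fid] = Subvolume(fid, FOCAL, sv.volume, sv.x)
    return Mesh(subvolumes, couplings, spines, name="mini")


def build_long_dendrite(preset: str = "paper", n_spines: int = 12) -> Mesh:
    """The ~23 um twelve-spine mesh used for microdomain/gradient runs.

    ``preset="paper"``: 57 axial slices x (3 wide x 2 deep) = 342 cuboids of
    0.2 x 0.2 x 0.4 um^3. ``preset="desk"``: the cross-section collapsed to a
    single 0.6 x 0.4 um^2 lane (57 axial subvolumes), preserving axial
    diffusion and total volume. No pools anchor in this dendrite, so no
    submembrane lanes are distinguished.
    """
    nx, dx, width, depth = 57, 0.4, 0.6, 0.4
    subvolumes: list[Subvolume] = []
    couplings: list[Coupling] = []
    if preset == "paper":
        nw, nd = 3, 2
        cw, cd = width / nw, depth / nd
        grid = np.empty((nx, nw, nd), dtype=int)
        for ix in range(nx):
            for iw in range(nw):
                for idp in range(nd):
                    sid = len(subvolumes)
                    subvolumes.append(Subvolume(sid, DEND_CYT, cw * cd * dx,
                                                (ix + 0.5) * dx))
                    grid[ix, iw, idp] = sid
        for ix in range(nx):
            for iw in range(nw):
                for idp in range(nd):
                    if ix + 1 < nx:
                        couplings.append(Coupling(grid[ix, iw, idp], grid[ix + 1, iw, idp],
                                                  cw * cd, dx))
                    if iw + 1 < nw:
                        couplings.append(Coupling(grid[ix, iw, idp], grid[ix, iw + 1, idp],
                                                  cd * dx, cw))
                    if idp + 1 < nd:
                        couplings.append(Coupling(grid[ix, iw, idp], grid[ix, iw, idp + 1],
                                                  cw * dx, cd))
        base_of = lambda ix: int(grid[ix, 1, 0])  # noqa: E731
        base_half = cd / 2
    elif preset == "desk":
        for ix in range(nx):
            subvolumes.append(Subvolume(ix, DEND_CYT, width * depth * dx,
                                        (ix + 0.5) * dx))
        for ix in range(nx - 1):
            couplings.append(Coupling(ix, ix + 1, width * depth, dx))
        base_of = lambda ix: ix  # noqa: E731
        base_half = depth / 2
    else:
        raise ValueError(f"unknown preset {preset!r}")

    spines: dict[int, dict] = {}
    length = nx * dx
    for s in range(n_spines):
        x = (s + 0.5) * length / n_spines
        ix = min(int(x / dx), nx - 1)
        _attach_spine(subvolumes, couplings, spines, s, base_of(ix), 0.3, x, base_half)
    return Mesh(subvolumes, couplings, spines, name=f"long-{preset}")
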