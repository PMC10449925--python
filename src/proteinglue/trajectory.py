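"""Interface-adhesion metrics for tagged coordinate trajectories.

Implements the desk-scale analysis quantities used to characterise how an
unfolded protein chain displaces the hydration layer and anchors to a
substrate: per-residue initial contact time against a surface (minimum
residue-surface distance < 0.35 nm, the diameter of a water molecule),
binned surface-water occupancy (water oxygens within 0.35 nm above the
surface plane), radius of gyration, Shrake-Rupley solvent-accessible surface
area, geometric hydrogen-bond counts, residue hydrophobicity indexing, and
the lap-shear strength readout tau = F / A.

Trajectories are multi-frame XYZ files (comment line carries ``time=`` in ns
and ``box=`` in nm) with a sidecar roster CSV mapping each atom to a residue
and a group tag (``protein`` / ``water`` / ``surface``).  Coordinates are in
nm; frames are assumed whole (no periodic wrapping) unless an orthorhombic
minimum-image box is requested explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._resources import (
    AVOGADRO,
    FULL_NAME_TO_ONE,
    THREE_TO_ONE,
    residue_scale,
    vdw_radii,
)

CONTACT_CUTOFF = 0.35  # nm, strict less-than
SURFACE_WATER_CUTOFF = 0.35  # nm above the surface plane
GROUPS = ("protein", "water", "surface")


@dataclass
class TrajectoryFrame:
    """One timestamped frame of tagged atoms (positions in nm, time in ns)."""

    time: float
    atom_ids: np.ndarray     # int
    atom_names: np.ndarray   # str
    residue_ids: np.ndarray  # int
    residue_names: np.ndarray
    groups: np.ndarray       # in GROUPS
    xyz: np.ndarray          # (n, 3) nm
    masses: np.ndarray       # u
    box: np.ndarray          # (3,) nm

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group tags {sorted(bad)}")
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("duplicate atom ids within a frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def select(
        self,
        group: str | None = None,
        residue_id: int | Iterable[int] | None = None,
    ) -> np.ndarray:
        """Index array of atoms matching the group and/or residue filter."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if group is not None:
            mask &= self.groups == group
        if residue_id is not None:
            rids = (
                {int(residue_id)}
                if np.isscalar(residue_id)
                else set(int(r) for r in residue_id)
            )
            mask &= np.isin(self.residue_ids, list(rids))
        return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# trajectory I/O: multi-frame XYZ + roster sidecar

def write_trajectory(
    frames: Sequence[TrajectoryFrame], xyz_path: str | Path, roster_path: str | Path
) -> None:
    f0 = frames[0]
    roster = pd.DataFrame(
        {
            "atom_id": f0.atom_ids,
            "atom_name": f0.atom_names,
            "residue_id": f0.residue_ids,
            "residue_name": f0.residue_names,
            "group": f0.groups,
            "mass": f0.masses,
        }
    )
    roster.to_csv(roster_path, index=False)
    with open(xyz_path, "w") as fh:
        for fr in frames:
            if not np.array_equal(fr.atom_ids, f0.atom_ids):
                raise ValueError("frames do not share the atom roster")
            fh.write(f"{fr.n_atoms}\n")
            bx = ",".join(f"{b:.6f}" for b in fr.box)
            fh.write(f"time={fr.time:.6f} box={bx}\n")
            for name, pos in zip(fr.atom_names, fr.xyz):
                fh.write(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n")


def read_trajectory(
    xyz_path: str | Path, roster_path: str | Path
) -> list[TrajectoryFrame]:
    roster = pd.read_csv(roster_path)
    atom_ids = roster["atom_id"].to_numpy(int)
    frames: list[TrajectoryFrame] = []
    with open(xyz_path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = dict(item.split("=", 1) for item in lines[i + 1].split())
        time = float(meta["time"])
        box = np.array([float(v) for v in meta["box"].split(",")])
        xyz = np.empty((n, 3))
        names = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            names.append(parts[0])
            xyz[j] = [float(p) for p in parts[1:4]]
        if len(names) != len(roster):
            raise ValueError("frame atom count disagrees with roster")
        frames.append(
            TrajectoryFrame(
                time=time,
                atom_ids=atom_ids,
                atom_names=np.asarray(names),
                residue_ids=roster["residue_id"].to_numpy(int),
                residue_names=roster["residue_name"].to_numpy(str),
                groups=roster["group"].to_numpy(str),
                xyz=xyz,
                masses=roster["mass"].to_numpy(float),
                box=box,
            )
        )
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# metrics

def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return cdist(a, b)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=-1))


def radius_of_gyration(frame: TrajectoryFrame, selection: np.ndarray) -> float:
    """Mass-weighted RMS distance from the selection's centre of mass (nm)."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    m = frame.masses[selection]
    if np.any(m <= 0):
        raise ValueError("non-positive masses in selection")
    x = frame.xyz[selection]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    sq = ((x - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def initial_contact_time(
    frames: Sequence[TrajectoryFrame],
    residue_id: int,
    surface_group: str = "surface",
    threshold: float = CONTACT_CUTOFF,
    minimum_image: bool = False,
) -> float | None:
    """Time (ns) of the first frame where min residue-surface distance < threshold.

    Returns None ("never") if no frame qualifies.
    """
    f0 = frames[0]
    res_idx = f0.select(group="protein", residue_id=residue_id)
    if len(res_idx) == 0:
        raise ValueError(f"unknown protein residue_id {residue_id}")
    surf_idx = f0.select(group=surface_group)
    if len(surf_idx) == 0:
        raise ValueError(f"no atoms in surface group {surface_group!r}")
    for fr in frames:
        box = fr.box if minimum_image else None
        d = _pair_distances(fr.xyz[res_idx], fr.xyz[surf_idx], box)
        if d.min() < threshold:
            return fr.time
    return None


def contact_report(
    frames: Sequence[TrajectoryFrame],
    surface_group: str = "surface",
    threshold: float = CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Per-residue initial contact time for every protein residue.

    Columns: residue_id, residue_name, contact_time_ns (NaN = never),
    hydrophobicity (Kyte-Doolittle index of the residue).
    """
    f0 = frames[0]
    prot = f0.select(group="protein")
    rows = []
    for rid in np.unique(f0.residue_ids[prot]):
        t = initial_contact_time(frames, int(rid), surface_group, threshold)
        rname = f0.residue_names[prot][f0.residue_ids[prot] == rid][0]
        try:
            hydro = hydrophobicity_index(str(rname))
        except KeyError:
            hydro = math.nan
        rows.append(
            {
                "residue_id": int(rid),
                "residue_name": str(rname),
                "contact_time_ns": math.nan if t is None else t,
                "hydrophobicity": hydro,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SurfaceWaterMap:
    """Binned counts of water oxygens hugging the surface."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray  # (nx, ny) int
    total: int
    height_cutoff: float


def surface_water_occupancy(
    frame: TrajectoryFrame,
    height_cutoff: float = SURFACE_WATER_CUTOFF,
    bin_size: float = 0.25,
    axis: int = 2,
    surface_group: str = "surface",
) -> SurfaceWaterMap:
    """Count water oxygens within ``height_cutoff`` above the surface plane.

    The surface plane is the maximal surface-atom coordinate along ``axis``;
    heights are measured from it and waters in [0, cutoff) are counted into
    a 2D grid over the two in-plane axes.  Zero-count bins mark dry
    (depleted) patches.
    """
    surf = frame.select(group=surface_group)
    if len(surf) == 0:
        raise ValueError("no surface atoms")
    waters = frame.select(group="water")
    oxy = waters[np.char.startswith(frame.atom_names[waters].astype(str), "O")]
    if len(oxy) == 0:
        raise ValueError("no water oxygen atoms")
    z0 = frame.xyz[surf, axis].max()
    height = frame.xyz[oxy, axis] - z0
    keep = (height >= 0.0) & (height < height_cutoff)
    in_plane = [i for i in range(3) if i != axis]
    u = frame.xyz[oxy[keep], in_plane[0]]
    v = frame.xyz[oxy[keep], in_plane[1]]
    lu, lv = frame.box[in_plane[0]], frame.box[in_plane[1]]
    edges_u = np.arange(0.0, lu + bin_size, bin_size)
    edges_v = np.arange(0.0, lv + bin_size, bin_size)
    counts, _, _ = np.histogram2d(u, v, bins=[edges_u, edges_v])
    counts = counts.astype(int)
    return SurfaceWaterMap(
        edges_x=edges_u,
        edges_y=edges_v,
        counts=counts,
        total=int(counts.sum()),
        height_cutoff=height_cutoff,
    )


def hydrogen_bond_count(
    frame: TrajectoryFrame,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    minimum_image: bool = False,
) -> int:
    """Geometric hydrogen-bond count.

    ``donors`` are (donor_heavy_atom_index, bonded_hydrogen_index) pairs;
    ``acceptors`` are heavy-atom indices.  A pair counts when the
    donor-acceptor distance is <= d_cut and the angle at the donor between
    the D->H and D->A directions is <= angle_cut degrees.
    """
    acceptors = np.asarray(acceptors, dtype=int)
    box = frame.box if minimum_image else None
    count = 0
    for d_idx, h_idx in donors:
        if h_idx < 0 or h_idx >= frame.n_atoms:
            raise ValueError(f"donor {d_idx} has no valid hydrogen ({h_idx})")
        acc = acceptors[(acceptors != d_idx) & (acceptors != h_idx)]
        if len(acc) == 0:
            continue
        d_pos = frame.xyz[d_idx][None, :]
        dist = _pair_distances(d_pos, frame.xyz[acc], box)[0]
        dh = frame.xyz[h_idx] - frame.xyz[d_idx]
        if box is not None:
            dh -= box * np.round(dh / box)
        da = frame.xyz[acc] - frame.xyz[d_idx]
        if box is not None:
            da -= box * np.round(da / box)
        cosang = (da @ dh) / (np.linalg.norm(da, axis=1) * np.linalg.norm(dh) + 1e-300)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        count += int(np.sum((dist <= d_cut) & (ang <= angle_cut)))
    return count


def _element_of(atom_name: str) -> str:
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        raise KeyError(f"cannot infer element from atom name {atom_name!r}")
    radii = vdw_radii()
    two = stripped[:2].capitalize()
    if two in radii:
        return two
    one = stripped[0].upper()
    if one in radii:
        return one
    raise KeyError(f"no van der Waals radius for atom name {atom_name!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def sasa(
    frame: TrajectoryFrame,
    selection: np.ndarray,
    probe: float = 0.14,
    n_points: int = 256,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Points on a Fibonacci lattice are placed on each atom's solvent-expanded
    sphere (vdW radius + probe) and counted accessible when outside every
    other selected atom's expanded sphere.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    radii_tab = vdw_radii()
    radii = np.array(
        [radii_tab[_element_of(str(n))] for n in frame.atom_names[selection]]
    )
    xyz = frame.xyz[selection]
    expanded = radii + probe
    unit = _fibonacci_sphere(n_points)
    area = 0.0
    for i in range(len(selection)):
        pts = xyz[i] + expanded[i] * unit
        others = np.ones(len(selection), dtype=bool)
        others[i] = False
        # only neighbours that can possibly occlude
        close = others & (
            np.linalg.norm(xyz - xyz[i], axis=1) < expanded[i] + expanded.max()
        )
        if close.any():
            d = cdist(pts, xyz[close])
            accessible = np.all(d >= expanded[close][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        area += frac * 4.0 * np.pi * expanded[i] ** 2
    return float(area)


def hydrophobicity_index(residue_name: str, scale: str = "kyte-doolittle") -> float:
    """Scale value for a residue given by 1-letter, 3-letter or full name."""
    table = residue_scale(scale)
    key = residue_name.strip().upper()
    if len(key) == 1 and key in table:
        return table[key]
    if key in THREE_TO_ONE:
        return table[THREE_TO_ONE[key]]
    if key in FULL_NAME_TO_ONE:
        return table[FULL_NAME_TO_ONE[key]]
    raise KeyError(f"unknown residue name {residue_name!r}")


_FORCE_TO_N = {
    "N": 1.0,
    "kJ/mol/nm": 1.0e3 / AVOGADRO / 1.0e-9,
}
_AREA_TO_M2 = {
    "m^2": 1.0,
    "nm^2": 1.0e-18,
    "cm^2": 1.0e-4,
}


def shear_strength(
    F: tuple[float, str], A: tuple[float, str]
) -> float:
    """Lap-shear adhesion strength tau = F / A in Pa.

    Inputs are (value, unit) pairs; forces in N or kJ/mol/nm (molar forces
    are converted to newtons via Avogadro's number), areas in m^2, cm^2 or
    nm^2.  Units must be tagged explicitly -- no guessing.
    """
    f_val, f_unit = F
    a_val, a_unit = A
    if f_unit not in _FORCE_TO_N:
        raise ValueError(f"untagged/unknown force unit {f_unit!r}")
    if a_unit not in _AREA_TO_M2:
        raise ValueError(f"untagged/unknown area unit {a_unit!r}")
    if f_val < 0:
        raise ValueError("force must be non-negative")
    if a_val <= 0:
        raise ValueError("area must be positive")
    return (f_val * _FORCE_TO_N[f_unit]) / (a_val * _AREA_TO_M2[a_unit])
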