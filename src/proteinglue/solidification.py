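"""Two-phase Fickian curing model of a glue disk immersed in water.

Water diffuses from the rim into a thin glue layer sandwiched between two
plates.  The transport law is Fick's second law with a dichotomy on the local
state::

    dc/dt = D1 * lap(c)   where c <  Cc   (liquid glue)
    dc/dt = D2 * lap(c)   where c >= Cc   (solidified glue)

Any point whose water concentration reaches the critical value Cc
(38.9 mol/L, i.e. 70% water by volume) solidifies immediately and
irreversibly.  Because the outer rim meets water first, the solid phase grows
inward as a ring; the tracked observable is the ring width versus time.

The solver is a conservative finite-volume discretisation on a uniform 1D
grid, either axisymmetric-radial (the disk geometry; Dirichlet rim,
zero-flux centre) or planar (a half-space proxy used for validation against
the closed-form single-diffusivity erf solution).  Time stepping is explicit
with an automatically chosen stable step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import erf, erfinv

from ._resources import WATER_MOLARITY

CRITICAL_CONCENTRATION = 38.9  # mol/L


class StabilityError(RuntimeError):
    """Requested time step violates the explicit stability bound."""


@dataclass(frozen=True)
class SolidificationConfig:
    """Physical and numerical parameters of a curing run.

    D1/D2 are the water diffusivities in liquid and solidified glue (m^2/s,
    solid faster than liquid: solidification opens water-filled pores);
    concentrations in mol/L; lengths in m; times in s.  ``radius`` is the
    half-width of the 6 mm disk.  ``c_init`` defaults to 20% water by volume
    (the 80%-stabilizer formulation); the rim is held at pure water.
    """

    D1: float = 1.0e-10
    D2: float = 5.0e-10
    Cc: float = CRITICAL_CONCENTRATION
    c_init: float = 11.1
    c_boundary: float = WATER_MOLARITY
    radius: float = 3.0e-3
    n_cells: int = 120
    t_end: float = 600.0
    output_every: float = 60.0
    geometry: Literal["radial", "planar"] = "radial"
    safety: float = 0.4

    def __post_init__(self):
        if self.D1 <= 0 or self.D2 <= 0:
            raise ValueError("diffusivities must be positive")
        if not (0.0 <= self.c_init < self.Cc <= self.c_boundary):
            raise ValueError("require 0 <= c_init < Cc <= c_boundary")
        if self.radius <= 0 or self.n_cells < 4:
            raise ValueError("radius must be positive and n_cells >= 4")
        if not 0 < self.safety < 1:
            raise ValueError("safety factor must lie in (0, 1)")

    @property
    def dr(self) -> float:
        return self.radius / self.n_cells

    @property
    def stable_dt(self) -> float:
        """Explicit stability bound: safety * dr^2 / (2 * max(D1, D2))."""
        return self.safety * self.dr**2 / (2.0 * max(self.D1, self.D2))


@dataclass
class ConcentrationField:
    """Cell-centred concentration plus the irreversible solid mask."""

    r: np.ndarray            # cell centres, m
    c: np.ndarray            # mol/L
    solid: np.ndarray        # bool, latches True
    time: float = 0.0
    boundary_influx: float = 0.0  # mol (per unit thickness) entering in the last step

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(
            self.r.copy(), self.c.copy(), self.solid.copy(), self.time,
            self.boundary_influx,
        )


@dataclass(frozen=True)
class FrontSeries:
    times: np.ndarray
    ring_width: np.ndarray


def initial_field(cfg: SolidificationConfig) -> ConcentrationField:
    r = (np.arange(cfg.n_cells) + 0.5) * cfg.dr
    c = np.full(cfg.n_cells, cfg.c_init, dtype=float)
    solid = c >= cfg.Cc
    return ConcentrationField(r=r, c=c, solid=solid)


def _cell_volumes(cfg: SolidificationConfig, r: np.ndarray) -> np.ndarray:
    # per-unit-thickness (radial) or per-unit-area (planar) cell volumes
    if cfg.geometry == "radial":
        return 2.0 * np.pi * r * cfg.dr
    return np.full_like(r, cfg.dr)


def step(
    field: ConcentrationField, cfg: SolidificationConfig, dt: float
) -> ConcentrationField:
    """One explicit conservative finite-volume update.

    Face diffusivities are harmonic means of the adjacent cells' phase
    diffusivities (flux continuity across the solid/liquid interface).  The
    Dirichlet boundary (rim for radial, x=0 for planar) acts over a half
    cell; the opposite boundary is zero-flux.  After the diffusion update the
    solid mask latches wherever c >= Cc.
    """
    if dt > cfg.stable_dt * (1.0 + 1e-12):
        raise StabilityError(
            f"dt={dt:.3e} s exceeds the stable step {cfg.stable_dt:.3e} s"
        )
    if not np.all(np.isfinite(field.c)):
        raise FloatingPointError("non-finite concentration encountered")

    n = cfg.n_cells
    dr = cfg.dr
    c = field.c
    D_cell = np.where(field.solid, cfg.D2, cfg.D1)
    # interior faces between cells i and i+1
    D_face = 2.0 * D_cell[:-1] * D_cell[1:] / (D_cell[:-1] + D_cell[1:])

    if cfg.geometry == "radial":
        r_face = np.arange(1, n) * dr          # interior face radii
        area_face = 2.0 * np.pi * r_face       # per unit thickness
        area_out = 2.0 * np.pi * cfg.radius
        dirichlet_last = True
    else:
        area_face = np.ones(n - 1)
        area_out = 1.0
        dirichlet_last = False

    flux = area_face * D_face * (c[1:] - c[:-1]) / dr  # mol/s toward lower i
    vol = _cell_volumes(cfg, field.r)
    dc = np.zeros(n)
    dc[:-1] += flux / vol[:-1]
    dc[1:] -= flux / vol[1:]

    if dirichlet_last:
        # rim held at c_boundary across a half cell
        f_b = area_out * D_cell[-1] * (cfg.c_boundary - c[-1]) / (dr / 2.0)
        dc[-1] += f_b / vol[-1]
    else:
        # planar: Dirichlet at the x=0 face, zero-flux at the far end
        f_b = 1.0 * D_cell[0] * (cfg.c_boundary - c[0]) / (dr / 2.0)
        dc[0] += f_b / vol[0]

    c_new = c + dt * dc
    if not np.all(np.isfinite(c_new)):
        raise FloatingPointError("diffusion step produced non-finite values")
    solid_new = field.solid | (c_new >= cfg.Cc)
    return ConcentrationField(
        r=field.r, c=c_new, solid=solid_new, time=field.time + dt,
        boundary_influx=f_b * dt,
    )


def total_mass(field: ConcentrationField, cfg: SolidificationConfig) -> float:
    """Water inventory of the domain (mol per unit thickness/area)."""
    return float(np.sum(field.c * _cell_volumes(cfg, field.r)))


def ring_width(field: ConcentrationField, cfg: SolidificationConfig) -> float:
    """Width of the contiguous solid layer attached to the wetted boundary.

    Radial: radius minus the innermost face of the solid ring touching the
    rim.  Planar: depth of the solid layer attached to x=0.  Zero when the
    wetted boundary cell is still liquid.
    """
    solid = field.solid
    dr = cfg.dr
    if cfg.geometry == "radial":
        if not solid[-1]:
            return 0.0
        j = len(solid) - 1
        while j > 0 and solid[j - 1]:
            j -= 1
        return cfg.radius - j * dr
    if not solid[0]:
        return 0.0
    j = 0
    while j < len(solid) - 1 and solid[j + 1]:
        j += 1
    return (j + 1) * dr


def front_position(field: ConcentrationField, cfg: SolidificationConfig) -> float:
    """Depth of the c = Cc level set from the wetted boundary (interpolated).

    Smooth (sub-cell) front tracker used for the sqrt(t) growth diagnostics;
    returns 0 before the boundary cell reaches Cc.
    """
    c = field.c
    dr = cfg.dr
    if cfg.geometry == "radial":
        prof = c[::-1]  # from rim inward
    else:
        prof = c
    if prof[0] < cfg.Cc:
        return 0.0
    below = np.nonzero(prof < cfg.Cc)[0]
    if len(below) == 0:
        return cfg.radius
    k = below[0]  # first cell (from the wetted side) still below Cc
    c_hi, c_lo = prof[k - 1], prof[k]
    frac = (c_hi - cfg.Cc) / (c_hi - c_lo)
    return (k - 0.5 + frac) * dr


def solve(
    cfg: SolidificationConfig,
) -> tuple[FrontSeries, list[ConcentrationField]]:
    """March the model to ``t_end``, snapshotting every ``output_every`` s."""
    if cfg.t_end <= 0:
        raise ValueError("t_end must be positive")
    field = initial_field(cfg)
    n_steps = int(np.ceil(cfg.t_end / cfg.stable_dt))
    dt = cfg.t_end / n_steps
    next_output = 0.0
    times: list[float] = []
    widths: list[float] = []
    snapshots: list[ConcentrationField] = []

    def record(f: ConcentrationField) -> None:
        times.append(f.time)
        widths.append(ring_width(f, cfg))
        snapshots.append(f.copy())

    record(field)
    next_output += cfg.output_every
    for _ in range(n_steps):
        field = step(field, cfg, dt)
        if field.time >= next_output - 1e-9 * cfg.t_end:
            record(field)
            next_output += cfg.output_every
    if times[-1] < field.time:
        record(field)
    return FrontSeries(np.asarray(times), np.asarray(widths)), snapshots


def analytic_reference_1d(
    D: float, c0: float, cb: float, x: np.ndarray | float, t: float
) -> np.ndarray | float:
    """Closed-form semi-infinite single-diffusivity solution.

    Fixed concentration ``cb`` at x = 0, uniform initial value ``c0``::

        c(x, t) = cb + (c0 - cb) * erf(x / (2 sqrt(D t)))

    Used as the validation oracle for the solver in planar mode with
    D1 = D2.
    """
    if t <= 0 or D <= 0:
        raise ValueError("require t > 0 and D > 0")
    if c0 == cb:
        raise ValueError("c0 = cb: front undefined")
    return cb + (c0 - cb) * erf(np.asarray(x) / (2.0 * np.sqrt(D * t)))


def analytic_front_position(D: float, c0: float, cb: float, Cc: float, t: float) -> float:
    """Level-set position of c = Cc for the erf solution: x_f = 2 sqrt(Dt) erfinv(.)"""
    if not min(c0, cb) <= Cc <= max(c0, cb):
        raise ValueError("Cc outside the (c0, cb) range: level set undefined")
    return 2.0 * np.sqrt(D * t) * float(erfinv((Cc - cb) / (c0 - cb)))
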