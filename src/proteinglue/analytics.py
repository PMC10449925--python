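"""Solution-state characterisation: SAXS Guinier/Kratky, viscometry, misc.

These are the analyses used to show that a stabilizer-unfolded protein is
really a swollen chain rather than a native globule, plus two small unit
formulas used elsewhere in the study (swelling ratio, Bragg d-spacing,
water volume-fraction -> molarity).

* Guinier regression: in the low-q regime ln I is linear in q^2 with slope
  -Rg^2/3; the fit is iterated and trimmed to q*Rg <= 1.3 (the standard
  Guinier-validity window).
* Kratky transform: I*q^2 vs q; compact globules produce an interior peak,
  unfolded chains a plateau.  The shape call is a declared heuristic.
* Viscometry: dilute-solution viscosity is fitted both by the Einstein hard-
  sphere law (relative viscosity eta/eta0 = 1 + 2.5 phi, phi = vbar * c, no
  free parameters) and by the Huggins chain law (eta_sp / c = [eta] +
  k_H [eta]^2 c, linear in c).  The better-fitting model classifies the
  solute as spherical (native) or chain-like (unfolded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from ._resources import WATER_MOLARITY

GUINIER_QRG_LIMIT = 1.3
PARTIAL_SPECIFIC_VOLUME = 0.73  # mL/g, typical globular protein


class CurveError(ValueError):
    """Malformed or unusable data series."""


@dataclass(frozen=True)
class ScatterCurve:
    """A scattering profile: q in 1/nm (strictly increasing), I > 0."""

    q: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if len(q) != len(I) or len(q) < 5:
            raise CurveError("q and I must have equal length >= 5")
        if np.any(np.diff(q) <= 0):
            raise CurveError("q must be strictly increasing")
        if np.any(I <= 0):
            raise CurveError("intensities must be positive")


@dataclass(frozen=True)
class GuinierFit:
    Rg: float           # nm
    I0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float


def guinier_fit(
    curve: ScatterCurve, qrg_limit: float = GUINIER_QRG_LIMIT
) -> GuinierFit:
    """Iterated Guinier regression ln I ~ q^2 restricted to q*Rg <= limit.

    Fits on all points, estimates Rg from the slope, trims to the validity
    window and refits until the retained point set stabilises.
    """
    q, I = curve.q, curve.I
    keep = np.ones(len(q), dtype=bool)
    for _ in range(50):
        if keep.sum() < 3:
            raise CurveError("fewer than 3 points inside the Guinier window")
        res = stats.linregress(q[keep] ** 2, np.log(I[keep]))
        if res.slope >= 0:
            raise CurveError("no Guinier decay: non-negative ln(I) ~ q^2 slope")
        rg = math.sqrt(-3.0 * res.slope)
        new_keep = q * rg <= qrg_limit
        if new_keep.sum() < 3:
            raise CurveError("fewer than 3 points inside the Guinier window")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return GuinierFit(
        Rg=rg,
        I0=float(np.exp(res.intercept)),
        q_min=float(q[keep].min()),
        q_max=float(q[keep].max()),
        n_points=int(keep.sum()),
        r_squared=float(res.rvalue**2),
    )


def kratky_transform(
    curve: ScatterCurve,
    peak_factor: float = 1.5,
    tail_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Return (q, I*q^2) and a shape flag.

    Flag is ``"peaked-globular"`` when the interior maximum of I*q^2 exceeds
    the mean of the high-q tail by ``peak_factor`` (a folded, compact
    particle), ``"plateau-unfolded"`` when the transform levels off without
    an interior peak, and ``"inconclusive"`` for degenerate tails.  The call
    mirrors the visual judgement usually applied to Kratky plots and is a
    heuristic, not a model fit.
    """
    y = curve.I * curve.q**2
    n = len(y)
    n_tail = max(2, int(round(tail_fraction * n)))
    tail_mean = float(y[-n_tail:].mean())
    if not np.isfinite(tail_mean) or tail_mean <= 0:
        return curve.q, y, "inconclusive"
    imax = int(np.argmax(y))
    interior = imax < n - n_tail
    if interior and y[imax] > peak_factor * tail_mean:
        return curve.q, y, "peaked-globular"
    return curve.q, y, "plateau-unfolded"


@dataclass(frozen=True)
class ViscositySeries:
    """Dilute-solution viscometry: c in g/mL, viscosities in mPa s."""

    concentration: np.ndarray
    viscosity: np.ndarray
    solvent_viscosity: float

    def __post_init__(self):
        c = np.asarray(self.concentration, dtype=float)
        v = np.asarray(self.viscosity, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "viscosity", v)
        if len(c) != len(v) or len(c) < 4:
            raise CurveError("need >= 4 (concentration, viscosity) points")
        if np.any(c <= 0) or np.any(v <= 0):
            raise CurveError("concentrations and viscosities must be positive")
        if self.solvent_viscosity <= 0:
            raise CurveError("solvent viscosity must be positive")


@dataclass(frozen=True)
class ShapeVerdict:
    r2_einstein: float
    r2_huggins: float
    verdict: Literal["spherical (native)", "chain-like (unfolded)", "inconclusive"]
    intrinsic_viscosity: float | None = None  # mL/g, Huggins [eta]
    huggins_constant: float | None = None


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def viscosity_model_select(
    series: ViscositySeries,
    vbar: float = PARTIAL_SPECIFIC_VOLUME,
    tie_band: float = 0.05,
    floor: float = 0.5,
) -> ShapeVerdict:
    """Discriminate spherical (Einstein) vs chain-like (Huggins) solutes.

    The Einstein hard-sphere law has no free parameter once the partial
    specific volume is fixed: eta_rel = 1 + 2.5 vbar c.  Its R^2 is computed
    directly on relative viscosity.  The Huggins law is the linear fit of the
    reduced viscosity eta_sp/c = [eta] + k_H [eta]^2 c; its R^2 is that of
    the linearisation (reported 0 when the reduced viscosity carries no
    variance, i.e. the Huggins fit is degenerate).  Verdict goes to the model
    with the higher R^2 when the margin exceeds ``tie_band``; if both R^2
    fall below ``floor`` the call is inconclusive.
    """
    c = series.concentration
    rel = series.viscosity / series.solvent_viscosity

    pred_e = 1.0 + 2.5 * vbar * c
    ss_res = float(((rel - pred_e) ** 2).sum())
    ss_tot = float(((rel - rel.mean()) ** 2).sum())
    r2_e = _clip01(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    reduced = (rel - 1.0) / c
    if float(((reduced - reduced.mean()) ** 2).sum()) <= 1e-30:
        r2_h = 0.0
        intrinsic = float(reduced.mean())
        kh = 0.0
    else:
        fit = stats.linregress(c, reduced)
        r2_h = _clip01(fit.rvalue**2)
        intrinsic = float(fit.intercept)
        kh = float(fit.slope / fit.intercept**2) if fit.intercept != 0 else math.nan

    if max(r2_e, r2_h) < floor:
        verdict = "inconclusive"
    elif r2_h - r2_e > tie_band:
        verdict = "chain-like (unfolded)"
    elif r2_e - r2_h > tie_band:
        verdict = "spherical (native)"
    else:
        verdict = "inconclusive"
    return ShapeVerdict(
        r2_einstein=r2_e,
        r2_huggins=r2_h,
        verdict=verdict,
        intrinsic_viscosity=intrinsic,
        huggins_constant=kh,
    )


def swelling_ratio(Vi: float, Vs: float) -> float:
    """Swelling ratio (%) = (Vs - Vi) / Vi * 100; negative = shrinkage."""
    if Vi <= 0:
        raise ValueError("initial volume must be positive")
    if Vs < 0:
        raise ValueError("swollen volume must be non-negative")
    return (Vs - Vi) / Vi * 100.0


def bragg_spacing(two_theta: float, wavelength: float = 0.154) -> float:
    """First-order Bragg d-spacing (nm): d = lambda / (2 sin(two_theta/2))."""
    if not 0.0 < two_theta <= 180.0:
        raise ValueError("2-theta must lie in (0, 180] degrees")
    return wavelength / (2.0 * math.sin(math.radians(two_theta) / 2.0))


def water_molarity_from_volume_fraction(
    phi: float, pure_water_molarity: float = WATER_MOLARITY
) -> float:
    """Molar water concentration of a mixture with water volume fraction phi."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("volume fraction must lie in [0, 1]")
    return phi * pure_water_molarity
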