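"""Closed-form force models of the gripped tadpole.

Grip friction: forceps compressing the head by a fraction dw of the head
width (h.w. = 0.83 mm) contact it over an area A(dw) = 1.35 dw - 0.0043
mm^2 per side.  Hooke's law with Young's modulus E ~ 700 Pa and skin/steel
friction coefficient mu = tan(slide angle) ~ 0.08 gives
F = 2 mu E A(dw) dw = 151.2 dw^2 - 0.48 dw uN; a simulation-fitted
alternative is F = 49 dw^2 + 19.8 dw uN.

Hydrodynamics: the side-view body is an ellipse (semi-axes a = L/2, b
from the total side area pi a b = 4.95 mm^2); section areas are
closed-form elliptic-segment integrals.  Pressure drag on each section is
Dp = zeta * A_proj * rho * v^2 / 2 (zeta ~ 1.18) directed against the
section's velocity; it dominates skin friction at the struggling Reynolds
number Re = rho v L / mu_dyn ~ 190.

Lever escape: a stiffened trunk pivoting on a forceps tip converts the
momentum force F1 of the moving segments into an axial extraction force
F2x = (F1 L1 / L2) cos(alpha), which frees the animal when it exceeds the
grip friction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import TrackedBody

__all__ = [
    "GripModel",
    "BodyModel",
    "LeverState",
    "LeverResult",
    "contact_area",
    "hooke_friction",
    "hooke_coefficients",
    "fitted_friction",
    "friction_coefficient",
    "section_areas",
    "reynolds",
    "pressure_drag",
    "mass_acceleration",
    "lever_escape",
    "sections_from_tracked",
]


@dataclass
class GripModel:
    """Friction-law parameters of the virtual forceps grip."""

    mu: float = 0.08                 # skin / stainless-steel friction coeff.
    elastic_modulus: float = 700.0   # Pa, soft-tissue estimate
    area_coeffs: tuple = (1.35, -0.0043)   # mm^2 per compression fraction
    fitted_coeffs: tuple = (49.0, 19.8)    # uN: quadratic, linear
    head_width: float = 0.83         # mm

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.elastic_modulus <= 0:
            raise ValueError("mu and elastic modulus must be positive")


@dataclass
class BodyModel:
    """Body geometry and fluid constants for drag and inertia."""

    body_length: float = 5.0          # mm
    total_side_area: float = 4.95     # mm^2
    zeta: float = 1.18                # pressure-drag shape coefficient
    water_density: float = 1000.0     # kg/m^3
    dynamic_viscosity: float = 0.00089  # Pa s (water, 20-25 C)
    total_mass: float = 141.41        # mg
    n_sections: int = 10
    section_masses: np.ndarray = field(default=None)  # ug per section

    def __post_init__(self) -> None:
        if self.body_length <= 0 or self.total_side_area <= 0:
            raise ValueError("body dimensions must be positive")
        if self.section_masses is None:
            # default: masses proportional to side-view section areas,
            # normalised to the total body mass
            areas = section_areas(self, self.n_sections)
            self.section_masses = (areas / areas.sum()
                                   * self.total_mass * 1000.0)
        self.section_masses = np.asarray(self.section_masses, dtype=float)
        if np.any(self.section_masses <= 0):
            raise ValueError("section masses must be positive")

    @property
    def semi_major(self) -> float:
        return self.body_length / 2.0

    @property
    def semi_minor(self) -> float:
        return self.total_side_area / (np.pi * self.semi_major)


@dataclass
class LeverState:
    """Lever geometry at the moment of a contraction."""

    f1: float        # uN, mass*acceleration of the moving segments
    l1: float        # mm, posterior lever arm
    l2: float        # mm, anterior lever arm
    alpha: float     # degrees between F2 and the forceps axis

    def __post_init__(self) -> None:
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("lever arms must be positive")
        if not 0 <= self.alpha < 90:
            raise ValueError("alpha must be in [0, 90) degrees")


@dataclass
class LeverResult:
    f2: float
    f2x: float
    escapes: bool


# ---------------------------------------------------------------------------
# grip friction

def _check_dw(dw: float) -> float:
    dw = float(dw)
    if not 0 <= dw < 1:
        raise ValueError("compression fraction dw must be in [0, 1)")
    return dw


def contact_area(dw: float, grip: GripModel | None = None) -> float:
    """Contact area (mm^2) between one forceps tip and the head at
    compression fraction dw, clamped at 0 for tiny compressions."""
    grip = grip or GripModel()
    dw = _check_dw(dw)
    c1, c0 = grip.area_coeffs
    return max(0.0, c1 * dw + c0)


def hooke_friction(dw: float, grip: GripModel | None = None) -> float:
    """Hooke's-law grip friction (uN): 2 mu E A(dw) dw.

    With the default parameters this expands to 151.2 dw^2 - 0.48 dw.
    """
    grip = grip or GripModel()
    dw = _check_dw(dw)
    return max(0.0, 2.0 * grip.mu * grip.elastic_modulus
               * contact_area(dw, grip) * dw)


def hooke_coefficients(grip: GripModel | None = None) -> tuple[float, float]:
    """(quadratic, linear) uN coefficients of the expanded Hooke friction
    polynomial 2 mu E (c1 dw + c0) dw."""
    grip = grip or GripModel()
    c1, c0 = grip.area_coeffs
    k = 2.0 * grip.mu * grip.elastic_modulus
    return k * c1, k * c0


def fitted_friction(dw: float, grip: GripModel | None = None) -> float:
    """Simulation-fitted grip friction (uN): 49 dw^2 + 19.8 dw by default."""
    grip = grip or GripModel()
    dw = _check_dw(dw)
    a, b = grip.fitted_coeffs
    return a * dw * dw + b * dw


def friction_coefficient(slide_angle: float) -> float:
    """Friction coefficient from the tilt angle (degrees) at which an
    anaesthetised animal starts to slide: mu = tan(alpha)."""
    if not 0 < slide_angle < 90:
        raise ValueError("slide angle must be in (0, 90) degrees")
    return float(np.tan(np.radians(slide_angle)))


# ---------------------------------------------------------------------------
# body geometry and hydrodynamics

def _ellipse_cumarea(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Integral of the full-height ellipse cross-section from -a to x."""
    x = np.clip(np.asarray(x, dtype=float), -a, a)
    return b * (x * np.sqrt(np.maximum(0.0, 1.0 - (x / a) ** 2))
                + a * np.arcsin(x / a)) + b * a * np.pi / 2.0


def section_areas(body: BodyModel, n_sections: int,
                  span: tuple[float, float] | None = None) -> np.ndarray:
    """Side-view areas (mm^2) of equal-length body sections.

    The body silhouette is the ellipse with semi-axes (L/2, b); ``span``
    is in body-axis coordinates centred at mid-body (default the whole
    [-L/2, L/2]).  Areas are exact elliptic-segment integrals, so they are
    additive over any partition.
    """
    a, b = body.semi_major, body.semi_minor
    if span is None:
        span = (-a, a)
    lo, hi = span
    if lo < -a - 1e-9 or hi > a + 1e-9 or hi <= lo:
        raise ValueError("span must be a non-empty interval within [-L/2, L/2]")
    edges = np.linspace(lo, hi, n_sections + 1)
    cum = _ellipse_cumarea(edges, a, b)
    return np.diff(cum)


def reynolds(v: float, length: float, body: BodyModel | None = None) -> float:
    """Reynolds number rho v L / mu_dyn; v in m/s, L in m."""
    body = body or BodyModel()
    if v < 0 or length < 0:
        raise ValueError("v and L must be non-negative")
    return body.water_density * v * length / body.dynamic_viscosity


def sections_from_tracked(tracked: TrackedBody) -> tuple[np.ndarray, np.ndarray]:
    """(times, endpoints) for per-section force calculations.

    The 11 tracked points become the endpoints of 10 sections; 2D input is
    lifted to 3D with z = 0 so all force outputs keep three axes.
    """
    pts = tracked.points
    if pts.shape[2] == 2:
        pts = np.concatenate([pts, np.zeros(pts.shape[:2] + (1,))], axis=2)
    return tracked.times, pts


def pressure_drag(body: BodyModel, times: np.ndarray, endpoints: np.ndarray,
                  areas: np.ndarray | None = None,
                  parallel_angle_deg: float = 15.0) -> pd.DataFrame:
    """Per-frame pressure drag of the sectioned body, in uN.

    endpoints has shape (n_frames, n_sections + 1, 3), mm.  Each section's
    centre velocity is the average of its two endpoint velocities; the
    projected area is the side area times sin(angle between the section
    axis and the velocity), i.e. full area for motion perpendicular to the
    axis, minimal for axial motion.  Drag magnitude is
    zeta * A_proj * rho * v^2 / 2 directed opposite the velocity; section
    vectors are summed and reported as (Fx, Fy, Fz, |F|).

    The formula is only trustworthy when sections move roughly broadside;
    the returned frame carries a ``low_validity`` column with the fraction
    of sections moving within ``parallel_angle_deg`` of their own axis.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    times = np.asarray(times, dtype=float)
    n_sections = endpoints.shape[1] - 1
    if areas is None:
        areas = section_areas(body, n_sections)
    areas = np.asarray(areas, dtype=float)
    if areas.size != n_sections:
        raise ValueError("areas must match the number of sections")

    vel = np.gradient(endpoints, times, axis=0)            # mm/s
    v_center = 0.5 * (vel[:, :-1, :] + vel[:, 1:, :])
    axis = endpoints[:, 1:, :] - endpoints[:, :-1, :]
    axis_len = np.linalg.norm(axis, axis=2)
    speed = np.linalg.norm(v_center, axis=2)

    zero_axis = axis_len < 1e-12
    if np.any(zero_axis):
        warnings.warn("zero-length section axis encountered; section "
                      "skipped", stacklevel=2)
    moving = (speed > 1e-12) & ~zero_axis
    cosang = np.zeros_like(speed)
    np.divide(np.abs(np.einsum("fsd,fsd->fs", axis, v_center)),
              axis_len * speed, out=cosang, where=moving)
    sinang = np.sqrt(np.clip(1.0 - cosang ** 2, 0.0, 1.0))
    a_proj_m2 = areas[None, :] * sinang * 1e-6
    v_ms = speed * 1e-3
    mag = 0.5 * body.zeta * body.water_density * a_proj_m2 * v_ms ** 2  # N
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(moving[..., None], v_center / speed[..., None], 0.0)
    drag = -(mag * 1e6)[..., None] * unit                  # uN, opposes v
    drag[zero_axis] = 0.0
    total = drag.sum(axis=1)
    low = np.degrees(np.arccos(np.clip(cosang, -1, 1))) < parallel_angle_deg
    frac_low = np.where(moving.any(axis=1),
                        (low & moving).sum(axis=1) / np.maximum(
                            moving.sum(axis=1), 1), 0.0)
    return pd.DataFrame({
        "time": times,
        "Fx": total[:, 0], "Fy": total[:, 1], "Fz": total[:, 2],
        "Fmag": np.linalg.norm(total, axis=1),
        "low_validity": frac_low,
    })


def mass_acceleration(body: BodyModel, times: np.ndarray,
                      endpoints: np.ndarray,
                      masses: np.ndarray | None = None,
                      smooth_cutoff: float | None = None) -> pd.DataFrame:
    """Per-frame sum of section mass x acceleration, in uN.

    Section mass centres are the endpoint midpoints; acceleration is the
    central second difference of position (optionally after a zero-phase
    Butterworth low-pass at ``smooth_cutoff`` Hz).  Masses default to the
    body model's area-proportional distribution (ug).
    """
    endpoints = np.asarray(endpoints, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 frames for acceleration")
    dt = np.diff(times)
    if np.any(np.abs(dt - dt[0]) > 0.01 * dt[0]):
        raise ValueError("frame times must be uniform")
    n_sections = endpoints.shape[1] - 1
    masses = np.asarray(masses if masses is not None
                        else body.section_masses, dtype=float)
    if masses.size != n_sections:
        raise ValueError("masses must match the number of sections")
    centers = 0.5 * (endpoints[:, :-1, :] + endpoints[:, 1:, :])
    if smooth_cutoff is not None:
        from scipy import signal as _sig
        fs = 1.0 / dt[0]
        sos = _sig.butter(4, smooth_cutoff, btype="low", fs=fs, output="sos")
        centers = _sig.sosfiltfilt(sos, centers, axis=0)
    acc = np.gradient(np.gradient(centers, times, axis=0), times, axis=0)
    force = (masses[None, :, None] * acc).sum(axis=1) * 1e-6  # ug*mm/s^2->uN
    return pd.DataFrame({
        "time": times,
        "Fx": force[:, 0], "Fy": force[:, 1], "Fz": force[:, 2],
        "Fmag": np.linalg.norm(force, axis=1),
    })


def lever_escape(state: LeverState, friction: float) -> LeverResult:
    """Lever force balance: F2 = F1 L1 / L2, F2x = F2 cos(alpha); the
    animal escapes when the axial component exceeds the grip friction."""
    f2 = state.f1 * state.l1 / state.l2
    f2x = f2 * float(np.cos(np.radians(state.alpha)))
    return LeverResult(f2=float(f2), f2x=float(f2x),
                       escapes=bool(f2x > friction))
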