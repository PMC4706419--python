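"""Forward whisking kinematics: protraction schedules and 3D node placement.

During a whisk the azimuth theta advances in fixed 0.1 deg steps; elevation
phi and roll zeta are affine functions of the protraction dtheta measured from
biomechanical rest, with row-specific coefficients.  A posed whisker is the
rigid motion

    nodes = basepoint + R_azimuth(theta) @ R_elevation(phi) @ R_roll(zeta) @ curve

so that theta reads back as the azimuth of the base tangent's horizontal
projection and phi as its angle above the horizontal plane, independent of
zeta.  Left-side whiskers are posed as exact mirror images of the equivalent
right-side motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tables
from .array_model import ArraySpec, ParameterError, WhiskerId, WhiskerSpec, canonical_curve

_MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class KinematicCoeffs:
    """Per-row elevation/roll coupling coefficients with optional per-whisker
    overrides (keyed by whisker label, e.g. ``"R-C2"``).

    Override keys: ``phi_intercept_delta`` (deg, added to the whisker's
    phi_rest), ``phi_slope``, ``zeta_slope`` (absolute replacements).
    """

    rows: dict = field(default_factory=lambda: {r: dict(v) for r, v in tables.KINEMATIC_ROWS.items()})
    overrides: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "KinematicCoeffs":
        return cls()

    def resolve(self, spec: WhiskerSpec) -> tuple[float, float, float, float]:
        """Effective (phi0, phi_slope, zeta0, zeta_slope) for one whisker."""
        row = self.rows[spec.id.row]
        ov = self.overrides.get(spec.id.label, {})
        phi0 = spec.phi_rest + ov.get("phi_intercept_delta", 0.0)
        phi_slope = ov.get("phi_slope", row["phi_slope"])
        zeta_slope = ov.get("zeta_slope", row["zeta_slope"])
        return phi0, phi_slope, spec.zeta_rest, zeta_slope

    def with_overrides(self, extra: dict) -> "KinematicCoeffs":
        merged = {k: dict(v) for k, v in self.overrides.items()}
        for label, ov in extra.items():
            merged.setdefault(label, {}).update(ov)
        return replace(self, overrides=merged)


@dataclass(frozen=True)
class ProtractionSchedule:
    """Angular trajectory of a whisk.

    start_mode 'rest' protracts from theta_rest through ``amplitude`` deg;
    'full_retraction' starts at the whisker's fully retracted azimuth and
    protracts to theta_rest + amplitude.  amplitude may be a uniform value
    (deg) or the string 'per_column' for the large-protraction variant in
    which the rostral-most column protracts 70 deg and each more caudal
    column 5 deg further (Greek: 100 deg).

    basepoint_translation: None, 'table' (the published extreme-protraction
    displacements) or a mapping label -> 3-vector (mm, head frame); applied
    linearly in protraction fraction.
    """

    step_size: float = 0.1
    start_mode: str = "rest"
    amplitude: float | str = 60.0
    basepoint_translation: object = None

    def __post_init__(self):
        if self.step_size <= 0:
            raise ParameterError("step_size must be > 0")
        if self.start_mode not in ("rest", "full_retraction"):
            raise ParameterError(f"unknown start_mode {self.start_mode!r}")
        if isinstance(self.amplitude, str) and self.amplitude != "per_column":
            raise ParameterError(f"unknown amplitude model {self.amplitude!r}")

    def amplitude_for(self, wid: WhiskerId) -> float:
        """Protraction amplitude from rest, deg."""
        if self.amplitude == "per_column":
            return tables.PER_COLUMN_AMPLITUDE[wid.col]
        return float(self.amplitude)

    def start_theta_for(self, wid: WhiskerId) -> float:
        fr, rest, _fp = tables.REST_ANGLES[(wid.row, wid.col)]
        return fr if self.start_mode == "full_retraction" else rest

    def total_sweep_for(self, wid: WhiskerId) -> float:
        fr, rest, _fp = tables.REST_ANGLES[(wid.row, wid.col)]
        amp = self.amplitude_for(wid)
        if self.start_mode == "full_retraction":
            return rest - fr + amp
        return amp

    def n_steps_for(self, wid: WhiskerId) -> int:
        return int(np.floor(self.total_sweep_for(wid) / self.step_size + 1e-9)) + 1

    def translation_for(self, spec: WhiskerSpec) -> np.ndarray:
        if self.basepoint_translation is None:
            return np.zeros(3)
        if self.basepoint_translation == "table":
            rostral, lateral, dorsal = tables.BASEPOINT_TRANSLATIONS[(spec.id.row, spec.id.col)]
            sign = 1.0 if spec.id.side == "right" else -1.0
            return np.array([sign * lateral, rostral, dorsal])
        vec = self.basepoint_translation.get(spec.id.label)
        return np.zeros(3) if vec is None else np.asarray(vec, dtype=float)


@dataclass
class WhiskerSweep:
    """Posed node trajectories of one whisker over a protraction."""

    whisker: WhiskerId
    theta_by_step: np.ndarray   # (S,) deg
    nodes_by_step: np.ndarray   # (S, n_nodes, 3) mm, head frame

    @property
    def steps(self) -> int:
        return len(self.theta_by_step)


def rotation_matrices(theta_deg, phi_deg, zeta_deg) -> np.ndarray:
    """Stack of head-frame rotations R_z(theta-90) @ R_y(-phi) @ R_x(zeta).

    Maps the canonical emergence axis +x to azimuth theta / elevation phi for
    a right-side whisker, applying roll about the emergence axis first.
    """
    a = np.radians(np.atleast_1d(theta_deg) - 90.0)
    b = np.radians(-np.atleast_1d(phi_deg))
    c = np.radians(np.atleast_1d(zeta_deg))
    a, b, c = np.broadcast_arrays(a, b, c)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    m = np.empty(a.shape + (3, 3))
    # R_z(a) @ R_y(b) @ R_x(c), composed symbolically
    m[..., 0, 0] = ca * cb
    m[..., 0, 1] = ca * sb * sc - sa * cc
    m[..., 0, 2] = ca * sb * cc + sa * sc
    m[..., 1, 0] = sa * cb
    m[..., 1, 1] = sa * sb * sc + ca * cc
    m[..., 1, 2] = sa * sb * cc - ca * sc
    m[..., 2, 0] = -sb
    m[..., 2, 1] = cb * sc
    m[..., 2, 2] = cb * cc
    return m


def pose_whisker(spec: WhiskerSpec, theta: float, phi: float, zeta: float,
                 basepoint_offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Place the whisker's canonical curve in the head frame at one pose."""
    return _pose_steps(spec, np.atleast_1d(theta), np.atleast_1d(phi),
                       np.atleast_1d(zeta), np.asarray(basepoint_offset, float)[None, :])[0]


def _pose_steps(spec, thetas, phis, zetas, offsets) -> np.ndarray:
    curve = canonical_curve(spec)
    base = np.asarray(spec.basepoint, dtype=float)
    mirror = spec.id.side == "left"
    if mirror:
        base = base * _MIRROR
        offsets = offsets * _MIRROR
    m = rotation_matrices(thetas, phis, zetas)          # (S,3,3)
    nodes = np.einsum("sij,nj->sni", m, curve)
    nodes += (base + offsets)[:, None, :]
    if mirror:
        nodes *= _MIRROR
    return nodes


def angles_at_step(spec: WhiskerSpec, coeffs: KinematicCoeffs,
                   schedule: ProtractionSchedule, step: int) -> tuple[float, float, float]:
    """(theta, phi, zeta) at one protraction step.

    dtheta is measured from theta_rest and is negative during the
    retracted-to-rest phase of a full-retraction whisk; the affine couplings
    are extrapolated there.
    """
    n = schedule.n_steps_for(spec.id)
    if not 0 <= step < n:
        raise IndexError(f"step {step} out of range [0, {n})")
    theta = schedule.start_theta_for(spec.id) + step * schedule.step_size
    dtheta = theta - spec.theta_rest
    phi0, phi_slope, zeta0, zeta_slope = coeffs.resolve(spec)
    return theta, phi0 + phi_slope * dtheta, zeta0 + zeta_slope * dtheta


def sweep_whisker(spec: WhiskerSpec, coeffs: KinematicCoeffs,
                  schedule: ProtractionSchedule) -> WhiskerSweep:
    n = schedule.n_steps_for(spec.id)
    thetas = schedule.start_theta_for(spec.id) + schedule.step_size * np.arange(n)
    dth = thetas - spec.theta_rest
    phi0, phi_slope, zeta0, zeta_slope = coeffs.resolve(spec)
    phis = phi0 + phi_slope * dth
    zetas = zeta0 + zeta_slope * dth
    frac = np.arange(n) / max(n - 1, 1)
    offsets = frac[:, None] * schedule.translation_for(spec)[None, :]
    nodes = _pose_steps(spec, thetas, phis, zetas, offsets)
    return WhiskerSweep(spec.id, thetas, nodes)


def sweep_all(array: ArraySpec, coeffs: KinematicCoeffs,
              schedule: ProtractionSchedule) -> list[WhiskerSweep]:
    """One WhiskerSweep per whisker of the array, deterministic."""
    return [sweep_whisker(w, coeffs, schedule) for w in array]


C2_VARIANTS = ("len+25%", "len-25%", "curv*2", "straight",
               "no_roll", "no_elevation", "no_roll_no_elevation")


def variant_c2(array: ArraySpec, coeffs: KinematicCoeffs,
               variant: str) -> tuple[ArraySpec, KinematicCoeffs]:
    """Single-whisker manipulation of C2 (both sides): geometry scaling or
    removal of elevation/roll coupling.  Inputs are left untouched."""
    if variant not in C2_VARIANTS:
        raise ParameterError(f"unknown C2 variant {variant!r}; choose from {C2_VARIANTS}")

    def is_c2(w):
        return w.id.row == "C" and w.id.col == 2

    whiskers = list(array.whiskers)
    if variant in ("len+25%", "len-25%", "curv*2", "straight"):
        for i, w in enumerate(whiskers):
            if not is_c2(w):
                continue
            if variant == "len+25%":
                whiskers[i] = replace(w, length=w.length * 1.25)
            elif variant == "len-25%":
                whiskers[i] = replace(w, length=w.length * 0.75)
            elif variant == "curv*2":
                whiskers[i] = replace(w, curvature_angle=w.curvature_angle * 2.0)
            else:
                whiskers[i] = replace(w, curvature_angle=0.0)
        return ArraySpec(tuple(whiskers)), coeffs

    ov = {}
    if "no_roll" in variant:
        ov["zeta_slope"] = 0.0
    if "no_elevation" in variant:
        ov["phi_slope"] = 0.0
    extra = {w.id.label: dict(ov) for w in whiskers if is_c2(w)}
    return array, coeffs.with_overrides(extra)
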