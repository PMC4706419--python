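"""Synthetic morphology of the 62-whisker vibrissal array.

The head frame has its origin at the midpoint of the nostrils: +x points to the
rat's right, +y rostral, +z dorsal.  Right-side basepoints have x >= 0, left
side x <= 0, and the left array is an exact mirror image of the right across
the midsagittal (x = 0) plane.

Published morphometry fixes whisker lengths, resting azimuths, and per-row
resting elevations; the basepoint layout, resting roll and intrinsic curvature
are not published per whisker and are generated here from a small, fully
config-exposed parameter set (a laterally facing ellipsoidal pad patch with
regular row/column spacing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tables

SIDES = ("right", "left")


class IdentityError(ValueError):
    """Unknown or inconsistent whisker identity."""


class ParameterError(ValueError):
    """Invalid morphology or schedule parameter."""


@dataclass(frozen=True, order=True)
class WhiskerId:
    """Identity of one vibrissa: row A-E, column 0 (Greek) to 6, side."""

    row: str
    col: int
    side: str

    def __post_init__(self):
        if (self.row, self.col) not in tables.LENGTHS_MM:
            raise IdentityError(f"no whisker at row={self.row!r} col={self.col}")
        if self.side not in SIDES:
            raise IdentityError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def name(self) -> str:
        return tables.whisker_name(self.row, self.col)

    @property
    def label(self) -> str:
        return f"{self.side[0].upper()}-{self.name}"

    def mirrored(self) -> "WhiskerId":
        other = "left" if self.side == "right" else "right"
        return WhiskerId(self.row, self.col, other)


@dataclass(frozen=True)
class WhiskerSpec:
    """Geometry and resting pose of a single vibrissa.

    theta_rest is the resting azimuth (0 deg caudal, 180 deg rostral),
    phi_rest the resting elevation above the head horizontal plane, and
    zeta_rest the resting roll about the whisker's own emergence axis.
    curvature_angle is the total arc angle subtended by the intrinsic
    circular curve (0 = straight).
    """

    id: WhiskerId
    length: float
    basepoint: tuple[float, float, float]
    theta_rest: float
    phi_rest: float
    zeta_rest: float = 0.0
    curvature_angle: float = 35.0
    n_nodes: int = 100

    def __post_init__(self):
        if not self.length > 0:
            raise ParameterError(f"{self.id.label}: length must be > 0")
        if self.curvature_angle < 0:
            raise ParameterError(f"{self.id.label}: curvature_angle must be >= 0")
        if self.n_nodes < 2:
            raise ParameterError(f"{self.id.label}: n_nodes must be >= 2")


@dataclass(frozen=True)
class MorphologyParams:
    """Config-exposed parameters of the synthetic basepoint layout.

    Basepoints sit on a laterally facing ellipsoidal patch of the mystacial
    pad, rows A (dorsal) to E (ventral) spaced ``row_spacing`` apart in z and
    columns Greek (caudal) to 6 (rostral) spaced ``col_spacing`` apart in y.
    The lateral bulge follows an ellipsoid with semi-axes
    (pad_center[0], pad_semiaxis_y, pad_semiaxis_z).  The Greek whiskers are
    offset slightly ventrally, as observed on the real pad.
    """

    pad_center: tuple[float, float, float] = (8.0, -9.0, 0.0)
    row_spacing: float = 2.5
    col_spacing: float = 2.5
    greek_dz: float = -1.25
    pad_semiaxis_y: float = 14.0
    pad_semiaxis_z: float = 10.0
    min_bulge: float = 0.15
    curvature_angle: float = 35.0
    zeta_rest: float = 0.0
    n_nodes: int = 100
    curvature_overrides: dict = field(default_factory=dict)
    zeta_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("row_spacing", "col_spacing", "pad_semiaxis_y", "pad_semiaxis_z"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        if not all(math.isfinite(c) for c in self.pad_center):
            raise ParameterError("pad_center components must be finite")


@dataclass(frozen=True)
class ArraySpec:
    """The full bilateral array: 31 right-side whiskers followed by their
    left-side mirror images (or any consistent subset thereof)."""

    whiskers: tuple[WhiskerSpec, ...]

    def __len__(self) -> int:
        return len(self.whiskers)

    def __iter__(self):
        return iter(self.whiskers)

    def side(self, side: str) -> tuple[WhiskerSpec, ...]:
        return tuple(w for w in self.whiskers if w.id.side == side)

    def get(self, label: str) -> WhiskerSpec:
        for w in self.whiskers:
            if w.id.label == label:
                return w
        raise IdentityError(f"no whisker labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [w.id.label for w in self.whiskers]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w in self.whiskers:
            x, y, z = w.basepoint
            rows.append(dict(
                label=w.id.label, row=w.id.row, col=w.id.col, side=w.id.side,
                length_mm=w.length, base_x_mm=x, base_y_mm=y, base_z_mm=z,
                theta_rest_deg=w.theta_rest, phi_rest_deg=w.phi_rest,
                zeta_rest_deg=w.zeta_rest, curvature_angle_deg=w.curvature_angle,
            ))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _basepoint(row: str, col: int, p: MorphologyParams) -> tuple[float, float, float]:
    cx, cy, cz = p.pad_center
    r_idx = tables.ROWS.index(row)
    dy = (col - 3) * p.col_spacing
    dz = (2 - r_idx) * p.row_spacing + (p.greek_dz if col == tables.GREEK else 0.0)
    bulge = 1.0 - (dy / p.pad_semiaxis_y) ** 2 - (dz / p.pad_semiaxis_z) ** 2
    x = cx * math.sqrt(max(p.min_bulge, bulge))
    return (x, cy + dy, cz + dz)


def build_default_array(params: MorphologyParams | None = None) -> ArraySpec:
    """Build the deterministic 62-whisker array from morphology parameters.

    Lengths, resting azimuths and per-row resting elevations come from the
    published tables; basepoints, roll, and curvature from ``params``.
    """
    p = params or MorphologyParams()
    right = []
    for (row, col) in tables.VALID_CELLS:
        name = tables.whisker_name(row, col)
        right.append(WhiskerSpec(
            id=WhiskerId(row, col, "right"),
            length=tables.LENGTHS_MM[(row, col)],
            basepoint=_basepoint(row, col, p),
            theta_rest=tables.REST_ANGLES[(row, col)][1],
            phi_rest=tables.KINEMATIC_ROWS[row]["phi_intercept"],
            zeta_rest=float(p.zeta_overrides.get(name, p.zeta_rest)),
            curvature_angle=float(p.curvature_overrides.get(name, p.curvature_angle)),
            n_nodes=p.n_nodes,
        ))
    return ArraySpec(tuple(right) + tuple(mirror_array(right)))


def mirror_array(right_side) -> tuple[WhiskerSpec, ...]:
    """Reflect right-side whisker specs across the midsagittal plane."""
    out = []
    for w in right_side:
        if w.id.side != "right":
            raise IdentityError(f"mirror_array expects right-side specs, got {w.id.label}")
        x, y, z = w.basepoint
        out.append(replace(w, id=w.id.mirrored(), basepoint=(-x, y, z)))
    return tuple(out)


def canonical_curve(spec: WhiskerSpec) -> np.ndarray:
    """Node polyline of the whisker in its canonical (unposed) frame.

    The base is at the origin with the base tangent along +x (the emergence
    axis); the intrinsic curve is a planar circular arc bending toward +y
    (the concave axis), sampled at n_nodes points evenly spaced in arc
    length.  Roll rotates this plane about +x before the whisker is posed.
    """
    return arc_curve(spec.length, spec.curvature_angle, spec.n_nodes)


def arc_curve(length: float, curvature_angle: float, n_nodes: int) -> np.ndarray:
    if n_nodes < 2:
        raise ParameterError("n_nodes must be >= 2")
    s = np.linspace(0.0, length, n_nodes)
    out = np.zeros((n_nodes, 3))
    a = math.radians(curvature_angle)
    if a == 0.0:
        out[:, 0] = s
        return out
    radius = length / a
    t = s / radius
    out[:, 0] = radius * np.sin(t)
    out[:, 1] = radius * (1.0 - np.cos(t))
    return out
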