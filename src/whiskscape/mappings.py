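"""Spatial summaries of a contact table.

Covers the reachable configuration space (head poses with at least one
whisker in contact, resting or whisking), the guaranteed-contact distance,
the head-centered blind spot (space no whisker node visits at any protraction
step), and the left-right contact-count difference nL - nR used as a yaw cue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .array_model import ArraySpec, ParameterError
from .contact_sim import CLASS_NONE, ContactTable
from .kinematics import KinematicCoeffs, ProtractionSchedule, sweep_all


@dataclass
class ReachabilitySummary:
    distances: np.ndarray
    yaws: np.ndarray
    pitches: np.ndarray
    n_contacts_left: np.ndarray    # (D,Y,P)
    n_contacts_right: np.ndarray
    reachable: np.ndarray          # (D,Y,P) bool, either side
    thresholds: pd.DataFrame       # per distance-threshold pose counts


def reachability(table: ContactTable, thresholds=(25.0, 40.0, 60.0)) -> ReachabilitySummary:
    """Per-pose contact counts and unreachable-pose fractions by distance
    threshold.  Resting and whisking contacts both count."""
    if not table.has_both_sides():
        raise ParameterError("reachability needs both array sides")
    n_left = table.n_contacts("left")
    n_right = table.n_contacts("right")
    reachable = (n_left + n_right) > 0
    rows = []
    for thr in thresholds:
        sel = table.distances <= thr + 1e-9
        n_poses = int(sel.sum()) * len(table.yaws) * len(table.pitches)
        n_unreach = int((~reachable[sel]).sum())
        rows.append(dict(threshold_mm=thr, n_poses=n_poses, n_unreachable=n_unreach,
                         fraction_unreachable=n_unreach / n_poses))
    return ReachabilitySummary(table.distances, table.yaws, table.pitches,
                               n_left, n_right, reachable, pd.DataFrame(rows))


def guaranteed_contact_distance(summary: ReachabilitySummary) -> float:
    """Largest grid distance D such that every pose with distance <= D is
    reachable.  Saturation at the grid edge or failure at distance 0 is
    reported via a warning."""
    all_reachable = summary.reachable.all(axis=(1, 2))
    bad = np.nonzero(~all_reachable)[0]
    if len(bad) == 0:
        warnings.warn("all grid distances fully reachable; result saturates at the grid edge")
        return float(summary.distances[-1])
    first_bad = bad[0]
    if first_bad == 0:
        warnings.warn("unreachable poses exist even at distance 0 (anomalous morphology)")
        return 0.0
    return float(summary.distances[first_bad - 1])


@dataclass
class BlindSpotVolume:
    voxel_size: float
    region: tuple                 # ((x0,x1),(y0,y1),(z0,z1)) mm
    amplitude: float              # deg protraction from rest
    occupied: np.ndarray          # (nx,ny,nz) bool
    blind: np.ndarray             # (nx,ny,nz) bool
    labels: np.ndarray            # connected components of blind
    n_components: int
    meta: dict = field(default_factory=dict)

    @property
    def blind_volume_mm3(self) -> float:
        return float(self.blind.sum()) * self.voxel_size ** 3

    def blind_points(self) -> np.ndarray:
        """Voxel-center xyz coordinates of the blind set (mm)."""
        idx = np.argwhere(self.blind)
        lo = np.array([b[0] for b in self.region])
        return lo + (idx + 0.5) * self.voxel_size


DEFAULT_PROBE_REGION = ((-25.0, 25.0), (0.0, 40.0), (-25.0, 25.0))


def blind_spot(array: ArraySpec, coeffs: KinematicCoeffs, amplitude: float,
               voxel_size: float = 1.0,
               probe_region=DEFAULT_PROBE_REGION) -> BlindSpotVolume:
    """Voxelized swept volume and its complement within an anterior probe box.

    A voxel is occupied if any node of any whisker visits it at any step of a
    rest-started protraction of the given amplitude; blind voxels are the
    unoccupied ones inside the probe region (head-centered coordinates).
    """
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be > 0")
    lo = np.array([b[0] for b in probe_region], dtype=float)
    hi = np.array([b[1] for b in probe_region], dtype=float)
    if not (hi > lo).all():
        raise ParameterError("empty probe region")
    shape = np.ceil((hi - lo) / voxel_size - 1e-9).astype(int)
    occupied = np.zeros(shape, dtype=bool)
    schedule = ProtractionSchedule(amplitude=amplitude)
    for sw in sweep_all(array, coeffs, schedule):
        pts = sw.nodes_by_step.reshape(-1, 3)
        idx = np.floor((pts - lo) / voxel_size).astype(int)
        ok = ((idx >= 0) & (idx < shape)).all(axis=1)
        idx = idx[ok]
        occupied[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    blind = ~occupied
    labels, n = ndimage.label(blind)
    return BlindSpotVolume(voxel_size, tuple(probe_region), amplitude,
                           occupied, blind, labels, int(n))


@dataclass
class YawEstimateCurve:
    distances: np.ndarray
    yaws: np.ndarray
    pitches: np.ndarray
    delta: np.ndarray       # (D,Y,P) nL - nR
    slopes: np.ndarray      # (D,) OLS slope of delta vs yaw, pitches pooled
    intercepts: np.ndarray  # (D,)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(dict(d_mm=self.distances, slope_per_deg=self.slopes,
                                 intercept=self.intercepts))


def yaw_from_contacts(table: ContactTable) -> YawEstimateCurve:
    """nL - nR per pose plus a per-distance least-squares line of the
    difference against yaw (pitches pooled)."""
    if not table.has_both_sides():
        raise ParameterError("yaw_from_contacts needs both array sides")
    delta = (table.n_contacts("left") - table.n_contacts("right")).astype(float)
    yaw_rep = np.broadcast_to(table.yaws[:, None],
                              (len(table.yaws), len(table.pitches))).ravel()
    xc = yaw_rep - yaw_rep.mean()
    denom = (xc ** 2).sum()
    slopes = np.empty(len(table.distances))
    intercepts = np.empty(len(table.distances))
    for i in range(len(table.distances)):
        y = delta[i].ravel()
        slopes[i] = (xc * (y - y.mean())).sum() / denom
        intercepts[i] = y.mean() - slopes[i] * yaw_rep.mean()
    return YawEstimateCurve(table.distances, table.yaws, table.pitches,
                            delta, slopes, intercepts)
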