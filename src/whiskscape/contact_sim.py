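"""Whisker-wall collision sweep over a grid of head poses.

A flat vertical wall is an infinite half-space at perpendicular distance d
from the nostril midpoint.  Rather than rotating the head, the wall is
expressed in head coordinates: a node p has crossed the wall iff
dot(p, normal) >= d.  For each (whisker, pose) the first protraction step at
which any node crosses is recorded, the contact is classified (resting if it
exists at step 0, whisking if it first occurs later, none otherwise), and the
whisker's azimuth at that step is stored as the contact angle theta_impact.

The grid simulation factorizes the work: node projections onto the wall
normal depend only on (yaw, pitch), so for each head orientation a running
per-step maximum projection is computed once per whisker and all distances
are resolved by thresholding.  ``first_contact`` is the reference
single-(whisker, pose) path; the two must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .array_model import ArraySpec, ParameterError
from .kinematics import KinematicCoeffs, ProtractionSchedule, WhiskerSweep, sweep_all

CLASS_NONE, CLASS_RESTING, CLASS_WHISKING = 0, 1, 2
CLASS_NAMES = {CLASS_NONE: "none", CLASS_RESTING: "resting", CLASS_WHISKING: "whisking"}


class HeadPose(NamedTuple):
    """Head pose relative to the wall: perpendicular distance (mm), yaw and
    pitch (deg).  Positive yaw turns the left whiskers toward the wall;
    positive pitch tips the head up (pitch 0 = whisker rows horizontal)."""

    distance: float
    yaw: float
    pitch: float


@dataclass(frozen=True)
class PoseGrid:
    """Lattice of head poses; the standard grid is 61 x 37 x 37 = 83,509."""

    distances: np.ndarray
    yaws: np.ndarray
    pitches: np.ndarray

    @classmethod
    def default(cls) -> "PoseGrid":
        return cls(distances=np.arange(0.0, 61.0, 1.0),
                   yaws=np.arange(-90.0, 91.0, 5.0),
                   pitches=np.arange(-90.0, 91.0, 5.0))

    @property
    def n_poses(self) -> int:
        return len(self.distances) * len(self.yaws) * len(self.pitches)

    def poses(self):
        for d in self.distances:
            for y in self.yaws:
                for p in self.pitches:
                    yield HeadPose(float(d), float(y), float(p))


def wall_frame(pose: HeadPose, rotation_order: str = "yaw_then_pitch"):
    """Head-frame unit vectors of the wall's normal and in-plane axes.

    Returns (normal, lateral, vertical): ``normal`` points from the rat
    toward the wall, ``lateral`` is the wall's horizontal in-plane axis and
    ``vertical`` its vertical axis.  The head rotation is composed as
    extrinsic yaw about the world vertical then pitch about the interaural
    axis; the alternative order is config-selectable and identical on all
    single-axis slices.
    """
    psi = np.radians(pose.yaw)
    chi = np.radians(pose.pitch)
    sy, cy = np.sin(psi), np.cos(psi)
    sp, cp = np.sin(chi), np.cos(chi)
    if rotation_order == "yaw_then_pitch":
        normal = np.array([-sy * cp, cy * cp, -sp])
        lateral = np.array([cy, sy, 0.0])
        vertical = np.array([-sy * sp, cy * sp, cp])
    elif rotation_order == "pitch_then_yaw":
        normal = np.array([-sy, cy * cp, -cy * sp])
        lateral = np.array([cy, sy * cp, -sy * sp])
        vertical = np.array([0.0, sp, cp])
    else:
        raise ParameterError(f"unknown rotation_order {rotation_order!r}")
    return normal, lateral, vertical


def plane_in_head_frame(pose: HeadPose, rotation_order: str = "yaw_then_pitch"):
    """Wall half-space in head coordinates: (unit normal, offset mm).

    A point p has crossed the wall iff dot(p, normal) >= offset.
    """
    normal, _, _ = wall_frame(pose, rotation_order)
    return normal, float(pose.distance)


@dataclass(frozen=True)
class ContactRecord:
    whisker: object          # WhiskerId
    pose: HeadPose | None
    contact_class: int
    theta_impact: float      # deg; start azimuth for resting; nan for none
    contact_step: int        # -1 for none
    contact_node: int        # -1 for none


def first_contact(sweep: WhiskerSweep, normal: np.ndarray, offset: float,
                  pose: HeadPose | None = None) -> ContactRecord:
    """First wall crossing of one sweep: smallest step, then smallest node
    index among crossing nodes at that step."""
    proj = sweep.nodes_by_step @ np.asarray(normal, float)   # (S, N)
    crossed = proj >= offset
    any_step = crossed.any(axis=1)
    if not any_step.any():
        return ContactRecord(sweep.whisker, pose, CLASS_NONE, np.nan, -1, -1)
    step = int(np.argmax(any_step))
    node = int(np.argmax(crossed[step]))
    cls = CLASS_RESTING if step == 0 else CLASS_WHISKING
    return ContactRecord(sweep.whisker, pose, cls,
                         float(sweep.theta_by_step[step]), step, node)


@dataclass
class ContactTable:
    """Dense per-(whisker, pose) contact classification and impact angles.

    Axes: whisker x distance x yaw x pitch.  ``theta_impact`` holds the
    whisking impact azimuth; for resting contacts it stores the start
    azimuth (flagged by contact_class) and is NaN for no-contacts.
    """

    labels: list[str]
    rows: np.ndarray        # (W,) str
    cols: np.ndarray        # (W,) int
    sides: np.ndarray       # (W,) str
    distances: np.ndarray
    yaws: np.ndarray
    pitches: np.ndarray
    contact_class: np.ndarray   # (W, D, Y, P) int8
    theta_impact: np.ndarray    # (W, D, Y, P) float32
    contact_step: np.ndarray    # (W, D, Y, P) int32, -1 = none
    contact_node: np.ndarray    # (W, D, Y, P) int16, -1 = none
    meta: dict = field(default_factory=dict)

    @property
    def n_whiskers(self) -> int:
        return len(self.labels)

    def side_mask(self, side: str) -> np.ndarray:
        return self.sides == side

    def has_both_sides(self) -> bool:
        return bool((self.sides == "left").any() and (self.sides == "right").any())

    def n_contacts(self, side: str | None = None) -> np.ndarray:
        """Number of whiskers (resting or whisking) in contact per pose."""
        m = slice(None) if side is None else self.side_mask(side)
        return (self.contact_class[m] != CLASS_NONE).sum(axis=0)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def dist_index(self, d: float) -> int:
        return int(np.flatnonzero(np.isclose(self.distances, d))[0])

    def yaw_index(self, y: float) -> int:
        return int(np.flatnonzero(np.isclose(self.yaws, y))[0])

    def pitch_index(self, p: float) -> int:
        return int(np.flatnonzero(np.isclose(self.pitches, p))[0])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form records (one row per whisker-pose)."""
        w, d, y, p = np.meshgrid(np.arange(self.n_whiskers), self.distances,
                                 self.yaws, self.pitches, indexing="ij")
        cls = self.contact_class.ravel()
        return pd.DataFrame(dict(
            row=self.rows[w.ravel()], col=self.cols[w.ravel()],
            side=self.sides[w.ravel()], d_mm=d.ravel(), yaw_deg=y.ravel(),
            pitch_deg=p.ravel(),
            contact_class=pd.Categorical.from_codes(cls, categories=["none", "resting", "whisking"]),
            theta_impact_deg=self.theta_impact.ravel().astype(float),
            step=self.contact_step.ravel(), node=self.contact_node.ravel(),
        ))

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=np.array(self.labels, dtype="S16"))
            f.create_dataset("rows", data=self.rows.astype("S1"))
            f.create_dataset("cols", data=self.cols.astype(np.int8))
            f.create_dataset("sides", data=self.sides.astype("S8"))
            for name in ("distances", "yaws", "pitches"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("contact_class", data=self.contact_class, compression="gzip")
            f.create_dataset("theta_impact", data=self.theta_impact, compression="gzip")
            f.create_dataset("contact_step", data=self.contact_step, compression="gzip")
            f.create_dataset("contact_node", data=self.contact_node, compression="gzip")
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "ContactTable":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(
                labels=[s.decode() for s in f["labels"][:]],
                rows=f["rows"][:].astype("U1"),
                cols=f["cols"][:].astype(int),
                sides=f["sides"][:].astype("U8"),
                distances=f["distances"][:], yaws=f["yaws"][:], pitches=f["pitches"][:],
                contact_class=f["contact_class"][:], theta_impact=f["theta_impact"][:],
                contact_step=f["contact_step"][:], contact_node=f["contact_node"][:],
                meta=dict(f.attrs),
            )


def simulate_grid(array: ArraySpec, coeffs: KinematicCoeffs,
                  schedule: ProtractionSchedule, grid: PoseGrid,
                  sweeps: list[WhiskerSweep] | None = None,
                  rotation_order: str = "yaw_then_pitch") -> ContactTable:
    """Full contact table over the pose grid.

    Equivalent to calling :func:`first_contact` for every (whisker, pose);
    the per-orientation projection factorization is only an optimization and
    is oracle-tested against the reference path.
    """
    if sweeps is None:
        sweeps = sweep_all(array, coeffs, schedule)
    W = len(sweeps)
    D, Y, P = len(grid.distances), len(grid.yaws), len(grid.pitches)
    steps = np.array([s.steps for s in sweeps])
    uniform = bool((steps == steps[0]).all())
    n_nodes = sweeps[0].nodes_by_step.shape[1]

    cls = np.zeros((W, D, Y, P), dtype=np.int8)
    theta = np.full((W, D, Y, P), np.nan, dtype=np.float32)
    step_out = np.full((W, D, Y, P), -1, dtype=np.int32)
    node_out = np.full((W, D, Y, P), -1, dtype=np.int16)

    distances = np.asarray(grid.distances, dtype=float)
    if uniform:
        S = int(steps[0])
        nodes = np.stack([s.nodes_by_step for s in sweeps])      # (W,S,N,3)
        flat = np.ascontiguousarray(nodes.reshape(-1, 3))
        thetas = np.stack([s.theta_by_step for s in sweeps])     # (W,S)
        for iy, yaw in enumerate(grid.yaws):
            for ip, pitch in enumerate(grid.pitches):
                normal, _ = plane_in_head_frame(HeadPose(0.0, yaw, pitch), rotation_order)
                proj = (flat @ normal).reshape(W, S, n_nodes)
                pmax = proj.max(axis=2)                          # (W,S)
                run = np.maximum.accumulate(pmax, axis=1)
                # first step whose running max reaches each distance (exact)
                idx = np.argmax(run[:, None, :] >= distances[None, :, None], axis=2)
                hit = run[:, -1][:, None] >= distances[None, :]
                idx = np.where(hit, idx, S)
                w_i, d_i = np.nonzero(hit)
                s_i = idx[w_i, d_i]
                cls[w_i, d_i, iy, ip] = np.where(s_i == 0, CLASS_RESTING, CLASS_WHISKING)
                theta[w_i, d_i, iy, ip] = thetas[w_i, s_i]
                step_out[w_i, d_i, iy, ip] = s_i
                if len(w_i):
                    crossing = proj[w_i, s_i, :] >= distances[d_i][:, None]
                    node_out[w_i, d_i, iy, ip] = np.argmax(crossing, axis=1)
    else:
        for iy, yaw in enumerate(grid.yaws):
            for ip, pitch in enumerate(grid.pitches):
                normal, _ = plane_in_head_frame(HeadPose(0.0, yaw, pitch), rotation_order)
                for w, sw in enumerate(sweeps):
                    proj = sw.nodes_by_step @ normal             # (S,N)
                    run = np.maximum.accumulate(proj.max(axis=1))
                    idx = np.searchsorted(run, distances)
                    hit = idx < sw.steps
                    d_i = np.nonzero(hit)[0]
                    s_i = idx[d_i]
                    cls[w, d_i, iy, ip] = np.where(s_i == 0, CLASS_RESTING, CLASS_WHISKING)
                    theta[w, d_i, iy, ip] = sw.theta_by_step[s_i]
                    step_out[w, d_i, iy, ip] = s_i
                    if len(d_i):
                        crossing = proj[s_i, :] >= distances[d_i][:, None]
                        node_out[w, d_i, iy, ip] = np.argmax(crossing, axis=1)

    ids = [s.whisker for s in sweeps]
    return ContactTable(
        labels=[w.label for w in ids],
        rows=np.array([w.row for w in ids]),
        cols=np.array([w.col for w in ids]),
        sides=np.array([w.side for w in ids]),
        distances=distances, yaws=np.asarray(grid.yaws, float),
        pitches=np.asarray(grid.pitches, float),
        contact_class=cls, theta_impact=theta,
        contact_step=step_out, contact_node=node_out,
        meta=dict(schedule_start=schedule.start_mode,
                  step_size=schedule.step_size,
                  rotation_order=rotation_order),
    )


def _cylinder_first_contact(sweep: WhiskerSweep, pose: HeadPose, radius: float,
                            rotation_order: str = "yaw_then_pitch") -> ContactRecord:
    """First contact with a vertical cylinder tangent to the wall plane at the
    foot of the head-to-wall perpendicular, curving away from the rat."""
    normal, lateral, _ = wall_frame(pose, rotation_order)
    a = sweep.nodes_by_step @ lateral
    b = sweep.nodes_by_step @ normal - (pose.distance + radius)
    crossed = a * a + b * b <= radius * radius
    any_step = crossed.any(axis=1)
    if not any_step.any():
        return ContactRecord(sweep.whisker, pose, CLASS_NONE, np.nan, -1, -1)
    step = int(np.argmax(any_step))
    node = int(np.argmax(crossed[step]))
    cls = CLASS_RESTING if step == 0 else CLASS_WHISKING
    return ContactRecord(sweep.whisker, pose, cls,
                         float(sweep.theta_by_step[step]), step, node)


def cylinder_contact_check(array: ArraySpec, coeffs: KinematicCoeffs,
                           schedule: ProtractionSchedule, radius: float,
                           pose_subset, sweeps=None) -> pd.DataFrame:
    """Impact-angle change when the flat wall is replaced by a vertical
    cylinder of the given radius (tangent to the wall, curving away).

    Returns one row per (whisker, pose) where a whisking contact occurs in
    both conditions: plane and cylinder impact angles, their absolute
    difference, and the plane contact's lateral offset in the wall frame.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if sweeps is None:
        sweeps = sweep_all(array, coeffs, schedule)
    out = []
    for pose in pose_subset:
        normal, lateral, _ = wall_frame(pose)
        for sw in sweeps:
            rp = first_contact(sw, normal, pose.distance, pose)
            rc = _cylinder_first_contact(sw, pose, radius)
            if rp.contact_class != CLASS_WHISKING or rc.contact_class != CLASS_WHISKING:
                continue
            contact_pt = sw.nodes_by_step[rp.contact_step, rp.contact_node]
            x_off = float(contact_pt @ lateral)
            out.append(dict(
                label=sw.whisker.label, d_mm=pose.distance, yaw_deg=pose.yaw,
                pitch_deg=pose.pitch, theta_plane_deg=rp.theta_impact,
                theta_cyl_deg=rc.theta_impact,
                dtheta_deg=abs(rc.theta_impact - rp.theta_impact),
                lateral_offset_mm=x_off,
            ))
    return pd.DataFrame(out)
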