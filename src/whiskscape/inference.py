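"""Statistical analyses of the contact table.

Distance-impact-angle correlations under pose uncertainty, the uniqueness of
whole-array contact patterns across head poses, and row/column-averaged
impact-angle maps.  Only whisking contacts carry impact-angle information;
resting contacts contribute to class patterns but never to angle statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .array_model import ParameterError
from .contact_sim import CLASS_RESTING, CLASS_WHISKING, ContactTable
from .tables import ROWS


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y)[0])


def correlation_fixed_pose(table: ContactTable, pitch: float, yaw: float,
                           side: str | None = None) -> pd.DataFrame:
    """Per-whisker Pearson r between distance and impact angle at a fixed
    (pitch, yaw), over whisking contacts along the distance axis.  Whiskers
    with fewer than 3 whisking contacts get r = NaN (undefined, not 0)."""
    iy, ip = table.yaw_index(yaw), table.pitch_index(pitch)
    out = []
    for w, label in enumerate(table.labels):
        if side is not None and table.sides[w] != side:
            continue
        whisk = table.contact_class[w, :, iy, ip] == CLASS_WHISKING
        d = table.distances[whisk]
        th = table.theta_impact[w, whisk, iy, ip].astype(float)
        out.append(dict(label=label, row=table.rows[w], col=table.cols[w],
                        side=table.sides[w], n_whisking=int(whisk.sum()),
                        r=_pearson(d, th)))
    return pd.DataFrame(out)


@dataclass
class CorrelationCurve:
    axis: str                 # 'yaw' or 'pitch'
    uncertainties: np.ndarray
    r_by_row: pd.DataFrame    # index: uncertainty, columns: rows A..E
    n_by_row: pd.DataFrame


def correlation_vs_uncertainty(table: ContactTable, axis: str,
                               uncertainties, side: str = "left") -> CorrelationCurve:
    """Row-pooled distance/impact-angle correlation as the pose window widens.

    For axis='yaw', whisking contacts at pitch 0 with yaw inside a window of
    total width u centered on 0 are pooled (u=180 spans the full +/-90 grid);
    axis='pitch' mirrors this with yaw fixed at 0.  Pearson r is computed per
    row over the pooled (distance, theta_impact) pairs of all row members.
    """
    if axis not in ("yaw", "pitch"):
        raise ParameterError(f"axis must be 'yaw' or 'pitch', got {axis!r}")
    u_arr = np.asarray(uncertainties, dtype=float)
    if ((u_arr < 0) | (u_arr > 180)).any():
        raise ParameterError("uncertainties must lie in [0, 180] deg")
    wsel = table.side_mask(side)
    if axis == "yaw":
        ip = table.pitch_index(0.0)
        sweep_vals = table.yaws
        cls = table.contact_class[wsel][:, :, :, ip]       # (w, D, Y)
        th = table.theta_impact[wsel][:, :, :, ip]
    else:
        iy = table.yaw_index(0.0)
        sweep_vals = table.pitches
        cls = table.contact_class[wsel][:, :, iy, :]       # (w, D, P)
        th = table.theta_impact[wsel][:, :, iy, :]
    rows_w = table.rows[wsel]
    dist = np.broadcast_to(table.distances[None, :, None], cls.shape)

    r_rows, n_rows = {}, {}
    for row in ROWS:
        rm = rows_w == row
        r_list, n_list = [], []
        for u in u_arr:
            win = np.abs(sweep_vals) <= u / 2 + 1e-9
            pool = (cls[rm][:, :, win] == CLASS_WHISKING)
            d = dist[rm][:, :, win][pool]
            t = th[rm][:, :, win][pool].astype(float)
            r_list.append(_pearson(d, t))
            n_list.append(len(d))
        r_rows[row] = r_list
        n_rows[row] = n_list
    return CorrelationCurve(axis, u_arr,
                            pd.DataFrame(r_rows, index=u_arr),
                            pd.DataFrame(n_rows, index=u_arr))


@dataclass
class UniquenessResult:
    tolerance: float
    min_whisking: int
    n_considered: int
    n_unique: int

    @property
    def fraction_unique(self) -> float:
        return self.n_unique / self.n_considered if self.n_considered else np.nan


def _mark_nonunique(X: np.ndarray, tol: float) -> np.ndarray:
    """Boolean mask of rows of X having another row within strict Chebyshev
    distance < tol."""
    k, d = X.shape
    non = np.zeros(k, dtype=bool)
    if k * k * d <= 2e8:
        chunk = max(1, int(2e7 // (k * d)) or 1)
        for s in range(0, k, chunk):
            e = min(s + chunk, k)
            diff = np.abs(X[s:e, None, :] - X[None, :, :]).max(axis=2)
            diff[np.arange(s, e) - s, np.arange(s, e)] = np.inf
            non[s:e] |= (diff < tol).any(axis=1)
    else:
        tree = cKDTree(X)
        pairs = tree.query_pairs(r=tol, p=np.inf, output_type="ndarray")
        if len(pairs):
            dd = np.abs(X[pairs[:, 0]] - X[pairs[:, 1]]).max(axis=1)
            strict = pairs[dd < tol]
            non[strict.ravel()] = True
    return non


def uniqueness(table: ContactTable, tolerance: float,
               min_whisking: int = 0, method: str = "pairwise") -> UniquenessResult:
    """Fraction of head poses with a unique whole-array contact pattern.

    Two poses are indistinguishable iff they share the identical per-whisker
    contact-class pattern and their whisking impact angles agree to within
    the tolerance.  method='pairwise' (default) compares paired angles
    directly (strict |delta| < tolerance on every whisking whisker);
    method='binned' discretizes each whisking angle into tolerance-wide bins
    and requires identical bin vectors, which is how a database lookup over
    rounded angles would behave.  With min_whisking > 0 only poses with at
    least that many whisking contacts are considered, both as candidates and
    as comparators.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    if method not in ("pairwise", "binned"):
        raise ParameterError(f"unknown uniqueness method {method!r}")
    W = table.n_whiskers
    cls = table.contact_class.reshape(W, -1)
    th = table.theta_impact.reshape(W, -1)
    n_whisk = (cls == CLASS_WHISKING).sum(axis=0)
    considered = np.nonzero(n_whisk >= min_whisking)[0]
    n_considered = len(considered)
    if n_considered == 0:
        return UniquenessResult(tolerance, min_whisking, 0, 0)

    if method == "binned":
        bins = np.where(cls == CLASS_WHISKING,
                        np.floor(th / tolerance), -1).astype(np.int32)
        code = np.concatenate([cls.astype(np.int32), bins])[:, considered].T
        _, inv, counts = np.unique(code, axis=0, return_inverse=True,
                                   return_counts=True)
        return UniquenessResult(tolerance, min_whisking, n_considered,
                                int((counts[inv] == 1).sum()))

    patterns = np.ascontiguousarray(cls[:, considered].T)
    _, inv = np.unique(patterns, axis=0, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    inv_sorted = inv[order]
    boundaries = np.nonzero(inv_sorted[1:] != inv_sorted[:-1])[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(inv_sorted)]])

    unique = np.ones(n_considered, dtype=bool)
    for s, e in zip(starts, ends):
        members = order[s:e]
        if len(members) < 2:
            continue
        dims = np.nonzero(patterns[members[0]] == CLASS_WHISKING)[0]
        if len(dims) == 0:
            unique[members] = False
            continue
        X = th[np.ix_(dims, considered[members])].T.astype(np.float64)
        unique[members] = ~_mark_nonunique(X, tolerance)
    return UniquenessResult(tolerance, min_whisking, n_considered, int(unique.sum()))


def uniqueness_bruteforce(table: ContactTable, tolerance: float,
                          min_whisking: int = 0) -> UniquenessResult:
    """O(n^2) all-pairs reference for :func:`uniqueness` (test oracle)."""
    W = table.n_whiskers
    cls = table.contact_class.reshape(W, -1)
    th = table.theta_impact.reshape(W, -1).astype(float)
    n_whisk = (cls == CLASS_WHISKING).sum(axis=0)
    considered = np.nonzero(n_whisk >= min_whisking)[0]
    n_unique = 0
    for i in considered:
        uniq = True
        for j in considered:
            if i == j:
                continue
            if not (cls[:, i] == cls[:, j]).all():
                continue
            wh = cls[:, i] == CLASS_WHISKING
            if not wh.any() or np.all(np.abs(th[wh, i] - th[wh, j]) < tolerance):
                uniq = False
                break
        n_unique += uniq
    return UniquenessResult(tolerance, min_whisking, len(considered), n_unique)


FLAG_NONE, FLAG_RESTING_ONLY, FLAG_WHISKING = 0, 1, 2


@dataclass
class GroupAverageMap:
    grouping: str             # 'row' or 'column'
    groups: list
    distances: np.ndarray
    pitches: np.ndarray
    mean_theta: np.ndarray    # (G, D, P) float, NaN without whisking contact
    flags: np.ndarray         # (G, D, P) int8

    def max_whisking_distance(self) -> dict:
        """Largest distance with any whisking contact, per group (NaN if none)."""
        out = {}
        for g, grp in enumerate(self.groups):
            has = (self.flags[g] == FLAG_WHISKING).any(axis=1)
            out[grp] = float(self.distances[has][-1]) if has.any() else np.nan
        return out


def group_average_maps(table: ContactTable, grouping: str,
                       side: str = "left") -> GroupAverageMap:
    """Impact angle averaged within rows or columns at yaw 0, over whisking
    contacts only; cells whose group has only resting contacts are flagged."""
    if grouping not in ("row", "column"):
        raise ParameterError(f"grouping must be 'row' or 'column', got {grouping!r}")
    iy = table.yaw_index(0.0)
    wsel = table.side_mask(side)
    cls = table.contact_class[wsel][:, :, iy, :]     # (w, D, P)
    th = table.theta_impact[wsel][:, :, iy, :].astype(float)
    key = table.rows[wsel] if grouping == "row" else table.cols[wsel]
    groups = sorted(set(key.tolist()))
    G, D, P = len(groups), len(table.distances), len(table.pitches)
    mean = np.full((G, D, P), np.nan)
    flags = np.zeros((G, D, P), dtype=np.int8)
    for g, grp in enumerate(groups):
        m = key == grp
        whisk = cls[m] == CLASS_WHISKING
        n = whisk.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean[g] = np.where(n > 0, np.where(whisk, th[m], 0.0).sum(axis=0) / n, np.nan)
        any_rest = (cls[m] == CLASS_RESTING).any(axis=0)
        flags[g] = np.where(n > 0, FLAG_WHISKING,
                            np.where(any_rest, FLAG_RESTING_ONLY, FLAG_NONE))
    return GroupAverageMap(grouping, groups, table.distances, table.pitches, mean, flags)
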