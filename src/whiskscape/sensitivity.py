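"""Monte-Carlo robustness of the impact-angle maps to morphology/kinematics.

Six parameter groups vary independently per whisker: arc length (uniformly up
to 20% shorter than nominal), resting elevation and resting roll (uniformly
+/-20% of nominal), the elevation and roll coupling coefficients (normal
within their published error bounds), and basepoint position (shifted up to
15% of the nearest-neighbor distance, uniformly in direction).  Each trial
re-runs the contact simulation on a reduced pose set and the impact-angle
dispersion is pooled per whisker across all trials and poses.

Draws are made for the right-side pad and mirrored to the left, matching the
way the array itself is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_model import ArraySpec, ParameterError, mirror_array
from .contact_sim import CLASS_WHISKING, PoseGrid, simulate_grid
from .inference import _pearson
from .kinematics import KinematicCoeffs, ProtractionSchedule
from .tables import ROWS


@dataclass(frozen=True)
class PerturbationSpec:
    """Magnitudes of the six perturbation groups (fractions / deg bounds)."""

    length_shrink_max: float = 0.20
    rest_scale_max: float = 0.20          # phi_0 and zeta_0, +/- fraction
    coeff_mode: str = "truncnorm"          # or 'uniform' on the bounds
    coeff_bound_scale: float = 1.0         # scales the published error bounds
    basepoint_frac_max: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.coeff_mode not in ("truncnorm", "uniform"):
            raise ParameterError(f"unknown coeff_mode {self.coeff_mode!r}")


def _truncated_normal(rng: np.random.Generator, bound: float, size=None) -> np.ndarray:
    """Normal with sigma = bound/2, truncated at +/-bound (rejection)."""
    if bound == 0:
        return np.zeros(size if size is not None else ())
    out = np.asarray(rng.normal(0.0, bound / 2.0, size=size))
    bad = np.abs(out) > bound
    while np.any(bad):
        out = np.where(bad, rng.normal(0.0, bound / 2.0, size=out.shape), out)
        bad = np.abs(out) > bound
    return out


def _coeff_draw(rng, bound, mode):
    if mode == "uniform":
        return rng.uniform(-bound, bound)
    return float(_truncated_normal(rng, bound))


def _nearest_neighbor_distances(specs) -> np.ndarray:
    pts = np.array([w.basepoint for w in specs])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(d2.min(axis=1))


def draw_perturbed_array(base: ArraySpec, coeffs: KinematicCoeffs,
                         spec: PerturbationSpec,
                         rng: np.random.Generator | None = None
                         ) -> tuple[ArraySpec, KinematicCoeffs]:
    """One random morphology/kinematics draw; base inputs are unmodified."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    right = list(base.side("right"))
    if not right:
        raise ParameterError("base array has no right side to perturb")
    has_left = len(base.side("left")) > 0
    nn = _nearest_neighbor_distances(right)
    new_right = []
    overrides = {}
    for w, nn_d in zip(right, nn):
        rowc = coeffs.rows[w.id.row]
        shrink = rng.uniform(0.0, spec.length_shrink_max)
        phi_scale = rng.uniform(-spec.rest_scale_max, spec.rest_scale_max)
        zeta_scale = rng.uniform(-spec.rest_scale_max, spec.rest_scale_max)
        phi_jitter = _coeff_draw(rng, rowc["phi_bound"] * spec.coeff_bound_scale,
                                 spec.coeff_mode)
        zeta_jitter = _coeff_draw(rng, rowc["zeta_bound"] * spec.coeff_bound_scale,
                                  spec.coeff_mode)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = rng.uniform(0.0, spec.basepoint_frac_max * nn_d) * direction
        new_right.append(replace(
            w,
            length=w.length * (1.0 - shrink),
            phi_rest=w.phi_rest * (1.0 + phi_scale),
            zeta_rest=w.zeta_rest * (1.0 + zeta_scale),
            basepoint=(w.basepoint[0] + shift[0], w.basepoint[1] + shift[1],
                       w.basepoint[2] + shift[2]),
        ))
        if phi_jitter != 0.0 or zeta_jitter != 0.0:
            ov = dict(phi_intercept_delta=phi_jitter,
                      zeta_slope=rowc["zeta_slope"] + zeta_jitter)
            overrides[w.id.label] = ov
            if has_left:
                overrides[w.id.mirrored().label] = dict(ov)
    whiskers = tuple(new_right)
    if has_left:
        whiskers = whiskers + mirror_array(new_right)
    return ArraySpec(whiskers), coeffs.with_overrides(overrides)


def default_config_set() -> PoseGrid:
    """Reduced pose set of the robustness study: distances 0-60 mm step 5,
    pitches -90..90 step 30, yaw fixed at 0."""
    return PoseGrid(distances=np.arange(0.0, 61.0, 5.0),
                    yaws=np.array([0.0]),
                    pitches=np.arange(-90.0, 91.0, 30.0))


@dataclass
class SensitivitySummary:
    per_whisker: pd.DataFrame      # label, row, col, mean/std theta, n trials
    reps: int
    n_configs: int
    spec: PerturbationSpec
    meta: dict = field(default_factory=dict)


def run_sensitivity(base: ArraySpec, coeffs: KinematicCoeffs,
                    config_set: PoseGrid | None = None, reps: int = 100,
                    seed: int = 0,
                    spec: PerturbationSpec | None = None) -> SensitivitySummary:
    """Pooled impact-angle statistics over parameter-varied simulations.

    Statistics are computed per whisker over whisking contacts only, pooled
    across all (configuration, repetition) trials.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    grid = config_set or default_config_set()
    if grid.n_poses == 0:
        raise ParameterError("empty configuration set")
    spec = spec or PerturbationSpec(seed=seed)
    rng = np.random.default_rng(seed)
    schedule = ProtractionSchedule()
    right = ArraySpec(tuple(base.side("right")))
    labels = [w.id.label for w in right]
    W = len(labels)
    shape = (W, len(grid.distances), len(grid.yaws), len(grid.pitches))
    s1 = np.zeros(shape)        # per-(whisker, config) running moments
    s2 = np.zeros(shape)
    n = np.zeros(shape, dtype=np.int64)
    for _ in range(reps):
        arr, cf = draw_perturbed_array(right, coeffs, spec, rng)
        table = simulate_grid(arr, cf, schedule, grid)
        whisk = table.contact_class == CLASS_WHISKING
        th = np.where(whisk, table.theta_impact.astype(float), 0.0)
        s1 += th
        s2 += th ** 2
        n += whisk
    rows = []
    for w, (spec_w, lab) in enumerate(zip(right, labels)):
        n_w = n[w]
        n_tot = int(n_w.sum())
        if n_tot:
            mean = s1[w].sum() / n_tot
            pooled_var = max(s2[w].sum() / n_tot - mean ** 2, 0.0)
            # dispersion attributable to parameter variation: variance within
            # each head configuration (across trials), pooled over configs
            multi = n_w >= 2
            if multi.any():
                m_c = s1[w][multi] / n_w[multi]
                var_c = np.maximum(s2[w][multi] / n_w[multi] - m_c ** 2, 0.0)
                within = np.sqrt((var_c * n_w[multi]).sum() / n_w[multi].sum())
            else:
                within = 0.0
        else:
            mean = pooled_var = within = np.nan
        rows.append(dict(label=lab, row=spec_w.id.row, col=spec_w.id.col,
                         mean_theta_impact_deg=mean,
                         std_theta_impact_deg=np.sqrt(pooled_var),
                         within_config_std_deg=within,
                         n_contact_trials=n_tot))
    return SensitivitySummary(pd.DataFrame(rows), reps, grid.n_poses, spec,
                              meta=dict(seed=seed))


def pitch_robustness_replicates(base: ArraySpec, coeffs: KinematicCoeffs,
                                n_replicates: int = 50, seed: int = 0,
                                uncertainty: float = 90.0,
                                spec: PerturbationSpec | None = None) -> pd.DataFrame:
    """Row-pooled distance/impact-angle correlation under pitch uncertainty,
    per perturbed replicate (yaw 0).  Used to check that the interior-row
    robustness ordering survives morphological perturbation."""
    spec = spec or PerturbationSpec(seed=seed)
    rng = np.random.default_rng(seed)
    half = uncertainty / 2.0
    grid = PoseGrid(distances=np.arange(0.0, 61.0, 5.0),
                    yaws=np.array([0.0]),
                    pitches=np.arange(-half, half + 1e-9, 5.0))
    schedule = ProtractionSchedule()
    right = ArraySpec(tuple(base.side("right")))
    out = []
    for rep in range(n_replicates):
        arr, cf = draw_perturbed_array(right, coeffs, spec, rng)
        table = simulate_grid(arr, cf, schedule, grid)
        rec = dict(replicate=rep)
        dist = np.broadcast_to(table.distances[None, :, None, None],
                               table.contact_class.shape)
        for row in ROWS:
            m = table.rows == row
            pool = table.contact_class[m] == CLASS_WHISKING
            d = dist[m][pool]
            t = table.theta_impact[m][pool].astype(float)
            rec[row] = _pearson(d, t)
        out.append(rec)
    return pd.DataFrame(out)
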