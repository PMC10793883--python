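"""Behavioral and neural learning metrics.

Covers: trajectory straightness scores, output-potent/output-null
group activity (with the medium-speed filter), direction-tuning fits
(preferred direction, tuning depth, R^2), the normalized |PD - AD|
statistic, logistic success-rate trends across sessions, trajectory
occupancy grids, and per-direction success rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .config import DecoderConfig
from .grouping import sector_of
from .session_log import SessionLog

__all__ = [
    "DirectionTuningFit",
    "PotentNullSeries",
    "LearningTrend",
    "trajectory_score",
    "potent_null_values",
    "session_potent_null",
    "fit_direction_tuning",
    "pd_ad_distance",
    "fit_success_logistic",
    "occupancy_map",
    "direction_binned_success",
    "unit_tuning_table",
]

#: toward-group column index per sector label, and its opposing group
_TOWARD = {"right": 0, "left": 1, "up": 2, "down": 3}
_AWAY = {0: 1, 1: 0, 2: 3, 3: 2}


# -- trajectory metrics --------------------------------------------------

def trajectory_score(
    trajectory: np.ndarray,
    start: tuple[float, float] | None = None,
    target_center: tuple[float, float] | None = None,
) -> float:
    """Path length divided by start-to-target-center distance.

    1 means perfectly straight; larger is more tortuous.  ``start``
    defaults to the trajectory's first point.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2 or traj.shape[0] < 1:
        raise ValueError("trajectory must be an (n, 2) array")
    if start is None:
        start = tuple(traj[0])
    if target_center is None:
        raise ValueError("target_center is required")
    chord = math.hypot(target_center[0] - start[0], target_center[1] - start[1])
    if chord == 0.0:
        raise ValueError("degenerate trial: start coincides with target center")
    seg = np.diff(traj, axis=0)
    path = float(np.sqrt((seg**2).sum(axis=1)).sum())
    return path / chord


def occupancy_map(
    trajectories: list[np.ndarray],
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> np.ndarray:
    """Per-cell visit counts pooled over trajectories.

    Returns an (len(x_edges)-1, len(y_edges)-1) integer grid.  Every
    logged position falls in some cell as long as the grid covers the
    workspace.
    """
    grid = np.zeros((len(x_edges) - 1, len(y_edges) - 1), dtype=np.int64)
    for traj in trajectories:
        traj = np.asarray(traj, dtype=float)
        h, _, _ = np.histogram2d(traj[:, 0], traj[:, 1], bins=[x_edges, y_edges])
        grid += h.astype(np.int64)
    return grid


# -- output-potent / output-null ----------------------------------------

@dataclass(frozen=True)
class PotentNullSeries:
    """Per-bin potent/null values for one trial, plus their means.

    potent = a_toward - a_away (drives the cursor toward the target);
    null = a_toward + a_away (no effect on the driven axis).  Since
    action values are non-negative, null >= |potent| pointwise.
    """

    potent: np.ndarray
    null: np.ndarray
    n_filtered_out: int = 0

    @property
    def mean_potent(self) -> float:
        return float(np.mean(self.potent)) if self.potent.size else float("nan")

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null)) if self.null.size else float("nan")

    @property
    def empty(self) -> bool:
        return self.potent.size == 0


def potent_null_values(
    action_series: np.ndarray,
    target_angle: float,
    cfg: DecoderConfig,
    speeds: np.ndarray | None = None,
    speed_filter: bool = False,
) -> PotentNullSeries:
    """Potent/null series for one trial's action values.

    ``action_series`` is (n_bins, 4) in group order (right, left, up,
    down); the target's sector picks the toward/away pair.  With
    ``speed_filter`` only bins whose cursor speed lies in
    [0.25, 0.75] * v_max (the medium-speed criterion) are kept;
    ``speeds`` must then be supplied, aligned with the series.
    """
    a = np.asarray(action_series, dtype=float)
    if a.ndim != 2 or a.shape[1] != 4:
        raise ValueError("action_series must be (n_bins, 4)")
    toward = _TOWARD[sector_of(target_angle)]
    away = _AWAY[toward]
    potent = a[:, toward] - a[:, away]
    null = a[:, toward] + a[:, away]
    n_out = 0
    if speed_filter:
        if speeds is None:
            raise ValueError("speed_filter requires aligned cursor speeds")
        speeds = np.asarray(speeds, dtype=float)
        if speeds.shape[0] != a.shape[0]:
            raise ValueError("speeds not aligned with action_series")
        keep = (speeds >= 0.25 * cfg.v_max) & (speeds <= 0.75 * cfg.v_max)
        n_out = int((~keep).sum())
        potent, null = potent[keep], null[keep]
    return PotentNullSeries(potent=potent, null=null, n_filtered_out=n_out)


def session_potent_null(
    log: SessionLog, speed_filter: bool = False, successful_only: bool = False
) -> pd.DataFrame:
    """Per-trial mean potent/null values for a session.

    Trials with no bins surviving the medium-speed filter are flagged
    (``excluded`` column) and carry NaN means.
    """
    rows = []
    for tr in log.trials:
        if successful_only and not tr.success:
            continue
        a = log.trial_action_values(tr)
        sl = log.frames.iloc[tr.movement_start_bin:tr.end_bin]
        speeds = np.hypot(sl["vx"].to_numpy(), sl["vy"].to_numpy())
        series = potent_null_values(
            a, tr.target_angle, log.decoder_cfg, speeds=speeds, speed_filter=speed_filter
        )
        rows.append(
            {
                "trial": tr.index,
                "target_angle": tr.target_angle,
                "outcome": tr.outcome,
                "mean_potent": series.mean_potent,
                "mean_null": series.mean_null,
                "excluded": series.empty,
            }
        )
    return pd.DataFrame(rows)


# -- direction tuning ----------------------------------------------------

@dataclass(frozen=True)
class DirectionTuningFit:
    """Cosine tuning fit fr = b0 + b1 cos(theta) + b2 sin(theta)."""

    b0: float
    b1: float
    b2: float
    pd_angle: float
    tuning_depth: float
    r2: float

    def __post_init__(self) -> None:
        if self.tuning_depth < 0:
            raise ValueError("tuning_depth must be >= 0")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


def fit_direction_tuning(rates: np.ndarray, target_angle: np.ndarray) -> DirectionTuningFit:
    """Least squares of firing rate on (1, cos theta, sin theta).

    PD = atan2(b2, b1); tuning depth = 2 * ||(b1, b2)|| (peak-to-trough
    of the fitted cosine).  For relative-direction analyses the caller
    supplies target angles relative to cursor direction.
    """
    rates = np.asarray(rates, dtype=float)
    theta = np.asarray(target_angle, dtype=float)
    if rates.shape[0] != theta.shape[0] or rates.shape[0] < 3:
        raise ValueError("need >= 3 matched (rate, angle) bins")
    if np.unique(np.round(np.remainder(theta, 2 * math.pi), 12)).size < 3:
        raise ValueError("need >= 3 distinct target angles for a cosine fit")
    X = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    beta, _, _, _ = np.linalg.lstsq(X, rates, rcond=None)
    resid = rates - X @ beta
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    b0, b1, b2 = (float(b) for b in beta)
    return DirectionTuningFit(
        b0=b0, b1=b1, b2=b2,
        pd_angle=math.atan2(b2, b1),
        tuning_depth=2.0 * math.hypot(b1, b2),
        r2=float(np.clip(r2, 0.0, 1.0)),
    )


def pd_ad_distance(pd_angle: float, ad_angle: float) -> float:
    """Normalized |PD - AD|: angular difference mapped from [-pi, pi]
    to [0, 1] — 0 for identical directions, 1 for opposite."""
    return abs(math.remainder(pd_angle - ad_angle, 2 * math.pi)) / math.pi


def unit_tuning_table(
    log: SessionLog, speed_filter: bool = False
) -> pd.DataFrame:
    """Direction-tuning fit of every channel over a session's movement bins.

    Rates are the 100 ms binned rates (Hz); the regressor is the
    current target's direction.  Bins outside trials or in freeze
    periods are excluded, and optionally bins failing the medium-speed
    criterion.
    """
    mask = log.movement_bin_mask()
    factor = int(round(log.decoder_cfg.bin_width / log.spikes.bin_width))
    binned = log.spikes.rebin(factor)[: len(log.frames)]
    angles = np.full(len(log.frames), np.nan)
    for tr in log.trials:
        angles[tr.movement_start_bin:tr.end_bin] = tr.target_angle
    keep = mask & np.isfinite(angles)
    if speed_filter:
        speeds = np.hypot(log.frames["vx"].to_numpy(), log.frames["vy"].to_numpy())
        keep &= (speeds >= 0.25 * log.decoder_cfg.v_max) & (speeds <= 0.75 * log.decoder_cfg.v_max)
    rates = binned[keep] / log.decoder_cfg.bin_width
    theta = angles[keep]
    rows = []
    direct = set(log.group_spec.channels)
    for j, ch in enumerate(log.spikes.channel_ids):
        fit = fit_direction_tuning(rates[:, j], theta)
        rows.append(
            {
                "channel_id": ch,
                "direct": j in direct,
                "b0": fit.b0, "b1": fit.b1, "b2": fit.b2,
                "pd_angle": fit.pd_angle,
                "tuning_depth": fit.tuning_depth,
                "r2": fit.r2,
            }
        )
    return pd.DataFrame(rows)


# -- success-rate trends -------------------------------------------------

@dataclass(frozen=True)
class LearningTrend:
    """Logistic fit of trial outcome on session index."""

    intercept: float
    slope: float
    slope_p: float
    pseudo_r2: float
    per_session_success: dict[int, float]
    separation: bool = False


def fit_success_logistic(
    session_index: np.ndarray, outcome: np.ndarray
) -> LearningTrend:
    """Logistic regression of binary trial outcome on session index.

    Reports the Wald p-value of the slope and McFadden's pseudo-R^2.
    Complete separation (including constant outcomes) is flagged and a
    ridge-penalized fit is used instead; its p-value is NaN.
    """
    s = np.asarray(session_index, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.shape != y.shape or s.size == 0:
        raise ValueError("session_index and outcome must be equal-length, non-empty")
    if np.unique(s).size < 2:
        raise ValueError("need trials from at least 2 sessions")
    # aggregate to per-session binomial counts: equivalent likelihood, faster
    sess = np.unique(s)
    k = np.array([y[s == v].sum() for v in sess])
    n = np.array([(s == v).sum() for v in sess])
    per_session = {int(v): float(ki / ni) for v, ki, ni in zip(sess, k, n)}
    X = sm.add_constant(sess)
    endog = np.column_stack([k, n - k])
    separation = bool(np.all(k == 0) or np.all(k == n))
    params = None
    slope_p = float("nan")
    if not separation:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
                params = np.asarray(res.params)
                if np.any(np.abs(params) > 30):
                    separation = True
                else:
                    slope_p = float(res.pvalues[1])
            except (PerfectSeparationError, PerfectSeparationWarning,
                    ConvergenceWarning, np.linalg.LinAlgError, ValueError):
                separation = True
    if separation:
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1.0, L1_wt=0.0
        )
        params = np.asarray(res.params)
        slope_p = float("nan")
    # McFadden pseudo-R^2 on the Bernoulli log-likelihood scale
    p_hat = 1.0 / (1.0 + np.exp(-(X @ params)))
    p_hat = np.clip(p_hat, 1e-12, 1 - 1e-12)
    llf = float(np.sum(k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)))
    p_bar = np.clip(k.sum() / n.sum(), 1e-12, 1 - 1e-12)
    llnull = float(k.sum() * np.log(p_bar) + (n.sum() - k.sum()) * np.log(1 - p_bar))
    pseudo_r2 = 0.0 if llnull == 0 else 1.0 - llf / llnull
    return LearningTrend(
        intercept=float(params[0]),
        slope=float(params[1]),
        slope_p=slope_p,
        pseudo_r2=float(pseudo_r2),
        per_session_success=per_session,
        separation=separation,
    )


def direction_binned_success(
    trials, n_bins: int = 4
) -> dict[str, float]:
    """Success proportion per angular quadrant of the target direction.

    Uses the same half-open sector convention as neuron grouping.
    Empty quadrants are reported as NaN.  Only four bins are supported
    (the sector scheme).
    """
    if n_bins != 4:
        raise ValueError("only the 4-sector binning is supported")
    succ: dict[str, list[bool]] = {lab: [] for lab in ("right", "up", "left", "down")}
    for tr in trials:
        succ[sector_of(tr.target_angle)].append(tr.success)
    return {
        lab: (float(np.mean(v)) if v else float("nan")) for lab, v in succ.items()
    }
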