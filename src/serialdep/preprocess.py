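"""Trial- and subject-level preprocessing of delayed-response data.

Steps, in the order the full pipeline applies them:

1. signed raw error per trial (response − stimulus, wrapped);
2. trial-history annotation (x_prev, previous delay, x_next) — computed
   *before* any trial is dropped, because a dropped trial's stimulus was
   still seen and therefore still biases the following trial;
3. trial filters: near-origin responses (eccentricity < 5° of visual angle)
   and errors further than 3 SD from the subject's mean error;
4. removal of stimulus-location-dependent systematic error by circular
   locally weighted regression (LOESS), per subject; the residual error is
   the quantity all tuning analyses operate on;
5. subject exclusion: overall mean absolute error greater than 10° of polar
   angle (strict inequality).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._angles import wrap_signed

ORIGIN_ECC_DEG = 5.0
SD_CRITERION = 3.0
EXCLUSION_DEG = 10.0
MIN_TRIALS_PER_SUBJECT = 10


@dataclass
class SubjectSummary:
    subject_id: str
    n_trials_total: int
    n_dropped_origin: int
    n_dropped_3sd: int
    mean_abs_error: float  # degrees, over surviving trials
    excluded: bool = False
    low_n: bool = False  # fewer than MIN_TRIALS_PER_SUBJECT survivors

    def to_dict(self):
        return asdict(self)


def add_raw_error(table: pd.DataFrame) -> pd.DataFrame:
    """Append raw_error = wrap(response_angle − stimulus_angle), degrees."""
    out = table.copy()
    out["raw_error"] = wrap_signed(
        out["response_angle"].to_numpy(dtype=float)
        - out["stimulus_angle"].to_numpy(dtype=float)
    )
    return out


def annotate_history(table: pd.DataFrame) -> pd.DataFrame:
    """Append x_prev, prev_delay_s and x_next, per subject.

    ``x_prev`` is the previous stimulus angle minus the current one, wrapped
    to (−180, 180] (positive error = counterclockwise, so attraction means
    the error shares the sign of x_prev); ``x_next`` is the same quantity for
    the upcoming trial, the future-trial control predictor. History never
    crosses subject boundaries (nor block boundaries, if a ``block`` column
    is present). First/last trials get NaN.
    """
    out = table.copy()
    group_cols = ["subject_id"] + (["block"] if "block" in out.columns else [])
    x_prev = np.full(len(out), np.nan)
    prev_delay = np.full(len(out), np.nan)
    x_next = np.full(len(out), np.nan)
    pos = np.arange(len(out))
    for _, g in out.groupby(group_cols, sort=False):
        idx = g["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError("trials must be ordered by trial_index within subject")
        stim = g["stimulus_angle"].to_numpy(dtype=float)
        rows = pos[out.index.get_indexer(g.index)]
        if len(stim) > 1:
            x_prev[rows[1:]] = wrap_signed(stim[:-1] - stim[1:])
            prev_delay[rows[1:]] = g["delay_s"].to_numpy(dtype=float)[:-1]
            x_next[rows[:-1]] = wrap_signed(stim[1:] - stim[:-1])
    out["x_prev"] = x_prev
    out["prev_delay_s"] = prev_delay
    out["x_next"] = x_next
    return out


def filter_trials(table: pd.DataFrame):
    """Drop invalid trials; return (filtered table, per-subject summaries).

    First removes responses within 5° of visual angle of the origin, then —
    per subject, in one pass on the survivors — trials whose signed raw error
    lies further than 3 SD from the subject's mean raw error. Subjects left
    with fewer than 10 trials are flagged (``low_n``), not silently fit.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    work = table if "raw_error" in table.columns else add_raw_error(table)
    keep_frames = []
    summaries = []
    for sid, g in work.groupby("subject_id", sort=False):
        n_total = len(g)
        ecc_ok = g["response_eccentricity"].to_numpy(dtype=float) >= ORIGIN_ECC_DEG
        n_origin = int((~ecc_ok).sum())
        g1 = g.loc[ecc_ok]
        e = g1["raw_error"].to_numpy(dtype=float)
        if len(e) >= 2:
            mu, sd = e.mean(), e.std(ddof=1)
            in_sd = np.abs(e - mu) <= SD_CRITERION * sd if sd > 0 else np.ones(len(e), bool)
        else:
            in_sd = np.ones(len(e), bool)
        n_3sd = int((~in_sd).sum())
        g2 = g1.loc[in_sd]
        mae = float(np.abs(g2["raw_error"]).mean()) if len(g2) else np.nan
        summaries.append(
            SubjectSummary(
                subject_id=str(sid),
                n_trials_total=n_total,
                n_dropped_origin=n_origin,
                n_dropped_3sd=n_3sd,
                mean_abs_error=mae,
                low_n=len(g2) < MIN_TRIALS_PER_SUBJECT,
            )
        )
        keep_frames.append(g2)
    filtered = pd.concat(keep_frames) if keep_frames else work.iloc[:0]
    return filtered, summaries


def estimate_systematic_error(stimulus_angles, raw_errors, span=0.3):
    """Estimate the smooth stimulus-location-dependent error by circular LOESS.

    Locally weighted linear regression (tricube weights) of raw error on
    stimulus angle, made periodic by concatenating the data shifted by ±360°
    and evaluating on the central copy. Returns a callable ``bias(theta_deg)``
    with period 360°, constrained so that its mean over [0, 360) equals the
    mean raw error.
    """
    theta = np.asarray(stimulus_angles, dtype=float)
    err = np.asarray(raw_errors, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(err)
    theta, err = theta[ok], err[ok]
    if len(theta) < 50:
        raise ValueError("need at least 50 trials to estimate systematic error")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if np.ptp(theta) < 1e-9:
        raise ValueError("degenerate input: all stimulus angles identical")
    theta3 = np.concatenate([theta - 360.0, theta, theta + 360.0])
    err3 = np.tile(err, 3)
    grid = np.arange(0.0, 360.0, 1.0)
    # span is relative to one copy of the data; the padded set is 3x larger
    est = lowess(err3, theta3, frac=span / 3.0, it=1, xvals=grid)
    est = est - est.mean() + err.mean()

    grid_closed = np.append(grid, 360.0)
    est_closed = np.append(est, est[0])

    def bias(angle_deg):
        a = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
        out = np.interp(a, grid_closed, est_closed)
        return float(out) if np.ndim(angle_deg) == 0 else out

    return bias


def residualize(table: pd.DataFrame, bias_fn) -> pd.DataFrame:
    """Append residual_error = wrap(raw_error − bias_fn(stimulus_angle))."""
    out = table.copy()
    est = bias_fn(out["stimulus_angle"].to_numpy(dtype=float))
    out["residual_error"] = wrap_signed(out["raw_error"].to_numpy(dtype=float) - est)
    return out


def exclude_subjects(summaries, threshold_deg=EXCLUSION_DEG):
    """Flag subjects whose mean absolute error strictly exceeds the threshold."""
    for s in summaries:
        s.excluded = bool(np.isfinite(s.mean_abs_error) and s.mean_abs_error > threshold_deg)
    return summaries


def preprocess_session(table: pd.DataFrame, span=0.3, exclusion_deg=EXCLUSION_DEG):
    """Run the full preprocessing chain on a raw trial table.

    Returns (annotated table of valid trials with residual errors, subject
    summaries). Trials dropped by the filters still act as history donors for
    x_prev of the following trial; subjects flagged as excluded are removed
    from the returned table.
    """
    work = add_raw_error(table)
    work = annotate_history(work)
    filtered, summaries = filter_trials(work)
    frames = []
    for sid, g in filtered.groupby("subject_id", sort=False):
        bias = estimate_systematic_error(
            g["stimulus_angle"].to_numpy(dtype=float),
            g["raw_error"].to_numpy(dtype=float),
            span=span,
        )
        frames.append(residualize(g, bias))
    out = pd.concat(frames) if frames else filtered
    summaries = exclude_subjects(summaries, threshold_deg=exclusion_deg)
    bad = {s.subject_id for s in summaries if s.excluded or s.low_n}
    out = out.loc[~out["subject_id"].astype(str).isin(bad)].reset_index(drop=True)
    out["valid"] = True
    return out, summaries
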