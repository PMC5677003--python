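"""Trial-history tuning curves and their least-squares fits.

Serial dependence (and its repulsive counterpart, adaptation) is quantified
by fitting a tuning function to the scatter of signed response errors ``y``
against the relative angle of the previous trial's stimulus ``x`` (both in
degrees, on (−180, 180]). Two shapes are supported:

* the derivative of Gaussian (DoG), ``y = x a w c exp(−(wx)²)`` with
  ``c = √2·e^{1/2}`` so the amplitude ``a`` equals the curve's peak height;
* the Clifford adaptation function, defined implicitly by
  ``sin(y + x) = sin x / √((s·cos x − c)² + sin²x)`` and able to express
  "peripheral bumps" (bias reversal at large |x|).

The effect size is the signed peak-to-peak of the fitted curve: max − min
over the full range of ``x``, with the sign of the small-positive-``x`` peak
(positive = attraction toward the previous stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._angles import DEG2RAD, RAD2DEG, wrap_signed

#: DoG normalizing constant √2/e^{−1/2}: makes the amplitude equal the peak height.
DOG_C = np.sqrt(2.0) * np.exp(0.5)

#: width bounds keeping the DoG peaks on-domain and the curve non-degenerate
W_MIN, W_MAX = 1e-4, 0.2


@dataclass(frozen=True)
class DoGParams:
    a: float  # signed amplitude, degrees (peak height)
    w: float  # width, per degree

    def __post_init__(self):
        if not self.w > 0:
            raise ValueError("DoG width w must be > 0")


@dataclass(frozen=True)
class CliffordParams:
    s_scale: float
    c_center: float
    sign: int = 1  # +1: raw adaptation orientation; −1: mirrored

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        x = np.linspace(-np.pi, np.pi, 721)
        denom = np.hypot(self.s_scale * np.cos(x) - self.c_center, np.sin(x))
        if not np.all(denom > 1e-9):
            raise ValueError("degenerate Clifford parameters: curve undefined")


@dataclass
class TuningFit:
    model: str  # "dog" | "clifford"
    params: object
    peak_to_peak: float  # signed degrees
    sse: float
    n: int
    converged: bool = True

    def curve(self, x):
        if self.model == "dog":
            return dog_curve(x, self.params)
        return clifford_curve(x, self.params)

    def to_dict(self):
        p = self.params
        if self.model == "dog":
            pdict = {"a": p.a, "w": p.w}
        else:
            pdict = {"s_scale": p.s_scale, "c_center": p.c_center, "sign": p.sign}
        return {
            "model": self.model,
            "params": pdict,
            "peak_to_peak": self.peak_to_peak,
            "sse": self.sse,
            "n": self.n,
            "converged": self.converged,
        }


@dataclass
class PowerLawFit:
    scale: float  # squared degrees
    t_offset: float  # seconds, > 0
    beta: float
    sse: float
    sse_linear: float
    linear_coef: tuple  # (slope, intercept)

    def predict(self, delay_s):
        return self.scale * (np.asarray(delay_s, dtype=float) + self.t_offset) ** self.beta


# ---------------------------------------------------------------------------
# curves


def dog_curve(x, params: DoGParams):
    """Derivative-of-Gaussian tuning curve, degrees in / degrees out."""
    x = np.asarray(x, dtype=float)
    wx = params.w * x
    return x * params.a * params.w * DOG_C * np.exp(-(wx**2))


def clifford_curve(x, params: CliffordParams):
    """Clifford tuning curve, degrees in / degrees out.

    Computed by the vector-angle construction: the response to a stimulus at
    angle ``x`` maps to the direction of the vector
    ``(s·cos x − c, sin x)``; the curve is the (wrapped) difference between
    that direction and ``x``. This picks, among the two arcsine branches of
    the implicit definition, the one continuous through y(0) = 0.
    """
    xr = np.asarray(x, dtype=float) * DEG2RAD
    theta = np.arctan2(np.sin(xr), params.s_scale * np.cos(xr) - params.c_center)
    y = wrap_signed((theta - xr) * RAD2DEG)
    return params.sign * y


# ---------------------------------------------------------------------------
# profiled DoG least squares (linear in the amplitude given the width)


def _dog_gain(x, w):
    """DoG with unit amplitude: dog_curve(x; a=1, w). Broadcasts."""
    wx = w * x
    return wx * DOG_C * np.exp(-(wx**2))


def _coarse_w_grid(n=40):
    return np.geomspace(W_MIN, W_MAX, n)


def profile_dog_batch(x_mat, y_mat, n_coarse=40, n_refine=2, n_zoom=9):
    """Profiled DoG least squares for a batch of datasets.

    ``x_mat``/``y_mat`` have shape (B, n): B independent datasets of n trials
    each. For fixed width ``w`` the model is linear in the amplitude, so
    ``â(w) = Σg·y / Σg²`` with ``g = dog(x; 1, w)``; the width is profiled on
    a log-spaced grid and refined by local grid zoom. Returns arrays
    (a_hat, w_hat, sse), each of shape (B,).

    This is the workhorse behind permutation and bootstrap resampling, where
    thousands of refits are needed.
    """
    x_mat = np.atleast_2d(np.asarray(x_mat, dtype=float))
    y_mat = np.atleast_2d(np.asarray(y_mat, dtype=float))
    if y_mat.shape[0] == 1 and x_mat.shape[0] > 1:
        y_mat = np.broadcast_to(y_mat, x_mat.shape)
    B = x_mat.shape[0]
    yy = (y_mat**2).sum(axis=1)

    def sse_at(w_col):
        # w_col: (B,) candidate width per dataset
        g = _dog_gain(x_mat, w_col[:, None])
        num = (g * y_mat).sum(axis=1)
        den = (g * g).sum(axis=1)
        den = np.where(den <= 0, np.inf, den)
        a = num / den
        return a, yy - num**2 / den

    w_grid = _coarse_w_grid(n_coarse)
    best_sse = np.full(B, np.inf)
    best_a = np.zeros(B)
    best_w = np.full(B, w_grid[0])
    for w in w_grid:
        a, sse = sse_at(np.full(B, w))
        better = sse < best_sse - 1e-12
        best_sse[better] = sse[better]
        best_a[better] = a[better]
        best_w[better] = w

    step = np.log(w_grid[1] / w_grid[0])
    for _ in range(n_refine):
        offsets = np.linspace(-step, step, n_zoom)
        logw0 = np.log(best_w)
        for off in offsets:
            w_col = np.clip(np.exp(logw0 + off), W_MIN, W_MAX)
            a, sse = sse_at(w_col)
            better = sse < best_sse - 1e-12
            best_sse[better] = sse[better]
            best_a[better] = a[better]
            best_w[better] = w_col[better]
        step = 2.0 * step / (n_zoom - 1)

    return best_a, best_w, np.maximum(best_sse, 0.0)


def dog_peak_to_peak_analytic(a, w):
    """Signed peak-to-peak of a DoG; vectorized over (a, w).

    Equals 2a whenever the peaks ±1/(w√2) fall inside [−180, 180]; for
    narrower widths the extrema sit at the domain boundary.
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    on_domain = 1.0 / (w * np.sqrt(2.0)) <= 180.0
    boundary = 180.0 * a * w * DOG_C * np.exp(-((w * 180.0) ** 2))
    return np.where(on_domain, 2.0 * a, 2.0 * boundary)


# ---------------------------------------------------------------------------
# fitting


def fit_tuning(x, y, model="dog") -> TuningFit:
    """Nonlinear least-squares fit of a tuning curve to (x, y) pairs.

    DoG: profiled grid search over the width followed by a Levenberg–
    Marquardt polish (deterministic; ties favor the smaller |a|). Clifford:
    multi-start trust-region least squares over (s, c) for both curve
    orientations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 20:
        raise ValueError("need at least 20 (x, y) pairs")
    if model == "dog":
        return _fit_dog(x, y)
    if model == "clifford":
        return _fit_clifford(x, y)
    raise ValueError(f"unknown tuning model: {model!r}")


def _fit_dog(x, y) -> TuningFit:
    a0, w0, sse0 = profile_dog_batch(x[None, :], y[None, :])
    a0, w0, sse0 = float(a0[0]), float(w0[0]), float(sse0[0])

    def resid(p):
        return _dog_gain(x, np.clip(p[1], W_MIN, W_MAX)) * p[0] - y

    sol = optimize.least_squares(
        resid,
        x0=[a0, w0],
        bounds=([-np.inf, W_MIN], [np.inf, W_MAX]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    a, w = float(sol.x[0]), float(np.clip(sol.x[1], W_MIN, W_MAX))
    sse = float((resid([a, w]) ** 2).sum())
    if sse > sse0 + 1e-12:  # polish must not lose to the grid solution
        a, w, sse = a0, w0, sse0
    params = DoGParams(a=a, w=w)
    fit = TuningFit("dog", params, 0.0, sse, len(x), converged=True)
    fit.peak_to_peak = peak_to_peak(fit)
    return fit


_CLIFFORD_STARTS = [(s, c) for s in (0.8, 1.0, 1.2) for c in (-0.3, 0.0, 0.3)]


def _clifford_raw(xr, s, c):
    theta = np.arctan2(np.sin(xr), s * np.cos(xr) - c)
    d = theta - xr
    return np.arctan2(np.sin(d), np.cos(d))  # wrap to (−π, π]


def _fit_clifford(x, y) -> TuningFit:
    xr = x * DEG2RAD
    best = None
    for sign in (1, -1):
        for s0, c0 in _CLIFFORD_STARTS:

            def resid(p, sign=sign):
                return sign * _clifford_raw(xr, p[0], p[1]) * RAD2DEG - y

            try:
                sol = optimize.least_squares(
                    resid,
                    x0=[s0, c0],
                    bounds=([0.05, -2.0], [5.0, 2.0]),
                    method="trf",
                    xtol=1e-10,
                    ftol=1e-10,
                )
            except Exception:
                continue
            sse = float((sol.fun**2).sum())
            if best is None or sse < best[0] - 1e-9:
                best = (sse, float(sol.x[0]), float(sol.x[1]), sign)
    if best is None:
        raise RuntimeError("Clifford fit failed from every start")
    sse, s, c, sign = best
    try:
        params = CliffordParams(s_scale=s, c_center=c, sign=sign)
        converged = True
    except ValueError:
        params = CliffordParams(s_scale=1.0, c_center=0.0, sign=1)
        sse = float((y**2).sum())
        converged = False
    fit = TuningFit("clifford", params, 0.0, sse, len(x), converged=converged)
    fit.peak_to_peak = peak_to_peak(fit)
    return fit


# ---------------------------------------------------------------------------
# peak-to-peak statistic


def peak_to_peak(fit: TuningFit, grid_step=0.05) -> float:
    """Signed peak-to-peak of a fitted tuning curve.

    Magnitude: max − min of the curve on a dense grid over [−180, 180].
    Sign: the sign of the curve at its first local extremum for x > 0 (the
    "small-positive-x peak"); positive means attraction. A curve that is
    monotone up to the boundary takes the sign of its value at 180°.
    """
    grid = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    yg = np.asarray(fit.curve(grid), dtype=float)

    def _refine(idx, sign):
        # polish a grid extremum by bounded scalar optimization
        lo = grid[max(idx - 1, 0)]
        hi = grid[min(idx + 1, len(grid) - 1)]
        if lo == hi:
            return sign * float(yg[idx])
        res = optimize.minimize_scalar(
            lambda v: -sign * float(fit.curve(v)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        return max(sign * float(yg[idx]), -float(res.fun))

    y_max = _refine(int(np.argmax(yg)), 1.0)
    y_min = -_refine(int(np.argmin(yg)), -1.0)
    rng = float(y_max - y_min)
    if rng < 1e-12:
        return 0.0
    pos = grid > 0
    ypos = yg[pos]
    dy = np.diff(ypos)
    sign_changes = np.nonzero(np.sign(dy[1:]) * np.sign(dy[:-1]) < 0)[0]
    if len(sign_changes):
        s = np.sign(ypos[sign_changes[0] + 1])
    else:
        s = np.sign(ypos[-1])
    if s == 0:
        s = 1.0
    return float(s * rng)


# ---------------------------------------------------------------------------
# descriptive curves and the variance time course


def moving_average(x, y, window_deg=20.0, grid_step=1.0):
    """Circular moving average of y over x, for plotting.

    Returns a dict of arrays ``grid`` (degrees), ``mean``, ``sem`` and
    ``count``. Grid points whose window contains no trials get NaN; the SEM
    is NaN where fewer than two trials fall in the window.
    """
    if window_deg <= 0:
        raise ValueError("window_deg must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    half = window_deg / 2.0
    dist = np.abs(wrap_signed(x[None, :] - grid[:, None]))
    inwin = dist <= half
    count = inwin.sum(axis=1)
    ysum = inwin @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, ysum / np.maximum(count, 1), np.nan)
        sq = inwin @ (y**2)
        var = (sq - count * mean**2) / np.maximum(count - 1, 1)
        sem = np.where(count > 1, np.sqrt(np.maximum(var, 0.0) / count), np.nan)
    return {"grid": grid, "mean": mean, "sem": sem, "count": count}


def variance_by_delay(table, value_col="residual_error", delay_col="delay_s",
                      n_boot=2000, level=0.95, seed=0):
    """Variance of response errors per delay, with bootstrap percentile CIs.

    Returns a list of dicts (delay, variance, ci_low, ci_high, n) sorted by
    delay.
    """
    rng = np.random.default_rng(seed)
    out = []
    for delay, g in sorted(table.groupby(delay_col), key=lambda kv: kv[0]):
        e = g[value_col].to_numpy(dtype=float)
        e = e[np.isfinite(e)]
        v = float(np.var(e, ddof=1))
        idx = rng.integers(0, len(e), size=(n_boot, len(e)))
        boots = np.var(e[idx], axis=1, ddof=1)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        out.append(
            {"delay": float(delay), "variance": v, "ci_low": float(lo),
             "ci_high": float(hi), "n": int(len(e))}
        )
    return out


def fit_variance_power_law(delays, variances) -> PowerLawFit:
    """Fit variance(d) = scale·(d + t)^β, plus a straight line for comparison.

    The offset t is constrained positive (log-parameterized) so the predicted
    variance is finite and positive at zero delay. Multi-start least squares;
    the linear fit is ordinary polyfit. Both SSEs are reported.
    """
    d = np.asarray(delays, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 delay levels")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")

    def resid(p):
        log_scale, log_t, beta = p
        return np.exp(log_scale) * (d + np.exp(log_t)) ** beta - v

    best = None
    for t0 in (0.5, 2.0, 5.0):
        for b0 in (0.3, 0.5, 1.0):
            s0 = np.log(max(v.mean() / (d.mean() + t0) ** b0, 1e-9))
            sol = optimize.least_squares(
                resid, x0=[s0, np.log(t0), b0], method="lm", xtol=1e-14, ftol=1e-14
            )
            sse = float((sol.fun**2).sum())
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol.x)
    sse, p = best
    slope, intercept = np.polyfit(d, v, 1)
    sse_lin = float(((slope * d + intercept - v) ** 2).sum())
    return PowerLawFit(
        scale=float(np.exp(p[0])),
        t_offset=float(np.exp(p[1])),
        beta=float(p[2]),
        sse=sse,
        sse_linear=sse_lin,
        linear_coef=(float(slope), float(intercept)),
    )
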