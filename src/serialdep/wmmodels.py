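"""Circular noise models for delayed-response errors, and their fits.

Three base models of the recall error distribution (all radian-scale
internally; the public API takes errors in degrees):

EP (equal precision)
    A single zero-mean von Mises with concentration κ.

VP (variable precision)
    Precision is redrawn each trial: Fisher information J ~ Gamma(mean J̄,
    scale τ); the trial's error is von Mises with κ = Φ(J), the inverse of
    J(κ) = κ·I₁(κ)/I₀(κ). The marginal density has no closed form and is
    estimated by Monte Carlo averaging over J draws.

VMRW (von Mises random walk)
    Derived from population coding: the report is the direction of the
    resultant of m unit vectors whose directions are i.i.d. von Mises(0, κ),
    with the spike count m ~ Poisson(ξ) (ξ is the gain). Conditioned on the
    resultant length r the error is von Mises with concentration κr, and r
    follows the Bessel-tilted random-walk length density
    p(r|m,κ) = I₀(κr)/I₀(κ)^m · rψₘ(r). Sampling step *directions* from
    VM(0, κ) draws r from exactly that tilted density, so the marginal is
    estimated as the Monte Carlo average of VM(κr) components; m = 0
    contributes the uniform density 1/2π.

Trial-history extensions: a DoG-shaped shift of the density's mean as a
function of the previous trial's relative angle (the serial-dependence
hybrid), and a swap mixture in which a fraction α of responses are centered
on the previous trial's stimulus. Models are fit per memory-delay condition
by simplex maximum likelihood and compared by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from ._angles import DEG2RAD, wrap_signed
from .tuning import DoGParams, dog_curve

#: evaluation grid for Monte-Carlo densities (degrees, closed interval)
GRID_DEG = np.linspace(-180.0, 180.0, 721)
_GRID_RAD = GRID_DEG * DEG2RAD


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class EPParams:
    kappa: float

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")


@dataclass(frozen=True)
class VPParams:
    J_bar: float  # mean Fisher information
    tau: float  # gamma scale

    def __post_init__(self):
        if not (self.J_bar > 0 and self.tau > 0):
            raise ValueError("J_bar and tau must be > 0")


@dataclass(frozen=True)
class VMRWParams:
    kappa: float  # per-step concentration
    xi: float  # expected step count (gain)

    def __post_init__(self):
        if not (self.kappa > 0 and self.xi > 0):
            raise ValueError("kappa and xi must be > 0")


@dataclass(frozen=True)
class HistoryExtension:
    kind: str = "none"  # none | dog_shift | swap
    a: float = 0.0  # DoG shift amplitude, degrees
    w: float = 0.02  # DoG shift width, per degree
    alpha_swap: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "dog_shift", "swap"):
            raise ValueError(f"unknown extension kind: {self.kind!r}")
        if not 0.0 <= self.alpha_swap <= 1.0:
            raise ValueError("alpha_swap must lie in [0, 1]")
        if self.kind == "dog_shift" and not self.w > 0:
            raise ValueError("w must be > 0")


@dataclass
class WMModelFit:
    model: str
    extension: str
    per_delay_params: dict  # delay -> parameter dict
    loglik: float
    k_params: int
    n_trials: int
    aicc: float
    converged: bool = True
    per_delay_extension: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "model": self.model,
            "extension": self.extension,
            "per_delay_params": {str(k): v for k, v in self.per_delay_params.items()},
            "per_delay_extension": {str(k): v for k, v in self.per_delay_extension.items()},
            "loglik": self.loglik,
            "k_params": self.k_params,
            "n_trials": self.n_trials,
            "aicc": self.aicc,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# von Mises primitives and the κ ↔ J map


def _vm_pdf_rad(err_rad, kappa):
    """Zero-mean von Mises density per radian; overflow-safe for large κ."""
    kappa = np.asarray(kappa, dtype=float)
    return np.exp(kappa * (np.cos(err_rad) - 1.0)) / (2.0 * np.pi * special.i0e(kappa))


def ep_density(error_deg, params: EPParams):
    """EP (single von Mises) density per radian at errors given in degrees."""
    err = np.asarray(error_deg, dtype=float) * DEG2RAD
    out = _vm_pdf_rad(err, params.kappa)
    return float(out) if np.ndim(error_deg) == 0 else out


def kappa_to_j(kappa):
    """Fisher information of a von Mises report: J = κ·I₁(κ)/I₀(κ)."""
    k = np.asarray(kappa, dtype=float)
    if np.any(k <= 0):
        raise ValueError("kappa must be > 0")
    out = k * special.i1e(k) / special.i0e(k)
    return float(out) if np.ndim(kappa) == 0 else out


_J_GRID_LOGK = np.linspace(np.log(1e-8), np.log(1e6), 6000)
_J_GRID_LOGJ = np.log(kappa_to_j(np.exp(_J_GRID_LOGK)))


def j_to_kappa(j):
    """Inverse of :func:`kappa_to_j`.

    Scalars are solved by bracketed root finding (round-trip error < 1e-8);
    arrays use monotone log-log interpolation on a dense precomputed grid
    (relative error < 1e-6), which is what the Monte-Carlo VP density needs.
    """
    if np.ndim(j) == 0:
        jv = float(j)
        if jv <= 0:
            raise ValueError("J must be > 0")
        f = lambda logk: kappa_to_j(np.exp(logk)) - jv
        lo, hi = np.log(1e-10), np.log(1e8)
        return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)))
    j = np.asarray(j, dtype=float)
    if np.any(j <= 0):
        raise ValueError("J must be > 0")
    logj = np.clip(np.log(j), _J_GRID_LOGJ[0], _J_GRID_LOGJ[-1])
    return np.exp(np.interp(logj, _J_GRID_LOGJ, _J_GRID_LOGK))


# ---------------------------------------------------------------------------
# Monte-Carlo densities with common random numbers


class VPSampler:
    """Fixed uniform draws for the VP mixture; J via gamma PPF inversion.

    Reusing one set of uniforms across parameter values makes the simplex
    objective deterministic and smooth in (J̄, τ).
    """

    def __init__(self, n_mc=2000, seed=0):
        if n_mc < 100:
            raise ValueError("n_mc must be >= 100")
        self.n_mc = n_mc
        # midpoint-stratified uniforms: lower MC variance, still unbiased
        u = (np.arange(n_mc) + np.random.default_rng(seed).random(n_mc)) / n_mc
        self.u = u

    def kappas(self, params: VPParams):
        j = stats.gamma.ppf(self.u, a=params.J_bar / params.tau, scale=params.tau)
        j = np.clip(j, 1e-12, None)
        return j_to_kappa(j)

    def density(self, err_rad, params: VPParams):
        k = self.kappas(params)
        return _vm_pdf_rad(err_rad[:, None], k[None, :]).mean(axis=1)


class VMRWSampler:
    """Fixed uniforms for the VMRW mixture.

    Spike counts come from Poisson PPF inversion on one set of uniforms;
    step directions from von Mises quantile inversion (grid-interpolated CDF)
    on another, so the resultant lengths vary smoothly with (κ, ξ).
    """

    _TH = np.linspace(-np.pi, np.pi, 2049)

    def __init__(self, n_mc=2000, seed=0, m_cap=120):
        if n_mc < 100:
            raise ValueError("n_mc must be >= 100")
        rng = np.random.default_rng(seed)
        self.n_mc = n_mc
        self.m_cap = m_cap
        self.u_m = (np.arange(n_mc) + rng.random(n_mc)) / n_mc
        rng.shuffle(self.u_m)
        self.u_steps = rng.random((n_mc, m_cap))

    def _step_angles(self, kappa, n_cols):
        cdf = stats.vonmises.cdf(self._TH, kappa)
        cdf[0], cdf[-1] = 0.0, 1.0
        return np.interp(self.u_steps[:, :n_cols], cdf, self._TH)

    def resultants(self, params: VMRWParams):
        """Resultant lengths r (and counts m) for each Monte-Carlo sample."""
        m = stats.poisson.ppf(self.u_m, params.xi)
        m = np.nan_to_num(m, nan=0.0, posinf=float(self.m_cap))
        m = np.minimum(m, self.m_cap).astype(int)
        n_cols = max(int(m.max()), 1)
        th = self._step_angles(params.kappa, n_cols)
        mask = np.arange(n_cols)[None, :] < m[:, None]
        c = (np.cos(th) * mask).sum(axis=1)
        s = (np.sin(th) * mask).sum(axis=1)
        r = np.hypot(c, s)
        r[m == 0] = 0.0
        return r, m

    def density(self, err_rad, params: VMRWParams):
        r, _ = self.resultants(params)
        return _vm_pdf_rad(err_rad[:, None], params.kappa * r[None, :]).mean(axis=1)


def vp_density(error_deg, params: VPParams, n_mc=10_000, seed=0, return_se=False):
    """VP density per radian at errors in degrees (Monte-Carlo estimate)."""
    err = np.atleast_1d(np.asarray(error_deg, dtype=float)) * DEG2RAD
    sampler = VPSampler(n_mc=n_mc, seed=seed)
    comps = _vm_pdf_rad(err[:, None], sampler.kappas(params)[None, :])
    dens = comps.mean(axis=1)
    if return_se:
        se = comps.std(axis=1, ddof=1) / np.sqrt(n_mc)
        return dens, se
    return float(dens[0]) if np.ndim(error_deg) == 0 else dens


def vmrw_density(error_deg, params: VMRWParams, n_mc=10_000, seed=0, return_se=False):
    """VMRW density per radian at errors in degrees (Monte-Carlo estimate)."""
    err = np.atleast_1d(np.asarray(error_deg, dtype=float)) * DEG2RAD
    sampler = VMRWSampler(n_mc=n_mc, seed=seed)
    r, _ = sampler.resultants(params)
    comps = _vm_pdf_rad(err[:, None], params.kappa * r[None, :])
    dens = comps.mean(axis=1)
    if return_se:
        se = comps.std(axis=1, ddof=1) / np.sqrt(n_mc)
        return dens, se
    return float(dens[0]) if np.ndim(error_deg) == 0 else dens


def vmrw_sample_errors(kappa, xi, n, rng: np.random.Generator):
    """Forward-simulate n VMRW errors (radians): the decoded report direction.

    Independent of :func:`vmrw_density`'s mixture route — draws m ~
    Poisson(ξ), m step directions from VM(0, κ), and returns the *angle* of
    the resultant (uniform when m = 0).
    """
    m = rng.poisson(xi, size=n)
    total = int(m.sum())
    th = rng.vonmises(0.0, kappa, size=total)
    ends = np.cumsum(m)
    starts = ends - m
    cc = np.concatenate([[0.0], np.cumsum(np.cos(th))])
    ss = np.concatenate([[0.0], np.cumsum(np.sin(th))])
    c = cc[ends] - cc[starts]
    s = ss[ends] - ss[starts]
    err = np.arctan2(s, c)
    zero = m == 0
    if zero.any():
        err[zero] = rng.uniform(-np.pi, np.pi, size=int(zero.sum()))
    return err


# ---------------------------------------------------------------------------
# likelihoods


def _base_density_fn(model, params, sampler=None, n_mc=2000, seed=0):
    """Return f(err_deg_array) -> density, via a cached grid for MC models."""
    if model == "EP":
        kappa = params.kappa if isinstance(params, EPParams) else params["kappa"]
        return lambda e: _vm_pdf_rad(np.asarray(e, dtype=float) * DEG2RAD, kappa)
    if model == "VP":
        p = params if isinstance(params, VPParams) else VPParams(**params)
        sampler = sampler or VPSampler(n_mc=n_mc, seed=seed)
        grid = sampler.density(_GRID_RAD, p)
    elif model == "VMRW":
        p = params if isinstance(params, VMRWParams) else VMRWParams(**params)
        sampler = sampler or VMRWSampler(n_mc=n_mc, seed=seed)
        grid = sampler.density(_GRID_RAD, p)
    else:
        raise ValueError(f"unknown model: {model!r}")
    return lambda e: np.interp(np.asarray(e, dtype=float), GRID_DEG, grid)


def model_loglik(trials, model, params, extension=HistoryExtension(),
                 n_mc=2000, seed=0, _sampler=None):
    """Log-likelihood of residual errors under a base model + extension.

    ``trials`` is a DataFrame with ``residual_error`` (degrees) and, for the
    history extensions, ``x_prev`` (degrees; NaN on first trials, which then
    use the base density).
    """
    y = trials["residual_error"].to_numpy(dtype=float)
    x_prev = (
        trials["x_prev"].to_numpy(dtype=float)
        if "x_prev" in trials
        else np.full(len(y), np.nan)
    )
    f = _base_density_fn(model, params, sampler=_sampler, n_mc=n_mc, seed=seed)
    has_prev = np.isfinite(x_prev)

    if extension.kind == "none":
        dens = f(y)
    elif extension.kind == "dog_shift":
        shift = np.zeros_like(y)
        shift[has_prev] = dog_curve(x_prev[has_prev], DoGParams(extension.a, extension.w))
        dens = f(wrap_signed(y - shift))
    elif extension.kind == "swap":
        dens = f(y).astype(float).copy()
        alt = f(wrap_signed(y[has_prev] - x_prev[has_prev]))
        dens[has_prev] = (1.0 - extension.alpha_swap) * dens[has_prev] \
            + extension.alpha_swap * alt
    else:
        raise ValueError(f"unknown extension kind: {extension.kind!r}")

    dens = np.asarray(dens, dtype=float)
    if not np.all(np.isfinite(dens)):
        return -np.inf
    return float(np.log(np.clip(dens, 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def aicc(k: int, n: int, loglik: float) -> float:
    """Akaike Information Criterion with the finite-sample correction."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


_N_BASE = {"EP": 1, "VP": 2, "VMRW": 2}
_N_EXT = {"none": 0, "dog_shift": 2, "swap": 1}


def _pack(model, ext_kind, base, ext):
    v = [np.log(x) for x in base]
    if ext_kind == "dog_shift":
        v += [ext[0], np.log(ext[1])]
    elif ext_kind == "swap":
        a = np.clip(ext[0], 1e-4, 1 - 1e-4)
        v += [np.log(a / (1 - a))]
    return np.array(v, dtype=float)


def _unpack(model, ext_kind, v):
    nb = _N_BASE[model]
    base = np.exp(np.clip(v[:nb], -30.0, 30.0))
    if model == "EP":
        params = EPParams(kappa=float(base[0]))
    elif model == "VP":
        params = VPParams(J_bar=float(base[0]), tau=float(base[1]))
    else:
        params = VMRWParams(kappa=float(base[0]), xi=float(base[1]))
    if ext_kind == "none":
        ext = HistoryExtension()
    elif ext_kind == "dog_shift":
        w = float(np.exp(np.clip(v[nb + 1], np.log(1e-3), np.log(0.2))))
        ext = HistoryExtension(kind="dog_shift", a=float(v[nb]), w=w)
    else:
        z = np.clip(v[nb], -30.0, 30.0)
        ext = HistoryExtension(kind="swap", alpha_swap=float(1 / (1 + np.exp(-z))))
    return params, ext


def _kappa_moment_estimate(y_deg):
    """Quick von Mises concentration estimate from the resultant length."""
    r = np.abs(np.exp(1j * np.asarray(y_deg, dtype=float) * DEG2RAD).mean())
    r = min(r, 1 - 1e-6)
    # Fisher's approximation, adequate for a starting value
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1 / (r**3 - 4 * r**2 + 3 * r)
    return max(k, 1e-3)


def _base_starts(model, y_deg):
    k0 = _kappa_moment_estimate(y_deg)
    if model == "EP":
        return [(k0,), (3 * k0,)]
    if model == "VP":
        return [(k0, k0 / 3), (2 * k0, k0)]
    # VMRW: with aligned steps r ≈ ξ·I1/I0(κ), so κ·ξ of order k0
    return [(max(k0 / 4, 0.2), 5.0), (max(k0 / 10, 0.1), 12.0)]


def _ext_starts(ext_kind, wide=True):
    if ext_kind == "none":
        return [()]
    if ext_kind == "dog_shift":
        return [(0.5, 0.02), (2.0, 0.02)] if wide else [(1.0, 0.02)]
    return [(0.05,), (0.3,)] if wide else [(0.1,)]


def fit_wm_model(trials, model="EP", extension_kind="none", per_delay=True,
                 n_mc=2000, seed=0, maxiter=400, wide_starts=True,
                 fatol=1e-4) -> WMModelFit:
    """Maximum-likelihood fit of a noise model, per memory-delay condition.

    Each delay condition gets its own parameter set (simplex search with
    multi-start on log/logit-transformed parameters); the total
    log-likelihood is the sum over conditions and k counts all per-condition
    parameters. Monte-Carlo densities reuse one seeded set of uniform draws
    per condition so the objective is deterministic.
    """
    if model not in _N_BASE:
        raise ValueError(f"unknown model: {model!r}")
    groups = (
        [(d, g) for d, g in trials.groupby("delay_s", sort=True)]
        if per_delay
        else [("all", trials)]
    )
    k_per = _N_BASE[model] + _N_EXT[extension_kind]
    total_ll = 0.0
    per_delay_params = {}
    per_delay_ext = {}
    converged = True
    for gi, (delay, g) in enumerate(groups):
        if len(g) <= k_per + 1:
            raise ValueError(f"condition {delay!r} has too few trials ({len(g)})")
        if model == "VP":
            sampler = VPSampler(n_mc=n_mc, seed=np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31))
        elif model == "VMRW":
            sampler = VMRWSampler(n_mc=n_mc, seed=np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31))
        else:
            sampler = None
        y = g["residual_error"].to_numpy(dtype=float)

        def negll(v):
            try:
                params, ext = _unpack(model, extension_kind, v)
            except ValueError:
                return np.inf
            ll = model_loglik(g, model, params, ext, _sampler=sampler)
            return -ll if np.isfinite(ll) else np.inf

        best = None
        for b0 in _base_starts(model, y):
            for e0 in _ext_starts(extension_kind, wide=wide_starts):
                v0 = _pack(model, extension_kind, b0, e0)
                res = optimize.minimize(
                    negll, v0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-4, "fatol": fatol},
                )
                if best is None or res.fun < best.fun:
                    best = res
        if not np.isfinite(best.fun):
            converged = False
        params, ext = _unpack(model, extension_kind, best.x)
        total_ll += -best.fun
        per_delay_params[delay] = params.__dict__.copy()
        if extension_kind != "none":
            per_delay_ext[delay] = {
                k: v for k, v in ext.__dict__.items() if k != "kind"
            }
    k = k_per * len(groups)
    n = int(len(trials))
    return WMModelFit(
        model=model,
        extension=extension_kind,
        per_delay_params=per_delay_params,
        per_delay_extension=per_delay_ext,
        loglik=total_ll,
        k_params=k,
        n_trials=n,
        aicc=aicc(k, n, total_ll),
        converged=converged,
    )


def fit_wm_model_shared_extension(trials, model="EP", extension_kind="dog_shift",
                                  n_mc=2000, seed=0, maxiter=400,
                                  n_rounds=2) -> WMModelFit:
    """Variant fit: per-delay base parameters, one shared history extension.

    Alternated coordinate descent: (1) per-delay base-parameter fits with
    the extension fixed; (2) a global simplex over the extension parameters
    with the base parameters fixed; repeated ``n_rounds`` times. k counts
    the per-delay base parameters plus one shared extension set.
    """
    if extension_kind not in ("dog_shift", "swap"):
        raise ValueError("shared-extension fit needs a history extension")
    groups = [(d, g) for d, g in trials.groupby("delay_s", sort=True)]
    samplers = {}
    for gi, (delay, _) in enumerate(groups):
        s = np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31)
        if model == "VP":
            samplers[delay] = VPSampler(n_mc=n_mc, seed=s)
        elif model == "VMRW":
            samplers[delay] = VMRWSampler(n_mc=n_mc, seed=s)
        else:
            samplers[delay] = None

    ext = HistoryExtension(extension_kind, a=0.0 if extension_kind == "dog_shift" else 0.0,
                           alpha_swap=0.0)
    base_params = {}

    def total_ll(ext_now, params_by_delay):
        return sum(
            model_loglik(g, model, params_by_delay[d], ext_now,
                         _sampler=samplers[d])
            for d, g in groups
        )

    for _ in range(n_rounds):
        # per-delay base refit with the extension frozen
        for gi, (delay, g) in enumerate(groups):
            y = g["residual_error"].to_numpy(dtype=float)

            def negll(v, delay=delay, g=g):
                try:
                    params, _ = _unpack(model, "none", v)
                except ValueError:
                    return np.inf
                ll = model_loglik(g, model, params, ext, _sampler=samplers[delay])
                return -ll if np.isfinite(ll) else np.inf

            best = None
            for b0 in _base_starts(model, y):
                res = optimize.minimize(
                    negll, _pack(model, "none", b0, ()), method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3},
                )
                if best is None or res.fun < best.fun:
                    best = res
            base_params[delay], _ = _unpack(model, "none", best.x)

        # shared extension refit with the bases frozen
        def neg_ext(v):
            if extension_kind == "dog_shift":
                w = float(np.exp(np.clip(v[1], np.log(1e-3), np.log(0.2))))
                e = HistoryExtension("dog_shift", a=float(v[0]), w=w)
            else:
                z = np.clip(v[0], -30.0, 30.0)
                e = HistoryExtension("swap", alpha_swap=float(1 / (1 + np.exp(-z))))
            ll = total_ll(e, base_params)
            return -ll if np.isfinite(ll) else np.inf

        if extension_kind == "dog_shift":
            v0 = np.array([ext.a if ext.a else 1.0, np.log(ext.w)])
        else:
            a0 = np.clip(ext.alpha_swap if ext.alpha_swap else 0.1, 1e-4, 1 - 1e-4)
            v0 = np.array([np.log(a0 / (1 - a0))])
        res = optimize.minimize(neg_ext, v0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-4,
                                         "fatol": 1e-3})
        if extension_kind == "dog_shift":
            w = float(np.exp(np.clip(res.x[1], np.log(1e-3), np.log(0.2))))
            ext = HistoryExtension("dog_shift", a=float(res.x[0]), w=w)
        else:
            z = np.clip(res.x[0], -30.0, 30.0)
            ext = HistoryExtension("swap", alpha_swap=float(1 / (1 + np.exp(-z))))

    ll = total_ll(ext, base_params)
    k = _N_BASE[model] * len(groups) + _N_EXT[extension_kind]
    n = int(len(trials))
    return WMModelFit(
        model=model,
        extension=f"{extension_kind}_shared",
        per_delay_params={d: p.__dict__.copy() for d, p in base_params.items()},
        per_delay_extension={"shared": {k_: v for k_, v in ext.__dict__.items()
                                        if k_ != "kind"}},
        loglik=float(ll),
        k_params=k,
        n_trials=n,
        aicc=aicc(k, n, float(ll)),
    )


def compare_models(fits_by_model: dict):
    """Pairwise ΔAICc across subjects, mean ± SEM.

    ``fits_by_model`` maps model label → list of :class:`WMModelFit`, one
    per subject (same subject order in every list). ΔAICc for a pair
    (A, B) is AICc(B) − AICc(A) per subject, so *positive values favor the
    first-named model*. Subjects missing a fit for either model are dropped
    from that pair.
    """
    import itertools

    rows = []
    for a, b in itertools.combinations(fits_by_model, 2):
        deltas = [
            fb.aicc - fa.aicc
            for fa, fb in zip(fits_by_model[a], fits_by_model[b])
            if fa is not None and fb is not None
        ]
        deltas = np.asarray(deltas, dtype=float)
        sem = float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else np.nan
        rows.append(
            {"model_a": a, "model_b": b, "delta_aicc_mean": float(deltas.mean()),
             "delta_aicc_sem": sem, "n_subjects": int(len(deltas))}
        )
    import pandas as pd

    return pd.DataFrame(rows)
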