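"""Permutation and bootstrap inference on the peak-to-peak statistic.

The permutation null shuffles the previous-trial relative angles ``x`` while
leaving the response errors ``y`` in place, refits the tuning curve, and
records the signed peak-to-peak. The default p-value is the proportion of
null statistics greater than or equal to the observed one (a one-sided test
of attraction, uniform under the null); ``alternative="less"`` tests the
repulsive direction, and ``alternative="auto"`` picks the tail from the
observed sign — convenient for descriptive condition tables, but note that
choosing the direction post hoc doubles the type-I error rate. Bootstrap
confidence intervals resample (x, y) pairs jointly with replacement and
take the percentile interval.

For the DoG model all refits go through the profiled batch fitter in
:mod:`serialdep.tuning`, which makes 10,000-resample runs cheap; the
Clifford model falls back to per-resample nonlinear fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tuning import dog_peak_to_peak_analytic, fit_tuning, profile_dog_batch


@dataclass
class ResampleResult:
    observed: float  # signed degrees
    null_or_boot: np.ndarray = field(repr=False)
    n_resamples: int = 0
    seed: int = 0
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_failed: int = 0

    def to_dict(self):
        d = {
            "observed": self.observed,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return d


def _clean(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _observed_p2p(x, y, model):
    if model == "dog":
        a, w, _ = profile_dog_batch(x[None, :], y[None, :])
        return float(dog_peak_to_peak_analytic(a, w)[0])
    return fit_tuning(x, y, model=model).peak_to_peak


def _null_p2p_dog(x, y, n_perm, rng, chunk=None):
    """Peak-to-peaks after shuffling x against y, vectorized in chunks."""
    n = len(x)
    if chunk is None:
        chunk = max(1, 4_000_000 // n)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        a, w, _ = profile_dog_batch(x[idx], y[None, :])
        out[done : done + b] = dog_peak_to_peak_analytic(a, w)
        done += b
    return out


def _null_p2p_generic(x, y, model, n_perm, rng):
    out = np.full(n_perm, np.nan)
    for i in range(n_perm):
        xs = rng.permutation(x)
        try:
            fit = fit_tuning(xs, y, model=model)
            if fit.converged:
                out[i] = fit.peak_to_peak
        except Exception:
            pass
    return out


def _tail_p(observed, null, alternative):
    if alternative == "auto":
        alternative = "greater" if observed >= 0 else "less"
    if alternative == "greater":
        return float((null >= observed).mean())
    if alternative == "less":
        return float((null <= observed).mean())
    raise ValueError("alternative must be 'greater', 'less' or 'auto'")


def permutation_test(x, y, model="dog", n_perm=10_000, seed=0,
                     alternative="greater") -> ResampleResult:
    """Group permutation test of the signed peak-to-peak against zero."""
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    x, y = _clean(x, y)
    rng = np.random.default_rng(seed)
    observed = _observed_p2p(x, y, model)
    if model == "dog":
        null = _null_p2p_dog(x, y, n_perm, rng)
    else:
        null = _null_p2p_generic(x, y, model, n_perm, rng)
    ok = np.isfinite(null)
    n_failed = int((~ok).sum())
    null_ok = null[ok]
    p = _tail_p(observed, null_ok, alternative)
    return ResampleResult(
        observed=observed, null_or_boot=null_ok, n_resamples=n_perm,
        seed=seed, p_value=p, n_failed=n_failed,
    )


def permutation_compare(x_a, y_a, x_b, y_b, model="dog", n_perm=10_000, seed=0,
                        alternative="greater") -> ResampleResult:
    """Permutation comparison of peak-to-peaks between two conditions.

    Each permutation shuffles x within each condition independently, refits
    both, and records the difference A − B of null peak-to-peaks; p is the
    proportion of null differences at least as large as the observed one
    (``alternative`` as in :func:`permutation_test`).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    x_a, y_a = _clean(x_a, y_a)
    x_b, y_b = _clean(x_b, y_b)
    rng = np.random.default_rng(seed)
    observed = _observed_p2p(x_a, y_a, model) - _observed_p2p(x_b, y_b, model)
    if model == "dog":
        null = _null_p2p_dog(x_a, y_a, n_perm, rng) - _null_p2p_dog(x_b, y_b, n_perm, rng)
        n_failed = 0
    else:
        na = _null_p2p_generic(x_a, y_a, model, n_perm, rng)
        nb = _null_p2p_generic(x_b, y_b, model, n_perm, rng)
        null = na - nb
        ok = np.isfinite(null)
        n_failed = int((~ok).sum())
        null = null[ok]
    p = _tail_p(observed, null, alternative)
    return ResampleResult(
        observed=observed, null_or_boot=np.asarray(null), n_resamples=n_perm,
        seed=seed, p_value=p, n_failed=n_failed,
    )


def bootstrap_ci(x, y, model="dog", n_boot=10_000, level=0.95, seed=0) -> ResampleResult:
    """Percentile bootstrap CI for the signed peak-to-peak (pairs resampling)."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    x, y = _clean(x, y)
    n = len(x)
    rng = np.random.default_rng(seed)
    observed = _observed_p2p(x, y, model)
    if model == "dog":
        chunk = max(1, 4_000_000 // n)
        boots = np.empty(n_boot)
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(b, n))
            a, w, _ = profile_dog_batch(x[idx], y[idx])
            boots[done : done + b] = dog_peak_to_peak_analytic(a, w)
            done += b
        n_failed = 0
    else:
        boots = np.full(n_boot, np.nan)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                fit = fit_tuning(x[idx], y[idx], model=model)
                if fit.converged:
                    boots[i] = fit.peak_to_peak
            except Exception:
                pass
        ok = np.isfinite(boots)
        n_failed = int((~ok).sum())
        boots = boots[ok]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ResampleResult(
        observed=observed, null_or_boot=np.asarray(boots), n_resamples=n_boot,
        seed=seed, ci_low=float(lo), ci_high=float(hi), n_failed=n_failed,
    )


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_p(p: float, n_resamples: int) -> str:
    """Human-readable p-value; a raw 0 prints as an upper bound."""
    if p == 0:
        return f"< {1.0 / n_resamples:g}"
    return f"{p:g}"
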