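"""Seeded synthetic delayed-response sessions.

Emulates the behavioral structure of a spatial delayed-response experiment:
stimuli at uniform random polar angles on an invisible circle, retention
delays (or inter-trial intervals) drawn from a small set, circular response
noise from one of the working-memory noise models (EP, VP, VMRW), a
delay-dependent trial-history bias with derivative-of-Gaussian or Clifford
tuning, a smooth stimulus-location-dependent systematic error, and rare
invalid responses (near-origin clicks, gross outliers).

Every downstream stage of the analysis is testable against sessions produced
here, with all injected effect sizes known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._angles import wrap_positive, wrap_signed

#: columns of a trial table, in canonical order
TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "stimulus_angle",
    "response_angle",
    "response_eccentricity",
    "delay_s",
    "iti_s",
]

#: eccentricity (degrees of visual angle) of a valid on-ring response
STIMULUS_ECCENTRICITY = 12.0

#: default trial-history amplitude schedule (degrees) per current-trial delay:
#: adaptation (negative) at 0 s flipping to attraction that peaks near 6 s
DEFAULT_AMPLITUDE_SCHEDULE = {0.0: -0.86, 1.0: 0.42, 3.0: 1.0, 6.0: 1.7, 10.0: 1.45}

# Sublinear accumulation of response variance with delay, var(d) in squared
# degrees; exponent 0.47 with offset/scale matching the observed 6-s and 10-s
# variance levels in the task this generator emulates.
_VAR_SCALE, _VAR_OFFSET, _VAR_BETA = 15.75, 2.67, 0.47


def default_variance_deg2(delay_s: float) -> float:
    """Default response variance (deg^2) as a power law of memory delay."""
    return _VAR_SCALE * (delay_s + _VAR_OFFSET) ** _VAR_BETA


def _default_ep_params(delay_set: Sequence[float]) -> dict:
    deg2rad = np.pi / 180.0
    return {
        float(d): {"kappa": 1.0 / (default_variance_deg2(d) * deg2rad**2)}
        for d in delay_set
    }


@dataclass
class GeneratorConfig:
    """Full description of a synthetic session.

    ``noise_params`` maps delay (s) to the parameter dict of ``noise_model``
    (EP: kappa; VP: J_bar, tau; VMRW: kappa, xi — all radian-scale). A single
    flat dict applies to every delay. ``bias_params`` holds, for DoG,
    ``amplitude`` (scalar or delay→degrees mapping) and ``w`` (per-degree
    width); for Clifford, ``s_scale``, ``c_center``, ``sign``.
    """

    n_subjects: int = 1
    n_trials_per_subject: int = 1000
    delay_set: Sequence[float] = (0.0, 1.0, 3.0, 6.0, 10.0)
    delay_weights: Sequence[float] | None = None
    iti_set: Sequence[float] = (1.0,)
    iti_weights: Sequence[float] | None = None
    noise_model: str = "EP"
    noise_params: Mapping | None = None
    bias_shape: str = "DoG"
    bias_params: Mapping | None = None
    systematic_error: Sequence[tuple] = field(default_factory=list)
    outlier_rate: float = 0.0
    origin_click_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_model not in ("EP", "VP", "VMRW"):
            raise ValueError(f"unknown noise_model: {self.noise_model!r}")
        if self.bias_shape not in ("DoG", "Clifford", "none"):
            raise ValueError(f"unknown bias_shape: {self.bias_shape!r}")
        if self.n_trials_per_subject < 2:
            raise ValueError("n_trials_per_subject must be >= 2")
        for rate in (self.outlier_rate, self.origin_click_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        self.delay_set = tuple(float(d) for d in self.delay_set)
        self.iti_set = tuple(float(i) for i in self.iti_set)
        self.delay_weights = _check_weights(self.delay_weights, len(self.delay_set))
        self.iti_weights = _check_weights(self.iti_weights, len(self.iti_set))


def _check_weights(weights, n):
    if weights is None:
        return tuple(1.0 / n for _ in range(n))
    w = np.asarray(weights, dtype=float)
    if len(w) != n or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return tuple(w)


def _noise_params_for(config: GeneratorConfig, delay: float) -> dict:
    if config.noise_params is None:
        if config.noise_model != "EP":
            raise ValueError(
                f"noise_params must be given explicitly for {config.noise_model}"
            )
        return _default_ep_params(config.delay_set)[delay]
    params = config.noise_params
    if delay in params:
        return dict(params[delay])
    if float(delay) in params:
        return dict(params[float(delay)])
    # flat dict applying to all delays
    return dict(params)


def _draw_noise_deg(model: str, params: dict, n: int, rng: np.random.Generator):
    """Draw n circular errors (degrees, signed) from one noise model."""
    rad2deg = 180.0 / np.pi
    if model == "EP":
        return rng.vonmises(0.0, params["kappa"], size=n) * rad2deg
    if model == "VP":
        from .wmmodels import j_to_kappa

        j_bar, tau = params["J_bar"], params["tau"]
        j = rng.gamma(shape=j_bar / tau, scale=tau, size=n)
        kappa = np.maximum(j_to_kappa(j), 1e-12)
        return rng.vonmises(0.0, kappa) * rad2deg
    if model == "VMRW":
        from .wmmodels import vmrw_sample_errors

        return vmrw_sample_errors(params["kappa"], params["xi"], n, rng) * rad2deg
    raise ValueError(f"unknown noise model: {model!r}")


def _bias_fn(config: GeneratorConfig):
    """Return bias(x_prev_deg, delay_s) -> degrees for the configured shape."""
    if config.bias_shape == "none":
        return lambda x, d: 0.0
    params = dict(config.bias_params or {})
    if config.bias_shape == "DoG":
        from .tuning import DoGParams, dog_curve

        amp = params.get("amplitude", DEFAULT_AMPLITUDE_SCHEDULE)
        width = params.get("w", 0.02)

        def bias(x, d):
            a = amp[d] if isinstance(amp, Mapping) else amp
            return dog_curve(x, DoGParams(a=a, w=width))

        return bias
    from .tuning import CliffordParams, clifford_curve

    cp = CliffordParams(
        s_scale=params.get("s_scale", 1.0),
        c_center=params.get("c_center", 0.2),
        sign=params.get("sign", 1),
    )
    return lambda x, d: clifford_curve(x, cp)


def generate_session(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a multi-subject synthetic session.

    Each subject's stream is seeded by (config.seed, subject index), so
    subjects are independently reproducible. The first trial of each subject
    carries no trial-history bias.
    """
    bias = _bias_fn(config)
    frames = []
    for si in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, si])
        n = config.n_trials_per_subject
        stim = rng.uniform(0.0, 360.0, size=n)
        delays = rng.choice(config.delay_set, size=n, p=config.delay_weights)
        itis = rng.choice(config.iti_set, size=n, p=config.iti_weights)

        # systematic error: smooth low-order sinusoids of stimulus angle
        sys_err = np.zeros(n)
        for order, amp_deg, phase_deg in config.systematic_error:
            sys_err += amp_deg * np.sin(
                np.deg2rad(order * stim + phase_deg)
            )

        noise = np.empty(n)
        for d in config.delay_set:
            mask = delays == d
            if mask.any():
                noise[mask] = _draw_noise_deg(
                    config.noise_model,
                    _noise_params_for(config, d),
                    int(mask.sum()),
                    rng,
                )

        x_prev = np.zeros(n)
        x_prev[1:] = wrap_signed(stim[:-1] - stim[1:])
        bias_term = np.array(
            [0.0] + [bias(x_prev[i], delays[i]) for i in range(1, n)]
        )

        error = wrap_signed(sys_err + bias_term + noise)

        # gross outliers: substitute an error beyond 3 SD of the noise
        if config.outlier_rate > 0:
            sd = float(np.std(noise))
            lo = min(3.0 * sd, 90.0)
            is_out = rng.random(n) < config.outlier_rate
            k = int(is_out.sum())
            if k:
                mag = rng.uniform(lo, 179.0, size=k)
                error[is_out] = mag * rng.choice([-1.0, 1.0], size=k)

        ecc = np.full(n, STIMULUS_ECCENTRICITY)
        resp = wrap_positive(stim + error)
        if config.origin_click_rate > 0:
            is_click = rng.random(n) < config.origin_click_rate
            k = int(is_click.sum())
            if k:
                ecc[is_click] = rng.uniform(0.0, 5.0, size=k)
                # a near-origin click has an arbitrary direction
                resp[is_click] = rng.uniform(0.0, 360.0, size=k)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{si:02d}",
                    "trial_index": np.arange(n),
                    "stimulus_angle": stim,
                    "response_angle": resp,
                    "response_eccentricity": ecc,
                    "delay_s": delays,
                    "iti_s": itis,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def validate_trials(table: pd.DataFrame) -> None:
    """Raise ValueError if a trial table violates the format invariants."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table) == 0:
        return
    for col in ("stimulus_angle", "response_angle"):
        v = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v >= 360.0):
            raise ValueError(f"{col} must lie in [0, 360)")
    if np.any(table["response_eccentricity"].to_numpy(dtype=float) < 0):
        raise ValueError("response_eccentricity must be >= 0")
    for _, g in table.groupby("subject_id", sort=False):
        idx = g["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError("trial_index must be strictly increasing per subject")


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as delimited text with header."""
    validate_trials(table)
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    validate_trials(table)
    return table
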