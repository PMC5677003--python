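import numpy as np
import pytest

from serialdep import preprocess as pp
from serialdep import synthetic_data as syn

#: von Mises concentration (radian-scale) giving ~5 deg error SD
KAPPA_5DEG = 1.0 / np.deg2rad(5.0) ** 2


def make_xy(
    seed,
    n=500,
    amplitude=0.0,
    w=0.02,
    kappa=KAPPA_5DEG,
    bias_shape=None,
):
    """One-subject session reduced to (x_prev, raw_error) pairs."""
    shape = bias_shape or ("DoG" if amplitude else "none")
    cfg = syn.GeneratorConfig(
        n_subjects=1,
        n_trials_per_subject=n,
        delay_set=(0.0,),
        noise_model="EP",
        noise_params={"kappa": kappa},
        bias_shape=shape,
        bias_params={"amplitude": amplitude, "w": w} if shape == "DoG" else None,
        seed=seed,
    )
    tab = pp.annotate_history(pp.add_raw_error(syn.generate_session(cfg)))
    x = tab["x_prev"].to_numpy(dtype=float)
    y = tab["raw_error"].to_numpy(dtype=float)
    ok = np.isfinite(x)
    return x[ok], y[ok]


@pytest.fixture
def biased_xy():
    """Session with an injected 3 deg DoG bias (true peak-to-peak 6 deg)."""
    return make_xy(seed=11, n=1000, amplitude=3.0)


@pytest.fixture
def unbiased_xy():
    return make_xy(seed=12, n=1000, amplitude=0.0)
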