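"""Circular arithmetic helpers.

All public angles in this package are degrees of polar angle. Signed angular
differences live on (−180, 180]; absolute angles on [0, 360).
"""

from __future__ import annotations

import numpy as np

DEG2RAD = np.pi / 180.0
RAD2DEG = 180.0 / np.pi


def wrap_signed(deg):
    """Wrap angle(s) in degrees to the half-open interval (−180, 180]."""
    d = np.asarray(deg, dtype=float)
    out = d - 360.0 * np.floor((d + 180.0) / 360.0)
    # floor maps +180 to -180; put the boundary back on the positive side
    out = np.where(out == -180.0, 180.0, out)
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(out)
    return out


def wrap_positive(deg):
    """Wrap angle(s) in degrees to [0, 360)."""
    d = np.asarray(deg, dtype=float)
    out = np.mod(d, 360.0)
    out = np.where(out == 360.0, 0.0, out)
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(out)
    return out


def circ_diff(a_deg, b_deg):
    """Signed circular difference a − b in degrees, wrapped to (−180, 180]."""
    return wrap_signed(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def circ_mean_deg(deg):
    """Circular mean of angles in degrees, returned in (−180, 180]."""
    r = np.asarray(deg, dtype=float) * DEG2RAD
    return wrap_signed(np.angle(np.exp(1j * r).mean()) * RAD2DEG)
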