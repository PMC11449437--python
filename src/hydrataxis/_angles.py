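"""Small helpers for angle arithmetic in degrees.

Angles live on the circle; the canonical signed representation used
throughout the package is the half-open interval (-180, 180].
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["wrap_deg", "circular_mean_deg"]


def wrap_deg(a):
    """Wrap angle(s) in degrees to (-180, 180].

    Works on scalars and arrays. The boundary maps to +180, never -180,
    so the representation is unique.
    """
    if np.isscalar(a):
        w = math.fmod(a + 180.0, 360.0)
        if w <= 0.0:
            w += 360.0
        return w - 180.0
    a = np.asarray(a, dtype=float)
    w = np.mod(a + 180.0, 360.0)
    w = np.where(w == 0.0, 360.0, w)
    return w - 180.0


def circular_mean_deg(angles) -> float:
    """Circular mean of angles in degrees, wrapped to (-180, 180]."""
    a = np.radians(np.asarray(angles, dtype=float))
    s = np.sin(a).mean()
    c = np.cos(a).mean()
    return float(wrap_deg(math.degrees(math.atan2(s, c))))
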