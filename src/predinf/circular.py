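"""Circular (angular) helpers used throughout the package.

All public angles are in degrees on [0, 360); signed differences live on
(-180, 180]. Radians appear only inside the Von Mises likelihood.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap360", "circ_diff"]


def wrap360(angle):
    """Reduce an angle (degrees) to [0, 360)."""
    r = np.asarray(angle) % 360.0
    # tiny negative inputs can round to exactly 360.0
    r = np.where(r >= 360.0, 0.0, r)
    if r.ndim == 0:
        return float(r)
    return r


def circ_diff(a, b):
    """Signed circular distance ``a - b`` in degrees, mapped to (-180, 180].

    This is the shortest signed arc from ``b`` to ``a``: positive when ``a``
    lies counter-clockwise of ``b``. Antipodal pairs return +180 by
    convention.

    Examples
    --------
    >>> circ_diff(10, 350)
    20.0
    >>> circ_diff(350, 10)
    -20.0
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d
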