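"""Haldane map function: genetic distance ↔ recombination fraction.

The whole package assumes crossovers without interference, so distance and
recombination fraction interconvert via c = (1 − e^(−2d))/2 for d in Morgans.
"""

from __future__ import annotations

import numpy as np


def haldane_c(d_morgan):
    """Recombination fraction for a genetic distance in Morgans."""
    d = np.asarray(d_morgan, dtype=float)
    if (d < 0).any():
        raise ValueError("genetic distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def haldane_c_cm(d_cm):
    """Recombination fraction for a genetic distance in centiMorgans."""
    return haldane_c(np.asarray(d_cm, dtype=float) / 100.0)


def inverse_haldane_cm(c):
    """Genetic distance in cM for a recombination fraction c < 0.5."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any() or (c >= 0.5).any():
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log1p(-2.0 * c)
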