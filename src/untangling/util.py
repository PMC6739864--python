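"""Small shared helpers: angle conventions and RNG coercion.

All public interfaces of the package use degrees; trigonometry is done in
radians internally.  These helpers centralise the conversions so that no
module hand-rolls its own.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def rad(deg):
    """Degrees to radians (array-safe)."""
    return np.deg2rad(deg)


def wrap_orientation(theta_deg):
    """Wrap an orientation into its principal range [0, 180)."""
    return np.mod(theta_deg, 180.0)


def wrap_phase(phi_deg):
    """Wrap a phase into its principal range [0, 360)."""
    return np.mod(phi_deg, 360.0)


def circ_orientation_distance(a_deg, b_deg):
    """Circular distance between orientations (period 180 deg), in [0, 90]."""
    d = np.mod(a_deg - b_deg, 180.0)
    return np.minimum(d, 180.0 - d)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, None, or Generator into a numpy Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
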