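"""6-12 Lennard-Jones pair potential and force.

The potential is written so that its minimum sits exactly at ``r = sigma``
with depth ``-epsilon``:

    P(r) = epsilon * [ (sigma/r)**12 - 2 * (sigma/r)**6 ]

and the force magnitude is f(r) = -dP/dr, positive (repulsive) for
r < sigma, negative (attractive) for sigma < r < cutoff, zero beyond the
cutoff.  No energy shift is applied at the cutoff: only forces drive the
overdamped dynamics, so the small force discontinuity there is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LJParams", "lj_potential", "lj_force_magnitude"]


class InvalidDistanceError(ValueError):
    """Pair distance outside the potential's domain (r <= 0)."""


@dataclass(frozen=True)
class LJParams:
    """epsilon: well depth (paper units, before epsilon_scale); sigma:
    equilibrium pair distance; cutoff: force truncation radius."""

    epsilon: float
    sigma: float = 2.5
    cutoff: float | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.cutoff is None:
            object.__setattr__(self, "cutoff", 3.0 * self.sigma)
        if self.cutoff <= self.sigma:
            raise ValueError("cutoff must exceed sigma")


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidDistanceError("pair distance must be > 0")
    return r


def lj_potential(r, params: LJParams):
    """Pair energy at distance r; 0 beyond the cutoff."""
    r = _check_r(r)
    s6 = (params.sigma / r) ** 6
    out = params.epsilon * (s6 * s6 - 2.0 * s6)
    return np.where(r > params.cutoff, 0.0, out)


def lj_force_magnitude(r, params: LJParams):
    """Radial force f(r) = -dP/dr = (12 eps / r) [(sigma/r)^12 - (sigma/r)^6];
    0 beyond the cutoff."""
    r = _check_r(r)
    s6 = (params.sigma / r) ** 6
    out = (12.0 * params.epsilon / r) * (s6 * s6 - s6)
    return np.where(r > params.cutoff, 0.0, out)
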