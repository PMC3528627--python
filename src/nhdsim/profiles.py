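"""Periodic, strictly positive diffusion-amplitude fields.

The membrane is a segment [-L, L) (1D) or square [-L, L)^2 (2D) with toric
topology.  A diffusion profile assigns to every position a noise amplitude
``a(x) > 0`` (the standard deviation entering the stochastic equation of
motion); the physical diffusion coefficient is its square, ``D = a**2``.
Slow zones -- "cholesterol patches" or Gaussian viscosity wells -- are
regions where the amplitude dips below the baseline.

All fields built here are exactly 2L-periodic and continuously
differentiable, which the closed-form theory requires.  Gaussian wells are
periodized by summing periodic images; the square patch is bounded by a
smooth logistic edge band instead of a hard discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DiffusionProfile",
    "GaussianWellSpec",
    "SquarePatchSpec",
    "make_gaussian_profile",
    "make_patch_profile",
    "make_constant_profile",
    "wrap",
    "minimum_image_displacement",
]

# kernel_spec kind codes shared with engine._kernels
KIND_CONSTANT = 0
KIND_PATCH = 1
KIND_GAUSSIAN = 2


class InvalidParameterError(ValueError):
    """A profile or simulation parameter violates its contract."""


def wrap(position, L: float):
    """Map coordinates into the half-open interval [-L, L) per axis.

    Idempotent; ``wrap(-L) == -L`` by convention.
    """
    return np.mod(np.asarray(position) + L, 2.0 * L) - L


def minimum_image_displacement(p1, p2, L: float):
    """Per-axis displacement from ``p1`` to ``p2`` under the minimum-image
    convention; its norm is the geodesic distance on the torus."""
    return wrap(np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float), L)


@dataclass(frozen=True)
class DiffusionProfile:
    """A spatial noise-amplitude field on the periodic domain.

    ``amplitude`` and ``gradient`` are vectorized callables.  For ``dim == 1``
    they take arrays of shape (...,) and return the same shape; for
    ``dim == 2`` they take (..., 2), with ``gradient`` returning (..., 2)
    (per-axis partial derivatives of the amplitude).
    """

    dim: int
    L: float
    amplitude: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    kernel_spec: tuple | None = field(default=None, compare=False)

    def diffusion(self, x) -> np.ndarray:
        """Diffusion coefficient D = amplitude**2."""
        return self.amplitude(x) ** 2


@dataclass(frozen=True)
class GaussianWellSpec:
    """Inverse-Gaussian well(s): a(x) = D0 * (1 - d * exp(-|x - c|^2 / omega)).

    ``d`` in [0, 1) keeps the amplitude strictly positive; ``omega`` is the
    squared width.  ``centers`` holds one scalar per well in 1D, or one
    (x, y) pair per well in 2D; the multi-well 2D field is the arithmetic
    mean of the single-well fields.
    """

    D0: float = 1.0
    d: float = 0.9
    omega: float = 0.1
    centers: tuple = (0.0,)

    def __post_init__(self):
        if not (0.0 <= self.d < 1.0):
            raise InvalidParameterError(f"well depth d={self.d} must be in [0, 1)")
        if self.omega <= 0.0:
            raise InvalidParameterError(f"squared width omega={self.omega} must be > 0")
        if self.D0 <= 0.0:
            raise InvalidParameterError(f"baseline D0={self.D0} must be > 0")
        object.__setattr__(self, "centers", tuple(
            tuple(c) if np.ndim(c) else float(c) for c in self.centers))

    @property
    def dim(self) -> int:
        return 2 if np.ndim(self.centers[0]) else 1


@dataclass(frozen=True)
class SquarePatchSpec:
    """A square slow zone where the amplitude is ``ratio_r`` times smaller.

    ``ratio_r = sqrt(D0 / D_patch) >= 1`` is the amplitude ratio between the
    bulk and the patch interior.  The boundary is a monotone logistic band of
    width ``edge_width`` so the field stays continuously differentiable.
    """

    patch_center: tuple[float, float]
    patch_side: float
    ratio_r: float
    edge_width: float

    def __post_init__(self):
        if self.ratio_r < 1.0:
            raise InvalidParameterError(f"ratio_r={self.ratio_r} must be >= 1")
        if self.edge_width <= 0.0:
            raise InvalidParameterError("edge_width must be > 0")
        if self.patch_side <= 0.0:
            raise InvalidParameterError("patch_side must be > 0")


def _n_images(omega: float, L: float) -> int:
    # images beyond exp(-((2m-1)L)^2/omega) < 1e-18 contribute nothing
    m = int(np.ceil((np.sqrt(43.0 * omega) / L + 1.0) / 2.0))
    return min(max(m, 1), 64)


def _periodic_gauss(u: np.ndarray, omega: float, L: float, m: int):
    """Sum of Gaussian images S(u) = sum_k exp(-(u + 2Lk)^2/omega) and dS/du,
    for u already wrapped into [-L, L)."""
    s = np.zeros_like(u)
    ds = np.zeros_like(u)
    for k in range(-m, m + 1):
        v = u + 2.0 * L * k
        e = np.exp(-v * v / omega)
        s += e
        ds += (-2.0 * v / omega) * e
    return s, ds


def make_constant_profile(D0: float = 1.0, L: float = 1.0, dim: int = 1) -> DiffusionProfile:
    """Homogeneous membrane: a(x) = D0 everywhere, zero gradient."""
    if D0 <= 0:
        raise InvalidParameterError("D0 must be > 0")

    if dim == 1:
        def amplitude(x):
            return np.full_like(np.asarray(x, dtype=float), D0)

        def gradient(x):
            return np.zeros_like(np.asarray(x, dtype=float))
    else:
        def amplitude(x):
            return np.full(np.asarray(x).shape[:-1], D0, dtype=float)

        def gradient(x):
            return np.zeros(np.asarray(x, dtype=float).shape)

    spec = (KIND_CONSTANT, np.array([D0], dtype=np.float64))
    return DiffusionProfile(dim=dim, L=L, amplitude=amplitude, gradient=gradient,
                            kernel_spec=spec)


def make_gaussian_profile(spec: GaussianWellSpec, L: float = 1.0) -> DiffusionProfile:
    """Build the periodized inverse-Gaussian well profile.

    1D:  a(x) = D0 * (1 - d * S(x - c))
    2D:  a(x, y) = (1/K) * sum_i D0 * (1 - d * Sx_i * Sy_i)
    with S the image-summed Gaussian, so the field is exactly 2L-periodic.
    """
    if spec.d == 0.0:
        return make_constant_profile(spec.D0, L, spec.dim)
    m = _n_images(spec.omega, L)
    D0, d, omega = spec.D0, spec.d, spec.omega

    if spec.dim == 1:
        centers = np.array(spec.centers, dtype=float)

        def amplitude(x):
            x = np.asarray(x, dtype=float)
            acc = np.zeros(x.shape)
            for c in centers:
                s, _ = _periodic_gauss(wrap(x - c, L), omega, L, m)
                acc += 1.0 - d * s
            return D0 * acc / len(centers)

        def gradient(x):
            x = np.asarray(x, dtype=float)
            acc = np.zeros(x.shape)
            for c in centers:
                _, ds = _periodic_gauss(wrap(x - c, L), omega, L, m)
                acc += -d * ds
            return D0 * acc / len(centers)
    else:
        centers = np.array([list(c) for c in spec.centers], dtype=float)

        def amplitude(x):
            x = np.asarray(x, dtype=float)
            acc = np.zeros(x.shape[:-1])
            for cx, cy in centers:
                sx, _ = _periodic_gauss(wrap(x[..., 0] - cx, L), omega, L, m)
                sy, _ = _periodic_gauss(wrap(x[..., 1] - cy, L), omega, L, m)
                acc += 1.0 - d * sx * sy
            return D0 * acc / len(centers)

        def gradient(x):
            x = np.asarray(x, dtype=float)
            out = np.zeros(x.shape)
            for cx, cy in centers:
                sx, dsx = _periodic_gauss(wrap(x[..., 0] - cx, L), omega, L, m)
                sy, dsy = _periodic_gauss(wrap(x[..., 1] - cy, L), omega, L, m)
                out[..., 0] += -d * dsx * sy
                out[..., 1] += -d * sx * dsy
            return D0 * out / len(centers)

        kparams = np.concatenate([[D0, d, omega, float(m), float(len(centers))],
                                  centers.ravel()]).astype(np.float64)
        prof = DiffusionProfile(dim=2, L=L, amplitude=amplitude, gradient=gradient,
                                kernel_spec=(KIND_GAUSSIAN, kparams))
        return prof

    return DiffusionProfile(dim=1, L=L, amplitude=amplitude, gradient=gradient)


def _smootherstep(z):
    """Quintic smoothstep: 0 below 0, 1 above 1, C2 at both ends."""
    zc = np.clip(z, 0.0, 1.0)
    s = zc ** 3 * (10.0 + zc * (-15.0 + 6.0 * zc))
    ds = np.where((z > 0.0) & (z < 1.0), 30.0 * zc ** 2 * (1.0 - zc) ** 2, 0.0)
    return s, ds


def make_patch_profile(spec: SquarePatchSpec, L: float, D0: float = 1.0) -> DiffusionProfile:
    """Square slow patch: amplitude exactly D0/r inside, exactly D0 outside,
    joined by a compactly supported C2 smoothstep band of width
    ``edge_width`` straddling the nominal boundary.  (A band with
    exponential tails would leak into the interior: the equilibrium density
    1/(1 - (1-1/r) f) is hypersensitive to f near 1 at large r.)  Wrap-aware,
    so a patch crossing the domain seam is handled correctly.  2D only."""
    if D0 <= 0:
        raise InvalidParameterError("D0 must be > 0")
    if spec.patch_side + spec.edge_width >= 2.0 * L:
        raise InvalidParameterError("patch does not fit inside the domain")
    cx, cy = spec.patch_center
    h = spec.patch_side / 2.0
    w = spec.edge_width
    r = spec.ratio_r
    depth = D0 * (1.0 - 1.0 / r)
    if h <= w / 2.0:
        raise InvalidParameterError("edge_width too large for the patch side")

    def _edge(u):
        # smooth indicator of [-h, h]: 1 for |u| <= h - w/2, 0 for |u| >= h + w/2
        s, ds = _smootherstep((h + w / 2.0 - np.abs(u)) / w)
        f = s
        df = -np.sign(u) * ds / w
        return f, df

    def amplitude(x):
        x = np.asarray(x, dtype=float)
        fx, _ = _edge(wrap(x[..., 0] - cx, L))
        fy, _ = _edge(wrap(x[..., 1] - cy, L))
        return D0 - depth * fx * fy

    def gradient(x):
        x = np.asarray(x, dtype=float)
        fx, dfx = _edge(wrap(x[..., 0] - cx, L))
        fy, dfy = _edge(wrap(x[..., 1] - cy, L))
        out = np.empty(x.shape)
        out[..., 0] = -depth * dfx * fy
        out[..., 1] = -depth * fx * dfy
        return out

    kparams = np.array([D0, r, cx, cy, h, w], dtype=np.float64)
    return DiffusionProfile(dim=2, L=L, amplitude=amplitude, gradient=gradient,
                            kernel_spec=(KIND_PATCH, kparams))
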