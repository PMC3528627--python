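"""Stochastic integrators for particles on the periodic membrane.

Non-interacting particles follow the multiplicative-noise SDE
``dX = a(X) dZ`` integrated either with the Milstein scheme for the
Stratonovich reading,

    X <- wrap(X + sqrt(dt) a(X) Z + (dt/2) a(X) a'(X) Z**2),

or with the plain Euler increment ``X <- wrap(X + sqrt(dt) a(X) Z)`` for the
Ito reading.  The two conventions equilibrate to different stationary laws
(rho ~ 1/a vs rho ~ 1/a**2), which is the scientific point of the contrast.

Interacting runs (2D) add a mobility-weighted Lennard-Jones drift
``dt * D(X_j) * sum_i f(r_ij) u_ij`` and an optional hard-core collision
pass; their inner loops are compiled (see ``_kernels``) but mirror the
public numpy functions below, which the tests cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .interactions import LJParams, lj_force_magnitude
from .profiles import DiffusionProfile, InvalidParameterError, minimum_image_displacement, wrap

__all__ = [
    "ParticleState",
    "SimConfig",
    "Trajectory",
    "milstein_step",
    "ito_step",
    "interaction_drift",
    "resolve_collisions",
    "build_neighbor_lists",
    "equilibrate_annealed",
    "sample_equilibrium_positions",
    "simulate",
]


class ConfigurationError(ValueError):
    pass


class InitializationError(ValueError):
    pass


class SimulationDivergedError(RuntimeError):
    pass


@dataclass
class ParticleState:
    """Positions of N particles at one time; shape (N, dim), wrapped."""

    positions: np.ndarray
    time: float = 0.0
    bleached: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class SimConfig:
    """Integrator and experiment parameters for one run."""

    n_particles: int
    n_steps: int
    dt: float = 0.01
    formalism: str = "stratonovich"
    seed: int = 0
    sample_every: int = 100
    interaction: Optional[LJParams] = None
    epsilon_scale: float = 1.5e-4
    mobility_weighted: bool = True
    collisions: bool = False
    core_diameter: Optional[float] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.n_steps < 1 or self.n_particles < 1:
            raise ConfigurationError("n_steps and n_particles must be >= 1")
        if self.formalism not in ("stratonovich", "ito"):
            raise ConfigurationError(f"unknown formalism {self.formalism!r}")
        if self.sample_every < 1 or self.sample_every > self.n_steps:
            raise ConfigurationError("sample_every must be in [1, n_steps]")
        if self.collisions and self.core_diameter is None and self.interaction is None:
            raise ConfigurationError(
                "collisions need core_diameter (or an interaction whose sigma is the default)")

    @property
    def effective_core(self) -> float:
        if self.core_diameter is not None:
            return self.core_diameter
        return self.interaction.sigma if self.interaction else 0.0

    @property
    def effective_epsilon(self) -> float:
        return self.interaction.epsilon * self.epsilon_scale if self.interaction else 0.0


@dataclass
class Trajectory:
    """States sampled every ``config.sample_every`` steps (excluding t=0)."""

    times: np.ndarray
    positions: np.ndarray  # (S, N, dim)
    config: SimConfig
    profile: DiffusionProfile = field(repr=False, default=None)

    @property
    def final_state(self) -> ParticleState:
        return ParticleState(self.positions[-1].copy(), time=float(self.times[-1]))

    def states_after(self, t_min: float) -> np.ndarray:
        """Positions of all samples with time >= t_min, shape (S', N, dim)."""
        return self.positions[self.times >= t_min - 1e-12]


def _amp_grad_arrays(profile: DiffusionProfile, positions: np.ndarray):
    if profile.dim == 1:
        x = positions[:, 0]
        return profile.amplitude(x)[:, None], profile.gradient(x)[:, None]
    return profile.amplitude(positions)[:, None], profile.gradient(positions)


def milstein_step(state: ParticleState, profile: DiffusionProfile, dt: float,
                  rng) -> ParticleState:
    """Stratonovich Milstein update; per particle and axis
    X += sqrt(dt) a Z + (dt/2) a (da/daxis) Z^2 with independent Z."""
    if profile.gradient is None:
        raise ConfigurationError("profile gradient unavailable")
    Z = rng.standard_normal(state.positions.shape)
    amp, grad = _amp_grad_arrays(profile, state.positions)
    new = state.positions + np.sqrt(dt) * amp * Z + 0.5 * dt * amp * grad * Z ** 2
    return ParticleState(wrap(new, profile.L), time=state.time + dt,
                         bleached=state.bleached)


def ito_step(state: ParticleState, profile: DiffusionProfile, dt: float,
             rng) -> ParticleState:
    """Euler update without the Stratonovich correction; long-run histogram
    converges to rho ~ 1/a**2."""
    Z = rng.standard_normal(state.positions.shape)
    amp, _ = _amp_grad_arrays(profile, state.positions)
    new = state.positions + np.sqrt(dt) * amp * Z
    return ParticleState(wrap(new, profile.L), time=state.time + dt,
                         bleached=state.bleached)


def build_neighbor_lists(positions: np.ndarray, cutoff: float, L: float):
    """Neighbor indices within ``cutoff`` under minimum image, per particle."""
    if cutoff >= L:
        raise InvalidParameterError("cutoff must be < L")
    positions = np.atleast_2d(positions)
    tree = cKDTree(np.mod(positions + L, 2.0 * L), boxsize=2.0 * L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = positions.shape[0]
    lists = [[] for _ in range(n)]
    for i, j in pairs:
        lists[i].append(j)
        lists[j].append(i)
    return [np.array(sorted(l), dtype=np.int64) for l in lists]


def interaction_drift(state: ParticleState, profile: DiffusionProfile,
                      lj: LJParams, dt: float, epsilon_scale: float = 1e-4,
                      mobility_weighted: bool = True,
                      drift_cap: Optional[float] = None) -> np.ndarray:
    """Deterministic per-particle displacement from pairwise forces:
    ``dt * D(X_j) * sum_{i != j, r_ij < cutoff} f(r_ij) u_ij`` with u_ij the
    unit vector from i to j.  Forces under 0.5 sigma are clamped to the value
    at 0.5 sigma; displacement norms are capped at ``drift_cap`` (default
    0.5 sigma)."""
    pos = state.positions
    L = profile.L
    eps = lj.epsilon * epsilon_scale
    if eps == 0.0:
        return np.zeros_like(pos)
    if drift_cap is None:
        drift_cap = 0.5 * lj.sigma
    clamped = LJParams(epsilon=eps, sigma=lj.sigma, cutoff=lj.cutoff)
    lists = build_neighbor_lists(pos, lj.cutoff, L)
    disp = np.zeros_like(pos)
    for j, neigh in enumerate(lists):
        if len(neigh) == 0:
            continue
        u = minimum_image_displacement(pos[neigh], pos[j], L)  # from i to j
        r = np.linalg.norm(u, axis=1)
        reff = np.maximum(r, 0.5 * lj.sigma)
        f = lj_force_magnitude(reff, clamped)
        disp[j] = (f / r) @ u
    if mobility_weighted:
        amp, _ = _amp_grad_arrays(profile, pos)
        disp *= amp ** 2
    disp *= dt
    norms = np.linalg.norm(disp, axis=1)
    over = norms > drift_cap
    if np.any(over):
        disp[over] *= (drift_cap / norms[over])[:, None]
    return disp


def resolve_collisions(proposed: np.ndarray, previous: np.ndarray,
                       core_diameter: float, L: float,
                       order: Optional[np.ndarray] = None,
                       rng=None) -> np.ndarray:
    """Hard-core pass: particles are visited once in (random) order; a move
    that would land within ``core_diameter`` of any other particle's current
    position is rejected, leaving the particle at its previous position."""
    previous = np.atleast_2d(previous)
    n = previous.shape[0]
    if order is None:
        order = (rng or np.random.default_rng()).permutation(n)
    current = previous.copy()
    for j in order:
        p = proposed[j]
        d = minimum_image_displacement(current, p, L)
        r2 = np.einsum("ij,ij->i", d, d)
        r2[j] = np.inf
        if r2.min() >= core_diameter ** 2:
            current[j] = p
    return current


def equilibrate_annealed(config: SimConfig, profile: DiffusionProfile,
                         ramp_time: float, n_stages: int = 5,
                         initial_positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Equilibration aid for strongly coupled interacting runs: ramp the
    interaction strength linearly from ``epsilon/n_stages`` to ``epsilon``
    over ``n_stages`` equal segments of total duration ``ramp_time``,
    returning the final positions.

    A direct quench to a deep attraction freezes clusters wherever they
    first nucleate; the ramp keeps the system near quasi-equilibrium at
    each coupling, so clusters grow where the stationary measure puts the
    density (the slow zones) instead of in metastable positions.
    """
    if config.interaction is None or config.interaction.epsilon <= 0:
        raise ConfigurationError("annealed equilibration needs an interaction")
    stage_steps = max(int(round(ramp_time / config.dt / n_stages)), 1)
    pos = initial_positions
    for k in range(1, n_stages + 1):
        lj_k = LJParams(epsilon=config.interaction.epsilon * k / n_stages,
                        sigma=config.interaction.sigma,
                        cutoff=config.interaction.cutoff)
        cfg_k = SimConfig(n_particles=config.n_particles, n_steps=stage_steps,
                          dt=config.dt, formalism=config.formalism,
                          seed=config.seed * 131 + k,
                          sample_every=stage_steps, interaction=lj_k,
                          epsilon_scale=config.epsilon_scale,
                          mobility_weighted=config.mobility_weighted,
                          collisions=config.collisions,
                          core_diameter=config.core_diameter)
        pos = simulate(cfg_k, profile, initial_positions=pos).positions[-1]
    return pos


def sample_equilibrium_positions(profile: DiffusionProfile, n: int, rng,
                                 formalism: str = "stratonovich",
                                 min_distance: float = 0.0,
                                 max_tries: int = 500) -> np.ndarray:
    """Draw n positions from the closed-form stationary law by rejection
    sampling (acceptance probability proportional to 1/a, or 1/a**2 for
    Ito).  With ``min_distance`` > 0 overlapping draws are redrawn until the
    configuration is core-free, giving a warm start for hard-core runs."""
    k = 1 if formalism == "stratonovich" else 2
    L, dim = profile.L, profile.dim

    def _amp(pts):
        return profile.amplitude(pts[:, 0] if dim == 1 else pts)

    grid = np.linspace(-L, L, 512)
    if dim == 1:
        amin = float(profile.amplitude(grid).min())
    else:
        X, Y = np.meshgrid(grid, grid, indexing="ij")
        amin = float(profile.amplitude(np.stack([X, Y], axis=-1)).min())

    out = np.empty((0, dim))
    for _ in range(max_tries):
        need = n - out.shape[0]
        if need <= 0:
            break
        cand = rng.uniform(-L, L, size=(4 * need + 16, dim))
        accept = rng.uniform(0, 1, cand.shape[0]) < (amin / _amp(cand)) ** k
        out = np.vstack([out, cand[accept]])
    if out.shape[0] < n:
        raise InitializationError("rejection sampling failed to fill the state")
    out = out[:n]
    if min_distance > 0:
        for _ in range(max_tries):
            lists = build_neighbor_lists(out, min_distance, L)
            bad = np.array([i for i, l in enumerate(lists) if len(l)], dtype=int)
            if bad.size == 0:
                break
            # redraw the later member of each overlapping pair from the law
            keep = np.ones(n, dtype=bool)
            for i, l in enumerate(lists):
                if len(l) and np.any(np.asarray(l) < i):
                    keep[i] = False
            redraw = int((~keep).sum())
            if redraw == 0:
                break
            out = np.vstack([out[keep],
                             sample_equilibrium_positions(profile, redraw, rng,
                                                          formalism)])
        else:
            raise InitializationError("could not remove hard-core overlaps")
    return out


def _place_nonoverlapping(n: int, dim: int, L: float, core: float, rng,
                          max_tries: int = 200) -> np.ndarray:
    pos = np.empty((0, dim))
    for _ in range(max_tries):
        need = n - pos.shape[0]
        if need <= 0:
            break
        cand = rng.uniform(-L, L, size=(need, dim))
        pool = np.vstack([pos, cand])
        tree = cKDTree(np.mod(pool + L, 2 * L), boxsize=2 * L)
        pairs = tree.query_pairs(core, output_type="ndarray")
        bad = set()
        for i, j in pairs:
            if j >= pos.shape[0]:
                bad.add(j)
            elif i >= pos.shape[0]:
                bad.add(i)
        keep = [k for k in range(pos.shape[0], pool.shape[0]) if k not in bad]
        pos = np.vstack([pos, pool[keep]])
    if pos.shape[0] < n:
        raise InitializationError(
            f"could not place {n} non-overlapping particles (core={core})")
    return pos[:n]


def _check_stability(config: SimConfig, profile: DiffusionProfile):
    # largest rms step must stay well inside the domain
    if profile.dim == 1:
        grid = np.linspace(-profile.L, profile.L, 512)
        amax = float(profile.amplitude(grid).max())
    else:
        ax = np.linspace(-profile.L, profile.L, 128)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        amax = float(profile.amplitude(np.stack([X, Y], axis=-1)).max())
    if np.sqrt(config.dt) * amax > profile.L / 2.0:
        raise ConfigurationError(
            f"dt={config.dt} too large: rms step {np.sqrt(config.dt) * amax:.3g} "
            f"exceeds L/2={profile.L / 2:.3g}")


def simulate(config: SimConfig, profile: DiffusionProfile,
             initial_positions: Optional[np.ndarray] = None) -> Trajectory:
    """Run one seeded trajectory; bit-reproducible given (config, seed).

    Initial positions default to uniform draws (non-overlapping when
    collisions are on).  Sampled states exclude t=0 and are taken every
    ``sample_every`` steps.
    """
    _check_stability(config, profile)
    rng = np.random.default_rng(config.seed)
    L, dim = profile.L, profile.dim
    core = config.effective_core
    interacting = (config.interaction is not None and config.effective_epsilon > 0.0) \
        or config.collisions

    if initial_positions is None:
        if config.collisions:
            pos0 = _place_nonoverlapping(config.n_particles, dim, L, core, rng)
        else:
            pos0 = rng.uniform(-L, L, size=(config.n_particles, dim))
    else:
        pos0 = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if pos0.shape != (config.n_particles, dim):
            raise ConfigurationError(
                f"initial positions shape {pos0.shape} != {(config.n_particles, dim)}")
        if config.collisions:
            lists = build_neighbor_lists(pos0, core, L) if core < L else None
            if lists is not None and any(len(l) for l in lists):
                raise InitializationError("initial configuration already overlapping")

    n_samples = config.n_steps // config.sample_every
    times = config.dt * config.sample_every * np.arange(1, n_samples + 1)

    if interacting:
        if dim != 2:
            raise ConfigurationError("interacting runs are 2D only")
        if profile.kernel_spec is None:
            raise ConfigurationError("profile does not support compiled runs")
        kind, params = profile.kernel_spec
        lj = config.interaction or LJParams(epsilon=0.0, sigma=max(core, 1e-12),
                                            cutoff=3 * max(core, 1e-12))
        eps = config.effective_epsilon
        drift_cap = 0.5 * lj.sigma
        kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
        samples = _kernels.run_interacting(
            pos0.copy(), config.n_steps, config.sample_every, config.dt, L,
            kind, params, config.formalism == "stratonovich",
            eps, lj.sigma, lj.cutoff, config.mobility_weighted,
            core, config.collisions, drift_cap, kernel_seed)
        if not np.all(np.isfinite(samples)):
            raise SimulationDivergedError("non-finite positions in sampled states")
        return Trajectory(times=times, positions=samples, config=config, profile=profile)

    state = ParticleState(pos0, time=0.0)
    step = milstein_step if config.formalism == "stratonovich" else ito_step
    samples = np.empty((n_samples, config.n_particles, dim))
    si = 0
    for k in range(config.n_steps):
        state = step(state, profile, config.dt, rng)
        if (k + 1) % config.sample_every == 0:
            if not np.all(np.isfinite(state.positions)):
                raise SimulationDivergedError(f"non-finite position at step {k + 1}")
            samples[si] = state.positions
            si += 1
    return Trajectory(times=times, positions=samples, config=config, profile=profile)
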