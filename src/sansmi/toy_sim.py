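"""Minimal Langevin dynamics with soft pair potentials and synthetic structures.

This engine exists so the metainference machinery can be exercised
end-to-end without external MD software: soft-core repulsion plus a
short-range Gaussian attraction is the simplest potential that forms
cohesive droplets, and a BAOAB-discretized Langevin integrator samples the
canonical ensemble accurately at moderate time steps.

Internal units: Angstrom, femtosecond, Dalton; energies in Da Angstrom^2/fs^2
(1 Da A^2/fs^2 = 1e4 kJ/mol) with kB = 8.31446e-7 of these per kelvin.
Friction is given in 1/ps as is conventional.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import SiteSet
from .metainference import (MetaInfState, SANSForwardModel,
                            bias_energy_and_forces, chi_squared, mc_update)

__all__ = [
    "KB",
    "SimConfig",
    "PairParams",
    "make_uniform_sphere",
    "make_dumbbell",
    "pair_forces",
    "langevin_step",
    "SimResult",
    "run_simulation",
]

KB = 8.31446262e-7  # Da Angstrom^2 fs^-2 K^-1


@dataclass
class SimConfig:
    dt: float = 10.0            # fs
    temperature: float = 300.0  # K
    friction: float = 1.0       # 1/ps
    steps: int = 1000
    bias_stride: int = 20       # bias force refreshed every this many steps
    box: float | None = None    # Angstrom (cubic); None = open boundaries
    seed: int = 0
    log_stride: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.bias_stride < 1:
            raise ValueError("bias_stride must be >= 1")


@dataclass
class PairParams:
    """U(r) = A (1 - r/r_c)^2 for r < r_c  -  B exp(-(r - r0)^2 / w^2)."""

    repulsion: float = 2e-4     # A, energy units
    r_cut: float = 6.0          # r_c, Angstrom
    attraction: float = 0.0     # B, energy units
    r_attr: float = 6.0         # r0, Angstrom
    width: float = 3.0          # w, Angstrom


def make_uniform_sphere(radius: float, n: int, b: float,
                        rng: np.random.Generator,
                        mass: float = 72.0,
                        center=(0.0, 0.0, 0.0)) -> SiteSet:
    """n sites uniform in a ball of the given radius (rejection sampling)."""
    if radius <= 0 or n < 1:
        raise ValueError("radius must be positive and n >= 1")
    pts = np.empty((n, 3))
    have = 0
    while have < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - have) + 16, 3))
        keep = cand[np.sum(cand * cand, axis=1) <= radius * radius]
        take = min(keep.shape[0], n - have)
        pts[have:have + take] = keep[:take]
        have += take
    return SiteSet(positions=pts + np.asarray(center, dtype=float),
                   scatlens=np.full(n, b), masses=np.full(n, mass),
                   labels=["X"] * n)


def make_dumbbell(radius: float, n_per_lobe: int, separation: float, b: float,
                  rng: np.random.Generator, mass: float = 72.0) -> SiteSet:
    """Two uniform balls with centres ``separation`` apart along x."""
    if separation < 0:
        raise ValueError("separation must be non-negative")
    half = separation / 2.0
    a = make_uniform_sphere(radius, n_per_lobe, b, rng, mass,
                            center=(-half, 0.0, 0.0))
    c = make_uniform_sphere(radius, n_per_lobe, b, rng, mass,
                            center=(half, 0.0, 0.0))
    return SiteSet(
        positions=np.vstack([a.positions, c.positions]),
        scatlens=np.concatenate([a.scatlens, c.scatlens]),
        masses=np.concatenate([a.masses, c.masses]),
        labels=a.labels + c.labels,
    )


def pair_forces(positions: np.ndarray, params: PairParams,
                box: float | np.ndarray | None = None):
    """Forces (-grad U) and potential energy of the soft pair potential.

    Overlapping sites (r < 1e-6 A) are guarded by clamping the distance,
    which caps the force; a warning is logged once per call.
    """
    x = np.asarray(positions, dtype=float)
    m = x.shape[0]
    forces = np.zeros_like(x)
    if m < 2:
        return forces, 0.0
    disp = x[:, None, :] - x[None, :, :]
    if box is not None:
        boxv = np.broadcast_to(np.asarray(box, dtype=float), (3,))
        disp -= boxv * np.round(disp / boxv)
    r = np.linalg.norm(disp, axis=-1)
    iu = np.triu_indices(m, k=1)
    rr = r[iu]
    if np.any(rr < 1e-6):
        warnings.warn("overlapping sites; pair force capped", stacklevel=2)
        rr = np.maximum(rr, 1e-6)
    # repulsion
    inside = rr < params.r_cut
    t = np.where(inside, 1.0 - rr / params.r_cut, 0.0)
    u_rep = params.repulsion * t * t
    f_rep = 2.0 * params.repulsion * t / params.r_cut  # magnitude, repulsive
    # attraction
    if params.attraction != 0.0:
        g = np.exp(-((rr - params.r_attr) ** 2) / params.width**2)
        u_att = -params.attraction * g
        f_att = -2.0 * params.attraction * (rr - params.r_attr) / params.width**2 * g
    else:
        u_att = np.zeros_like(rr)
        f_att = np.zeros_like(rr)
    fmag = f_rep + f_att  # dU/dr with sign flipped: positive pushes apart
    unit = disp[iu] / rr[:, None]
    fvec = fmag[:, None] * unit
    np.add.at(forces, iu[0], fvec)
    np.add.at(forces, iu[1], -fvec)
    return forces, float(np.sum(u_rep + u_att))


def langevin_step(positions, velocities, forces, force_fn, masses,
                  cfg: SimConfig, rng: np.random.Generator):
    """One BAOAB Langevin update; returns (positions, velocities, forces).

    With friction 0 the O-step is the identity and the scheme reduces to
    velocity Verlet (NVE); at T = 0 with zero forces and velocities the
    update is the identity.
    """
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite forces entering integrator")
    m = np.asarray(masses, dtype=float)[:, None]
    dt = cfg.dt
    half = 0.5 * dt
    v = velocities + half * forces / m
    x = positions + half * v
    gamma = cfg.friction * 1e-3  # 1/ps -> 1/fs
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(KB * cfg.temperature * (1.0 - c1 * c1) / m)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + half * v
    f_new = force_fn(x)
    if not np.all(np.isfinite(f_new)):
        raise FloatingPointError("non-finite forces produced by force field")
    v = v + half * f_new / m
    return x, v, f_new


@dataclass
class SimResult:
    positions: np.ndarray
    velocities: np.ndarray
    trajectory: list = field(default_factory=list)   # logged positions
    energies: list = field(default_factory=list)     # (step, potential, bias)
    chi2: list = field(default_factory=list)         # (step, chi^2)
    spectra: list = field(default_factory=list)      # (step, scaled spectrum)
    acceptance: dict = field(default_factory=dict)


def run_simulation(sites: SiteSet, cfg: SimConfig, params: PairParams,
                   model: SANSForwardModel | None = None,
                   state: MetaInfState | None = None,
                   target=None,
                   velocities: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   sample_nuisance: bool = True) -> SimResult:
    """Langevin run, optionally biased by the metainference SANS restraint.

    The bias force is refreshed (and the nuisance parameters MC-updated)
    every ``cfg.bias_stride`` steps and held constant in between.  Passing
    ``velocities`` and ``rng`` continues a previous run bit-identically
    (checkpoint semantics); otherwise velocities start at zero and the
    generator is seeded from ``cfg.seed``.
    """
    biased = model is not None and state is not None
    if biased and target is None:
        raise ValueError("a biased run needs the target intensities")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    x = sites.positions.copy()
    v = np.zeros_like(x) if velocities is None else velocities.copy()

    def phys_forces(pos):
        f, _ = pair_forces(pos, params, box=cfg.box)
        return f

    bias_forces = np.zeros_like(x)
    bias_energy = 0.0

    def refresh_bias(pos):
        nonlocal bias_forces, bias_energy
        current = sites.with_positions(pos)
        if sample_nuisance:
            calc = model.intensity(current)
            mc_update(state, calc, target, rng)
        res = bias_energy_and_forces(current, model, target, state)
        bias_forces = res.forces
        bias_energy = res.energy
        return res

    if biased:
        refresh_bias(x)

    def total_forces(pos):
        return phys_forces(pos) + (bias_forces if biased else 0.0)

    f = total_forces(x)
    result = SimResult(positions=x, velocities=v)
    for step in range(cfg.steps):
        if biased and step > 0 and step % cfg.bias_stride == 0:
            refresh_bias(x)
            f = total_forces(x)
        x, v, f = langevin_step(x, v, f, total_forces, sites.masses, cfg, rng)
        if cfg.box is not None and np.any(np.abs(x) > 10.0 * cfg.box):
            raise RuntimeError(f"simulation diverged at step {step}")
        if (step + 1) % cfg.log_stride == 0 or step + 1 == cfg.steps:
            _, pot = pair_forces(x, params, box=cfg.box)
            result.trajectory.append(x.copy())
            result.energies.append((step + 1, pot, bias_energy))
            if biased:
                calc = model.intensity(sites.with_positions(x))
                result.spectra.append((step + 1, calc))
                result.chi2.append(
                    (step + 1, chi_squared(state.scale * calc + state.offset,
                                           target, state.sigma[0]))
                )
    result.positions = x
    result.velocities = v
    if biased:
        result.acceptance = dict(state.counters)
    return result
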