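"""Gaussian-noise metainference energy, biasing forces and nuisance-parameter MC.

Metainference augments the physical Hamiltonian with a Bayesian data
restraint.  For N_d selected scattering vectors and N_r replicas, with a
Gaussian noise model, the bias energy is

    E = kT * sum_r sum_i [ (s * I_calc(<q>_i) + I0 - I_exp(<q>_i))^2
                           / (2 sigma_{r,i}^2)
                           + 1/2 * log(2 pi sigma_{r,i}^2)
                           - log p(sigma_{r,i}) ]

where s is a scale factor, I0 an offset and sigma_{r,i} the effective
uncertainty absorbing experimental, systematic and forward-model error.  The
structural prior log p(R_r) is the physical force field of the simulator and
is not part of this term.  With more than one replica the replica-averaged
calculated intensity enters every residual.

The effective uncertainties (and optionally s and I0) are Metropolis-sampled
within user bounds; per-point bounds follow the heuristic SIGMA_MAX = 8% of
the experimental intensity, SIGMA_MIN = 25% and DSIGMA = 4% of SIGMA_MAX,
which in practice gives biasing forces that are neither destabilizing nor
too weak.

Forces are minus the gradient of E propagated through the q0 scaling, the
smearing matrix and the Debye gradients at the knots; the smearing matrix is
precomputed once (see :mod:`sansmi.resolution`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import resolution
from .debye_forward import QGrid, debye_gradient, debye_intensity, scale_anchor
from .io_model import ExperimentalCurve, SiteSet

__all__ = [
    "MetaInfState",
    "MIResult",
    "mi_energy",
    "mi_forces",
    "mc_update",
    "sigma_defaults",
    "SANSForwardModel",
    "bias_energy_and_forces",
    "chi_squared",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def sigma_defaults(i_exp) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point (sigma_max, sigma_min, dsigma) from experimental intensities.

    sigma_max = 0.08 * I_exp, sigma_min = 0.25 * sigma_max and
    dsigma = 0.04 * sigma_max, one value per q.
    """
    i_exp = np.asarray(i_exp, dtype=float)
    if np.any(i_exp <= 0):
        raise ValueError("experimental intensities must be positive")
    sigma_max = 0.08 * i_exp
    sigma_min = 0.25 * sigma_max
    dsigma = 0.04 * sigma_max
    return sigma_max, sigma_min, dsigma


@dataclass
class MetaInfState:
    """Nuisance parameters of the metainference bias and their MC settings."""

    sigma: np.ndarray            # (n_replicas, N_d) effective uncertainties
    sigma_min: np.ndarray        # (N_d,)
    sigma_max: np.ndarray        # (N_d,)
    dsigma: np.ndarray           # (N_d,) MC step; 0 freezes sigma
    scale: float = 1.0
    offset: float = 0.0
    sample_scale: bool = False
    sample_offset: bool = False
    dscale: float = 0.05
    doffset: float = 0.0
    scale_bounds: tuple[float, float] = (0.1, 10.0)
    offset_bounds: tuple[float, float] = (0.0, 0.0)
    kT: float = 1.0
    n_replicas: int = 1
    prior: str = "flat"          # "flat" or "jeffreys" prior on sigma
    counters: dict = field(default_factory=lambda: {
        "sigma_proposed": 0, "sigma_accepted": 0,
        "scale_proposed": 0, "scale_accepted": 0,
        "offset_proposed": 0, "offset_accepted": 0,
    })

    def __post_init__(self) -> None:
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        nd = self.sigma.shape[1]
        for name in ("sigma_min", "sigma_max", "dsigma"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (nd,)
            ).copy()
            setattr(self, name, arr)
        if self.sigma.shape[0] != self.n_replicas:
            raise ValueError("sigma must have one row per replica")
        if np.any(self.sigma_min <= 0):
            raise ValueError("sigma_min must be positive")
        if np.any(self.sigma_min > self.sigma_max):
            raise ValueError("sigma_min must not exceed sigma_max")
        if np.any(self.dsigma < 0):
            raise ValueError("dsigma must be non-negative")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.prior not in ("flat", "jeffreys"):
            raise ValueError("prior must be 'flat' or 'jeffreys'")
        self._check_sigma()

    def _check_sigma(self) -> None:
        if np.any(self.sigma < self.sigma_min) or np.any(self.sigma > self.sigma_max):
            raise ValueError("sigma outside [sigma_min, sigma_max]")

    @property
    def n_points(self) -> int:
        return self.sigma.shape[1]

    @classmethod
    def from_curve(cls, curve: ExperimentalCurve, kT: float = 1.0,
                   **kwargs) -> "MetaInfState":
        """Initialize with the 8%/25%/4% heuristic; sigma starts at sigma_max."""
        sigma_max, sigma_min, dsigma = sigma_defaults(curve.intensity)
        i_max = float(np.max(curve.intensity))
        kwargs.setdefault("offset_bounds", (-i_max, i_max))
        return cls(sigma=sigma_max[None, :].copy(), sigma_min=sigma_min,
                   sigma_max=sigma_max, dsigma=dsigma, kT=kT, **kwargs)


@dataclass
class MIResult:
    energy: float
    forces: np.ndarray | None
    residuals: np.ndarray
    counters: dict


def _neg_log_prior(sigma: np.ndarray, prior: str) -> np.ndarray:
    if prior == "jeffreys":
        return np.log(sigma)
    return np.zeros_like(sigma)  # flat: constant, set to zero


def _replica_mean(calc: np.ndarray) -> np.ndarray:
    calc = np.asarray(calc, dtype=float)
    return calc.mean(axis=0) if calc.ndim == 2 else calc


def mi_energy(calc, i_exp, state: MetaInfState) -> float:
    """Metainference bias energy (in the same units as state.kT).

    ``calc`` is either the (N_d,) calculated spectrum or an (N_r, N_d) array
    of per-replica spectra, whose replica mean enters every residual.
    """
    state._check_sigma()
    i_exp = np.asarray(i_exp, dtype=float)
    mean_calc = _replica_mean(calc)
    res = state.scale * mean_calc + state.offset - i_exp  # (N_d,)
    sig = state.sigma
    terms = (res[None, :] ** 2) / (2.0 * sig ** 2) \
        + 0.5 * (_LOG_2PI + 2.0 * np.log(sig)) \
        + _neg_log_prior(sig, state.prior)
    return float(state.kT * terms.sum())


def mi_forces(knot_gradients: np.ndarray, smear_map: np.ndarray,
              residuals: np.ndarray, state: MetaInfState,
              dscaled_dknot: np.ndarray | None = None) -> np.ndarray:
    """Assemble per-site biasing forces from knot gradients.

    ``knot_gradients`` is (K, M, 3): the Debye gradient at each knot.
    ``dscaled_dknot`` is the (N_d, K) Jacobian of the scaled intensities with
    respect to the raw knot values (q0 normalization included); when omitted
    it defaults to ``smear_map`` (no normalization stage).  Forces are
    -dE/dx and sum to zero by translation invariance.
    """
    if knot_gradients is None:
        raise ValueError("knot gradients are required to compute forces")
    jac = smear_map if dscaled_dknot is None else dscaled_dknot
    inv_var = (1.0 / state.sigma ** 2).sum(axis=0)  # sum over replicas
    de_dI = state.kT * state.scale * residuals * inv_var / state.n_replicas
    g = de_dI @ jac  # (K,)
    return -np.tensordot(g, knot_gradients, axes=(0, 0))


def mc_update(state: MetaInfState, calc, i_exp,
              rng: np.random.Generator) -> MetaInfState:
    """One Metropolis sweep over sigma (per point/replica), then s, then I0.

    Proposals are uniform in +/- the step width; proposals falling outside
    their bounds are rejected outright.  With the calculated spectrum fixed,
    each sigma term is independent, so sigma moves are accepted point-wise.
    Deterministic under a fixed generator state.  Counters accumulate in
    ``state.counters``; sigma acceptances count only moves that changed the
    value (a zero step proposes the current value and is not counted).
    """
    i_exp = np.asarray(i_exp, dtype=float)
    mean_calc = _replica_mean(calc)
    res = state.scale * mean_calc + state.offset - i_exp

    nr, nd = state.sigma.shape
    # --- sigma moves (point-wise independent at fixed residuals)
    prop = state.sigma + rng.uniform(-1.0, 1.0, size=(nr, nd)) * state.dsigma
    u = rng.uniform(size=(nr, nd))
    in_bounds = (prop >= state.sigma_min) & (prop <= state.sigma_max)
    safe_prop = np.where(in_bounds, prop, state.sigma)
    d_terms = (
        (res[None, :] ** 2) / 2.0 * (1.0 / safe_prop**2 - 1.0 / state.sigma**2)
        + np.log(safe_prop / state.sigma)
        + _neg_log_prior(safe_prop, state.prior)
        - _neg_log_prior(state.sigma, state.prior)
    )
    accept = in_bounds & (np.log(u) < -d_terms)
    changed = accept & (prop != state.sigma)
    state.sigma = np.where(accept, prop, state.sigma)
    state.counters["sigma_proposed"] += nr * nd
    state.counters["sigma_accepted"] += int(changed.sum())

    def _energy() -> float:
        return mi_energy(mean_calc, i_exp, state)

    # --- scale move
    if state.sample_scale and state.dscale > 0:
        e_old = _energy()
        prop_s = state.scale + rng.uniform(-state.dscale, state.dscale)
        u_s = rng.uniform()
        state.counters["scale_proposed"] += 1
        if state.scale_bounds[0] <= prop_s <= state.scale_bounds[1]:
            old = state.scale
            state.scale = prop_s
            if np.log(u_s) < -(_energy() - e_old) / state.kT:
                state.counters["scale_accepted"] += 1
            else:
                state.scale = old

    # --- offset move
    if state.sample_offset and state.doffset > 0:
        e_old = _energy()
        prop_o = state.offset + rng.uniform(-state.doffset, state.doffset)
        u_o = rng.uniform()
        state.counters["offset_proposed"] += 1
        if state.offset_bounds[0] <= prop_o <= state.offset_bounds[1]:
            old = state.offset
            state.offset = prop_o
            if np.log(u_o) < -(_energy() - e_old) / state.kT:
                state.counters["offset_accepted"] += 1
            else:
                state.offset = old
    return state


def chi_squared(calc, i_exp, sigma) -> float:
    """chi^2 = sum_i residual_i^2 / sigma_i^2 at unit scale and zero offset."""
    calc = np.asarray(calc, dtype=float)
    i_exp = np.asarray(i_exp, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), i_exp.shape)
    return float(np.sum((calc - i_exp) ** 2 / sigma ** 2))


class SANSForwardModel:
    """Coordinates -> scaled, smeared SANS intensities, with gradients.

    Precomputes the quadrature and the smearing matrix once (they depend
    only on the q grid and sigma1).  The scaled spectrum is

        I_i = A * smeared_i / smeared_0,   smeared = C @ raw,

    with A the experimental intensity at q0 (1 without a curve) and
    ``raw`` the Debye cross section at the knots.
    """

    def __init__(self, grid: QGrid, curve: ExperimentalCurve | None = None,
                 sigma1=None, n_quad: int = 10,
                 use_minimum_image: bool = False) -> None:
        self.grid = grid
        self.curve = curve
        self.use_minimum_image = use_minimum_image
        if sigma1 is None and curve is not None and curve.sigma_res is not None:
            sigma1 = np.interp(grid.q, curve.q, curve.sigma_res)
        if sigma1 is not None and np.any(np.asarray(sigma1) > 0):
            quad = resolution.build_quadrature(grid, sigma1, n_quad)
            self.smear_map = resolution.smear_matrix(quad)
            self.quadrature = quad
        else:
            self.smear_map = np.eye(grid.n_points)
            self.quadrature = None
        self.anchor = scale_anchor(grid.q0, curve)

    # -- forward values -----------------------------------------------------
    def raw(self, sites: SiteSet) -> np.ndarray:
        return debye_intensity(sites, self.grid,
                               use_minimum_image=self.use_minimum_image)

    def intensity(self, sites: SiteSet) -> np.ndarray:
        """Scaled, smeared intensity at the knots."""
        smeared = self.smear_map @ self.raw(sites)
        if smeared[0] <= 0:
            raise ValueError("smeared intensity at q0 is non-positive")
        return self.anchor * smeared / smeared[0]

    def scaled_jacobian(self, raw: np.ndarray) -> np.ndarray:
        """(N_d, K) Jacobian d(scaled_i)/d(raw_k) at the given raw values."""
        c = self.smear_map
        sm = c @ raw
        s0 = sm[0]
        return self.anchor * (c * s0 - np.outer(sm, c[0])) / (s0 * s0)

    def knot_gradients(self, sites: SiteSet) -> np.ndarray:
        """(K, M, 3) Debye gradients at every knot."""
        return np.stack([
            debye_gradient(sites, qk, use_minimum_image=self.use_minimum_image)
            for qk in self.grid.q
        ])

    def intensity_and_jacobian(self, sites: SiteSet):
        """Scaled intensities plus their (N_d, M, 3) coordinate Jacobian."""
        raw = self.raw(sites)
        sm = self.smear_map @ raw
        scaled = self.anchor * sm / sm[0]
        dscaled = self.scaled_jacobian(raw)          # (N_d, K)
        kg = self.knot_gradients(sites)              # (K, M, 3)
        jac = np.tensordot(dscaled, kg, axes=(1, 0))  # (N_d, M, 3)
        return scaled, jac


def bias_energy_and_forces(sites: SiteSet, model: SANSForwardModel,
                           i_exp, state: MetaInfState) -> MIResult:
    """Total metainference bias energy and per-site forces for one structure."""
    i_exp = np.asarray(i_exp, dtype=float)
    raw = model.raw(sites)
    sm = model.smear_map @ raw
    if sm[0] <= 0:
        raise ValueError("smeared intensity at q0 is non-positive")
    scaled = model.anchor * sm / sm[0]
    energy = mi_energy(scaled, i_exp, state)
    residuals = state.scale * scaled + state.offset - i_exp
    forces = mi_forces(
        model.knot_gradients(sites), model.smear_map, residuals, state,
        dscaled_dknot=model.scaled_jacobian(raw),
    )
    return MIResult(energy=energy, forces=forces, residuals=residuals,
                    counters=dict(state.counters))
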