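"""Debye-equation SANS intensities, coordinate gradients and q0 scaling.

The orientationally averaged coherent cross section of M scattering centres
with scattering lengths b_i is

    dsigma(q)/dOmega = (1/M) sum_i sum_j b_i b_j sin(q r_ij) / (q r_ij)

with the i = j terms contributing b_i^2 (sinc(0) = 1).  Reported intensities
are normalized by the value at the lowest scattering vector q0 and, when an
experimental curve is available, scaled to match the experimental intensity
at q0 — absolute units therefore cancel.

Two evaluation paths are provided: a plain O(M^2) double loop that serves as
the reference, and a vectorized path over the condensed distance matrix used
for real work.  Both must agree to 1e-10 relative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .io_model import ExperimentalCurve, SiteSet, SpectrumResult

__all__ = [
    "QGrid",
    "sinc",
    "debye_intensity",
    "debye_gradient",
    "normalize_and_scale",
    "scale_anchor",
    "compute_spectrum",
    "average_spectrum",
]

_SINC_SMALL = 1e-4


@dataclass
class QGrid:
    """Strictly increasing, positive scattering-vector values (1/Angstrom)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        if self.q.size < 1:
            raise ValueError("q grid must contain at least one point")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q grid must be finite")
        if np.any(self.q <= 0):
            raise ValueError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q values must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.q.size

    @property
    def q0(self) -> float:
        return float(self.q[0])


def sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the removable singularity guarded by its series.

    For x < 1e-4 the truncation error of 1 - x^2/6 is below 1e-17.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SINC_SMALL
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x * x / 6.0, np.sin(safe) / safe)


def _check_sites(sites: SiteSet) -> None:
    if not np.any(sites.scatlens != 0.0):
        raise ValueError(
            "scattering lengths are unset (all zero); assign them before "
            "computing intensities"
        )


def _pair_distances(sites: SiteSet, use_minimum_image: bool) -> np.ndarray:
    """Condensed upper-triangle distance vector (i < j)."""
    if not use_minimum_image:
        return pdist(sites.positions)
    if sites.box is None:
        raise ValueError("minimum-image distances require a box")
    x = sites.positions
    disp = x[:, None, :] - x[None, :, :]
    disp -= sites.box * np.round(disp / sites.box)
    iu = np.triu_indices(x.shape[0], k=1)
    return np.linalg.norm(disp[iu], axis=-1)


def debye_intensity(sites: SiteSet, grid: QGrid,
                    use_minimum_image: bool = False,
                    method: str = "fast") -> np.ndarray:
    """Raw Debye cross section dsigma/dOmega (fm^2) at each grid point.

    ``method="brute"`` runs the explicit O(M^2) double loop and exists as the
    reference the vectorized path is validated against.
    """
    _check_sites(sites)
    q = grid.q
    b = sites.scatlens
    m = sites.n_sites
    if method == "brute":
        out = np.zeros(q.size)
        x = sites.positions
        box = sites.box
        for i in range(m):
            for j in range(m):
                if i == j:
                    out += b[i] * b[i]
                    continue
                d = x[i] - x[j]
                if use_minimum_image:
                    d = d - box * np.round(d / box)
                r = float(np.sqrt(d @ d))
                out += b[i] * b[j] * sinc(q * r)
        return out / m
    if method != "fast":
        raise ValueError(f"unknown method {method!r}")
    r = _pair_distances(sites, use_minimum_image)
    iu = np.triu_indices(m, k=1)
    bb = b[iu[0]] * b[iu[1]]
    diag = float(np.sum(b * b))
    # sum over pairs in chunks to bound the (n_pairs x n_q) intermediate
    out = np.full(q.size, diag)
    chunk = max(1, int(4e7 // max(q.size, 1)))
    for start in range(0, r.size, chunk):
        sl = slice(start, start + chunk)
        out += 2.0 * (bb[sl][:, None] * sinc(np.outer(r[sl], q))).sum(axis=0)
    return out / m


def debye_gradient(sites: SiteSet, q: float,
                   use_minimum_image: bool = False) -> np.ndarray:
    """Analytic gradient of dsigma(q)/dOmega with respect to coordinates.

    Returns an (M, 3) array in fm^2/Angstrom.  Gradients sum to the zero
    vector (the cross section depends only on pair distances).
    """
    _check_sites(sites)
    if q <= 0:
        raise ValueError("q must be positive")
    x = sites.positions
    b = sites.scatlens
    m = sites.n_sites
    disp = x[:, None, :] - x[None, :, :]
    if use_minimum_image:
        if sites.box is None:
            raise ValueError("minimum-image distances require a box")
        disp -= sites.box * np.round(disp / sites.box)
    r = np.linalg.norm(disp, axis=-1)
    np.fill_diagonal(r, 1.0)  # dummy; diagonal contributes zero
    qr = q * r
    # d/dr [sin(qr)/(qr)] = (cos(qr) - sinc(qr)) / r
    fprime = (np.cos(qr) - sinc(qr)) / r
    np.fill_diagonal(fprime, 0.0)
    coef = (b[:, None] * b[None, :]) * fprime / r  # (M, M)
    grad = 2.0 * (coef[:, :, None] * disp).sum(axis=1) / m
    return grad


def scale_anchor(grid_q0: float, curve: ExperimentalCurve | None) -> float:
    """Intensity the spectrum is anchored to at q0 (1 without a curve)."""
    if curve is None:
        return 1.0
    return float(np.interp(grid_q0, curve.q, curve.intensity))


def normalize_and_scale(raw: np.ndarray,
                        curve: ExperimentalCurve | None = None,
                        qbar: np.ndarray | None = None) -> np.ndarray:
    """Normalize a spectrum by its value at q0 and anchor to the experiment.

    q0 is the lowest <q> (the first entry; ``raw`` must be ordered by q).
    Without a curve the result equals raw/raw[0]; with a curve it is further
    multiplied by I_exp(q0).
    """
    raw = np.asarray(raw, dtype=float)
    if raw[0] <= 0:
        raise ValueError(
            f"intensity at q0 is {raw[0]:g} <= 0 (degenerate contrast); "
            "cannot normalize"
        )
    anchor = 1.0
    if curve is not None:
        q0 = float(qbar[0]) if qbar is not None else float(curve.q[0])
        anchor = scale_anchor(q0, curve)
    return raw / raw[0] * anchor


def compute_spectrum(sites: SiteSet, grid: QGrid,
                     curve: ExperimentalCurve | None = None,
                     sigma1: np.ndarray | float | None = None,
                     n_quad: int = 21,
                     use_minimum_image: bool = False) -> SpectrumResult:
    """Full single-structure pipeline: Debye -> smear -> normalize/scale."""
    from . import resolution  # local import; resolution depends on QGrid

    raw = debye_intensity(sites, grid, use_minimum_image=use_minimum_image)
    if sigma1 is not None and np.any(np.asarray(sigma1) > 0):
        quad = resolution.build_quadrature(grid, sigma1, n_quad)
        spline = resolution.fit_spline(grid.q, raw)
        smeared = resolution.smear_spectrum(spline, quad)
    else:
        smeared = raw.copy()
    scaled = normalize_and_scale(smeared, curve, grid.q)
    return SpectrumResult(
        qbar=grid.q, raw=raw, smeared=smeared, scaled=scaled,
        normalization="experiment" if curve is not None else "self",
    )


def average_spectrum(frames, grid: QGrid,
                     curve: ExperimentalCurve | None = None,
                     sigma1: np.ndarray | float | None = None,
                     n_quad: int = 21,
                     use_minimum_image: bool = False,
                     mode: str = "scaled") -> SpectrumResult:
    """Trajectory-averaged spectrum.

    ``mode="scaled"`` (default) averages the per-frame scaled spectra;
    ``mode="raw"`` averages the raw cross sections first and scales the
    average once.
    """
    if mode not in ("scaled", "raw"):
        raise ValueError("mode must be 'scaled' or 'raw'")
    raws, smeareds, scaleds = [], [], []
    for frame in frames:
        res = compute_spectrum(frame, grid, curve=curve, sigma1=sigma1,
                               n_quad=n_quad,
                               use_minimum_image=use_minimum_image)
        raws.append(res.raw)
        smeareds.append(res.smeared)
        scaleds.append(res.scaled)
    raw = np.mean(raws, axis=0)
    smeared = np.mean(smeareds, axis=0)
    if mode == "scaled":
        scaled = np.mean(scaleds, axis=0)
    else:
        scaled = normalize_and_scale(smeared, curve, grid.q)
    return SpectrumResult(
        qbar=grid.q, raw=raw, smeared=smeared, scaled=scaled,
        normalization="experiment" if curve is not None else "self",
    )
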