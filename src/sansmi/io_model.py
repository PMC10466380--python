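"""Shared domain types and file I/O.

Structures come in as PDB, GRO or XYZ files (multi-frame XYZ acts as a
trajectory); experimental SANS curves are whitespace-separated text columns
``q  I  [err]  [sigma1]``; computed spectra go out as 4-column text that can
be re-read as a curve.

Internal units are Angstrom for lengths (GRO nanometres are converted on
read), inverse Angstrom for the scattering vector q, femtometres for coherent
scattering lengths and Dalton for masses.  Only orthorhombic boxes are
accepted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SiteSet",
    "ExperimentalCurve",
    "SpectrumResult",
    "read_structure",
    "read_trajectory",
    "read_experimental_curve",
    "write_spectrum",
    "write_xyz",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SiteSet:
    """A set of scattering centres: positions plus per-site attributes.

    Attributes
    ----------
    positions : (M, 3) float array, Angstrom
    scatlens : (M,) float array, fm
        Coherent scattering lengths b_i; zero until assigned.  May be
        negative (e.g. -3.739 fm for hydrogen).
    masses : (M,) float array, Da
        Defaults to 1.0 per site when the input format carries no masses.
    box : optional (3,) float array, Angstrom
        Orthorhombic box edge lengths.
    labels : list of str
        Element or bead names, in file order.  File order is the binding
        index for scattering-length files (1-based).
    """

    positions: np.ndarray
    scatlens: np.ndarray = None  # type: ignore[assignment]
    masses: np.ndarray = None  # type: ignore[assignment]
    box: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        m = self.positions.shape[0]
        if m < 1 or self.positions.shape[1] != 3:
            raise ValueError("positions must be a non-empty (M, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.scatlens is None:
            self.scatlens = np.zeros(m)
        self.scatlens = np.asarray(self.scatlens, dtype=float)
        if self.scatlens.shape != (m,):
            raise ValueError("scatlens must have one value per site")
        if not np.all(np.isfinite(self.scatlens)):
            raise ValueError("scatlens must be finite")
        if self.masses is None:
            self.masses = np.ones(m)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (m,):
            raise ValueError("masses must have one value per site")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")
        if not self.labels:
            self.labels = [""] * m
        if len(self.labels) != m:
            raise ValueError("labels must have one entry per site")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SiteSet":
        return SiteSet(
            positions=self.positions.copy(),
            scatlens=self.scatlens.copy(),
            masses=self.masses.copy(),
            box=None if self.box is None else self.box.copy(),
            labels=list(self.labels),
        )

    def with_positions(self, positions: np.ndarray) -> "SiteSet":
        """New SiteSet sharing attributes but holding different coordinates."""
        out = self.copy()
        out.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if out.positions.shape != self.positions.shape:
            raise ValueError("replacement positions must keep the same shape")
        return out


@dataclass
class ExperimentalCurve:
    """Experimental SANS curve on a strictly increasing positive q grid."""

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray | None = None
    sigma_res: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        n = self.q.size
        if n < 1:
            raise ValueError("curve must contain at least one point")
        if self.intensity.size != n:
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q values must be strictly positive")
        order = np.argsort(self.q, kind="stable")
        self.q = self.q[order]
        self.intensity = self.intensity[order]
        if np.any(np.diff(self.q) == 0):
            raise ValueError("duplicate q values are not allowed")
        for name in ("error", "sigma_res"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float).ravel()
                if arr.size != n:
                    raise ValueError(f"{name} must have one value per point")
                setattr(self, name, arr[order])
        if self.sigma_res is not None and np.any(self.sigma_res < 0):
            raise ValueError("sigma_res must be non-negative")

    @property
    def n_points(self) -> int:
        return self.q.size

    def subset(self, indices: Sequence[int]) -> "ExperimentalCurve":
        idx = np.asarray(indices, dtype=int)
        return ExperimentalCurve(
            q=self.q[idx],
            intensity=self.intensity[idx],
            error=None if self.error is None else self.error[idx],
            sigma_res=None if self.sigma_res is None else self.sigma_res[idx],
        )


@dataclass
class SpectrumResult:
    """Computed SANS spectrum at the user-selected <q>_i values.

    ``raw`` holds the Debye cross section dsigma/dOmega (fm^2), ``smeared``
    the resolution-smeared intensity (equal to raw when no sigma1 was given)
    and ``scaled`` the q0-normalized intensity, anchored to the experimental
    intensity at q0 when a curve was supplied.
    """

    qbar: np.ndarray
    raw: np.ndarray
    smeared: np.ndarray
    scaled: np.ndarray
    gradients: np.ndarray | None = None
    normalization: str = "self"

    def __post_init__(self) -> None:
        self.qbar = np.asarray(self.qbar, dtype=float).ravel()
        self.raw = np.asarray(self.raw, dtype=float).ravel()
        self.smeared = np.asarray(self.smeared, dtype=float).ravel()
        self.scaled = np.asarray(self.scaled, dtype=float).ravel()
        n = self.qbar.size
        if n < 1:
            raise ValueError("spectrum must contain at least one point")
        if not (self.raw.size == self.smeared.size == self.scaled.size == n):
            raise ValueError("spectrum columns must have equal length")


# ---------------------------------------------------------------------------
# structure reading


def _read_xyz_frames(path: Path) -> Iterator[tuple[list[str], np.ndarray]]:
    """Parse a (multi-frame) XYZ file, yielding (labels, positions) pairs."""
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame = 0
    nline = len(lines)
    while i < nline:
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {i + 1}: expected an atom count, got "
                f"{lines[i].strip()!r}"
            ) from exc
        if i + 2 + natoms > nline:
            raise FormatError(
                f"{path}: truncated frame after frame {frame - 1} "
                f"(last complete frame index {frame - 1})"
            )
        labels: list[str] = []
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {ln + 1}: expected 'label x y z', got "
                    f"{lines[ln].strip()!r} (last complete frame index {frame - 1})"
                )
            labels.append(parts[0])
            try:
                pos[k] = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {ln + 1}: non-numeric coordinate"
                ) from exc
        yield labels, pos
        frame += 1
        i += 2 + natoms


def _box_from_mda(dimensions: np.ndarray | None, path: Path) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise FormatError(
            f"{path}: triclinic box (angles {dims[3:]}) not supported; "
            "only orthorhombic boxes are accepted"
        )
    return dims[:3].copy()


def _read_structure_mda(path: Path) -> SiteSet:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise FormatError(f"{path}: cannot parse structure: {exc}") from exc
        atoms = u.atoms
        if len(atoms) == 0:
            raise FormatError(f"{path}: structure contains no atoms")
        try:
            masses = np.asarray(atoms.masses, dtype=float)
            if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
                masses = np.ones(len(atoms))
        except Exception:  # noqa: BLE001 - mass guessing is best effort
            masses = np.ones(len(atoms))
        # MDAnalysis reports positions in Angstrom for every format (GRO
        # nanometres are converted by its reader).
        return SiteSet(
            positions=atoms.positions.astype(float),
            masses=masses,
            box=_box_from_mda(u.dimensions, path),
            labels=[str(n) for n in atoms.names],
        )


def read_structure(path: str | Path, format_hint: str | None = None) -> SiteSet:
    """Read a single structure from a PDB, GRO or XYZ file.

    Positions are returned in Angstrom; scattering lengths are left at zero
    until assigned (e.g. from a SCATLEN file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        gen = _read_xyz_frames(path)
        try:
            labels, pos = next(gen)
        except StopIteration:
            raise FormatError(f"{path}: empty XYZ file") from None
        return SiteSet(positions=pos, labels=labels)
    if fmt in ("pdb", "gro"):
        return _read_structure_mda(path)
    raise FormatError(f"{path}: unsupported structure format {fmt!r}")


def read_trajectory(path: str | Path, topology: SiteSet) -> list[SiteSet]:
    """Read a multi-frame XYZ trajectory against a topology.

    Each frame inherits scattering lengths, masses, labels and box from
    ``topology``; a frame whose atom count differs from the topology is a
    contract violation reported with the index of the last complete frame.
    """
    path = Path(path)
    frames: list[SiteSet] = []
    for idx, (labels, pos) in enumerate(_read_xyz_frames(path)):
        if pos.shape[0] != topology.n_sites:
            raise FormatError(
                f"{path}: frame {idx} has {pos.shape[0]} sites, topology has "
                f"{topology.n_sites} (last complete frame index {idx - 1})"
            )
        frame = topology.copy()
        frame.positions = pos
        frames.append(frame)
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def write_xyz(frames: SiteSet | Sequence[SiteSet], path: str | Path,
              comment: str = "") -> None:
    """Write one or more SiteSets as a (multi-frame) XYZ file."""
    if isinstance(frames, SiteSet):
        frames = [frames]
    with open(path, "w") as fh:
        for i, fr in enumerate(frames):
            fh.write(f"{fr.n_sites}\n{comment or f'frame {i}'}\n")
            for lbl, (x, y, z) in zip(fr.labels, fr.positions):
                fh.write(f"{lbl or 'X'} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# curves and spectra


def read_experimental_curve(path: str | Path) -> ExperimentalCurve:
    """Read an experimental curve: columns q, I, [err], [sigma1].

    Lines starting with ``#`` are ignored; rows are sorted by q; duplicate q
    values and non-positive q are rejected.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from exc
            if ncols is None:
                ncols = len(vals)
                if ncols not in (2, 3, 4):
                    raise FormatError(
                        f"{path}: line {lineno}: expected 2-4 columns, "
                        f"got {ncols}"
                    )
            elif len(vals) != ncols:
                raise FormatError(
                    f"{path}: line {lineno}: ragged row ({len(vals)} columns, "
                    f"expected {ncols})"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows)
    try:
        return ExperimentalCurve(
            q=data[:, 0],
            intensity=data[:, 1],
            error=data[:, 2] if data.shape[1] >= 3 else None,
            sigma_res=data[:, 3] if data.shape[1] >= 4 else None,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum(result: SpectrumResult, path: str | Path) -> None:
    """Write a spectrum as 4-column text (qbar, raw, smeared, scaled).

    The header records the normalization mode; :func:`read_spectrum` is the
    paired reader and round-trips every column at the printed precision.
    """
    with open(path, "w") as fh:
        fh.write("# sansmi spectrum\n")
        fh.write(f"# normalization: {result.normalization}\n")
        fh.write("# columns: qbar raw smeared scaled\n")
        for q, r, s, c in zip(result.qbar, result.raw, result.smeared,
                              result.scaled):
            fh.write(f"{q:.12e} {r:.12e} {s:.12e} {c:.12e}\n")


def read_spectrum(path: str | Path) -> SpectrumResult:
    """Read back a file written by :func:`write_spectrum`."""
    path = Path(path)
    normalization = "self"
    rows = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("# normalization:"):
                normalization = stripped.split(":", 1)[1].strip()
            if not stripped or stripped.startswith("#"):
                continue
            rows.append([float(v) for v in stripped.split()])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows)
    if data.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns")
    return SpectrumResult(qbar=data[:, 0], raw=data[:, 1], smeared=data[:, 2],
                          scaled=data[:, 3], normalization=normalization)
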