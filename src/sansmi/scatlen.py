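"""Neutron scattering lengths for atoms and coarse-grained beads.

Atomic bound coherent scattering lengths come from the standard Sears
compilation.  A coarse-grained bead scatters with the sum of the scattering
lengths of the atoms mapped onto it; swapping hydrogen for deuterium (and
back) models contrast-variation experiments, since b(1H) = -3.739 fm while
b(2H) = +6.671 fm.

The on-disk dialect is one line per site, ``SCATLEN<k>=<value>`` with k the
1-based site index in file order.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import FormatError

__all__ = [
    "SEARS_B",
    "sears_b",
    "Bead",
    "BeadMapping",
    "ScatlenTable",
    "map_bead_scatlens",
    "read_mapping_file",
    "write_scatlen_file",
    "read_scatlen_file",
    "resolve_element",
]

# Bound coherent scattering lengths, fm (Sears compilation; natural-abundance
# values except H/D which are the pure-isotope values used for contrast work).
SEARS_B: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "F": 5.654,
    "Na": 3.63,
    "Mg": 5.375,
    "Si": 4.1491,
    "P": 5.13,
    "S": 2.847,
    "Cl": 9.5770,
    "K": 3.67,
    "Ca": 4.70,
    "Fe": 9.45,
    "Zn": 5.680,
    "Br": 6.795,
    "I": 5.28,
}


def sears_b(element: str, isotope: str | None = None) -> float:
    """Bound coherent scattering length of an element, in fm.

    ``isotope="D"`` (or element "D") selects deuterium.
    """
    sym = element.strip()
    if isotope is not None and isotope.upper() == "D":
        sym = "D"
    key = sym.capitalize() if len(sym) > 1 else sym.upper()
    if key == "D":
        key = "D"
    if key not in SEARS_B:
        raise KeyError(
            f"unknown element {element!r}; supported symbols: "
            + ", ".join(sorted(SEARS_B))
        )
    return SEARS_B[key]


_ELEMENT_RE = re.compile(r"^[A-Za-z]{1,2}")


def resolve_element(atom_name: str) -> str:
    """Resolve an atom name (e.g. ``C1``, ``HW2``, ``NA``) to an element symbol.

    Tries a two-letter match first (Na, Cl, ...), then one letter.  Atom
    names written ``D``/``D1`` resolve to deuterium.
    """
    m = _ELEMENT_RE.match(atom_name.strip())
    if not m:
        raise KeyError(f"cannot resolve element from atom name {atom_name!r}")
    head = m.group(0)
    two = head[:2].capitalize()
    if len(head) >= 2 and two in SEARS_B and two != "D":
        return two
    one = head[0].upper()
    if one in SEARS_B:
        return one
    raise KeyError(
        f"cannot resolve element from atom name {atom_name!r}; supported "
        "symbols: " + ", ".join(sorted(SEARS_B))
    )


@dataclass
class Bead:
    name: str
    atoms: list[str]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"bead {self.name!r} has no member atoms")


@dataclass
class BeadMapping:
    """Ordered all-atom -> coarse-grain mapping for one molecule type."""

    beads: list[Bead]
    nmols: int = 1

    def __post_init__(self) -> None:
        if not self.beads:
            raise ValueError("mapping must contain at least one bead")
        if self.nmols < 1:
            raise ValueError("nmols must be >= 1")


@dataclass
class ScatlenTable:
    """Per-site scattering lengths keyed by contiguous 1-based indices."""

    index: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.index.size != self.b.size:
            raise ValueError("index and b must have equal length")
        if self.index.size == 0:
            raise ValueError("table must contain at least one entry")
        order = np.argsort(self.index, kind="stable")
        self.index = self.index[order]
        self.b = self.b[order]
        if np.any(np.diff(self.index) == 0):
            raise ValueError("duplicate site index in scattering-length table")
        if np.any(np.diff(self.index) != 1):
            raise ValueError("site indices must be contiguous")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("scattering lengths must be finite")

    @property
    def start_index(self) -> int:
        return int(self.index[0])

    def bind(self, n_sites: int) -> np.ndarray:
        """Return the b array for a system of ``n_sites`` sites.

        The table must start at index 1 and cover every site.
        """
        if self.start_index != 1 or self.index.size != n_sites:
            raise ValueError(
                f"table covers indices {self.start_index}..{int(self.index[-1])} "
                f"but the system has sites 1..{n_sites}"
            )
        return self.b.copy()


def map_bead_scatlens(mapping: BeadMapping, swap_h_to_d: bool = False,
                      swap_d_to_h: bool = False,
                      start_index: int = 1) -> ScatlenTable:
    """Sum atomic scattering lengths into per-bead values.

    One entry per bead per molecule copy, molecule-major order (all beads of
    molecule 1, then molecule 2, ...).  The H<->D swaps apply to every
    hydrogen (or deuterium) in the mapping.
    """
    if swap_h_to_d and swap_d_to_h:
        raise ValueError("swap_h_to_d and swap_d_to_h are mutually exclusive")
    per_bead = []
    for bead in mapping.beads:
        total = 0.0
        for atom in bead.atoms:
            elem = resolve_element(atom)
            if swap_h_to_d and elem == "H":
                elem = "D"
            elif swap_d_to_h and elem == "D":
                elem = "H"
            total += sears_b(elem)
        per_bead.append(total)
    b = np.tile(per_bead, mapping.nmols)
    idx = np.arange(start_index, start_index + b.size)
    return ScatlenTable(index=idx, b=b)


def read_mapping_file(path: str | Path, nmols: int = 1) -> BeadMapping:
    """Read a mapping file with one bead per line: ``beadname: atom1 atom2 ...``.

    Lines without a colon are read as ``beadname atom1 atom2 ...`` (the
    CG-builder map style).  Blank lines and '#' comments are ignored.
    """
    path = Path(path)
    beads: list[Bead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if ":" in stripped:
                name, rest = stripped.split(":", 1)
                atoms = rest.split()
            else:
                parts = stripped.split()
                name, atoms = parts[0], parts[1:]
            if not atoms:
                raise FormatError(
                    f"{path}: line {lineno}: bead {name.strip()!r} lists no atoms"
                )
            beads.append(Bead(name=name.strip(), atoms=atoms))
    if not beads:
        raise FormatError(f"{path}: no beads found")
    return BeadMapping(beads=beads, nmols=nmols)


_SCATLEN_EQ_RE = re.compile(r"^SCATLEN(\d+)\s*=\s*([-+0-9.eEdD]+)$")
_SCATLEN_WS_RE = re.compile(r"^SCATLEN\s+(\d+)\s+([-+0-9.eEdD]+)$")


def write_scatlen_file(table: ScatlenTable, path: str | Path,
                       append: bool = False, start_index: int = 1) -> None:
    """Write ``SCATLEN<k>=<value>`` lines.

    With ``append``, the file's last index + 1 must equal ``start_index`` so
    that indices stay contiguous across invocations (the --start-index
    convention for multi-species systems).
    """
    path = Path(path)
    if start_index < 1:
        raise ValueError("start_index must be >= 1")
    if append and path.exists():
        existing = read_scatlen_file(path)
        expected = int(existing.index[-1]) + 1
        if start_index != expected:
            raise ValueError(
                f"append requires start_index {expected} "
                f"(file ends at index {int(existing.index[-1])}), got {start_index}"
            )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for offset, b in enumerate(table.b):
            fh.write(f"SCATLEN{start_index + offset}={float(b)!r}\n")


def read_scatlen_file(path: str | Path, allow_spaces: bool = False) -> ScatlenTable:
    """Parse a SCATLEN file back into a table (sorted by index).

    ``allow_spaces`` additionally accepts the looser ``SCATLEN k v`` form.
    """
    path = Path(path)
    indices: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            m = _SCATLEN_EQ_RE.match(stripped)
            if m is None and allow_spaces:
                m = _SCATLEN_WS_RE.match(stripped)
            if m is None:
                raise FormatError(
                    f"{path}: line {lineno}: malformed SCATLEN line "
                    f"{stripped!r}"
                )
            idx = int(m.group(1))
            if idx in indices:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate index {idx}"
                )
            indices.append(idx)
            values.append(float(m.group(2).replace("d", "e").replace("D", "e")))
    if not indices:
        raise FormatError(f"{path}: no SCATLEN lines found")
    return ScatlenTable(index=np.array(indices), b=np.array(values))
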