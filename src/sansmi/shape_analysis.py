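"""Micelle shape descriptors and aggregate detection.

Shape is summarized by the radius of gyration, the three principal moments
of inertia I1 >= I2 >= I3 (eigenvalues of the inertia tensor about the
centre of mass) and the asphericity

    alpha = (2 I1 - I2 - I3) / (I1 + I2 + I3)

which is 0 for a perfectly spherical micelle and grows as it elongates
(0.5 for an ideal rod or disc).

Aggregates are found by single-linkage clustering: sites closer than a
maximum-distance criterion (10 Angstrom is the conventional choice for
surfactant tails) are connected, minimum-image distances being used in a
periodic box, and connected components are the aggregates.  When molecule
identities are given, a whole molecule joins a cluster as soon as any of
its selected sites does, and sizes are counted in molecules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_model import SiteSet

__all__ = [
    "ShapeParams",
    "AggregateLabels",
    "radius_of_gyration",
    "principal_moments",
    "asphericity",
    "find_aggregates",
    "size_histogram",
    "shape_params",
]

DA_A2_TO_1E4_DA_NM2 = 1e-6  # Da A^2 -> 1e-4 Da nm^2 (1 A^2 = 1e-2 nm^2)


@dataclass
class ShapeParams:
    rg: float                       # Angstrom
    moments: tuple[float, float, float]  # I1 >= I2 >= I3, Da Angstrom^2
    alpha: float

    @property
    def moments_table_units(self) -> tuple[float, float, float]:
        """Moments in 1e-4 Da nm^2, the conventional reporting unit."""
        return tuple(m * DA_A2_TO_1E4_DA_NM2 for m in self.moments)


@dataclass
class AggregateLabels:
    labels: np.ndarray              # per-site cluster id; -1 = unassigned
    sizes: dict[int, int]           # cluster-size histogram {size: count}
    n_clusters: int
    molecule_labels: np.ndarray | None = None  # per-molecule cluster id


def radius_of_gyration(sites: SiteSet, mass_weighted: bool = True) -> float:
    """Rg^2 = sum_i m_i |r_i - r_cm|^2 / sum_i m_i (unit weights optional)."""
    w = sites.masses if mass_weighted else np.ones(sites.n_sites)
    total = w.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (w[:, None] * sites.positions).sum(axis=0) / total
    d2 = np.sum((sites.positions - com) ** 2, axis=1)
    return float(np.sqrt((w * d2).sum() / total))


def principal_moments(sites: SiteSet) -> tuple[float, float, float]:
    """Eigenvalues of the inertia tensor about the centre of mass, descending.

    Units are mass times length squared of the inputs (Da Angstrom^2 for a
    standard SiteSet); divide by 1e6 for the 1e-4 Da nm^2 reporting unit.
    """
    m = sites.masses
    com = (m[:, None] * sites.positions).sum(axis=0) / m.sum()
    r = sites.positions - com
    r2 = np.sum(r * r, axis=1)
    # I_ab = sum_i m_i (r_i^2 delta_ab - r_ia r_ib)
    inertia = np.eye(3) * np.sum(m * r2) - np.einsum("i,ia,ib->ab", m, r, r)
    eig = np.linalg.eigvalsh(inertia)[::-1]
    eig = np.clip(eig, 0.0, None)
    return float(eig[0]), float(eig[1]), float(eig[2])


def asphericity(i1: float, i2: float, i3: float) -> float:
    """alpha = (2 I1 - I2 - I3) / (I1 + I2 + I3); 0 for a sphere."""
    if not (i1 >= i2 >= i3 >= 0):
        raise ValueError("moments must satisfy I1 >= I2 >= I3 >= 0")
    total = i1 + i2 + i3
    if total == 0:
        raise ValueError("all principal moments are zero")
    return float((2.0 * i1 - i2 - i3) / total)


def shape_params(sites: SiteSet, mass_weighted: bool = True) -> ShapeParams:
    """Convenience: Rg, principal moments and asphericity in one call."""
    moments = principal_moments(sites)
    return ShapeParams(
        rg=radius_of_gyration(sites, mass_weighted=mass_weighted),
        moments=moments,
        alpha=asphericity(*moments),
    )


def _pairwise_adjacency(pos: np.ndarray, cutoff: float,
                        box: np.ndarray | None) -> csr_matrix:
    disp = pos[:, None, :] - pos[None, :, :]
    if box is not None:
        disp -= box * np.round(disp / box)
    d2 = np.sum(disp * disp, axis=-1)
    adj = d2 <= cutoff * cutoff
    np.fill_diagonal(adj, False)
    return csr_matrix(adj)


def find_aggregates(sites: SiteSet, selection=None, cutoff: float = 10.0,
                    box=None, molecules=None) -> AggregateLabels:
    """Single-linkage aggregates under a maximum-distance criterion.

    Parameters
    ----------
    selection : indices of the sites considered for distances (e.g. tail
        beads plus the first head bead); default all sites.
    cutoff : maximum distance (Angstrom) for two sites to be connected.
    box : orthorhombic box lengths for minimum-image distances; defaults to
        ``sites.box``.
    molecules : optional per-site molecule ids; clusters sharing a molecule
        are merged, every site of a molecule inherits its cluster, and the
        size histogram counts molecules instead of sites.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = sites.n_sites
    sel = np.arange(n) if selection is None else np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("selection must not be empty")
    boxv = None
    if box is not None:
        boxv = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    elif sites.box is not None:
        boxv = sites.box
    adj = _pairwise_adjacency(sites.positions[sel], cutoff, boxv)
    n_comp, comp = connected_components(adj, directed=False)

    labels = np.full(n, -1, dtype=int)
    labels[sel] = comp

    mol_labels = None
    if molecules is not None:
        mol = np.asarray(molecules, dtype=int)
        if mol.shape != (n,):
            raise ValueError("molecules must give one id per site")
        # merge clusters connected through a shared molecule (union-find)
        parent = np.arange(n_comp)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for mid in np.unique(mol[sel]):
            comps = np.unique(comp[mol[sel] == mid])
            for c in comps[1:]:
                ra, rb = find(int(comps[0])), find(int(c))
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(c) for c in range(n_comp)])
        _, renum = np.unique(roots, return_inverse=True)
        comp = renum[comp]
        n_comp = int(comp.max()) + 1
        # every site of a molecule inherits the molecule's cluster
        mol_labels = np.full(int(mol.max()) + 1, -1, dtype=int)
        for s_idx, c in zip(sel, comp):
            mol_labels[mol[s_idx]] = c
        labels = np.where(mol_labels[mol] >= 0, mol_labels[mol], -1)
        member = mol_labels[mol_labels >= 0]
        counts = np.bincount(member, minlength=n_comp)
    else:
        labels = np.full(n, -1, dtype=int)
        labels[sel] = comp
        counts = np.bincount(comp, minlength=n_comp)

    sizes: dict[int, int] = {}
    for c in counts:
        if c > 0:
            sizes[int(c)] = sizes.get(int(c), 0) + 1
    return AggregateLabels(labels=labels, sizes=sizes, n_clusters=n_comp,
                           molecule_labels=mol_labels)


def size_histogram(frames) -> dict[int, float]:
    """Cluster-size histogram, averaged over frames.

    ``frames`` is one AggregateLabels or a sequence of them; counts are per
    size bin, divided by the number of frames.
    """
    if isinstance(frames, AggregateLabels):
        frames = [frames]
    hist: dict[int, float] = {}
    for fr in frames:
        for size, count in fr.sizes.items():
            hist[size] = hist.get(size, 0.0) + count
    return {s: c / len(frames) for s, c in sorted(hist.items())}
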