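import numpy as np
import pytest

from sansmi.io_model import ExperimentalCurve, SiteSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eight_site_cluster(rng):
    """Small random cluster with mixed scattering lengths."""
    return SiteSet(
        positions=rng.uniform(-5.0, 5.0, (8, 3)),
        scatlens=rng.uniform(0.5, 3.0, 8),
    )


@pytest.fixture
def smooth_curve():
    """Smooth synthetic experimental curve with resolution column."""
    q = np.linspace(0.02, 0.3, 15)
    return ExperimentalCurve(
        q=q,
        intensity=np.exp(-((q / 0.15) ** 2)),
        error=np.full(q.size, 0.01),
        sigma_res=np.full(q.size, 0.005),
    )


@pytest.fixture
def pdb_beads(tmp_path):
    """Tiny PDB with five HETATM coarse-grained beads."""
    lines = []
    coords = [(0.0, 0.0, 0.0), (4.7, 0.0, 0.0), (9.4, 0.0, 0.0),
              (0.0, 4.7, 0.0), (0.0, 0.0, 4.7)]
    names = ["C1", "C2", "C3", "GL1", "GL2"]
    for i, (name, (x, y, z)) in enumerate(zip(names, coords), start=1):
        lines.append(
            f"HETATM{i:5d} {name:<4s}BOG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        )
    lines.append("END")
    path = tmp_path / "beads.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
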