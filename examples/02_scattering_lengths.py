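"""Coarse-grained scattering lengths with hydrogen/deuterium contrast.

A coarse bead scatters with the sum of its atoms' coherent scattering
lengths.  Because b(1H) = -3.739 fm while b(2H) = +6.671 fm, swapping H for
D flips the sign and magnitude of hydrogen-rich beads — the basis of
contrast-variation SANS.  The table is written in the SCATLEN file dialect
and read back.
"""
import tempfile
from pathlib import Path

from sansmi.scatlen import (Bead, BeadMapping, map_bead_scatlens,
                            read_scatlen_file, write_scatlen_file)

# a 4-water bead and a butane-like tail bead, 2 molecule copies
mapping = BeadMapping(
    beads=[
        Bead("W", ["O", "H", "H"] * 4),
        Bead("C1", ["C", "H", "H", "C", "H", "H", "C", "H", "H", "C",
                    "H", "H", "H", "H"]),
    ],
    nmols=2,
)

plain = map_bead_scatlens(mapping)
deuterated = map_bead_scatlens(mapping, swap_h_to_d=True)
print("bead scattering lengths, fm (per molecule copy):")
for name, b_h, b_d in zip(["W", "C1"], plain.b[:2], deuterated.b[:2]):
    print(f"  {name:3s}  H-form {b_h:8.3f}   D-form {b_d:8.3f}")
print("negative H-form values mean the bead scatters out of phase;")
print("deuteration flips the contrast.")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "scatlens.plumed"
    write_scatlen_file(plain, path)
    print("\nSCATLEN file:")
    print(path.read_text(), end="")
    assert read_scatlen_file(path).b.size == 4
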