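"""Cavity volumes of self-assembled DNA crystal lattices.

The tightly packed trigonal lattice leaves triangular pores (3-nm edges,
height = the ~6.1-nm c-axis); the open lattice leaves hexagonal channels
(6.4-nm edges, 6.0-nm height).  Idealized solid-prism volumes quantify
how much guest-scaffolding space each symmetry offers.
"""

from hjkit.lattice import CavitySpec, CellGroup, cavity_volume, cell_statistics, volume_ratio
from hjkit.structure_io import LatticeParams

tri = CavitySpec("triangular", edge=3.0, height=6.1)
hexa = CavitySpec("hexagonal", edge=6.4, height=6.0)
print(f"triangular pore: {cavity_volume(tri):6.1f} nm^3")
print(f"hexagonal channel: {cavity_volume(hexa):6.1f} nm^3")
print(f"fold change: {volume_ratio(hexa, tri):.1f}x")

cells = CellGroup(
    "P32 (example cells)",
    (
        LatticeParams(68.29, 68.29, 52.77, 90, 90, 120, "P 32"),
        LatticeParams(68.29, 68.29, 55.68, 90, 90, 120, "P 32"),
        LatticeParams(68.29, 68.29, 60.36, 90, 90, 120, "P 32"),
    ),
)
print("\nunit-cell statistics (A / deg):")
print(cell_statistics(cells).round(2).to_string())
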