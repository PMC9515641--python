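"""Forward optics: the light-scattering profile of one cell.

Models an unpolarized M0-like macrophage as a coated sphere (nucleus of
index 1.42 inside cytoplasm of 1.39) and prints its scattered intensity at
a few angles of the 2-30 degree instrument window.
"""

import numpy as np

from scattercyte import CoreShellCell, OpticalConfig, integrated_intensity, lsp_intensity

cell = CoreShellCell(diameter=15.66, nc_ratio=0.85, ri_nucleus=1.42, ri_cytoplasm=1.39)
optics = OpticalConfig()  # 632.8 nm HeNe, PBS medium, 2-30 deg at 0.1 deg

lsp = lsp_intensity(cell, optics)
print(f"angular grid: {lsp.angles.size} points from {lsp.angles[0]} to {lsp.angles[-1]} deg")
for theta in (2.0, 5.0, 10.0, 20.0, 30.0):
    i = lsp.intensities[np.argmin(np.abs(lsp.angles - theta))]
    print(f"  I({theta:4.1f} deg) = {i:12.4g}  (relative units)")
print(f"window-integrated power: {integrated_intensity(lsp):.4g}")
print(
    "The forward lobe carries most of the signal; the fringe spacing "
    "(~1.7 deg for this cell) encodes the diameter, and the fringe depth/"
    "placement encode the core size and index contrast."
)
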