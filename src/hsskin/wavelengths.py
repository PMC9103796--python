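"""Band-center wavelength grids of the imager.

The instrument captures two LED/band groups: a visible group (VIS, two LED
types on) and a visible-to-near-infrared group (VNIR, seven LED types on).
Each group is captured once per light direction, so one measurement is
3 directions x 2 groups = 6 radiance cubes. Combined, the two groups give
33 bands from 477 to 891 nm.
"""

from __future__ import annotations

import numpy as np

#: Visible-range band centers in nm (17 bands).
VIS_WAVELENGTHS_NM: tuple[float, ...] = (
    477, 500, 524, 540, 550, 575, 578, 582, 600,
    626, 630, 639, 651, 669, 677, 681, 686,
)

#: Visible/near-infrared band centers in nm (16 bands).
VNIR_WAVELENGTHS_NM: tuple[float, ...] = (
    700, 725, 735, 750, 760, 765, 775, 783, 790,
    801, 812, 825, 834, 851, 878, 891,
)

#: Full combined grid, ascending (33 bands).
ALL_WAVELENGTHS_NM: tuple[float, ...] = VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM

#: Wavelength of the depth channel fed to the classifier's 2-D branch.
DEFAULT_DEPTH_WAVELENGTH_NM: float = 575.0


def as_grid(wavelengths) -> np.ndarray:
    """Validate and return a wavelength grid as a float array.

    A grid must be one-dimensional, strictly ascending and finite.
    """
    grid = np.asarray(wavelengths, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(grid)):
        raise ValueError("wavelength grid contains non-finite values")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    return grid


def band_index(wavelengths, target_nm: float) -> int:
    """Index of ``target_nm`` in the grid, or raise listing available bands."""
    grid = as_grid(wavelengths)
    matches = np.nonzero(np.isclose(grid, float(target_nm)))[0]
    if matches.size == 0:
        raise ValueError(
            f"wavelength {target_nm} nm not in grid; available bands: "
            f"{', '.join(f'{w:g}' for w in grid)}"
        )
    return int(matches[0])
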