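"""Bayer demosaicing and the FPI/RGB spectral-calibration transform.

The imager pairs a tunable Fabry-Perot interferometer (FPI) with an RGB
Bayer sensor.  One FPI air gap transmits up to three wavelength peaks, so
one demosaiced RGB response vector s (per pixel) mixes the radiance at
those peaks linearly: S = C R, with S the 3 x n response matrix (pixels as
columns), R the 3 x n radiance at the peak wavelengths and C a per-gap
3 x 3 coefficient matrix determined in a separate spectral calibration.
Radiance is then recovered as R = C^-1 S.

The calibration campaign itself (monochromator sweeps, power-meter
radiometry) is hardware work and out of scope; this module implements its
mathematical product: fitting C from reference exposures and applying its
inverse, plus a plain-text tabular format for per-gap calibration records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "BayerFrame",
    "CalibrationMatrix",
    "demosaic_bilinear",
    "fit_calibration_matrix",
    "reconstruct_radiance",
    "read_calibration_table",
    "write_calibration_table",
]

BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")

#: Default ceiling on cond(C) before inversion is refused.
DEFAULT_CONDITION_LIMIT = 1e6


@dataclass(frozen=True)
class BayerFrame:
    """One raw mosaicked frame: 2x2 color tiling over an even-sized grid."""

    values: np.ndarray
    pattern: str = "RGGB"
    exposure_ms: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("Bayer frame must be 2-D")
        if v.shape[0] % 2 or v.shape[1] % 2:
            raise ValueError(
                f"Bayer frame dimensions must be even (2x2 color tiling), got {v.shape}"
            )
        if np.any(v < 0):
            raise ValueError("Bayer frame values must be >= 0")
        if self.pattern not in BAYER_PATTERNS:
            raise ValueError(f"pattern must be one of {BAYER_PATTERNS}")


@dataclass
class CalibrationMatrix:
    """Per-FPI-gap 3x3 coefficients mapping peak radiance to RGB response."""

    C: np.ndarray
    peak_wavelengths: np.ndarray
    fpi_gap_id: str = ""

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, 3) or not np.all(np.isfinite(self.C)):
            raise ValueError("C must be a finite 3x3 matrix")
        self.peak_wavelengths = np.asarray(self.peak_wavelengths, dtype=float)
        if self.peak_wavelengths.size > 3:
            raise ValueError("at most 3 transmission peaks per FPI gap")
        if np.any(np.diff(self.peak_wavelengths) <= 0):
            raise ValueError("peak wavelengths must be ascending")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.C))


def _channel_masks(shape, pattern: str):
    """Boolean site masks (R, G, B) for a Bayer pattern on the given shape."""
    H, W = shape
    rows = np.arange(H)[:, None] % 2
    cols = np.arange(W)[None, :] % 2
    # pattern string lists the 2x2 tile row-major: positions (0,0) (0,1) (1,0) (1,1)
    tile = {(0, 0): pattern[0], (0, 1): pattern[1], (1, 0): pattern[2], (1, 1): pattern[3]}
    masks = {}
    for ch in "RGB":
        m = np.zeros((H, W), dtype=bool)
        for (tr, tc), letter in tile.items():
            if letter == ch:
                m |= (rows == tr) & (cols == tc)
        masks[ch] = m
    return masks["R"], masks["G"], masks["B"]


def demosaic_bilinear(frame: BayerFrame) -> np.ndarray:
    """Bilinear demosaic: H x W x 3 RGB from one Bayer frame.

    Each output channel keeps the raw value at its native sites and fills
    the other sites with the average of the nearest same-channel neighbors
    (normalized 3x3 convolution, which reduces to the classic bilinear
    kernels in the interior and to the mean of available neighbors at the
    borders).
    """
    v = np.asarray(frame.values, dtype=float)
    kernel = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])
    out = np.empty(v.shape + (3,))
    for i, mask in enumerate(_channel_masks(v.shape, frame.pattern)):
        num = convolve2d(v * mask, kernel, mode="same", boundary="fill")
        den = convolve2d(mask.astype(float), kernel, mode="same", boundary="fill")
        ch = num / den
        ch[mask] = v[mask]  # native sites are exact
        out[:, :, i] = ch
    return out


def fit_calibration_matrix(
    S_obs: np.ndarray,
    R_ref: np.ndarray,
    peak_wavelengths=None,
    fpi_gap_id: str = "",
) -> CalibrationMatrix:
    """Least-squares fit of C in S = C R from m calibration exposures.

    ``S_obs`` and ``R_ref`` are 3 x m (exposures as columns).  Requires
    R_ref to span its nonzero rows; a rank-deficient reference design is
    rejected with the observed rank.  When the gap transmits fewer than
    three peaks the absent peaks are all-zero rows of R_ref; the
    corresponding columns of C are unconstrained by the data and are
    regularized to zero.
    """
    S = np.asarray(S_obs, dtype=float)
    R = np.asarray(R_ref, dtype=float)
    if S.ndim != 2 or S.shape[0] != 3 or R.shape != S.shape:
        raise ValueError("S_obs and R_ref must both be 3 x m with matching m")
    if S.shape[1] < 3:
        raise ValueError("need at least 3 calibration exposures")

    active = ~np.all(R == 0.0, axis=1)  # peaks actually present
    n_active = int(active.sum())
    rank = np.linalg.matrix_rank(R[active])
    if rank < n_active:
        raise ValueError(
            f"rank-deficient reference radiance: rank {rank} < {n_active} active peaks"
        )
    C = np.zeros((3, 3))
    # solve R_active^T C_active^T = S^T  (columns of C for absent peaks stay 0)
    sol, *_ = np.linalg.lstsq(R[active].T, S.T, rcond=None)
    C[:, active] = sol.T
    if peak_wavelengths is None:
        peak_wavelengths = np.arange(n_active, dtype=float)
    return CalibrationMatrix(C=C, peak_wavelengths=peak_wavelengths, fpi_gap_id=fpi_gap_id)


def reconstruct_radiance(
    S: np.ndarray,
    cal: CalibrationMatrix,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> np.ndarray:
    """Invert the calibration: R = C^-1 S per pixel (3 x n in, 3 x n out).

    Refuses ill-conditioned calibrations, reporting cond(C).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != 3:
        raise ValueError("S must be 3 x n (pixels as columns)")
    cond = cal.condition_number
    if not np.isfinite(cond) or cond > condition_limit:
        raise ValueError(
            f"calibration matrix condition number {cond:.3e} exceeds limit "
            f"{condition_limit:.3e}; refusing inversion"
        )
    return np.linalg.solve(cal.C, S)


def write_calibration_table(path, cals) -> None:
    """Write per-gap calibration records as tabular text.

    One record per line: gap id, number of peaks, peak wavelengths (nm),
    then the 9 coefficients of C row-major, whitespace-separated.
    """
    with open(path, "w") as fh:
        fh.write("# gap_id n_peaks peak_wavelengths_nm... C_row_major...\n")
        for cal in cals:
            peaks = " ".join(f"{w:.6g}" for w in cal.peak_wavelengths)
            coeffs = " ".join(f"{c:.12g}" for c in cal.C.ravel())
            fh.write(f"{cal.fpi_gap_id or 'gap'} {cal.peak_wavelengths.size} {peaks} {coeffs}\n")


def read_calibration_table(path) -> list[CalibrationMatrix]:
    """Read records written by :func:`write_calibration_table`."""
    cals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            gap_id, n_peaks = parts[0], int(parts[1])
            vals = [float(x) for x in parts[2:]]
            if len(vals) != n_peaks + 9:
                raise ValueError(
                    f"calibration record for {gap_id!r} has {len(vals)} numbers, "
                    f"expected {n_peaks} peaks + 9 coefficients"
                )
            cals.append(
                CalibrationMatrix(
                    C=np.asarray(vals[n_peaks:]).reshape(3, 3),
                    peak_wavelengths=np.asarray(vals[:n_peaks]),
                    fpi_gap_id=gap_id,
                )
            )
    return cals
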