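"""Raw-cube processing and machine-learning preprocessing.

Two stages of preprocessing feed the classifier.  The raw-image pipeline
turns radiance cubes into reflectance ((R - D) / (W - D) against the white
and dark references), concatenates the VIS and VNIR band groups into one
33-band cube per light direction, and smooths albedo spectra with
total-variation denoising along the wavelength axis only.

The machine-learning stage assembles the 34-channel feature stack
(33 albedo bands + the depth map of one visible band, 575 nm by default,
min-max normalized per channel with non-finite values zeroed), splits each
scene at the lesion's vertical midline (training pixels sampled strictly
left of the slice, test pixels strictly right), extracts 30 x 30 x 34
windows centered on the sampled pixels, balances classes by random
over-sampling to the majority count, and quadruples the training set with
vertical/horizontal/double flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .wavelengths import DEFAULT_DEPTH_WAVELENGTH_NM, as_grid

__all__ = [
    "ReflectanceCube",
    "FeatureStack",
    "PixelSample",
    "SubCubeSet",
    "compute_reflectance",
    "combine_vis_vnir",
    "tv_denoise_spectral",
    "build_feature_stack",
    "slice_half_sample",
    "extract_windows",
    "balance_oversample",
    "augment_flips",
]

WINDOW = 30
MARGIN = WINDOW // 2  # sampled centers must sit >= 15 px from every border
STEP = 5

# provenance codes for sub-cubes
PROV_ORIGINAL = 0
PROV_OVERSAMPLED = 1
PROV_VFLIP = 2
PROV_HFLIP = 3
PROV_VHFLIP = 4


@dataclass
class ReflectanceCube:
    """White/dark-corrected reflectance for one light direction."""

    values: np.ndarray  # (H, W, bands), unitless
    wavelengths: np.ndarray
    light_direction_id: int = 0
    valid: np.ndarray | None = None  # False where white - dark <= 0


@dataclass
class FeatureStack:
    """Per-scene classifier input: 33 albedo channels + 1 depth channel."""

    values: np.ndarray  # (H, W, 34) in [0, 1], float32
    wavelengths: np.ndarray  # 33 albedo band centers, ascending nm
    depth_wavelength_nm: float = DEFAULT_DEPTH_WAVELENGTH_NM
    bounds: np.ndarray | None = None  # (34, 2) per-channel (min, max) used


@dataclass(frozen=True)
class PixelSample:
    """One sampled pixel: scene, slice side, coordinates and class label."""

    scene_id: int
    side: str  # "left" | "right"
    row: int
    col: int
    label: int  # 0 healthy, 1 intradermal nevus, 2 BCC


@dataclass
class SubCubeSet:
    """A batch of 30 x 30 x 34 windows with labels and provenance flags."""

    cubes: np.ndarray  # (n, 30, 30, 34) float32
    labels: np.ndarray  # (n,) int
    scene_ids: np.ndarray  # (n,) int
    provenance: np.ndarray  # (n,) int codes (original/oversampled/flips)
    grid_shape: tuple[int, int] | None = None  # set in map mode

    def __len__(self) -> int:
        return int(self.cubes.shape[0])

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def compute_reflectance(
    radiance: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    wavelengths=None,
    white_wavelengths=None,
    light_direction_id: int = 0,
) -> ReflectanceCube:
    """Reflectance (R - D) / (W - D); pixels with W - D <= 0 flagged and zeroed."""
    R = np.asarray(radiance, dtype=float)
    W = np.asarray(white, dtype=float)
    D = np.asarray(dark, dtype=float)
    if R.shape != W.shape or R.shape != D.shape:
        raise ValueError(
            f"shape mismatch: radiance {R.shape}, white {W.shape}, dark {D.shape}"
        )
    if wavelengths is not None and white_wavelengths is not None:
        wl = as_grid(wavelengths)
        wwl = as_grid(white_wavelengths)
        if wl.size != wwl.size or not np.allclose(wl, wwl):
            raise ValueError(
                f"wavelength grids differ: radiance grid {wl.tolist()} vs "
                f"white grid {wwl.tolist()}"
            )
    denom = W - D
    valid = denom > 0
    out = np.zeros_like(R)
    np.divide(R - D, denom, out=out, where=valid)
    out[~valid] = 0.0
    if wavelengths is None:
        wavelengths = np.arange(R.shape[-1], dtype=float)
    return ReflectanceCube(
        values=out,
        wavelengths=as_grid(wavelengths),
        light_direction_id=light_direction_id,
        valid=valid,
    )


def combine_vis_vnir(vis: ReflectanceCube, vnir: ReflectanceCube) -> ReflectanceCube:
    """Concatenate the two band groups into one cube, ascending in nm."""
    if vis.light_direction_id != vnir.light_direction_id:
        raise ValueError("cubes belong to different light directions")
    if vis.values.shape[:2] != vnir.values.shape[:2]:
        raise ValueError("cubes have different spatial shapes")
    wl_vis = as_grid(vis.wavelengths)
    wl_vnir = as_grid(vnir.wavelengths)
    overlap = np.intersect1d(wl_vis, wl_vnir)
    if overlap.size:
        raise ValueError(
            f"wavelength ranges overlap at {overlap.tolist()} nm; groups must be disjoint"
        )
    wl = np.concatenate([wl_vis, wl_vnir])
    values = np.concatenate([vis.values, vnir.values], axis=2)
    order = np.argsort(wl)
    valid = None
    if vis.valid is not None and vnir.valid is not None:
        valid = np.concatenate([vis.valid, vnir.valid], axis=2)[:, :, order]
    return ReflectanceCube(
        values=values[:, :, order],
        wavelengths=wl[order],
        light_direction_id=vis.light_direction_id,
        valid=valid,
    )


def tv_denoise_spectral(
    albedo: np.ndarray,
    weight: float = 10.0,
    n_iter: int = 30,
    tol: float = 1e-5,
) -> np.ndarray:
    """Split-Bregman total-variation denoising along the wavelength axis.

    Each pixel's spectrum is treated as an independent 1-D signal u
    minimizing  weight/2 * ||u - f||^2 + sum |u[k+1] - u[k]|;  larger
    ``weight`` keeps the output closer to the input (the fidelity-weight
    convention).  Spatial structure is untouched: pixels never mix.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    a = np.asarray(albedo)
    if not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    nb = a.shape[-1]
    if nb < 2:
        return a.astype(float).copy()
    f = np.ascontiguousarray(a.reshape(-1, nb).T, dtype=np.float64)  # (bands, npix)

    D = np.diff(np.eye(nb), axis=0)  # (nb-1, nb) first-difference operator
    mu = 2.0 * weight
    A = weight * np.eye(nb) + mu * (D.T @ D)
    chol = cho_factor(A, check_finite=False)

    def dt(y):  # D.T @ y without the matmul (bidiagonal structure)
        out = np.empty((nb, y.shape[1]), dtype=y.dtype)
        out[0] = -y[0]
        out[-1] = y[-1]
        np.subtract(y[:-1], y[1:], out=out[1:-1])
        return out

    u = f.copy()
    d = np.zeros((nb - 1, f.shape[1]))
    b = np.zeros_like(d)
    for _ in range(n_iter):
        rhs = weight * f + mu * dt(d - b)
        u_new = cho_solve(chol, rhs, check_finite=False)
        s = np.diff(u_new, axis=0)
        s += b
        d = np.sign(s) * np.maximum(np.abs(s) - 1.0 / mu, 0.0)
        b = s - d
        change = np.abs(u_new - u).max()
        u = u_new
        if change < tol:
            break
    return u.T.reshape(a.shape).astype(float)


def build_feature_stack(
    albedo: np.ndarray,
    depth_per_wavelength,
    wavelengths,
    depth_wavelength_nm: float = DEFAULT_DEPTH_WAVELENGTH_NM,
) -> FeatureStack:
    """Stack 33 albedo channels with the depth channel of one wavelength.

    ``depth_per_wavelength`` maps wavelength (nm) to an (H, W) depth array
    (a single array is accepted and taken to be the requested wavelength).
    Non-finite values are set to 0, then every channel is min-max
    normalized to [0, 1] (constant channels map to 0).
    """
    wl = as_grid(wavelengths)
    a = np.asarray(albedo, dtype=float)
    if a.ndim != 3 or a.shape[2] != wl.size:
        raise ValueError(f"albedo shape {a.shape} does not match {wl.size} bands")

    if isinstance(depth_per_wavelength, np.ndarray):
        depth = depth_per_wavelength
    else:
        avail = {float(k): v for k, v in dict(depth_per_wavelength).items()}
        if float(depth_wavelength_nm) not in avail:
            raise ValueError(
                f"depth at {depth_wavelength_nm} nm not available; have "
                f"{sorted(avail)}"
            )
        depth = avail[float(depth_wavelength_nm)]
    depth = np.asarray(depth, dtype=float)
    if depth.shape != a.shape[:2]:
        raise ValueError(f"depth shape {depth.shape} does not match image {a.shape[:2]}")

    raw = np.concatenate([a, depth[:, :, None]], axis=2)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    lo = raw.min(axis=(0, 1))
    hi = raw.max(axis=(0, 1))
    span = np.where(hi > lo, hi - lo, 1.0)
    values = (raw - lo) / span
    values[:, :, hi == lo] = 0.0
    return FeatureStack(
        values=values.astype(np.float32),
        wavelengths=wl,
        depth_wavelength_nm=float(depth_wavelength_nm),
        bounds=np.column_stack([lo, hi]),
    )


def _eligible(mask: np.ndarray, margin: int) -> np.ndarray:
    """Zero out mask entries closer than ``margin`` to any border."""
    out = np.zeros_like(mask, dtype=bool)
    out[margin:-margin, margin:-margin] = mask[margin:-margin, margin:-margin]
    return out


def slice_half_sample(
    class_mask: np.ndarray,
    healthy_mask: np.ndarray,
    n_lesion: int = 250,
    n_healthy: int = 100,
    seed: int = 0,
    scene_id: int = 0,
    margin: int = MARGIN,
) -> tuple[list[PixelSample], list[PixelSample]]:
    """Sample train/test pixel centers on either side of the lesion midline.

    The slice column is the horizontal centroid of the lesion mask; training
    pixels are drawn strictly left of it, test pixels strictly right, all at
    least ``margin`` px from every border so each window fits.  Exactly
    ``n_lesion`` lesion + ``n_healthy`` healthy pixels per side, without
    replacement; a side with too few eligible pixels raises with the deficit.
    """
    cm = np.asarray(class_mask)
    hm = np.asarray(healthy_mask, dtype=bool)
    if cm.shape != hm.shape:
        raise ValueError("class_mask and healthy_mask shapes differ")
    lesion = (cm == 1) | (cm == 2)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    slice_col = int(round(np.nonzero(lesion)[1].mean()))

    lesion_ok = _eligible(lesion, margin)
    healthy_ok = _eligible(hm & (cm == 0), margin)
    cols = np.arange(cm.shape[1])[None, :]
    rng = np.random.default_rng(seed)

    out: dict[str, list[PixelSample]] = {}
    for side, region in (("left", cols < slice_col), ("right", cols > slice_col)):
        samples = []
        for mask, n_req, kind in ((lesion_ok, n_lesion, "lesion"), (healthy_ok, n_healthy, "healthy")):
            rr, cc = np.nonzero(mask & region)
            if rr.size < n_req:
                raise ValueError(
                    f"scene {scene_id}: only {rr.size} eligible {kind} pixels on the "
                    f"{side} side, {n_req} requested (deficit {n_req - rr.size})"
                )
            pick = rng.choice(rr.size, size=n_req, replace=False)
            for i in pick:
                label = int(cm[rr[i], cc[i]]) if kind == "lesion" else 0
                samples.append(PixelSample(scene_id, side, int(rr[i]), int(cc[i]), label))
        out[side] = samples
    return out["left"], out["right"]


def extract_windows(
    stack: FeatureStack,
    pixels=None,
    window: int = WINDOW,
    step: int = STEP,
) -> SubCubeSet:
    """Cut 30 x 30 x 34 sub-cubes out of a feature stack.

    With ``pixels`` given, one window per sample centered on it (rows
    r-15..r+14, cols c-15..c+14).  In map mode (``pixels=None``) windows
    tile the image on a step grid: floor((H - window) / step) + 1 per axis,
    recorded in ``grid_shape``; labels are set to -1.
    """
    v = stack.values
    H, W, C = v.shape
    half = window // 2
    if pixels is not None:
        n = len(pixels)
        cubes = np.empty((n, window, window, C), dtype=np.float32)
        labels = np.empty(n, dtype=np.int64)
        scene_ids = np.empty(n, dtype=np.int64)
        for i, px in enumerate(pixels):
            r, c = px.row, px.col
            if r - half < 0 or c - half < 0 or r + half > H or c + half > W:
                raise ValueError(
                    f"pixel ({r}, {c}) violates the {half} px window margin "
                    f"for image {H}x{W}"
                )
            cubes[i] = v[r - half : r + half, c - half : c + half, :]
            labels[i] = px.label
            scene_ids[i] = px.scene_id
        return SubCubeSet(
            cubes=cubes,
            labels=labels,
            scene_ids=scene_ids,
            provenance=np.full(n, PROV_ORIGINAL, dtype=np.int8),
        )

    if H < window or W < window:
        raise ValueError(f"stack {H}x{W} smaller than the {window} px window")
    n_rows = (H - window) // step + 1
    n_cols = (W - window) // step + 1
    cubes = np.empty((n_rows * n_cols, window, window, C), dtype=np.float32)
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            cubes[k] = v[i * step : i * step + window, j * step : j * step + window, :]
            k += 1
    n = n_rows * n_cols
    return SubCubeSet(
        cubes=cubes,
        labels=np.full(n, -1, dtype=np.int64),
        scene_ids=np.full(n, -1, dtype=np.int64),
        provenance=np.full(n, PROV_ORIGINAL, dtype=np.int8),
        grid_shape=(n_rows, n_cols),
    )


def balance_oversample(sset: SubCubeSet, seed: int = 0) -> SubCubeSet:
    """Random over-sampling: duplicate minority-class cubes (seeded, with
    replacement) until every class matches the majority count.

    Added cubes are flagged ``oversampled``.  An already balanced set is
    returned unchanged.
    """
    counts = sset.class_counts()
    missing = sorted(set(range(3)) - set(counts))
    if missing or min(counts.values()) == 0:
        raise ValueError(
            f"every class needs at least one sample; counts {counts}, "
            f"missing classes {missing}"
        )
    majority = max(counts.values())
    if all(c == majority for c in counts.values()):
        return sset
    rng = np.random.default_rng(seed)
    extra_idx = []
    for cls, count in sorted(counts.items()):
        if count < majority:
            idx = np.nonzero(sset.labels == cls)[0]
            extra_idx.append(rng.choice(idx, size=majority - count, replace=True))
    extra = np.concatenate(extra_idx)
    return SubCubeSet(
        cubes=np.concatenate([sset.cubes, sset.cubes[extra]]),
        labels=np.concatenate([sset.labels, sset.labels[extra]]),
        scene_ids=np.concatenate([sset.scene_ids, sset.scene_ids[extra]]),
        provenance=np.concatenate(
            [sset.provenance, np.full(extra.size, PROV_OVERSAMPLED, dtype=np.int8)]
        ),
    )


def augment_flips(sset: SubCubeSet) -> SubCubeSet:
    """Quadruple a set with vertical, horizontal and double spatial flips.

    Output order: originals, vertical flips, horizontal flips, double
    flips; labels, scene ids and (flip-coded) provenance follow along.
    """
    v = sset.cubes
    parts = [v, v[:, ::-1, :, :], v[:, :, ::-1, :], v[:, ::-1, ::-1, :]]
    prov = [
        sset.provenance,
        np.full(len(sset), PROV_VFLIP, dtype=np.int8),
        np.full(len(sset), PROV_HFLIP, dtype=np.int8),
        np.full(len(sset), PROV_VHFLIP, dtype=np.int8),
    ]
    return SubCubeSet(
        cubes=np.concatenate(parts),
        labels=np.tile(sset.labels, 4),
        scene_ids=np.tile(sset.scene_ids, 4),
        provenance=np.concatenate(prov),
        grid_shape=sset.grid_shape,
    )
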