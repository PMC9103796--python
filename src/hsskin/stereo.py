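"""Per-wavelength photometric stereo and Fourier-domain depth integration.

Three images of a static Lambertian scene under known light directions
determine, per pixel and per band, the vector a*N (albedo times unit
normal): stacking the three reflectances r_i = a * max(0, N . L_i) and
inverting the 3x3 light-direction matrix L gives v = L^-1 r, whose length
is the albedo and whose direction is the surface normal.  The normal
field is converted to depth gradients p = dz/dx, q = dz/dy and integrated
into a relative height map with the Frankot-Chellappa algorithm: the
least-squares integrable surface in the Fourier domain,

    Z = Re IFFT[ (-i wx P - i wy Q) / (wx^2 + wy^2 + eps) ],

with P = FFT(p), Q = FFT(q).  Depth is defined up to a constant; the
zero-frequency term is set to zero so the returned map has zero mean.

Coordinates: x = column index increasing rightward, y = row index
increasing downward, z toward the camera.  The light matrix is defined
for the center of the imaging field; away from the center the true light
directions differ and reconstruction quality degrades toward the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavelengths import band_index

__all__ = [
    "LightGeometry",
    "NormalAlbedoMap",
    "GradientField",
    "DepthMap",
    "light_direction_matrix",
    "solve_albedo_normals",
    "gradients_from_normals",
    "frankot_chellappa",
    "reconstruct_surface",
]

#: Default regularizer added to wx^2 + wy^2 in the integration quotient.
DEFAULT_EPSILON = 1e-8

#: Default clamp on the normal's z component when forming gradients.
DEFAULT_CLAMP_NZ = 0.01


@dataclass(frozen=True)
class LightGeometry:
    """Geometry of the three-direction LED illumination.

    elevation_deg is the angle between the object plane and the arriving
    light vector; the instrument uses 60 degrees with same-wavelength LEDs
    120 degrees apart on the ring. The ring dimension is exposed as a
    parameter (reported inner radius and diameter readings disagree in the
    source hardware description); it does not enter the center-field light
    matrix, which depends only on the angles.
    """

    elevation_deg: float = 60.0
    azimuths_deg: tuple[float, float, float] = (90.0, 330.0, 210.0)
    distance_mm: float = 65.0
    ring_dimension_mm: float = 33.0

    def __post_init__(self):
        if not 0.0 < self.elevation_deg <= 90.0:
            raise ValueError("elevation must be in (0, 90] degrees")
        if len(self.azimuths_deg) != 3:
            raise ValueError("exactly 3 azimuths required")
        az = np.mod(np.asarray(self.azimuths_deg, dtype=float), 360.0)
        if len({round(a, 9) for a in az}) != 3:
            raise ValueError("azimuths must be pairwise distinct")


@dataclass
class NormalAlbedoMap:
    """Albedo cube and per-wavelength unit surface normals.

    albedo has shape (H, W, L); normals has shape (H, W, L, 3) because the
    stereo solve is independent per band, and depth maps are computed per
    wavelength.  degenerate marks pixels/bands whose solution had zero
    length (normal set to (0, 0, 1), albedo 0).
    """

    albedo: np.ndarray
    normals: np.ndarray
    wavelengths: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def band(self, wavelength_nm: float) -> int:
        return band_index(self.wavelengths, wavelength_nm)


@dataclass
class GradientField:
    """Depth partial derivatives p = dz/dx, q = dz/dy (height per pixel)."""

    p: np.ndarray
    q: np.ndarray


@dataclass
class DepthMap:
    """Relative surface height, zero mean, arbitrary (pixel-equivalent) units."""

    Z: np.ndarray
    wavelength_nm: float | None = None
    epsilon: float = DEFAULT_EPSILON


def light_direction_matrix(geometry: LightGeometry) -> np.ndarray:
    """Unit light-direction matrix L (rows = directions) for the field center.

    Row i is (cos e cos phi_i, cos e sin phi_i, sin e) with e the elevation
    and phi_i the azimuth of LED set i.  Raises if the three directions are
    coplanar through the origin (|det L| < 1e-9), which happens at zenith
    elevation where all rows collapse to (0, 0, 1).
    """
    e = np.deg2rad(geometry.elevation_deg)
    phi = np.deg2rad(np.asarray(geometry.azimuths_deg, dtype=float))
    L = np.column_stack(
        [np.cos(e) * np.cos(phi), np.cos(e) * np.sin(phi), np.full(3, np.sin(e))]
    )
    det = np.linalg.det(L)
    if abs(det) < 1e-9:
        raise ValueError(
            f"degenerate light geometry: |det L| = {abs(det):.3e} < 1e-9 "
            "(directions coplanar; cannot invert)"
        )
    return L


def _as_cube(arr: np.ndarray) -> np.ndarray:
    """Promote (H, W) to (H, W, 1)."""
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValueError(f"reflectance must be (H, W) or (H, W, bands), got {a.shape}")
    return a


def solve_albedo_normals(
    refl_triplet,
    L: np.ndarray,
    wavelengths=None,
) -> NormalAlbedoMap:
    """Per-pixel, per-band albedo and unit normal from three reflectance cubes.

    For each pixel and band, v = L^-1 (r0, r1, r2); albedo = |v|; normal =
    v / |v|.  Zero-length solutions are flagged degenerate and assigned
    normal (0, 0, 1) with albedo 0.
    """
    cubes = [_as_cube(c) for c in refl_triplet]
    if len(cubes) != 3:
        raise ValueError(f"expected 3 reflectance cubes, got {len(cubes)}")
    shape = cubes[0].shape
    for i, c in enumerate(cubes[1:], start=1):
        if c.shape != shape:
            raise ValueError(
                f"reflectance cube {i} has shape {c.shape}, expected {shape} "
                "(must match cube 0)"
            )
    L = np.asarray(L, dtype=float)
    if L.shape != (3, 3):
        raise ValueError("light matrix must be 3x3")
    H, W, nb = shape

    r = np.stack([c.reshape(-1) for c in cubes], axis=0)  # (3, H*W*nb)
    v = np.linalg.solve(L, r)  # (3, H*W*nb)
    a = np.linalg.norm(v, axis=0)
    degen = a == 0.0
    n = np.where(degen, np.array([[0.0], [0.0], [1.0]]), v / np.where(degen, 1.0, a))

    albedo = a.reshape(H, W, nb)
    normals = np.moveaxis(n.reshape(3, H, W, nb), 0, -1)  # (H, W, nb, 3)
    if wavelengths is None:
        wavelengths = np.arange(nb, dtype=float)
    return NormalAlbedoMap(
        albedo=albedo,
        normals=normals,
        wavelengths=np.asarray(wavelengths, dtype=float),
        degenerate=degen.reshape(H, W, nb),
    )


def gradients_from_normals(
    nmap,
    clamp_nz: float = DEFAULT_CLAMP_NZ,
    band: int = 0,
    negate: bool = False,
) -> GradientField:
    """Depth gradients from unit normals: p = n0 / n2, q = n1 / n2.

    Implemented exactly in the printed ratio form; ``negate=True`` flips the
    sign to the convention in which the normal of a surface z(x, y) is
    proportional to (-dz/dx, -dz/dy, 1), so that the integrated depth comes
    out upright.  The z component is clamped from below at ``clamp_nz`` to
    keep grazing normals finite.

    ``nmap`` is a NormalAlbedoMap (use ``band`` to pick a wavelength) or a
    raw (H, W, 3) array of normals.
    """
    if isinstance(nmap, NormalAlbedoMap):
        normals = nmap.normals[:, :, band, :]
    else:
        normals = np.asarray(nmap, dtype=float)
        if normals.ndim != 3 or normals.shape[-1] != 3:
            raise ValueError("normals must have shape (H, W, 3)")
    nz = np.maximum(normals[..., 2], clamp_nz)
    sign = -1.0 if negate else 1.0
    return GradientField(p=sign * normals[..., 0] / nz, q=sign * normals[..., 1] / nz)


def frankot_chellappa(fieldv: GradientField, epsilon: float = DEFAULT_EPSILON) -> DepthMap:
    """Least-squares integration of a gradient field in the Fourier domain.

    Returns the real part of IFFT[(-i wx P - i wy Q) / (wx^2 + wy^2 + eps)]
    on the standard DFT angular-frequency grid (2*pi*k/N with negative
    frequencies in the upper half).  The zero-frequency quotient is set to
    zero, fixing the free additive constant so the output has exactly zero
    mean.
    """
    p = np.asarray(fieldv.p, dtype=float)
    q = np.asarray(fieldv.q, dtype=float)
    if p.shape != q.shape or p.ndim != 2:
        raise ValueError("p and q must be 2-D arrays of identical shape")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("gradient field contains non-finite values")
    H, W = p.shape
    wx = 2.0 * np.pi * np.fft.fftfreq(W)[None, :]  # x = column
    wy = 2.0 * np.pi * np.fft.fftfreq(H)[:, None]  # y = row
    P = np.fft.fft2(p)
    Q = np.fft.fft2(q)
    denom = wx**2 + wy**2 + float(epsilon)
    denom[0, 0] = 1.0  # DC quotient is forced to zero below
    quot = (-1j * wx * P - 1j * wy * Q) / denom
    quot[0, 0] = 0.0
    Z = np.real(np.fft.ifft2(quot))
    Z = Z - Z.mean()  # exact zero mean despite float round-off
    return DepthMap(Z=Z, epsilon=float(epsilon))


def reconstruct_surface(
    refl_triplet,
    L: np.ndarray,
    wavelengths=None,
    epsilon: float = DEFAULT_EPSILON,
    depth_wavelength_nm=None,
    clamp_nz: float = DEFAULT_CLAMP_NZ,
    upright: bool = True,
):
    """Chain the stereo solve, gradient formation and depth integration.

    Returns (NormalAlbedoMap, depth) where depth is a single DepthMap when
    ``depth_wavelength_nm`` is a scalar (default: first band), or a list of
    DepthMaps when it is a sequence.  ``upright=True`` (default) negates the
    printed gradient ratios so the recovered height increases toward the
    camera.
    """
    nmap = solve_albedo_normals(refl_triplet, L, wavelengths=wavelengths)

    def depth_at(idx: int, wl: float | None) -> DepthMap:
        grad = gradients_from_normals(nmap, clamp_nz=clamp_nz, band=idx, negate=upright)
        d = frankot_chellappa(grad, epsilon=epsilon)
        d.wavelength_nm = wl
        return d

    if depth_wavelength_nm is None:
        depth = depth_at(0, float(nmap.wavelengths[0]))
    elif np.isscalar(depth_wavelength_nm):
        idx = nmap.band(float(depth_wavelength_nm))
        depth = depth_at(idx, float(depth_wavelength_nm))
    else:
        depth = [depth_at(nmap.band(float(w)), float(w)) for w in depth_wavelength_nm]
    return nmap, depth
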