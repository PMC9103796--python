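"""Synthetic labeled measurements with the structure the pipeline assumes.

Clinical hyperspectral measurements of skin lesions are not publicly
distributable, so this module generates scenes that carry the same
statistical and geometric structure: a known height field, class-dependent
smooth albedo spectra (healthy skin, intradermal nevus, basal cell
carcinoma), Lambertian shading under three known light directions, a
multiplicative illumination profile (captured separately as the white
reference), a constant additive dark level, and additive Gaussian sensor
noise.  Every scene is paired with its ground truth, so each downstream
stage has an exact oracle.

The shading model is Lambertian with a hard shadow clamp max(0, N . L);
real skin is only approximately Lambertian, so passing tests here show
correctness of the inversion, not fidelity to skin optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .stereo import LightGeometry, light_direction_matrix
from .wavelengths import VIS_WAVELENGTHS_NM, VNIR_WAVELENGTHS_NM, as_grid

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Measurement",
    "LESION_CLASSES",
    "make_height_map",
    "make_albedo_spectra",
    "default_illum_profile",
    "render_measurement",
    "make_scene",
    "make_dataset",
]

#: Class index mapping used throughout: 0 healthy, 1 intradermal nevus, 2 BCC.
LESION_CLASSES = ("healthy", "id_nevus", "bcc")

#: Sampling margin (window half-width) that lesions must respect.
WINDOW_MARGIN = 15

_N_VIS = len(VIS_WAVELENGTHS_NM)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    height_px: int = 256
    width_px: int = 256
    surface_kind: str = "skin_lesion"  # flat | hemisphere | brick | skin_lesion
    lesion_class: str = "bcc"
    lesion_center: tuple[int, int] | None = None  # (row, col); default image center
    lesion_radius: float = 48.0
    lesion_height: float = 6.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("scene must be at least 64x64 pixels")
        if self.surface_kind not in ("flat", "hemisphere", "brick", "skin_lesion"):
            raise ValueError(f"unknown surface_kind {self.surface_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.surface_kind in ("hemisphere", "skin_lesion"):
            r, c = self.center
            margin = self.lesion_radius + WINDOW_MARGIN
            for coord, size, name in (
                (r, self.height_px, "rows"),
                (c, self.width_px, "cols"),
            ):
                if coord - margin < 0 or coord + margin > size - 1:
                    raise ValueError(
                        f"lesion (center {self.center}, radius {self.lesion_radius}) "
                        f"plus the {WINDOW_MARGIN} px window margin exceeds the image "
                        f"bounds along {name} (needs {margin:.0f} px clearance)"
                    )

    @property
    def center(self) -> tuple[int, int]:
        if self.lesion_center is not None:
            return self.lesion_center
        return (self.height_px // 2, self.width_px // 2)


@dataclass
class GroundTruth:
    """Exact per-scene truth: height, class labels, masks, albedo cube."""

    height_map: np.ndarray  # (H, W)
    class_mask: np.ndarray  # (H, W) uint8: 0 healthy, 1 ID, 2 BCC, 255 outside field
    healthy_mask: np.ndarray  # (H, W) bool: pixels eligible as healthy samples
    albedo_true: np.ndarray  # (H, W, 33) in [0, 1]
    lesion_class: str = "healthy"


@dataclass
class Measurement:
    """Six radiance cubes (3 directions x {VIS, VNIR}) plus references."""

    radiance_vis: list  # 3 cubes, each (H, W, 17)
    radiance_vnir: list  # 3 cubes, each (H, W, 16)
    white_vis: np.ndarray
    white_vnir: np.ndarray
    dark_vis: np.ndarray
    dark_vnir: np.ndarray
    light_geometry: LightGeometry = field(default_factory=LightGeometry)
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.asarray(VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM)
    )


def _dist_from(spec: SceneSpec) -> np.ndarray:
    r0, c0 = spec.center
    rows = np.arange(spec.height_px)[:, None]
    cols = np.arange(spec.width_px)[None, :]
    return np.hypot(rows - r0, cols - c0)


def make_height_map(spec: SceneSpec) -> np.ndarray:
    """Ground-truth relative height field (pixel-equivalent units).

    flat: identically zero.  hemisphere: spherical cap of the lesion radius
    (height = radius at the center, 0 at and beyond the rim).  brick: a flat
    plateau with four circular studs (exactly three distinct height levels).
    skin_lesion: a smooth dome bump of ``lesion_height`` over flat skin.
    """
    H, W = spec.height_px, spec.width_px
    if spec.surface_kind == "flat":
        return np.zeros((H, W))
    if spec.surface_kind == "hemisphere":
        d = _dist_from(spec)
        r = spec.lesion_radius
        return np.sqrt(np.maximum(r**2 - d**2, 0.0))
    if spec.surface_kind == "brick":
        h = np.zeros((H, W))
        half_h, half_w = int(0.3 * H), int(0.3 * W)
        r0, c0 = H // 2, W // 2
        h[r0 - half_h : r0 + half_h, c0 - half_w : c0 + half_w] = 10.0
        stud_r = min(half_h, half_w) / 3.0
        rows = np.arange(H)[:, None]
        cols = np.arange(W)[None, :]
        for dr in (-half_h // 2, half_h // 2):
            for dc in (-half_w // 2, half_w // 2):
                d = np.hypot(rows - (r0 + dr), cols - (c0 + dc))
                h[d <= stud_r] = 12.0
        return h
    # skin_lesion: smooth elevated dome, amplitude lesion_height
    d = _dist_from(spec)
    sigma = spec.lesion_radius / 2.0
    return spec.lesion_height * np.exp(-0.5 * (d / sigma) ** 2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(lam, mu, sd):
    return np.exp(-0.5 * ((lam - mu) / sd) ** 2)


def _class_template(class_id: str, lam: np.ndarray) -> np.ndarray:
    """Smooth parametric mean albedo spectrum for one class.

    The curves are qualitative emulations of skin optics, not fits to any
    measured spectra: healthy skin rises from green to NIR with hemoglobin
    absorption dips near 542/575 nm; the nevus template is darker overall
    (melanin) and rises later; the carcinoma template is brighter with
    shallower dips.
    """
    if class_id == "healthy":
        return (
            0.32
            + 0.28 * _sigmoid((lam - 600.0) / 40.0)
            - 0.10 * _gauss(lam, 575.0, 12.0)
            - 0.06 * _gauss(lam, 542.0, 10.0)
        )
    if class_id == "id_nevus":
        return 0.14 + 0.38 * _sigmoid((lam - 690.0) / 55.0)
    if class_id == "bcc":
        return (
            0.46
            + 0.22 * _sigmoid((lam - 560.0) / 50.0)
            - 0.03 * _gauss(lam, 575.0, 12.0)
            + 0.05 * _gauss(lam, 660.0, 40.0)
        )
    raise ValueError(
        f"unknown class_id {class_id!r}; valid classes: {', '.join(LESION_CLASSES)}"
    )


#: Scale of the smooth within-class spectral perturbation (per draw).
PERTURB_SD = 0.01


def make_albedo_spectra(class_id, wavelengths, seed=0, perturb_sd: float = PERTURB_SD):
    """One draw of a class albedo spectrum on the given grid.

    The class template is perturbed by a smooth random curve (random
    amplitudes on three broad Gaussian bumps, scale ``perturb_sd``), then
    clipped to [0.05, 0.95].  Same class and seed always give the same
    spectrum.  Class templates are pairwise separated by far more than the
    perturbation scale, so class identity is never washed out.
    """
    lam = as_grid(wavelengths)
    if lam[0] < 450.0 or lam[-1] > 1000.0:
        raise ValueError("wavelengths must lie within [450, 1000] nm")
    if isinstance(class_id, (int, np.integer)):
        class_id = LESION_CLASSES[int(class_id)]
    template = _class_template(class_id, lam)
    rng = np.random.default_rng(seed)
    centers = rng.uniform(lam[0], lam[-1], size=3)
    amps = rng.normal(0.0, perturb_sd, size=3)
    perturb = sum(a * _gauss(lam, c, 90.0) for a, c in zip(amps, centers))
    return np.clip(template + perturb, 0.05, 0.95)


def default_illum_profile(wavelengths) -> np.ndarray:
    """Smooth strictly-positive relative illumination spectrum (LED-like)."""
    lam = as_grid(wavelengths)
    prof = (
        0.55
        + 0.35 * _gauss(lam, 560.0, 90.0)
        + 0.45 * _gauss(lam, 800.0, 80.0)
        + 0.10 * _gauss(lam, 680.0, 30.0)
    )
    return prof


def _normals_from_height(height: np.ndarray) -> np.ndarray:
    """Unit normals of z = height(row, col): N ~ (-dz/dx, -dz/dy, 1).

    Central differences with unit pixel spacing; one-sided at the borders
    (numpy gradient convention).  x is the column axis, y the row axis.
    """
    gy, gx = np.gradient(height)
    n = np.stack([-gx, -gy, np.ones_like(height)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def render_measurement(
    spec: SceneSpec,
    ground_truth: GroundTruth,
    light_geometry: LightGeometry | None = None,
    illum_profile=None,
    seed=None,
    dark_level: float = 50.0,
    signal_scale: float = 1000.0,
) -> Measurement:
    """Forward-render one measurement from ground truth.

    Per band b and light direction i:

        radiance_i[..., b] = scale * illum[b] * albedo[..., b]
                             * max(0, N . L_i) + dark + noise,

    with noise ~ N(0, noise_sd * scale * illum[b]) so that the
    white-corrected reflectance carries noise of sd ~ noise_sd.  The white
    reference is the same illumination rendering of the unit-albedo
    reference target, white[..., b] = scale * illum[b] + dark, which the
    reflectance correction (R - D) / (W - D) divides out exactly; the dark
    cube is the constant ``dark_level``.
    """
    geom = light_geometry or LightGeometry()
    L = light_direction_matrix(geom)
    lam = np.asarray(VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM, dtype=float)
    illum = default_illum_profile(lam) if illum_profile is None else np.asarray(
        illum_profile, dtype=float
    )
    if illum.shape != lam.shape:
        raise ValueError(f"illumination profile must have {lam.size} bands")
    if np.any(illum <= 0):
        raise ValueError("illumination profile must be strictly positive")

    albedo = ground_truth.albedo_true
    if albedo.shape[:2] != (spec.height_px, spec.width_px) or albedo.shape[2] != lam.size:
        raise ValueError(
            f"albedo_true shape {albedo.shape} inconsistent with spec "
            f"({spec.height_px}, {spec.width_px}, {lam.size})"
        )
    normals = _normals_from_height(ground_truth.height_map)
    shading = np.maximum(normals @ L.T, 0.0)  # (H, W, 3)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rad_vis, rad_vnir = [], []
    for i in range(3):
        signal = signal_scale * illum * albedo * shading[:, :, i : i + 1]
        if spec.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, spec.noise_sd * signal_scale * illum, size=signal.shape
            )
        cube = signal + dark_level
        rad_vis.append(cube[:, :, :_N_VIS])
        rad_vnir.append(cube[:, :, _N_VIS:])

    white = signal_scale * illum + dark_level
    H, W = spec.height_px, spec.width_px
    white_vis = np.broadcast_to(white[:_N_VIS], (H, W, _N_VIS)).copy()
    white_vnir = np.broadcast_to(white[_N_VIS:], (H, W, lam.size - _N_VIS)).copy()
    dark_vis = np.full((H, W, _N_VIS), dark_level)
    dark_vnir = np.full((H, W, lam.size - _N_VIS), dark_level)
    return Measurement(
        radiance_vis=rad_vis,
        radiance_vnir=rad_vnir,
        white_vis=white_vis,
        white_vnir=white_vnir,
        dark_vis=dark_vis,
        dark_vnir=dark_vnir,
        light_geometry=geom,
        wavelengths=lam,
    )


def make_scene(
    spec: SceneSpec,
    light_geometry: LightGeometry | None = None,
    lesion_template: str | None = None,
) -> tuple[Measurement, GroundTruth]:
    """Build ground truth for one lesion scene and render its measurement.

    The lesion occupies a smooth-edged disk of ``lesion_radius``; its albedo
    blends from the healthy spectrum to the lesion-class spectrum across the
    rim.  ``lesion_template`` overrides the spectral template used inside
    the lesion while keeping the nominal class label: "outlier" emulates a
    lesion with scene-unique features by borrowing the *other* lesion
    class's spectral shape plus distinctive narrow markers (552 and
    735 nm) — a model that never saw this scene has every reason to call
    it the wrong class, while a model trained on the scene's own left
    half can learn the markers.
    """
    if spec.lesion_class not in ("id_nevus", "bcc"):
        raise ValueError("lesion_class must be 'id_nevus' or 'bcc'")
    lam = np.asarray(VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM, dtype=float)
    rng = np.random.default_rng(spec.seed)
    s_healthy, s_lesion = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))

    healthy_spec = make_albedo_spectra("healthy", lam, seed=s_healthy)
    template = lesion_template or spec.lesion_class
    if template == "outlier":
        other = "id_nevus" if spec.lesion_class == "bcc" else "bcc"
        base = (
            _class_template(other, lam)
            + 0.15 * _gauss(lam, 552.0, 10.0)
            + 0.12 * _gauss(lam, 735.0, 14.0)
        )
    else:
        base = _class_template(template, lam)
    lesion_spec = np.clip(
        base
        + (make_albedo_spectra("healthy", lam, seed=s_lesion) - _class_template("healthy", lam)),
        0.05,
        0.95,
    )

    d = _dist_from(spec)
    blend = _sigmoid((spec.lesion_radius - d) / (0.06 * spec.lesion_radius))
    albedo = healthy_spec[None, None, :] + blend[:, :, None] * (
        lesion_spec - healthy_spec
    )[None, None, :]
    # mild smooth spatial texture so scenes are not piecewise-constant
    tex = rng.normal(0.0, 1.0, size=(spec.height_px // 8 + 2, spec.width_px // 8 + 2))
    tex = np.kron(tex, np.ones((8, 8)))[: spec.height_px, : spec.width_px]
    tex = gaussian_filter(tex, sigma=6.0)
    tex = tex / max(np.abs(tex).max(), 1e-12)
    albedo = np.clip(albedo * (1.0 + 0.02 * tex)[:, :, None], 0.02, 0.98)

    class_idx = LESION_CLASSES.index(spec.lesion_class)
    class_mask = np.zeros((spec.height_px, spec.width_px), dtype=np.uint8)
    class_mask[blend > 0.5] = class_idx
    healthy_mask = d > 1.5 * spec.lesion_radius

    gt = GroundTruth(
        height_map=make_height_map(spec),
        class_mask=class_mask,
        healthy_mask=healthy_mask,
        albedo_true=albedo,
        lesion_class=spec.lesion_class,
    )
    meas = render_measurement(spec, gt, light_geometry=light_geometry)
    return meas, gt


#: Class mix of the emulated study set: 10 carcinomas + 7 nevi out of 17.
DEFAULT_CLASS_MIX = {"bcc": 10 / 17, "id_nevus": 7 / 17}


def make_dataset(
    n_scenes: int,
    class_mix: dict | None = None,
    seed: int = 0,
    height_px: int = 256,
    width_px: int = 256,
    noise_sd: float = 0.005,
    outlier_scenes: tuple[int, ...] = (),
) -> list[tuple[Measurement, GroundTruth]]:
    """Generate a reproducible labeled dataset of lesion scenes.

    ``class_mix`` maps lesion class to its proportion (must sum to 1);
    counts are assigned by largest remainder, so the default 17-scene mix
    yields exactly 10 carcinoma and 7 nevus scenes.  ``outlier_scenes``
    lists scene indices whose lesion is rendered with the atypical
    "outlier" spectral template (label unchanged) — the synthetic analogue
    of a lesion with unique features.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    mix = DEFAULT_CLASS_MIX if class_mix is None else class_mix
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions sum to {total}, expected 1")
    for cls in mix:
        if cls not in ("id_nevus", "bcc"):
            raise ValueError(f"class_mix key {cls!r} not a lesion class")

    # largest-remainder apportionment of n_scenes among classes
    raw = {c: p * n_scenes for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = n_scenes - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1
    labels = [c for c in sorted(counts) for _ in range(counts[c])]

    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    order_rng.shuffle(labels)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_scenes)]

    dataset = []
    for i, (cls, cseed) in enumerate(zip(labels, child_seeds)):
        srng = np.random.default_rng(cseed)
        radius = float(srng.uniform(0.16, 0.21) * min(height_px, width_px))
        jitter = (radius + WINDOW_MARGIN + 2)
        r0 = int(srng.integers(int(jitter), height_px - int(jitter)))
        c0 = int(srng.integers(int(jitter), width_px - int(jitter)))
        spec = SceneSpec(
            height_px=height_px,
            width_px=width_px,
            surface_kind="skin_lesion",
            lesion_class=cls,
            lesion_center=(r0, c0),
            lesion_radius=radius,
            lesion_height=float(srng.uniform(4.0, 8.0)),
            noise_sd=noise_sd,
            seed=cseed,
        )
        template = "outlier" if i in tuple(outlier_scenes) else None
        dataset.append(make_scene(spec, lesion_template=template))
    return dataset
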