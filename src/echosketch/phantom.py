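"""Synthetic four-chamber cardiac phantom: paired (sketch, ultrasound) images.

The phantom emulates an apical four-chamber echocardiographic view inside a
sector-shaped field of view: four elliptical blood pools (two atria, two
ventricles) embedded in bright, speckled myocardium. Ultrasound texture is
simulated with the classic point-scatterer model — tissue response as a cloud
of random scattering centres whose amplitude depends on tissue class (muscle
scatters more strongly than blood), convolved with a Gaussian point-spread
function, envelope-detected and log-compressed.

The sketch counterpart is a black-and-white line drawing of the chamber
boundaries, the myocardial contour and the sector boundary — the annotation
style used for echo teaching material.

Everything is a pure function of its parameters including the seed, so
datasets regenerate byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "EllipseSpec",
    "PhantomParams",
    "LabelMap",
    "PairedSample",
    "CLASS_BACKGROUND",
    "CLASS_SECTOR",
    "CLASS_CHAMBER",
    "CLASS_MYOCARDIUM",
    "generate_label_map",
    "label_map_to_sketch",
    "render_ultrasound",
    "generate_paired_sample",
    "vary_params",
    "generate_paired_dataset",
    "generate_pretrain_segmentation_set",
    "read_manifest",
    "load_image",
    "load_mask",
    "save_image",
]

CLASS_BACKGROUND = 0
CLASS_SECTOR = 1
CLASS_CHAMBER = 2
CLASS_MYOCARDIUM = 3


@dataclass(frozen=True)
class EllipseSpec:
    """One chamber, in coordinates normalised to the image size (x right, y down)."""

    name: str
    center: tuple[float, float]  # (x, y)
    axes: tuple[float, float]  # semi-axes (a, b)
    rotation_deg: float = 0.0


def _default_chambers() -> tuple[EllipseSpec, ...]:
    # Apex at top: ventricles in the upper half, atria below, septum between
    # left/right columns. Sizes give a plausible four-chamber layout.
    return (
        EllipseSpec("left_ventricle", (0.40, 0.46), (0.075, 0.115), -10.0),
        EllipseSpec("right_ventricle", (0.61, 0.46), (0.07, 0.105), 10.0),
        EllipseSpec("left_atrium", (0.41, 0.72), (0.07, 0.08), 0.0),
        EllipseSpec("right_atrium", (0.62, 0.72), (0.065, 0.075), 0.0),
    )


@dataclass(frozen=True)
class PhantomParams:
    """Geometry + acoustics of the phantom. Distances in pixels unless noted."""

    image_size: int = 64
    sector_angle: float = 80.0  # full opening angle, degrees
    chambers: tuple[EllipseSpec, ...] = field(default_factory=_default_chambers)
    wall_thickness: int = 3
    sketch_thickness: int = 2  # stroke width scale-matched to 64 px rasters
    scatterer_density: float = 0.5  # scatterers per pixel^2
    amplitude_blood: float = 0.06
    amplitude_muscle: float = 1.0
    psf_sigma: float = 1.1
    log_compression_db: float = 40.0
    jitter: float = 0.015  # per-sample geometric jitter, normalised units
    seed: int = 0

    def validate(self) -> None:
        if self.image_size % 32 != 0:
            raise ValueError(
                f"image_size must be divisible by 32, got {self.image_size}"
            )
        if not (self.amplitude_muscle > self.amplitude_blood >= 0):
            raise ValueError(
                "require amplitude_muscle > amplitude_blood >= 0, got "
                f"{self.amplitude_muscle} vs {self.amplitude_blood}"
            )
        if self.psf_sigma <= 0:
            raise ValueError(f"psf_sigma must be positive, got {self.psf_sigma}")
        if len(self.chambers) != 4:
            raise ValueError(f"expected 4 chamber ellipses, got {len(self.chambers)}")
        if self.wall_thickness < 1:
            raise ValueError("wall_thickness must be >= 1 pixel")


@dataclass
class LabelMap:
    """Per-pixel tissue class: 0 background, 1 sector interior (blood-free
    far field), 2 chamber blood pool, 3 myocardium."""

    classes: np.ndarray  # (H, W) uint8

    @property
    def size(self) -> tuple[int, int]:
        return self.classes.shape

    def mask(self, cls: int) -> np.ndarray:
        return self.classes == cls

    @property
    def sector_region(self) -> np.ndarray:
        """Everything inside the sector (interior + chambers + myocardium)."""
        return self.classes != CLASS_BACKGROUND


@dataclass
class PairedSample:
    ultrasound: np.ndarray  # (H, W) float in [-1, 1]
    sketch: np.ndarray  # (H, W) float, values -1 / +1
    label_map: LabelMap
    seed: int


# ---------------------------------------------------------------------------
# geometry


def _sector_mask(size: int, angle_deg: float) -> np.ndarray:
    """Annular wedge, apex at top-centre, opening downwards."""
    apex = (size * 0.02, size * 0.5)  # (y, x)
    r_min, r_max = 0.06 * size, 0.95 * size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - apex[0], xx - apex[1]
    r = np.hypot(dy, dx)
    # angle from the downward vertical
    theta = np.degrees(np.arctan2(dx, dy))
    return (r >= r_min) & (r <= r_max) & (np.abs(theta) <= angle_deg / 2.0)


def _ellipse_mask(size: int, ell: EllipseSpec) -> np.ndarray:
    cy, cx = ell.center[1] * size, ell.center[0] * size
    a, b = ell.axes[0] * size, ell.axes[1] * size
    phi = np.radians(ell.rotation_deg)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _jittered_chambers(params: PhantomParams, rng: np.random.Generator):
    out = []
    for ell in params.chambers:
        dcx, dcy = rng.uniform(-params.jitter, params.jitter, size=2)
        scale = 1.0 + rng.uniform(-params.jitter, params.jitter)
        drot = rng.uniform(-5.0, 5.0) * (params.jitter / 0.02 if params.jitter else 0)
        out.append(
            replace(
                ell,
                center=(ell.center[0] + dcx, ell.center[1] + dcy),
                axes=(ell.axes[0] * scale, ell.axes[1] * scale),
                rotation_deg=ell.rotation_deg + drot,
            )
        )
    return out


def generate_label_map(params: PhantomParams) -> LabelMap:
    """Rasterise the phantom geometry into a tissue-class map.

    Deterministic for fixed params: all jitter is drawn from ``params.seed``.
    Raises ``ValueError`` naming the offending chamber if jittered geometry
    would leave the sector.
    """
    params.validate()
    size = params.image_size
    rng = np.random.default_rng(params.seed)
    sector = _sector_mask(size, params.sector_angle)
    chambers = _jittered_chambers(params, rng)

    chamber_mask = np.zeros((size, size), dtype=bool)
    struct = ndimage.generate_binary_structure(2, 2)  # chebyshev ball
    for ell in chambers:
        m = _ellipse_mask(size, ell)
        dil = ndimage.binary_dilation(m, struct, iterations=params.wall_thickness)
        if not np.all(sector[dil]):
            raise ValueError(
                f"chamber {ell.name!r} (centre {ell.center}) plus its wall does "
                "not fit inside the sector"
            )
        chamber_mask |= m

    myo = (
        ndimage.binary_dilation(chamber_mask, struct, iterations=params.wall_thickness)
        & ~chamber_mask
    )
    classes = np.full((size, size), CLASS_BACKGROUND, dtype=np.uint8)
    classes[sector] = CLASS_SECTOR
    classes[myo] = CLASS_MYOCARDIUM
    classes[chamber_mask] = CLASS_CHAMBER
    return LabelMap(classes)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` with a 4-neighbour outside it (1-px inner outline)."""
    eroded = ndimage.binary_erosion(
        mask, ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def _thicken(fg: np.ndarray, width: int) -> np.ndarray:
    """Grow 1-px lines to exactly ``width`` px by one-sided shift-OR."""
    out = fg.copy()
    h, w = fg.shape
    for dy in range(width):
        for dx in range(width):
            if dy == 0 and dx == 0:
                continue
            out[dy:, dx:] |= fg[: h - dy, : w - dx]
    return out


def label_map_to_sketch(label_map: LabelMap, thickness: int = 1) -> np.ndarray:
    """Render the black-and-white sketch: chamber outlines, the myocardial
    contour and the sector boundary, drawn with ``thickness``-px strokes.
    Returns float array of -1 (background) and +1 (line)."""
    fg = (
        _boundary(label_map.mask(CLASS_CHAMBER))
        | _boundary(label_map.mask(CLASS_CHAMBER) | label_map.mask(CLASS_MYOCARDIUM))
        | _boundary(label_map.sector_region)
    )
    if thickness > 1:
        fg = _thicken(fg, thickness)
    return np.where(fg, 1.0, -1.0)


# ---------------------------------------------------------------------------
# speckle rendering


def render_ultrasound(label_map: LabelMap, params: PhantomParams) -> np.ndarray:
    """Point-scatterer speckle simulation.

    Uniform random scatterer positions; each scatterer's amplitude is its
    tissue-class amplitude times a unit-Rayleigh draw, with a random phase.
    The complex scatter field is blurred with a Gaussian PSF, envelope
    detected, log-compressed to ``log_compression_db`` of dynamic range,
    masked to the sector and rescaled to [-1, 1].
    """
    params.validate()
    h, w = label_map.size
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5CA77E]))
    n_scat = int(round(params.scatterer_density * h * w))

    ys = rng.uniform(0, h, size=n_scat)
    xs = rng.uniform(0, w, size=n_scat)
    iy = np.clip(ys.astype(int), 0, h - 1)
    ix = np.clip(xs.astype(int), 0, w - 1)
    cls = label_map.classes[iy, ix]
    class_amp = np.zeros(4)
    class_amp[CLASS_CHAMBER] = params.amplitude_blood
    class_amp[CLASS_MYOCARDIUM] = params.amplitude_muscle
    class_amp[CLASS_SECTOR] = 0.25 * params.amplitude_muscle  # faint far field
    amp = class_amp[cls] * rng.rayleigh(scale=1.0, size=n_scat)
    phase = rng.uniform(0, 2 * np.pi, size=n_scat)

    field = np.zeros((h, w), dtype=complex)
    np.add.at(field, (iy, ix), amp * np.exp(1j * phase))
    blurred = ndimage.gaussian_filter(field.real, params.psf_sigma) + 1j * (
        ndimage.gaussian_filter(field.imag, params.psf_sigma)
    )
    env = np.abs(blurred)

    peak = env.max()
    if peak <= 0:
        db = np.full((h, w), -params.log_compression_db)
    else:
        db = 20.0 * np.log10(np.maximum(env, 1e-30) / peak)
        db = np.clip(db, -params.log_compression_db, 0.0)
    img = 2.0 * (db + params.log_compression_db) / params.log_compression_db - 1.0
    img[~label_map.sector_region] = -1.0
    return img


def generate_paired_sample(params: PhantomParams) -> PairedSample:
    lm = generate_label_map(params)
    return PairedSample(
        ultrasound=render_ultrasound(lm, params),
        sketch=label_map_to_sketch(lm, params.sketch_thickness),
        label_map=lm,
        seed=params.seed,
    )


def vary_params(base: PhantomParams, seed: int, variability: float = 1.0) -> PhantomParams:
    """Draw a per-sample parameter set emulating inter-patient / inter-frame
    variability: anatomy (geometry jitter), gain and acoustics all vary.

    Clinical echo frames differ in probe position, depth setting, gain and
    patient anatomy; a dataset of identical hearts would make the few-shot
    problem unrealistically easy. ``variability`` scales all ranges (0 =
    the base phantom exactly). Geometry that violates the sector or
    four-chamber invariants is rejected and redrawn deterministically.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base.seed, seed, 0xD1F]))
    v = variability
    for _ in range(32):
        candidate = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            jitter=min(0.015 + 0.02 * v, 0.05),
            sector_angle=float(base.sector_angle + rng.uniform(-5, 8) * v),
            scatterer_density=float(
                base.scatterer_density * (1 + rng.uniform(-0.4, 0.6) * v)
            ),
            amplitude_blood=float(
                np.clip(base.amplitude_blood * (1 + rng.uniform(-0.5, 1.0) * v), 0, 0.3)
            ),
            psf_sigma=float(base.psf_sigma * (1 + rng.uniform(-0.2, 0.35) * v)),
            log_compression_db=float(
                base.log_compression_db + rng.uniform(-6, 8) * v
            ),
        )
        try:
            lm = generate_label_map(candidate)
        except ValueError:
            continue
        _, n = ndimage.label(lm.mask(CLASS_CHAMBER))
        if n == 4:
            return candidate
    raise RuntimeError("could not draw valid phantom geometry in 32 attempts")


# ---------------------------------------------------------------------------
# disk I/O


def save_image(arr: np.ndarray, path: str | os.PathLike) -> None:
    """[-1, 1] float -> 8-bit grayscale PNG."""
    u8 = np.clip(np.round((np.asarray(arr) + 1.0) * 127.5), 0, 255).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(path, format="PNG")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """8-bit grayscale PNG -> [-1, 1] float."""
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def generate_paired_dataset(
    n: int, params: PhantomParams, out_dir: str | os.PathLike
) -> str:
    """Write ``n`` paired samples as PNGs plus a TSV manifest
    (path_ultrasound, path_sketch, seed); sample i uses seed ``params.seed + i``.
    Returns the manifest path."""
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        p = replace(params, seed=params.seed + i)
        sample = generate_paired_sample(p)
        u_path = os.path.join(out_dir, f"ultrasound_{i:04d}.png")
        s_path = os.path.join(out_dir, f"sketch_{i:04d}.png")
        save_image(sample.ultrasound, u_path)
        save_image(sample.sketch, s_path)
        rows.append((u_path, s_path, p.seed))
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("path_ultrasound\tpath_sketch\tseed\n")
        for u, s, seed in rows:
            fh.write(f"{u}\t{s}\t{seed}\n")
    return manifest


def read_manifest(path: str | os.PathLike) -> list[dict]:
    """Parse a TSV manifest into a list of row dicts (header-driven)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [
            dict(zip(header, line.rstrip("\n").split("\t")))
            for line in fh
            if line.strip()
        ]


def _random_shape_mask(rng: np.random.Generator, image_size: int) -> np.ndarray:
    """One random primitive: ellipse, rectangle, annulus or wedge."""
    kind = rng.choice(["ellipse", "rect", "annulus", "wedge"])
    if kind == "ellipse":
        ell = EllipseSpec(
            "s",
            center=tuple(rng.uniform(0.15, 0.85, size=2)),
            axes=tuple(rng.uniform(0.06, 0.2, size=2)),
            rotation_deg=rng.uniform(0, 180),
        )
        return _ellipse_mask(image_size, ell)
    if kind == "rect":
        y0, x0 = rng.integers(0, image_size // 2, size=2)
        hgt, wdt = rng.integers(image_size // 8, image_size // 2, size=2)
        m = np.zeros((image_size, image_size), dtype=bool)
        m[y0 : y0 + hgt, x0 : x0 + wdt] = True
        return m
    if kind == "annulus":
        ell = EllipseSpec(
            "s",
            center=tuple(rng.uniform(0.2, 0.8, size=2)),
            axes=tuple(rng.uniform(0.1, 0.25, size=2)),
            rotation_deg=rng.uniform(0, 180),
        )
        outer = _ellipse_mask(image_size, ell)
        inner = _ellipse_mask(
            image_size,
            EllipseSpec(
                "s", ell.center, (ell.axes[0] * 0.6, ell.axes[1] * 0.6), ell.rotation_deg
            ),
        )
        return outer & ~inner
    cy, cx = rng.uniform(0.1, 0.5), rng.uniform(0.3, 0.7)
    half = rng.uniform(20, 50)
    rmax = rng.uniform(0.4, 0.9)
    yy, xx = np.mgrid[0:image_size, 0:image_size] / image_size
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dx, dy))
    return (r < rmax) & (np.abs(theta) < half)


def _speckle_render(
    amp_map: np.ndarray, rng: np.random.Generator, db_range: float = 40.0
) -> np.ndarray:
    """Gaussian speckle: complex scatter field with per-pixel amplitude,
    PSF blur, envelope, log compression to [-1, 1]."""
    z = amp_map * (rng.normal(size=amp_map.shape) + 1j * rng.normal(size=amp_map.shape))
    z = ndimage.gaussian_filter(z.real, 1.0) + 1j * ndimage.gaussian_filter(z.imag, 1.0)
    env = np.abs(z)
    peak = max(env.max(), 1e-30)
    db = np.clip(20.0 * np.log10(np.maximum(env, 1e-30) / peak), -db_range, 0.0)
    return 2.0 * (db + db_range) / db_range - 1.0


def generate_pretrain_segmentation_set(
    n: int,
    seed: int,
    out_dir: str | os.PathLike,
    n_classes: int = 3,
    image_size: int = 64,
    boundary_class: bool = False,
) -> str:
    """Synthetic multi-class segmentation pairs for parent-network pretraining.

    Each sample is a set of random primitives (ellipses, rectangles, annuli,
    wedges) of ``n_classes`` foreground classes rendered with speckle texture
    (class-dependent scatter amplitude); the mask is a VOC-style class-index
    PNG (0 = background). With ``boundary_class`` an extra outline class
    (index ``n_classes + 1``) traces the shape boundaries, playing the role of
    VOC's void band around objects. Returns the manifest path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        mask = np.zeros((image_size, image_size), dtype=np.uint8)
        n_shapes = rng.integers(2, 6)
        for _ in range(n_shapes):
            mask[_random_shape_mask(rng, image_size)] = int(
                rng.integers(1, n_classes + 1)
            )
        amp = rng.uniform(0.15, 1.0, size=n_classes + 1)
        img = _speckle_render(amp[mask], rng)
        if boundary_class:
            fg = mask > 0
            inner = fg & ~ndimage.binary_erosion(
                fg, ndimage.generate_binary_structure(2, 1), border_value=0
            )
            outline = _thicken(inner, 2)  # stroke width matches the sketches
            mask = mask.copy()
            mask[outline] = n_classes + 1

        img_path = os.path.join(out_dir, f"image_{i:04d}.png")
        mask_path = os.path.join(out_dir, f"mask_{i:04d}.png")
        save_image(img, img_path)
        Image.fromarray(mask, mode="L").save(mask_path, format="PNG")
        rows.append((img_path, mask_path))
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("path_image\tpath_mask\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
    return manifest


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Class-index PNG -> (H, W) int array."""
    return np.asarray(Image.open(path), dtype=np.int64)
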