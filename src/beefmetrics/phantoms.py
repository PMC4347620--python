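"""Ground-truthed synthetic phantoms for every pipeline stage.

Real carcass / ultrasound databases of this kind are proprietary, so the test
and calibration harness runs on phantoms with known geometry:

* **Steak phantoms** - a bright steak on a near-black background: an elliptical
  rib eye (meat), satellite muscles separated by white fat seams, and a
  peripheral subcutaneous-fat band whose thickness profile t(s) along the
  upper arc is prescribed (constant or linear ramp).
* **Ultrasound phantoms** - speckle-textured B-mode frames with a thin bright
  horizontal subcutaneous-fat band in the upper third, two rib echoes
  (bright arc over an acoustic shadow), and an inter-rib texture whose bright
  speck density grows monotonically with a latent intramuscular-fat scalar.

Every generator is a pure function of its spec (which includes the seed):
the same spec yields a bit-identical image, and the returned
:class:`GroundTruth` rasters are exactly the geometry that was drawn.

The speckle model is deliberately simple - the sum of squares of two low-pass
filtered Gaussian fields (a Rayleigh-like intensity envelope) applied
multiplicatively - controllable, not probe-accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

__all__ = [
    "Ellipse",
    "SteakPhantomSpec",
    "USPhantomSpec",
    "GroundTruth",
    "generate_steak_phantom",
    "generate_us_phantom",
    "generate_imf_dataset",
    "random_steak_spec",
    "random_us_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in image coordinates (x right, y down), rotation in radians."""

    cx: float
    cy: float
    a: float
    b: float
    rotation: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dx = xx - self.cx
        dy = yy - self.cy
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        return (xr / self.a) ** 2 + (yr / self.b) ** 2 <= 1.0

    def boundary_point(self, t: np.ndarray) -> np.ndarray:
        """(N, 2) array of (x, y) boundary points at parameter angles t."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        ex = self.a * np.cos(t)
        ey = self.b * np.sin(t)
        return np.stack([self.cx + c * ex - s * ey, self.cy + s * ex + c * ey], axis=1)

    def outward_normal(self, t: np.ndarray) -> np.ndarray:
        """(N, 2) unit outward normals at parameter angles t."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        nx = self.b * np.cos(t)
        ny = self.a * np.sin(t)
        n = np.stack([c * nx - s * ny, s * nx + c * ny], axis=1)
        return n / np.linalg.norm(n, axis=1, keepdims=True)


@dataclass(frozen=True)
class SteakPhantomSpec:
    """Geometry, colors and noise of one steak phantom."""

    shape: tuple[int, int] = (420, 480)  # (H, W)
    ribeye: Ellipse = Ellipse(cx=240.0, cy=255.0, a=115.0, b=70.0, rotation=-0.12)
    satellites: tuple[Ellipse, ...] = (
        Ellipse(cx=100.0, cy=330.0, a=45.0, b=24.0, rotation=0.3),
        Ellipse(cx=385.0, cy=330.0, a=48.0, b=22.0, rotation=-0.25),
    )
    seam_width: int = 4
    band_theta: tuple[float, float] = (np.pi + 0.45, 2 * np.pi - 0.45)
    band_thickness: tuple[float, float] = (20.0, 20.0)  # linear ramp t(0) -> t(1)
    meat_color: tuple[int, int, int] = (158, 48, 52)
    fat_color: tuple[int, int, int] = (235, 228, 212)
    background_color: tuple[int, int, int] = (10, 10, 12)
    noise_sigma: float = 6.0
    seed: int = 0

    def thickness_at(self, s: np.ndarray) -> np.ndarray:
        t0, t1 = self.band_thickness
        return t0 + (t1 - t0) * np.asarray(s, dtype=np.float64)

    def validate(self) -> None:
        h, w = self.shape
        if min(self.band_thickness) < 0:
            raise ValueError("band thickness must be non-negative")
        for ch, bound in ((self.meat_color, 255), (self.fat_color, 255)):
            if min(ch) < 0 or max(ch) > bound:
                raise ValueError("colors must lie in [0, 255]")
        top = self.ribeye.cy - self.ribeye.a - max(self.band_thickness) - self.seam_width
        if top < 2:
            raise ValueError("rib eye + backfat band does not fit inside the image")
        if self.ribeye.cx - self.ribeye.a < 2 or self.ribeye.cx + self.ribeye.a > w - 2:
            raise ValueError("rib eye does not fit horizontally")


@dataclass
class GroundTruth:
    """Rasterized truth accompanying a phantom (fields used vary by phantom kind)."""

    masks: dict = field(default_factory=dict)
    area_px: int | None = None
    profile_arc: np.ndarray | None = None  # arc positions s in [0, 1]
    profile_thickness: np.ndarray | None = None  # t(s) in px
    profile_points: np.ndarray | None = None  # (N, 2) inner-band attachment points
    rib_positions: list | None = None
    fat_rows: tuple[int, int] | None = None
    imf_scalar: float | None = None


def generate_steak_phantom(spec: SteakPhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a steak phantom; returns (H, W, 3) uint8 image and its truth."""
    spec.validate()
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    ribeye = spec.ribeye.mask((h, w))
    meat = ribeye.copy()
    for sat in spec.satellites:
        meat |= sat.mask((h, w))
    # fat seams around each muscle plus a connective-fat web joining them:
    # a real steak is a single connected piece
    body = ndi.binary_dilation(meat, structure=morphology.disk(spec.seam_width))
    body |= morphology.convex_hull_image(meat)

    # backfat band: polygon between the rib eye's upper boundary arc and the
    # arc offset outward by the thickness profile
    t = np.linspace(spec.band_theta[0], spec.band_theta[1], 900)
    inner = spec.ribeye.boundary_point(t)
    normals = spec.ribeye.outward_normal(t)
    seg = np.linalg.norm(np.diff(inner, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = arc / arc[-1]
    thickness = spec.thickness_at(s)
    outer = inner + normals * thickness[:, None]
    poly = np.vstack([inner, outer[::-1]])
    rr, cc = skdraw.polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    band = np.zeros((h, w), dtype=bool)
    band[rr, cc] = True
    band &= ~meat

    steak = body | band
    nonmeat = steak & ~meat

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color
    img[nonmeat] = spec.fat_color
    img[meat] = spec.meat_color
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        masks={
            "steak": steak,
            "meat": meat,
            "nonmeat": nonmeat,
            "ribeye": ribeye,
            "backfat_band": band,
        },
        area_px=int(ribeye.sum()),
        profile_arc=s,
        profile_thickness=thickness,
        profile_points=inner,
    )
    return img, truth


@dataclass(frozen=True)
class USPhantomSpec:
    """Geometry, texture and noise of one B-mode ultrasound phantom."""

    shape: tuple[int, int] = (256, 256)
    fat_top: int = 38
    fat_height: int = 16
    fat_brightness: float = 225.0
    rib_xs: tuple[int, int] = (70, 186)
    rib_y: int = 178
    rib_radius: int = 11
    rib_brightness: float = 235.0
    background_level: float = 60.0
    speckle_corr: float = 1.2
    speckle_weight: float = 0.3
    imf_scalar: float = 4.0
    speck_density: float = 0.004  # specks per zone pixel per unit imf
    speck_brightness: float = 95.0
    echogenicity_gain: float = 0.035  # fractional muscle brightening per unit imf
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        if h < 200 or w < 200:
            raise ValueError("ultrasound frames must be at least 200 x 200")
        if not (0 <= self.fat_top and self.fat_top + self.fat_height < h // 3):
            raise ValueError("fat band must lie in the upper third")
        if self.rib_y <= self.fat_top + self.fat_height:
            raise ValueError("ribs must lie below the fat band")
        if self.imf_scalar < 0:
            raise ValueError("imf_scalar must be non-negative")


def _stamp_rib(base: np.ndarray, x: int, y: int, radius: int, brightness: float) -> None:
    """Draw one rib echo: a bright upper arc with an acoustic shadow beneath."""
    h, w = base.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    arc = (np.abs(r - radius) <= 1.8) & (yy <= y + 1)
    base[arc] = brightness
    shadow = (np.abs(xx - x) <= radius * 0.8) & (yy > y + 1)
    base[shadow] *= 0.35


def generate_us_phantom(spec: USPhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render an ultrasound phantom; returns (H, W) uint8 image and its truth."""
    spec.validate()
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    base = np.full((h, w), spec.background_level, dtype=np.float64)
    fat_bottom = spec.fat_top + spec.fat_height
    fat_mask = np.zeros((h, w), dtype=bool)
    fat_mask[spec.fat_top : fat_bottom, :] = True
    base[fat_mask] = spec.fat_brightness

    # marbling raises the diffuse echogenicity of the muscle below the band
    muscle_top = fat_bottom + 4
    muscle_bottom = spec.rib_y - spec.rib_radius - 4
    base[muscle_top:muscle_bottom, :] *= 1.0 + spec.echogenicity_gain * spec.imf_scalar

    for x in spec.rib_xs:
        _stamp_rib(base, x, spec.rib_y, spec.rib_radius, spec.rib_brightness)

    # intramuscular-fat specks in the inter-rib zone below the fat band
    zone_top = fat_bottom + 10
    zone_bottom = spec.rib_y - spec.rib_radius - 6
    zone_left = min(spec.rib_xs) + spec.rib_radius + 4
    zone_right = max(spec.rib_xs) - spec.rib_radius - 4
    zone_area = max(zone_bottom - zone_top, 1) * max(zone_right - zone_left, 1)
    n_specks = int(round(spec.speck_density * spec.imf_scalar * zone_area))
    if n_specks > 0 and zone_bottom > zone_top and zone_right > zone_left:
        ys = rng.integers(zone_top, zone_bottom, size=n_specks)
        xs = rng.integers(zone_left, zone_right, size=n_specks)
        specks = np.zeros((h, w))
        np.add.at(specks, (ys, xs), 1.0)
        specks = ndi.gaussian_filter(specks, 1.0)
        base += spec.speck_brightness * 6.0 * specks

    # Rayleigh-like multiplicative speckle envelope
    g1 = ndi.gaussian_filter(rng.standard_normal((h, w)), spec.speckle_corr)
    g2 = ndi.gaussian_filter(rng.standard_normal((h, w)), spec.speckle_corr)
    env = g1**2 + g2**2
    env /= env.mean()
    img = base * ((1.0 - spec.speckle_weight) + spec.speckle_weight * env)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        masks={"fat_band": fat_mask},
        fat_rows=(spec.fat_top, fat_bottom),
        rib_positions=[(x, spec.rib_y) for x in spec.rib_xs],
        imf_scalar=float(spec.imf_scalar),
    )
    return img, truth


def _sample_satellite(rng: np.random.Generator, x_range: tuple[float, float]) -> Ellipse:
    return Ellipse(
        cx=float(rng.uniform(*x_range)),
        cy=float(rng.uniform(320, 342)),
        a=float(rng.uniform(38, 50)),
        b=float(rng.uniform(19, 27)),
        rotation=float(rng.uniform(-0.4, 0.4)),
    )


def random_steak_spec(seed: int, shape: tuple[int, int] = (420, 480)) -> SteakPhantomSpec:
    """A randomized but always-valid steak phantom spec (geometry jitter).

    Satellite muscles are rejection-sampled (deterministically) until they
    keep a fat-seam gap of at least 10 px to the rib eye: a satellite that
    touches the rib eye would merge the meat into one component and make the
    rib eye ground truth itself ill-defined.
    """
    rng = np.random.default_rng(seed)
    a = float(rng.uniform(100, 128))
    b = float(rng.uniform(60, 78))
    thickness = float(rng.uniform(12, 38))
    ribeye = Ellipse(
        cx=float(rng.uniform(228, 252)),
        cy=float(rng.uniform(248, 268)),
        a=a,
        b=b,
        rotation=float(rng.uniform(-0.18, 0.18)),
    )
    clearance = ndi.binary_dilation(ribeye.mask(shape), structure=morphology.disk(10))
    satellites = []
    for x_range in ((88.0, 112.0), (372.0, 396.0)):
        for _ in range(50):
            sat = _sample_satellite(rng, x_range)
            if not (clearance & sat.mask(shape)).any():
                satellites.append(sat)
                break
        else:  # shrink until clear of the rib eye (always terminates)
            while (clearance & sat.mask(shape)).any() and sat.a > 10:
                sat = Ellipse(sat.cx, sat.cy + 2.0, sat.a * 0.85, sat.b * 0.85, sat.rotation)
            satellites.append(sat)
    return SteakPhantomSpec(
        shape=shape,
        ribeye=ribeye,
        satellites=tuple(satellites),
        band_thickness=(thickness, thickness),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def random_us_spec(seed: int, imf_scalar: float | None = None) -> USPhantomSpec:
    """A randomized but always-valid ultrasound phantom spec."""
    rng = np.random.default_rng(seed)
    if imf_scalar is None:
        imf_scalar = float(rng.uniform(0.5, 9.5))
    return USPhantomSpec(
        fat_top=int(rng.integers(34, 43)),
        fat_height=int(rng.integers(12, 19)),
        rib_xs=(int(rng.integers(58, 80)), int(rng.integers(176, 196))),
        rib_y=int(rng.integers(172, 186)),
        imf_scalar=imf_scalar,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class IMFDataset:
    """A grouped synthetic ultrasound IMF dataset (several frames per animal)."""

    images: list
    labels: np.ndarray
    truths: list
    animal_ids: np.ndarray
    imf_scalars: np.ndarray


def generate_imf_dataset(
    n_animals: int = 69,
    images_per_animal: int = 4,
    label_noise_sigma: float = 0.3,
    seed: int = 0,
    label_intercept: float = 2.0,
    label_slope: float = 0.8,
) -> IMFDataset:
    """Simulate the grouped acquisition design: several frames per animal.

    Each animal carries a latent intramuscular-fat scalar drawn uniformly from
    [0.5, 9.5]; each of its frames is an independent ultrasound phantom with
    that scalar.  Chemical-analysis style labels are an affine function of the
    scalar plus Gaussian noise, one label per frame.
    """
    if n_animals < 5:
        raise ValueError("need at least 5 animals")
    rng = np.random.default_rng(seed)
    images, truths, labels, animals, scalars = [], [], [], [], []
    for animal in range(n_animals):
        imf = float(rng.uniform(0.5, 9.5))
        for _ in range(images_per_animal):
            spec = random_us_spec(int(rng.integers(0, 2**31 - 1)), imf_scalar=imf)
            img, truth = generate_us_phantom(spec)
            images.append(img)
            truths.append(truth)
            noise = rng.normal(0.0, label_noise_sigma) if label_noise_sigma > 0 else 0.0
            labels.append(label_intercept + label_slope * imf + noise)
            animals.append(animal)
            scalars.append(imf)
    return IMFDataset(
        images=images,
        labels=np.array(labels),
        truths=truths,
        animal_ids=np.array(animals),
        imf_scalars=np.array(scalars),
    )
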