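"""Region-of-interest detection in B-mode ultrasound frames.

The intramuscular-fat texture is read from the muscle between the 12th and
13th rib, below the subcutaneous fat.  Three structures anchor the ROI:

* the subcutaneous fat band - after Otsu binarization and labeling, the
  bright component in the upper third of the frame with the highest
  horizontal/vertical extent ratio;
* the two ribs - peaks of the normalized cross-correlation between the
  anisotropically diffused frame and a synthetic rib template (a bright
  convex arc over an acoustic shadow);
* the ROI itself - an 80 x 80 px square centered horizontally between the
  ribs and vertically midway between the bottom of the fat band and the rib
  depth.

When the available zone cannot host the square, a :class:`DetectionError` is
raised so a caller can fall back to manual ROI placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import measure

from .errors import DetectionError
from .preprocess import DiffusionParams, anisotropic_diffusion, otsu_threshold

__all__ = [
    "ROIBox",
    "RibTemplate",
    "detect_subcutaneous_fat",
    "make_rib_template",
    "detect_ribs",
    "extract_roi",
    "ROI_SIDE",
]

ROI_SIDE = 80


@dataclass(frozen=True)
class ROIBox:
    """An axis-aligned square region of interest, side fixed at 80 px."""

    x: int
    y: int
    side: int = ROI_SIDE

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.side != ROI_SIDE:
            raise ValueError(f"ROI side must be exactly {ROI_SIDE}")
        if not (0 <= self.x and self.x + self.side <= w and 0 <= self.y and self.y + self.side <= h):
            raise ValueError("ROI box falls outside the image bounds")

    def extract(self, img: np.ndarray) -> np.ndarray:
        self.validate(img.shape[:2])
        return img[self.y : self.y + self.side, self.x : self.x + self.side]


@dataclass(frozen=True)
class RibTemplate:
    """Synthetic generic-rib template: bright convex arc over a dark shadow."""

    pixels: np.ndarray
    width: int
    height: int


def detect_subcutaneous_fat(img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Locate the subcutaneous fat band.

    Otsu-binarizes the raw frame, labels the bright components, keeps those
    whose centroid lies in the upper third, and returns the one with the
    highest width/height bounding-box ratio (thin, long, horizontal) together
    with its row extent ``(top, bottom)``.
    """
    img = np.asarray(img)
    h = img.shape[0]
    t = otsu_threshold(img)
    bright = img >= t
    labels = measure.label(bright, connectivity=2)
    best = None
    for region in measure.regionprops(labels):
        cy = region.centroid[0]
        if cy >= h / 3.0:
            continue
        r0, c0, r1, c1 = region.bbox
        ratio = (c1 - c0) / max(r1 - r0, 1)
        if best is None or ratio > best[0]:
            best = (ratio, region)
    if best is None:
        raise DetectionError("no bright component found in the upper third of the frame")
    region = best[1]
    mask = labels == region.label
    r0, _, r1, _ = region.bbox
    return mask, (int(r0), int(r1))


def make_rib_template(width: int = 26, height: int = 30) -> RibTemplate:
    """Deterministic rib template: blurred bright semicircular arc, shadow below.

    Column-symmetric by construction (averaged with its mirror image).
    """
    if width < 8 or height < 8:
        raise ValueError("template must be at least 8 x 8")
    yy, xx = np.mgrid[0:height, 0:width]
    cx = (width - 1) / 2.0
    radius = 0.4 * width
    cy = radius + 1.0
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    tpl = np.full((height, width), 80.0)
    arc = (np.abs(r - radius) <= 1.5) & (yy <= cy)
    tpl[arc] = 255.0
    shadow = (np.abs(xx - cx) <= radius * 0.8) & (yy > cy)
    tpl[shadow] = 25.0
    tpl = ndi.gaussian_filter(tpl, 1.0)
    tpl = 0.5 * (tpl + tpl[:, ::-1])
    return RibTemplate(pixels=tpl, width=width, height=height)


def detect_ribs(
    img: np.ndarray,
    template: RibTemplate | None = None,
    min_separation: float | None = None,
    nms_window: int = 31,
    min_correlation: float = 0.7,
    diffusion: DiffusionParams | None = None,
) -> list[tuple[int, int]]:
    """Locate the two rib echoes by template correlation.

    The frame is anisotropically diffused, normalized cross-correlation with
    the rib template is computed, local maxima are extracted by non-maximum
    suppression in an ``nms_window`` square, and the two strongest admissible
    maxima (correlation above ``min_correlation``, horizontal separation at
    least ``min_separation``, default W/4) are returned sorted by x.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if template is None:
        template = make_rib_template()
    if min_separation is None:
        min_separation = w / 4.0
    smoothed = anisotropic_diffusion(img, diffusion)
    ncc = skfeature.match_template(smoothed, template.pixels, pad_input=True)
    maxima = ndi.maximum_filter(ncc, size=nms_window, mode="nearest")
    peaks = np.argwhere((ncc == maxima) & (ncc >= min_correlation))
    if len(peaks) == 0:
        raise DetectionError("no admissible correlation maxima (rib echoes not found)")
    order = np.argsort(ncc[peaks[:, 0], peaks[:, 1]])[::-1]
    chosen: list[tuple[int, int]] = []
    for k in order:
        y, x = int(peaks[k, 0]), int(peaks[k, 1])
        if all(abs(x - cx) >= min_separation for cx, _ in chosen):
            chosen.append((x, y))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise DetectionError(
            f"only {len(chosen)} admissible correlation maximum(s); two ribs required"
        )
    return sorted(chosen)


def extract_roi(
    img: np.ndarray,
    template: RibTemplate | None = None,
    diffusion: DiffusionParams | None = None,
) -> ROIBox:
    """Place the 80 x 80 ROI between the fat band and the ribs.

    Horizontal center: midway between the two rib x-positions.  Vertical
    center: midway between the bottom of the fat band and the mean rib depth.
    Raises :class:`DetectionError` when the available zone is shorter than
    80 px (callers may fall back to a manual ROI).
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    _, (_, fat_bottom) = detect_subcutaneous_fat(img)
    ribs = detect_ribs(img, template=template, diffusion=diffusion)
    rib_depth = int(round(np.mean([y for _, y in ribs])))
    zone_height = rib_depth - fat_bottom
    if zone_height < ROI_SIDE:
        raise DetectionError(
            f"zone between fat band and ribs is {zone_height} px tall; "
            f"cannot host an {ROI_SIDE} x {ROI_SIDE} ROI"
        )
    cx = int(round(np.mean([x for x, _ in ribs])))
    cy = int(round((fat_bottom + rib_depth) / 2.0))
    x = min(max(cx - ROI_SIDE // 2, 0), w - ROI_SIDE)
    y = min(max(cy - ROI_SIDE // 2, 0), h - ROI_SIDE)
    box = ROIBox(x=x, y=y)
    box.validate((h, w))
    return box
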