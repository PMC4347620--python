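"""Color-image preprocessing: background elimination and meat / non-meat detection.

A carcass cross-section photograph shows a bright steak (muscle, fat, bone) on a
near-black background.  Background elimination thresholds the red channel with
Otsu's method, fills enclosed gaps and keeps the largest connected component.
Meat vs. non-meat (fat, bone) is decided by combining per-channel Otsu
binarizations of the u and L channels of CIE Luv (D65 white point) and the
green channel of RGB, restricted to the steak mask.

The module also provides the shared edge-preserving smoother (Perona–Malik
anisotropic diffusion) used before edge-map computation on both color and
ultrasound images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure

from .errors import DegenerateInputError, NoSteakFoundError

__all__ = [
    "DiffusionParams",
    "otsu_threshold",
    "remove_background",
    "detect_meat_nonmeat",
    "anisotropic_diffusion",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the explicit 4-neighbour Perona–Malik scheme.

    ``conduction_coefficient`` is on the 8-bit intensity scale: gradients well
    below it diffuse freely, gradients well above it are preserved as edges.
    ``step`` must stay at or below 0.25 for the explicit scheme to obey the
    discrete maximum principle (no new extrema).
    """

    iterations: int = 15
    conduction_coefficient: float = 30.0
    step: float = 0.15

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.conduction_coefficient <= 0:
            raise ValueError("conduction_coefficient must be positive")
        if not (0 < self.step <= 0.25):
            raise ValueError("step must lie in (0, 0.25] for stability")


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's optimal threshold on an 8-bit raster.

    Scans all 256 candidate cut points ``t`` and returns the one minimizing the
    within-class intensity variance of the two classes ``v < t`` and
    ``v >= t``; ties are broken by the smallest ``t``.

    Raises
    ------
    DegenerateInputError
        If the raster is constant (a single intensity), naming the intensity.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise DegenerateInputError("empty raster")
    flat = gray.reshape(-1).astype(np.int64)
    if flat.min() == flat.max():
        raise DegenerateInputError(
            f"constant raster of intensity {int(flat[0])}: no threshold exists"
        )
    hist = np.bincount(np.clip(flat, 0, 255), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)

    # cumulative statistics of the lower class {v < t} for t = 0..255
    csum = np.concatenate([[0.0], np.cumsum(hist)])[:256]
    cmean_num = np.concatenate([[0.0], np.cumsum(hist * levels)])[:256]
    csq_num = np.concatenate([[0.0], np.cumsum(hist * levels**2)])[:256]

    w0 = csum
    w1 = n - csum
    total_mean_num = float((hist * levels).sum())
    total_sq_num = float((hist * levels**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cmean_num / w0
        m1 = (total_mean_num - cmean_num) / w1
        v0 = csq_num / w0 - m0**2
        v1 = (total_sq_num - csq_num) / w1 - m1**2
    v0 = np.where(w0 > 0, v0, 0.0)
    v1 = np.where(w1 > 0, v1, 0.0)
    within = (w0 * v0 + w1 * v1) / n
    return int(np.argmin(within))


def remove_background(img: np.ndarray) -> np.ndarray:
    """Segment the steak from the dark background of a carcass photograph.

    Otsu-thresholds the red channel, fills all enclosed background gaps and
    keeps the largest connected foreground component.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
        RGB carcass image, bright foreground on dark background.

    Returns
    -------
    (H, W) bool array — the steak mask.

    Raises
    ------
    NoSteakFoundError
        If the image is constant or no foreground survives cleanup.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    red = img[..., 0]
    try:
        t = otsu_threshold(red)
    except DegenerateInputError as e:
        raise NoSteakFoundError(f"no steak found: {e}") from e
    fg = red >= t
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoSteakFoundError("no foreground component after cleanup")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    steak = labels == int(np.argmax(counts))
    return steak


# channel polarity convention: in G and L the meat is the darker Otsu class,
# in u (red-green chroma) it is the higher class.  A channel is only allowed
# to vote when its two Otsu classes are separated by more than a noise floor
# (raw channel units); otherwise the "split" is just noise.
_CHANNEL_POLARITY = {"u": "high", "L": "low", "G": "low"}
_CHANNEL_MIN_SEPARATION = {"u": 8.0, "L": 5.0, "G": 12.0}


def _masked_channel_vote(
    values: np.ndarray, mask: np.ndarray, polarity: str, min_separation: float
) -> np.ndarray | None:
    """Otsu-binarize one channel inside ``mask``; return the boolean meat vote.

    The channel is min-max rescaled to 0..255 within the mask before
    thresholding.  Returns None (caller warns) when the channel is constant
    or its Otsu class means are closer than ``min_separation`` raw units.
    """
    v = values[mask].astype(np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return None
    scaled = np.zeros_like(values, dtype=np.uint8)
    scaled[mask] = np.round((values[mask] - lo) / (hi - lo) * 255.0).astype(np.uint8)
    t = otsu_threshold(scaled[mask])
    low_class = v[scaled[mask] < t]
    high_class = v[scaled[mask] >= t]
    if low_class.size == 0 or high_class.size == 0:
        return None
    if high_class.mean() - low_class.mean() < min_separation:
        return None
    if polarity == "low":
        vote = scaled < t
    else:
        vote = scaled >= t
    return vote & mask


def detect_meat_nonmeat(
    img: np.ndarray,
    steak: np.ndarray,
    rule: str = "majority",
) -> tuple[np.ndarray, np.ndarray]:
    """Split the steak mask into meat and non-meat (fat / bone) regions.

    Per-channel Otsu binarizations of u, L (CIE Luv, D65) and G (RGB),
    restricted to the steak mask, are combined by ``rule``:

    - ``"majority"``: a pixel is meat when >= 2 of the available channels vote meat
    - ``"and"`` / ``"or"``: conjunction / disjunction of the votes

    Returns ``(meat, nonmeat)`` boolean masks partitioning the steak mask.
    Channels that are degenerate (constant, or Otsu classes separated by less
    than a per-channel noise floor) are excluded with a warning.  If every
    channel is strictly constant a :class:`DegenerateInputError` is raised;
    if all channels merely lack separation (e.g. a steak that is entirely
    fat), an empty meat mask is returned with a warning.
    """
    img = np.asarray(img)
    steak = np.asarray(steak, dtype=bool)
    if not steak.any():
        raise ValueError("steak mask is empty")
    luv = skcolor.rgb2luv(img.astype(np.float64) / 255.0)
    channels = {"u": luv[..., 1], "L": luv[..., 0], "G": img[..., 1].astype(np.float64)}

    votes = []
    any_varying = False
    for name, values in channels.items():
        if np.ptp(values[steak]) > 0:
            any_varying = True
        vote = _masked_channel_vote(
            values, steak, _CHANNEL_POLARITY[name], _CHANNEL_MIN_SEPARATION[name]
        )
        if vote is None:
            warnings.warn(
                f"channel {name} is degenerate within the steak mask; excluded from vote",
                stacklevel=2,
            )
            continue
        votes.append(vote)
    if not votes:
        if not any_varying:
            raise DegenerateInputError("all channels constant within the steak mask")
        meat = np.zeros_like(steak)
        warnings.warn(
            "no channel separates meat from non-meat; returning an empty meat mask",
            stacklevel=2,
        )
        return meat, steak.copy()

    stack = np.stack(votes)
    if rule == "majority":
        needed = len(votes) // 2 + 1
        meat = stack.sum(axis=0) >= needed
    elif rule == "and":
        meat = stack.all(axis=0)
    elif rule == "or":
        meat = stack.any(axis=0)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    meat = meat & steak
    nonmeat = steak & ~meat
    if not meat.any():
        warnings.warn("meat mask is empty (steak appears to be all fat/bone)", stacklevel=2)
    return meat, nonmeat


def anisotropic_diffusion(
    gray: np.ndarray, params: DiffusionParams | None = None
) -> np.ndarray:
    """Perona–Malik edge-preserving smoothing (exponential conduction).

    Explicit 4-neighbour scheme with replicated borders (zero-flux boundary).
    Smooths within near-uniform regions while preserving strong step edges;
    never produces values outside the input range.

    Returns a float64 raster of the same shape.
    """
    if params is None:
        params = DiffusionParams()
    u = np.asarray(gray, dtype=np.float64).copy()
    if u.ndim != 2:
        raise ValueError("expected a 2-D raster")
    k2 = params.conduction_coefficient**2
    for _ in range(params.iterations):
        dn = np.vstack([u[:1], u[:-1]]) - u
        ds = np.vstack([u[1:], u[-1:]]) - u
        de = np.hstack([u[:, 1:], u[:, -1:]]) - u
        dw = np.hstack([u[:, :1], u[:, :-1]]) - u
        u = u + params.step * (
            np.exp(-(dn**2) / k2) * dn
            + np.exp(-(ds**2) / k2) * ds
            + np.exp(-(de**2) / k2) * de
            + np.exp(-(dw**2) / k2) * dw
        )
    return u
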