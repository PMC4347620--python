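"""Backfat thickness profiling by normal evolution between two curves.

The subcutaneous fat (backfat) band lies between two closed curves: the
convex hull of the detected meat (inner, initial curve) and the outer steak
boundary (target curve).  Each control point of the resampled inner curve
marches outward along its local normal, a fixed step per iteration, until it
reaches the target; the recorded thickness at that point is the cumulative
Euclidean path length.  Points are inserted / merged during the march to keep
the sampling density roughly constant.

Reported measurements follow the industry convention: thickness at the
perpendicular projections of 1/2 and 3/4 of the rib eye's principal axis,
plus the full thickness profile between those two marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import draw as skdraw
from skimage import measure, morphology

from .errors import CurveEvolutionError, DetectionError
from .preprocess import detect_meat_nonmeat, remove_background

__all__ = [
    "Curve",
    "AxisSpec",
    "ThicknessProfile",
    "EvolutionResult",
    "build_initial_curve",
    "build_target_curve",
    "evolve_between_curves",
    "ribeye_axis",
    "measure_backfat",
]


@dataclass
class Curve:
    """A closed (or open) polyline in (x, y) pixel coordinates, sub-pixel allowed."""

    points: np.ndarray  # (N, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ValueError("a curve needs at least 3 points")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(d == 0):
            raise ValueError("consecutive duplicate points are forbidden")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Filled-polygon raster of the closed curve."""
        rr, cc = skdraw.polygon(self.points[:, 1], self.points[:, 0], shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out


@dataclass(frozen=True)
class AxisSpec:
    """Principal axis of a region: centroid, unit direction, half-extent (px)."""

    centroid: tuple[float, float]
    direction: tuple[float, float]
    half_length: float


@dataclass
class ThicknessProfile:
    """Backfat profile between the 1/2 and 3/4 marks.

    ``samples`` holds (arc_position in [0, 1], thickness px) rows, arc
    position strictly increasing; the two marks are the industry measurement
    points.
    """

    samples: np.ndarray  # (M, 2)
    thickness_half: float
    thickness_threequarter: float
    mark_points: dict | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != 2:
            raise ValueError("samples must be an (M, 2) array")
        if np.any(s[:, 1] < 0):
            raise ValueError("thickness must be non-negative")
        if np.any(np.diff(s[:, 0]) <= 0):
            raise ValueError("arc positions must be strictly increasing")
        self.samples = s


def build_initial_curve(meat: np.ndarray) -> Curve:
    """Convex hull of the meat mask as a closed polygon (hull vertex order)."""
    meat = np.asarray(meat, dtype=bool)
    ys, xs = np.nonzero(meat)
    if len(xs) < 3:
        raise CurveEvolutionError("meat mask has fewer than 3 pixels")
    pts = np.column_stack([xs, ys]).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except Exception as e:  # qhull: collinear / degenerate input
        raise CurveEvolutionError(f"meat mask is degenerate for a convex hull: {e}") from e
    return Curve(points=pts[hull.vertices], closed=True)


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise CurveEvolutionError("mask has no boundary contour")
    c = max(contours, key=len)
    return c[:, ::-1]  # (row, col) -> (x, y)


def build_target_curve(
    steak: np.ndarray, initial: Curve, contact_dilation: int = 2
) -> Curve:
    """Outer boundary of (steak region UNION initial-curve region).

    Wherever that boundary would touch the initial curve, the region is
    locally pushed outward by ``contact_dilation`` px (a dilation of the
    hull region, which is interior to the union everywhere else), so the two
    curves never intersect.
    """
    steak = np.asarray(steak, dtype=bool)
    hull_mask = initial.mask(steak.shape)
    union = steak | hull_mask
    if measure.label(union, connectivity=2).max() != 1:
        raise CurveEvolutionError("steak and initial-curve regions form a disconnected union")
    pushed = union | ndi.binary_dilation(
        hull_mask, structure=morphology.disk(contact_dilation)
    )
    boundary = _longest_contour(pushed)
    return Curve(points=boundary, closed=True)


def _resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polyline at (approximately) uniform arc spacing."""
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / spacing)), 4)
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, arc, pts[:, 0])
    y = np.interp(targets, arc, pts[:, 1])
    return np.column_stack([x, y])


def _normals_closed(points: np.ndarray) -> np.ndarray:
    """Unit normals of a closed polyline from central-difference tangents."""
    t = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
    return np.column_stack([t[:, 1], -t[:, 0]])


@dataclass
class EvolutionResult:
    """Per-point outcome of the normal evolution between two curves."""

    start: np.ndarray  # (M, 2) resampled initial-curve points
    end: np.ndarray  # (M, 2) positions where the target was reached
    path_length: np.ndarray  # (M,) cumulative Euclidean path per point


def evolve_between_curves(
    initial: Curve,
    target: Curve,
    step: float = 1.0,
    resample_every: float = 50.0,
    max_iterations: int = 500,
    shape: tuple[int, int] | None = None,
) -> EvolutionResult:
    """March the initial curve outward along its normals to the target curve.

    The initial curve is densified and resampled to control points roughly
    ``resample_every`` px apart.  Each iteration every active point advances
    ``step`` px along its current outward normal (recomputed from the evolving
    polyline, orientation kept consistent); a point freezes once its distance
    to the target boundary falls below ``step``, adding the residual to its
    path.  Midpoints are inserted where active neighbours spread beyond twice
    the nominal spacing and merged where they bunch below a third of it.

    Raises :class:`CurveEvolutionError` listing stuck points if any point
    fails to reach the target within ``max_iterations``.
    """
    if shape is None:
        all_pts = np.vstack([initial.points, target.points])
        shape = (
            int(np.ceil(all_pts[:, 1].max())) + 4,
            int(np.ceil(all_pts[:, 0].max())) + 4,
        )
    target_mask = target.mask(shape)
    inner_mask = initial.mask(shape)
    # distance to the outside of the target region, sampled bilinearly
    dist_in = ndi.distance_transform_edt(target_mask)

    def sample_dist(p: np.ndarray) -> np.ndarray:
        d = ndi.map_coordinates(dist_in, [p[:, 1], p[:, 0]], order=1, mode="nearest")
        # EDT measures to outside pixel *centers*; the continuous boundary
        # runs half a pixel closer
        return np.maximum(d - 0.5, 0.0)

    pos = _resample_closed(initial.points, resample_every)
    m = len(pos)
    start = pos.copy()
    length = np.zeros(m)
    active = np.ones(m, dtype=bool)
    prev_normals = _normals_closed(pos)
    # orient outward: flip normals pointing into the initial region
    probe = pos + 2.0 * prev_normals
    inside = ndi.map_coordinates(
        inner_mask.astype(np.float64), [probe[:, 1], probe[:, 0]], order=1, mode="nearest"
    )
    flip = inside > 0.5
    prev_normals[flip] *= -1.0

    spacing0 = resample_every

    for _ in range(max_iterations):
        if not active.any():
            break
        normals = _normals_closed(pos)
        # keep orientation consistent with the previous iteration
        dots = np.einsum("ij,ij->i", normals, prev_normals)
        normals[dots < 0] *= -1.0
        prev_normals = normals

        d = sample_dist(pos)
        reach = active & (d <= step)
        if reach.any():
            adv = np.clip(d[reach], 0.0, step)
            pos[reach] += normals[reach] * adv[:, None]
            length[reach] += adv
            active[reach] = False
        move = active
        if move.any():
            pos[move] += normals[move] * step
            length[move] += step

        # maintain sampling density among consecutive active pairs
        gaps = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
        nxt = np.roll(np.arange(m), -1)
        insert_at = [
            i for i in range(m) if active[i] and active[nxt[i]] and gaps[i] > 2.0 * spacing0
        ]
        if insert_at:
            new_pos, new_start, new_len, new_act, new_nrm = [], [], [], [], []
            for i in range(m):
                new_pos.append(pos[i]); new_start.append(start[i])
                new_len.append(length[i]); new_act.append(active[i])
                new_nrm.append(prev_normals[i])
                if i in insert_at:
                    j = nxt[i]
                    new_pos.append((pos[i] + pos[j]) / 2.0)
                    new_start.append((start[i] + start[j]) / 2.0)
                    new_len.append((length[i] + length[j]) / 2.0)
                    new_act.append(True)
                    nn = prev_normals[i] + prev_normals[j]
                    nn /= max(np.linalg.norm(nn), 1e-12)
                    new_nrm.append(nn)
            pos = np.array(new_pos); start = np.array(new_start)
            length = np.array(new_len); active = np.array(new_act)
            prev_normals = np.array(new_nrm)
            m = len(pos)
        elif m > 8:
            drop = [
                i for i in range(m)
                if active[i] and active[nxt[i]] and gaps[i] < spacing0 / 3.0
            ]
            if drop:
                keep = np.ones(m, dtype=bool)
                keep[drop[::2]] = False  # never remove adjacent pairs at once
                pos, start = pos[keep], start[keep]
                length, active = length[keep], active[keep]
                prev_normals = prev_normals[keep]
                m = len(pos)

    if active.any():
        stuck = np.flatnonzero(active)
        raise CurveEvolutionError(
            f"{stuck.size} point(s) failed to reach the target within "
            f"{max_iterations} iterations: indices {stuck.tolist()[:10]}"
        )
    return EvolutionResult(start=start, end=pos, path_length=length)


def ribeye_axis(ribeye: np.ndarray, isotropy_tolerance: float = 0.05) -> AxisSpec:
    """Principal axis of the rib eye mask from its image moments.

    Centroid from first moments; direction is the major eigenvector of the
    second central moment (covariance) matrix; half_length is the maximal
    centroid-relative extent of the mask along that direction.  Near-isotropic
    masks (principal moments within ``isotropy_tolerance`` of each other)
    trigger a degenerate-direction warning and the x-axis is used.
    """
    ribeye = np.asarray(ribeye, dtype=bool)
    ys, xs = np.nonzero(ribeye)
    if len(xs) == 0:
        raise ValueError("rib eye mask is empty")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0 or (evals[1] - evals[0]) / evals[1] < isotropy_tolerance:
        warnings.warn(
            "principal moments are nearly equal; axis direction is degenerate, using x-axis",
            stacklevel=2,
        )
        direction = np.array([1.0, 0.0])
    else:
        direction = evecs[:, 1]
        if direction[0] < 0:
            direction = -direction
    proj = dx * direction[0] + dy * direction[1]
    half_length = float(np.abs(proj).max())
    return AxisSpec(
        centroid=(float(cx), float(cy)),
        direction=(float(direction[0]), float(direction[1])),
        half_length=half_length,
    )


def _band_chord(
    band: np.ndarray, origin: np.ndarray, direction: np.ndarray, max_range: float
) -> tuple[float, float] | None:
    """First entry distance and chord length of a ray through the band mask."""
    ts = np.arange(0.0, max_range, 0.5)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    h, w = band.shape
    valid = (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
    vals = np.zeros(len(ts), dtype=bool)
    if valid.any():
        sampled = ndi.map_coordinates(
            band.astype(np.float64), [pts[valid, 1], pts[valid, 0]], order=0
        )
        vals[valid] = sampled > 0.5
    if not vals.any():
        return None
    # contiguous chord through the band, tolerating 1-px rasterization gaps
    idx = np.nonzero(vals)[0]
    breaks = np.nonzero(np.diff(idx) > 3)[0]
    last = idx[breaks[0]] if breaks.size else idx[-1]
    return ts[idx[0]], (last - idx[0] + 1) * 0.5


def measure_backfat(
    img: np.ndarray,
    ribeye: np.ndarray,
    step: float = 1.0,
    resample_every: float = 50.0,
    precomputed: dict | None = None,
) -> ThicknessProfile:
    """Measure the backfat thickness profile of a carcass image.

    Builds the meat convex hull (initial curve) and the outer steak boundary
    (target curve), runs the normal evolution between them, locates the
    perpendicular projections of 1/2 and 3/4 of the rib eye's principal axis
    on the backfat band, and reports the thickness at both marks plus the
    profile between them.
    """
    img = np.asarray(img)
    pre = precomputed or {}
    steak = pre.get("steak")
    if steak is None:
        steak = remove_background(img)
    meat = pre.get("meat")
    if meat is None:
        meat, _ = detect_meat_nonmeat(img, steak)

    initial = build_initial_curve(meat)
    target = build_target_curve(steak, initial)
    evo = evolve_between_curves(
        initial, target, step=step, resample_every=resample_every, shape=steak.shape
    )

    hull_mask = initial.mask(steak.shape)
    band = target.mask(steak.shape) & ~hull_mask

    axis = ribeye_axis(ribeye)
    c = np.array(axis.centroid)
    d = np.array(axis.direction)
    perp = np.array([-d[1], d[0]])
    end0 = c - d * axis.half_length
    axis_len = 2.0 * axis.half_length
    max_range = float(max(steak.shape)) * 1.5

    marks = {}
    mark_idx = {}
    for frac in (0.5, 0.75):
        base = end0 + frac * axis_len * d
        best = None
        for sgn in (1.0, -1.0):
            hit = _band_chord(band, base, sgn * perp, max_range)
            if hit is None:
                continue
            entry, chord = hit
            if best is None or chord > best[2]:
                best = (sgn, entry, chord)
        if best is None:
            raise DetectionError(
                f"perpendicular at axis fraction {frac} does not meet the backfat band"
            )
        sgn, entry, chord = best
        entry_pt = base + sgn * perp * entry
        idx = int(np.argmin(np.linalg.norm(evo.start - entry_pt, axis=1)))
        marks[frac] = float(evo.path_length[idx])
        mark_idx[frac] = idx

    i0, i1 = mark_idx[0.5], mark_idx[0.75]
    m = len(evo.start)
    # the two candidate arcs between the marks; keep the one running through the band
    fwd = list(range(i0, i1 + 1)) if i0 <= i1 else list(range(i0, m)) + list(range(0, i1 + 1))
    bwd = list(range(i1, i0 + 1)) if i1 <= i0 else list(range(i1, m)) + list(range(0, i0 + 1))

    def arc_band_score(idxs: list[int]) -> float:
        mids = evo.start[idxs] + 0.5 * (evo.end[idxs] - evo.start[idxs])
        h, w = band.shape
        mids[:, 0] = np.clip(mids[:, 0], 0, w - 1)
        mids[:, 1] = np.clip(mids[:, 1], 0, h - 1)
        vals = ndi.map_coordinates(band.astype(np.float64), [mids[:, 1], mids[:, 0]], order=0)
        return float(vals.mean())

    arc = fwd if arc_band_score(fwd) >= arc_band_score(bwd) else bwd[::-1]
    pts = evo.start[arc]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc_len = np.concatenate([[0.0], np.cumsum(seg)])
    if arc_len[-1] <= 0:
        positions = np.linspace(0.0, 1.0, len(arc))
    else:
        positions = arc_len / arc_len[-1]
    # enforce strictly increasing positions (duplicate control points collapse)
    keep = np.concatenate([[True], np.diff(positions) > 0])
    samples = np.column_stack([positions[keep], evo.path_length[arc][keep]])

    return ThicknessProfile(
        samples=samples,
        thickness_half=marks[0.5],
        thickness_threequarter=marks[0.75],
        mark_points={
            "half_index": i0,
            "threequarter_index": i1,
            "half_point": evo.start[i0].tolist(),
            "threequarter_point": evo.start[i1].tolist(),
            # midpoints of the evolution paths: interior points of the band
            "half_band_point": (0.5 * (evo.start[i0] + evo.end[i0])).tolist(),
            "threequarter_band_point": (0.5 * (evo.start[i1] + evo.end[i1])).tolist(),
            "axis": axis,
        },
    )
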