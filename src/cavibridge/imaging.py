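"""Shadowgraph metrology: segmentation, cavity tracking, bubble measurement.

Conventions.  Frames are backlit grayscale images: liquid/gel is dark,
background and air (cavity interior, entrained bubbles) are bright.  The
impact point (``origin``, pixel coordinates) is the metrology origin and the
jet axis points into the bridge; axial positions are measured in metres from
the origin along the axis.  The dark capillary bridge is segmented once per
stack (it does not move) as the convex hull of the largest dark component
after a morphological opening that removes the thin jet column.

Two cavity masks are distinguished per frame:

* the *open* cavity — bright pixels inside the bridge connected to the
  cavity mouth at the origin; its per-column half-width is the profile
  R(x,t), and the cavity is *closed* when this mask is empty;
* the *total* cavity — all bright pixels inside the bridge, which also
  counts sealed-off pockets; its axial extent tracks the front H_c(t) and
  component splitting detects pinch-off events.

Bubble metrology runs on the post-collapse frame: dark-region holes are
bubbles; holes closer than the optical detection floor (100 um default) are
merged into one bubble carrying the combined hole area, and a merged
cluster is counted only if its bounding extent reaches the floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image, disk

DEFAULT_DT = 1.0 / 50_000.0       # s, 50k frames per second
DEFAULT_PIXEL_SIZE = 10e-6        # m per pixel
DETECTION_FLOOR = 100e-6          # m, minimum resolvable bubble diameter
JET_OPEN_RADIUS = 8               # px, opening radius that removes the jet column

_CONN8 = np.ones((3, 3), dtype=bool)


class InsufficientDataError(RuntimeError):
    """Too few usable frames for the requested fit."""


@dataclass
class FrameStack:
    """Ordered grayscale frames with acquisition metadata.

    ``origin`` is (row, col) of the impact point; ``axis`` the jet direction
    in (drow, dcol) form and must be axis-aligned (one of the four unit
    pixel directions).
    """

    frames: np.ndarray               # (T, H, W) uint8
    dt: float = DEFAULT_DT
    pixel_size: float = DEFAULT_PIXEL_SIZE
    origin: tuple[int, int] = (0, 0)
    axis: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")
        if tuple(map(abs, self.axis)) not in ((0, 1), (1, 0)):
            raise ValueError("axis must be one of the four pixel directions")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.dt


@dataclass(frozen=True)
class Bubble:
    centroid_px: tuple[float, float]
    area_px: float
    area_m2: float
    d_eq_m: float


@dataclass
class BubbleSet:
    """Entrained-bubble census of a post-collapse frame."""

    bubbles: list[Bubble]
    A_total: float   # m^2, dark area including bubble interiors
    A_bubbles: float # m^2

    def __post_init__(self) -> None:
        if self.A_bubbles > self.A_total * (1 + 1e-9):
            raise ValueError("bubble area cannot exceed total area")

    @property
    def count(self) -> int:
        return len(self.bubbles)

    @property
    def ratio(self) -> float:
        return self.A_bubbles / self.A_total if self.A_total > 0 else 0.0


@dataclass
class StackMeasurement:
    """Per-frame kinematic measurements of one stack."""

    times: np.ndarray
    front_m: np.ndarray        # H_c(t), nan where no cavity
    area_m2: np.ndarray        # total cavity area A(t)
    open_area_m2: np.ndarray   # mouth-connected cavity area
    n_components: np.ndarray
    i_A_max: int
    A_max: float
    L_max: float
    t_col: Optional[float]
    open_ended: bool
    pinch_positions: list[float]
    dome_closed_during_expansion: bool


def binarize(frame: np.ndarray, strategy: str = "otsu", threshold: Optional[float] = None) -> np.ndarray:
    """Boolean mask of the dark (liquid/gel) region.

    ``strategy="otsu"`` picks a global Otsu threshold; ``"fixed"`` uses the
    supplied ``threshold``.  Pixels strictly below the threshold are dark.
    Deterministic for fixed inputs.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if strategy == "fixed":
        if threshold is None:
            raise ValueError("fixed strategy requires a threshold")
        return frame < threshold
    if strategy == "otsu":
        if frame.min() == frame.max():
            return np.zeros(frame.shape, dtype=bool)
        return frame <= threshold_otsu(frame)
    raise ValueError(f"unknown binarization strategy {strategy!r}")


def bridge_mask(dark: np.ndarray, open_radius: int = JET_OPEN_RADIUS) -> np.ndarray:
    """Bridge region: convex hull of the largest dark blob after opening.

    The opening removes thin dark structures (the jet column); the convex
    hull restores the cavity cut-out so the mask covers the whole bridge
    disk including the carved cavity.
    """
    opened = (
        ndimage.binary_opening(dark, structure=disk(open_radius))
        if open_radius > 0
        else dark
    )
    labels, n = ndimage.label(opened, structure=_CONN8)
    if n == 0:
        return np.zeros_like(dark)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    hull = convex_hull_image(keep)
    # the hull of a rasterised disk overfills its boundary by ~1 px; trim it
    return ndimage.binary_erosion(hull, structure=disk(2))


def analytic_bridge_mask(
    shape: tuple[int, int],
    origin: tuple[int, int],
    axis: tuple[int, int],
    diameter_m: float,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> np.ndarray:
    """Bridge disk from calibrated geometry: the known bridge diameter and
    pixel scale place a circle tangent to the impact point along the axis.

    Preferred over :func:`bridge_mask` whenever the bridge diameter is known
    (it always is in a configured run): the image-derived convex hull
    over-covers when the bridge is clipped by the frame.
    """
    r_px = diameter_m / 2.0 / pixel_size
    rows = np.arange(shape[0])[:, None].astype(float)
    cols = np.arange(shape[1])[None, :].astype(float)
    cr = origin[0] + axis[0] * r_px
    cc = origin[1] + axis[1] * r_px
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= r_px**2


def _canonical(stack_frames: np.ndarray, origin: tuple[int, int], axis: tuple[int, int]):
    """Rotate/flip frames so the jet axis points along +columns."""
    fr = stack_frames
    r0, c0 = origin
    if axis == (0, 1):
        return fr, (r0, c0)
    if axis == (0, -1):
        return fr[..., ::-1], (r0, fr.shape[-1] - 1 - c0)
    if axis == (1, 0):
        return np.swapaxes(fr, -1, -2), (c0, r0)
    if axis == (-1, 0):
        sw = np.swapaxes(fr, -1, -2)
        return sw[..., ::-1], (c0, sw.shape[-1] - 1 - r0)
    raise ValueError(f"axis {axis} is not a pixel direction")


def _cavity_masks(dark: np.ndarray, bridge: np.ndarray, origin_rc: tuple[int, int]):
    """(open_mask, total_mask, n_components) of the cavity, canonical orientation.

    Labeling runs on the cavity's bounding box for speed.
    """
    total = (~dark) & bridge
    if not total.any():
        return total, total, 0
    rr, cc = np.nonzero(total.any(axis=1)), np.nonzero(total.any(axis=0))
    r_lo, r_hi = rr[0][0], rr[0][-1] + 1
    c_lo, c_hi = cc[0][0], cc[0][-1] + 1
    sub = total[r_lo:r_hi, c_lo:c_hi]
    labels, n = ndimage.label(sub, structure=_CONN8)
    r0, c0 = origin_rc
    h, w = dark.shape
    # seed: a small window just inside the bridge at the mouth
    rows = slice(max(r0 - 3 - r_lo, 0), max(r0 + 4 - r_lo, 0))
    cols = slice(max(c0 - c_lo, 0), max(c0 + 4 - c_lo, 0))
    seed_labels = np.unique(labels[rows, cols])
    seed_labels = seed_labels[seed_labels > 0]
    open_mask = np.zeros_like(total)
    if seed_labels.size:
        open_mask[r_lo:r_hi, c_lo:c_hi] = np.isin(labels, seed_labels)
    return open_mask, total, n


def extract_cavity_profile(
    mask: np.ndarray,
    origin: tuple[int, int],
    axis: tuple[int, int] = (0, 1),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    bridge: Optional[np.ndarray] = None,
    min_area_px: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled cavity half-width R(x) from a dark mask.

    Axial bins are one pixel wide; the half-width is half the count of
    open-cavity pixels in the bin (averaging the two sides).  Returns
    ``(x_m, R_m)`` from the origin to the front; both empty when no cavity
    is found (a pre-impact frame is not an error).
    """
    dark, origin_rc = _canonical(np.asarray(mask), origin, axis)
    br = bridge_mask(dark) if bridge is None else _canonical(bridge, origin, axis)[0]
    open_mask, _, _ = _cavity_masks(dark, br, origin_rc)
    if open_mask.sum() < min_area_px:
        return np.array([]), np.array([])
    c0 = origin_rc[1]
    cols = open_mask[:, c0:]
    counts = cols.sum(axis=0)
    if not counts.any():
        return np.array([]), np.array([])
    front = int(np.max(np.nonzero(counts)[0]))
    x = np.arange(front + 1) * pixel_size
    R = counts[: front + 1] * pixel_size / 2.0
    return x, R


def analyze_stack(
    stack: FrameStack,
    strategy: str = "otsu",
    threshold: Optional[float] = None,
    bridge: Optional[np.ndarray] = None,
    bridge_diameter: Optional[float] = None,
    min_area_px: int = 8,
) -> StackMeasurement:
    """Segment every frame and measure front, areas, components and events.

    The analysis region is the bridge disk: from ``bridge_diameter`` when the
    geometry is calibrated (preferred), from an explicit ``bridge`` mask, or
    segmented from the first frame as a fallback.
    """
    frames, origin_rc = _canonical(stack.frames, stack.origin, stack.axis)
    n_t = frames.shape[0]
    if bridge is not None:
        br = _canonical(bridge, stack.origin, stack.axis)[0]
    elif bridge_diameter is not None:
        br = analytic_bridge_mask(
            frames.shape[1:], origin_rc, (0, 1), bridge_diameter, stack.pixel_size
        )
    else:
        dark0 = binarize(frames[0], strategy, threshold)
        br = bridge_mask(dark0)
    px = stack.pixel_size
    c0 = origin_rc[1]

    front = np.full(n_t, np.nan)
    area = np.zeros(n_t)
    open_area = np.zeros(n_t)
    n_comp = np.zeros(n_t, dtype=int)
    gaps_per_frame: list[list[float]] = []
    for i in range(n_t):
        dark = binarize(frames[i], strategy, threshold)
        open_mask, total, n = _cavity_masks(dark, br, origin_rc)
        total_px = int(total.sum())
        if total_px < min_area_px:
            gaps_per_frame.append([])
            continue
        area[i] = total_px * px**2
        open_area[i] = open_mask.sum() * px**2
        counts = total[:, c0:].sum(axis=0)
        occupied = np.nonzero(counts)[0]
        if occupied.size:
            front[i] = occupied.max() * px
        n_comp[i] = n
        # axial gaps between occupied columns mark pinch positions
        gaps = []
        if n >= 2 and occupied.size:
            holes = np.where(np.diff(occupied) > 1)[0]
            for j in holes:
                gaps.append(0.5 * (occupied[j] + occupied[j + 1]) * px)
        gaps_per_frame.append(gaps)

    if not area.any():
        return StackMeasurement(
            times=stack.times, front_m=front, area_m2=area, open_area_m2=open_area,
            n_components=n_comp, i_A_max=0, A_max=0.0, L_max=0.0, t_col=None,
            open_ended=True, pinch_positions=[], dome_closed_during_expansion=False,
        )

    # the cavity episode: from the first detected cavity to the first frame
    # where it has vanished again (later bright features, e.g. entrained
    # bubbles after the liquid settles, are not cavity kinematics)
    active = np.nonzero(area > 0)[0]
    i_first = int(active[0])
    after = np.nonzero(area[i_first:] == 0.0)[0]
    i_gone = i_first + int(after[0]) if after.size else n_t

    # last frame attaining the maximum (ties resolve to the latest frame)
    episode = area[:i_gone]
    i_max = int(np.flatnonzero(episode == episode.max())[-1])
    # closure: first frame at/after A_max whose mouth-connected cavity is gone
    closed_idx = None
    for i in range(i_max, min(i_gone + 1, n_t)):
        if open_area[i] == 0.0:
            closed_idx = i
            break
    t_col = None if closed_idx is None else (closed_idx - i_max) * stack.dt
    # pinch events: frames where the cavity splits, collected over the episode
    last = i_gone
    pinch_positions: list[float] = []
    for i in range(last):
        for g in gaps_per_frame[i]:
            if not any(abs(g - p) < 2 * px for p in pinch_positions):
                pinch_positions.append(g)
    # dome closure: sealed mouth while the total area is still growing
    dome = any(
        open_area[i] == 0.0 and area[i] > 0.0 for i in range(0, i_max)
    )
    pre_closure = front[:last]
    l_max = float(np.nanmax(pre_closure)) if np.isfinite(pre_closure).any() else 0.0
    return StackMeasurement(
        times=stack.times, front_m=front, area_m2=area, open_area_m2=open_area,
        n_components=n_comp, i_A_max=i_max, A_max=float(area[i_max]), L_max=l_max,
        t_col=t_col, open_ended=closed_idx is None, pinch_positions=pinch_positions,
        dome_closed_during_expansion=dome,
    )


def fit_front_velocity(
    stack: FrameStack,
    measurement: Optional[StackMeasurement] = None,
    strategy: str = "otsu",
    threshold: Optional[float] = None,
    bridge: Optional[np.ndarray] = None,
    bridge_diameter: Optional[float] = None,
) -> tuple[float, float]:
    """Cavity front speed U_c from a linear fit of H_c(t) during expansion.

    Uses the frames up to the area maximum that have a detected front;
    returns (slope, standard error) in m/s.  Raises
    :class:`InsufficientDataError` below 3 usable frames.
    """
    m = measurement or analyze_stack(
        stack, strategy, threshold, bridge=bridge, bridge_diameter=bridge_diameter
    )
    sel = np.isfinite(m.front_m[: m.i_A_max + 1])
    idx = np.nonzero(sel)[0]
    if idx.size >= 3:
        # drop the stalled tail: fit only while the front is still advancing
        fmax = np.max(m.front_m[idx])
        advancing = idx[m.front_m[idx] < fmax]
        if advancing.size >= 3:
            idx = advancing
    if idx.size < 3:
        raise InsufficientDataError(
            f"only {idx.size} expansion frames with a detected front"
        )
    t = m.times[idx]
    h = m.front_m[idx]
    if np.ptp(h) == 0:
        return 0.0, 0.0
    res = stats.linregress(t, h)
    return float(res.slope), float(res.stderr)


def cavity_area_series(
    stack: FrameStack,
    strategy: str = "otsu",
    threshold: Optional[float] = None,
    bridge: Optional[np.ndarray] = None,
    bridge_diameter: Optional[float] = None,
) -> tuple[np.ndarray, float, Optional[float], bool]:
    """Per-frame cavity area, its maximum, and the collapse time.

    Returns ``(A(t), A_max, t_col, open_ended)``; ``t_col`` is the delay
    from the area maximum to the first frame with a closed cavity and is
    ``None`` (with the flag set) when the cavity never closes in the stack.
    """
    m = analyze_stack(
        stack, strategy, threshold, bridge=bridge, bridge_diameter=bridge_diameter
    )
    return m.area_m2, m.A_max, m.t_col, m.open_ended


def measure_bubbles(
    final_mask: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    floor: float = DETECTION_FLOOR,
) -> BubbleSet:
    """Bubble census of a post-collapse dark mask.

    Holes in the dark region are bubbles.  Holes with gaps below the
    detection floor are merged (morphological closing with a disk of radius
    half the floor) into a single bubble with the combined hole area; a
    cluster is counted only if its bounding extent reaches the floor.
    ``A_total`` is the dark area including bubble interiors.
    """
    dark = np.asarray(final_mask, dtype=bool)
    filled = ndimage.binary_fill_holes(dark)
    holes = filled & ~dark
    A_total = float(filled.sum()) * pixel_size**2
    if not holes.any():
        return BubbleSet([], A_total, 0.0)
    floor_px = max(int(round(floor / pixel_size)), 1)
    clusters = ndimage.binary_closing(holes, structure=disk(max(floor_px // 2, 1)))
    clusters = (clusters & filled) | holes
    labels = label(clusters, connectivity=2)
    bubbles: list[Bubble] = []
    for prop in regionprops(labels):
        extent_px = max(prop.bbox[2] - prop.bbox[0], prop.bbox[3] - prop.bbox[1])
        if extent_px * pixel_size < floor:
            continue
        comp = labels == prop.label
        area_px = float((holes & comp).sum())
        if area_px == 0:
            continue
        area_m2 = area_px * pixel_size**2
        cr, cc = ndimage.center_of_mass(holes & comp)
        bubbles.append(
            Bubble(
                centroid_px=(float(cr), float(cc)),
                area_px=area_px,
                area_m2=area_m2,
                d_eq_m=2.0 * np.sqrt(area_m2 / np.pi),
            )
        )
    A_bubbles = float(sum(b.area_m2 for b in bubbles))
    return BubbleSet(bubbles, A_total, A_bubbles)
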