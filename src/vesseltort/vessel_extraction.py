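"""From an ROI and a rough hand-line to a parametrized vessel centerline.

The measurement chain for a single vessel segment:

1. crop a vessel ROI around a user-supplied hand line (20 px pad);
2. binarize the vessel (pluggable binarizer; the default flattens the
   background with a large median filter on the green channel, applies a
   global threshold and keeps the component joining the two tentative
   endpoints), then close with a 7-px-radius disk;
3. thin the mask to a 1-px 8-connected skeleton;
4. classify skeleton pixels by 8-neighbor count (1 -> endpoint, >= 3 ->
   branching), pick the two principal endpoints as the labeled candidates
   closest to the tentative ones, and prune needle branches by
   iteratively deleting non-principal endpoints;
5. order the surviving path from the principal endpoint closest to the
   image origin and smooth it with a 3-term moving average, yielding a
   ``VesselCurve`` with parameter t = 1..N.

Connectivity is 8-connected throughout.  All pixel coordinates are
0-based (row, col).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.ndimage import convolve, median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing, disk, skeletonize

from .curve_geometry import VesselCurve, smooth_curve
from .errors import (
    AmbiguousEndpointError,
    ParameterError,
    SegmentationError,
    TopologyError,
)

__all__ = [
    "VesselRoi",
    "SkeletonImage",
    "build_vessel_roi",
    "default_binarizer",
    "binarize_and_close",
    "skeletonize_mask",
    "classify_skeleton_points",
    "select_principal_endpoints",
    "prune_needle_branches",
    "extract_curve",
    "extract_vessel",
    "LABEL_REGULAR",
    "LABEL_ENDPOINT",
    "LABEL_BRANCHING",
]

LABEL_NONE = 0
LABEL_REGULAR = 1
LABEL_ENDPOINT = 2
LABEL_BRANCHING = 3

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)


@dataclass
class VesselRoi:
    """A crop around one vessel's hand line.

    ``offset`` is the (row, col) of the crop's origin in the parent
    image; ``tentative_endpoints`` are in crop coordinates.
    """

    image: np.ndarray
    offset: tuple[int, int]
    tentative_endpoints: np.ndarray  # (2, 2) float (row, col), crop coords

    def to_parent(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + np.array(self.offset, dtype=float)

    def to_crop(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) - np.array(self.offset, dtype=float)


@dataclass
class SkeletonImage:
    """A 1-px skeleton with per-pixel labels and (optionally) principal endpoints."""

    pixels: np.ndarray  # bool
    labels: np.ndarray  # int, LABEL_* codes
    principal_endpoints: np.ndarray | None = None  # (2, 2) int (row, col)


def build_vessel_roi(
    image: np.ndarray,
    hand_line: np.ndarray,
    tentative_endpoints: np.ndarray | None = None,
    pad: int = 20,
) -> VesselRoi:
    """Crop the bounding box of the hand line expanded by ``pad`` pixels.

    The pad (about three times the thickest vessel diameter) guarantees
    the whole vessel tube fits in the crop.  Tentative endpoints default
    to the first and last hand-line points.
    """
    hl = np.asarray(hand_line, dtype=float)
    if hl.ndim != 2 or hl.shape[1] != 2 or len(hl) == 0:
        raise ParameterError("hand line must be a non-empty (k, 2) array")
    if tentative_endpoints is None:
        tentative_endpoints = hl[[0, -1]]
    te = np.asarray(tentative_endpoints, dtype=float)
    h, w = image.shape[:2]
    r0 = max(0, int(math.floor(hl[:, 0].min())) - pad)
    c0 = max(0, int(math.floor(hl[:, 1].min())) - pad)
    r1 = min(h, int(math.ceil(hl[:, 0].max())) + pad + 1)
    c1 = min(w, int(math.ceil(hl[:, 1].max())) + pad + 1)
    te_crop = te - np.array([r0, c0], dtype=float)
    if (
        np.any(te_crop < -0.5)
        or np.any(te_crop[:, 0] > r1 - r0 - 0.5)
        or np.any(te_crop[:, 1] > c1 - c0 - 0.5)
    ):
        raise ParameterError("tentative endpoints fall outside the clipped crop")
    return VesselRoi(
        image=image[r0:r1, c0:c1].copy(),
        offset=(r0, c0),
        tentative_endpoints=te_crop,
    )


def default_binarizer(
    img: np.ndarray, background_window: int = 31
) -> np.ndarray:
    """Background-flattening binarizer for dark vessels on a variable background.

    Works on the green channel (best vessel contrast in fundus images):
    subtracts a large-window median estimate of the background, then
    thresholds the vessel response (background minus image) with Otsu's
    method.
    """
    green = img[..., 1] if img.ndim == 3 else img
    green = green.astype(float)
    bg = median_filter(green, size=background_window, mode="nearest")
    response = bg - green  # dark vessels -> positive response
    if response.max() <= response.min():
        return np.zeros(green.shape, dtype=bool)
    thr = threshold_otsu(response)
    return response > thr


def binarize_and_close(
    roi: VesselRoi,
    binarizer: Callable[[np.ndarray], np.ndarray] | None = None,
    closing_radius: int = 7,
    endpoint_reach: float = 10.0,
) -> np.ndarray:
    """Binarize the ROI, keep the endpoint-connected component, close gaps.

    The (pluggable) binarizer produces a foreground mask; a morphological
    closing with a discrete disk of radius ``closing_radius`` (the
    thickest vessel width) smooths small irregularities and bridges small
    gaps; then the connected component whose pixels reach both tentative
    endpoints' neighborhoods (disks of radius ``endpoint_reach``) is
    retained, discarding other vessels caught in the crop.
    """
    if roi.image.size == 0:
        raise ParameterError("empty ROI")
    mask = (binarizer or default_binarizer)(roi.image)
    if mask.shape != roi.image.shape[:2]:
        raise ParameterError("binarizer returned a mask of the wrong shape")
    if not mask.any():
        raise SegmentationError("binarization produced an empty mask")
    if closing_radius > 0:
        mask = _closing(mask, disk(closing_radius))

    lab = cc_label(mask, connectivity=2)
    h, w = mask.shape
    yy, xx = np.ogrid[0:h, 0:w]
    keep: set[int] | None = None
    for r, c in roi.tentative_endpoints:
        near = (yy - r) ** 2 + (xx - c) ** 2 <= endpoint_reach**2
        labels_here = set(np.unique(lab[near & mask])) - {0}
        keep = labels_here if keep is None else keep & labels_here
    if not keep:
        raise SegmentationError(
            "no foreground component reaches both tentative endpoints"
        )
    # largest qualifying component
    sizes = np.bincount(lab.ravel())
    target = max(keep, key=lambda l: sizes[l])
    return lab == target


def skeletonize_mask(mask: np.ndarray) -> SkeletonImage:
    """Thin a binary mask to a 1-px-wide, 8-connected, labeled skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("cannot skeletonize an empty mask")
    skel = skeletonize(mask)
    return classify_skeleton_points(
        SkeletonImage(pixels=skel, labels=np.zeros(skel.shape, dtype=int))
    )


def _neighbor_counts(pixels: np.ndarray) -> np.ndarray:
    return convolve(pixels.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def classify_skeleton_points(skel: SkeletonImage) -> SkeletonImage:
    """Label skeleton pixels by 8-neighbor count.

    One neighbor -> endpoint; three or more -> branching (bifurcation or
    crossing); otherwise regular.
    """
    counts = _neighbor_counts(skel.pixels)
    labels = np.zeros(skel.pixels.shape, dtype=int)
    labels[skel.pixels] = LABEL_REGULAR
    labels[skel.pixels & (counts <= 1)] = LABEL_ENDPOINT
    labels[skel.pixels & (counts >= 3)] = LABEL_BRANCHING
    return replace(skel, labels=labels)


def _border_mask(shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def select_principal_endpoints(
    skel: SkeletonImage,
    tentative_endpoints: np.ndarray,
    include_border: bool = True,
) -> SkeletonImage:
    """Pick the two principal endpoints nearest the tentative ones.

    Candidates are endpoint- and branching-labeled pixels plus (by
    default) skeleton pixels on the ROI border, where a vessel may leave
    the crop.  Distance ties are broken lexicographically by (row, col);
    mapping both tentatives to one candidate is an error.
    """
    cand = (skel.labels == LABEL_ENDPOINT) | (skel.labels == LABEL_BRANCHING)
    if include_border:
        cand |= skel.pixels & _border_mask(skel.pixels.shape)
    rc = np.argwhere(cand)
    if len(rc) < 2:
        raise TopologyError("fewer than 2 principal-endpoint candidates")
    # lexicographic ordering makes argmin ties deterministic
    order = np.lexsort((rc[:, 1], rc[:, 0]))
    rc = rc[order]
    principals = []
    for r, c in np.asarray(tentative_endpoints, dtype=float):
        d2 = (rc[:, 0] - r) ** 2 + (rc[:, 1] - c) ** 2
        principals.append(rc[int(np.argmin(d2))])
    principals_arr = np.array(principals, dtype=int)
    if np.array_equal(principals_arr[0], principals_arr[1]):
        raise AmbiguousEndpointError(
            "both tentative endpoints map to the same skeleton candidate"
        )
    return replace(skel, principal_endpoints=principals_arr)


def prune_needle_branches(skel: SkeletonImage) -> SkeletonImage:
    """Iteratively delete non-principal endpoints until only principals remain.

    Each pass removes every endpoint-labeled pixel other than the two
    principals, then relabels; needle branches erode one pixel per pass
    and vanish.  Pruning must leave the principals 8-connected.
    """
    if skel.principal_endpoints is None:
        raise ParameterError("principal endpoints must be set before pruning")
    pixels = skel.pixels.copy()
    p1, p2 = skel.principal_endpoints
    protect = np.zeros(pixels.shape, dtype=bool)
    protect[p1[0], p1[1]] = True
    protect[p2[0], p2[1]] = True
    if not (pixels[p1[0], p1[1]] and pixels[p2[0], p2[1]]):
        raise TopologyError("principal endpoints are not on the skeleton")

    for _ in range(int(pixels.sum()) + 1):
        counts = _neighbor_counts(pixels)
        secondary = pixels & (counts <= 1) & ~protect
        if not secondary.any():
            break
        pixels[secondary] = False

    lab = cc_label(pixels, connectivity=2)
    if lab[p1[0], p1[1]] != lab[p2[0], p2[1]] or lab[p1[0], p1[1]] == 0:
        raise TopologyError("pruning disconnected the principal endpoints")
    # keep only the principals' component
    pixels = lab == lab[p1[0], p1[1]]
    out = classify_skeleton_points(
        SkeletonImage(pixels=pixels, labels=np.zeros(pixels.shape, dtype=int))
    )
    return replace(out, principal_endpoints=skel.principal_endpoints.copy())


def _shortest_pixel_path(
    pixels: np.ndarray, start: tuple[int, int], goal: tuple[int, int]
) -> list[tuple[int, int]]:
    """Dijkstra over skeleton pixels; steps cost their Euclidean length."""
    sqrt2 = math.sqrt(2.0)
    h, w = pixels.shape
    dist: dict[tuple[int, int], float] = {start: 0.0}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap: list[tuple[float, tuple[int, int]]] = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == goal:
            break
        if d > dist.get(node, math.inf):
            continue
        r, c = node
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w) or not pixels[nr, nc]:
                    continue
                nd = d + (sqrt2 if dr and dc else 1.0)
                if nd < dist.get((nr, nc), math.inf):
                    dist[(nr, nc)] = nd
                    prev[(nr, nc)] = node
                    heapq.heappush(heap, (nd, (nr, nc)))
    if goal not in dist:
        raise TopologyError("no skeleton path between the principal endpoints")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return path[::-1]


def extract_curve(
    skel: SkeletonImage,
    offset: tuple[int, int] = (0, 0),
    smooth_window: int = 3,
) -> VesselCurve:
    """Order the pruned skeleton into a parametrized centerline.

    The pixel string starts at the principal endpoint closest to the
    parent image's (0, 0) pixel and follows the (shortest) skeleton path
    to the other principal; each pixel is visited once and the parameter
    runs t = 1..N.  Points are returned as (x, y) = (col, row) in parent
    coordinates and smoothed with a 3-term moving average.
    """
    if skel.principal_endpoints is None:
        raise ParameterError("principal endpoints must be set before extraction")
    p1, p2 = (tuple(int(v) for v in p) for p in skel.principal_endpoints)
    off = np.array(offset, dtype=float)
    d1 = np.hypot(*(np.array(p1) + off))
    d2 = np.hypot(*(np.array(p2) + off))
    start, goal = (p1, p2) if d1 <= d2 else (p2, p1)
    path = _shortest_pixel_path(skel.pixels, start, goal)
    rc = np.array(path, dtype=float) + off
    pts = np.column_stack([rc[:, 1], rc[:, 0]])  # (x, y) = (col, row)
    curve = VesselCurve(pts)
    if smooth_window > 1:
        curve = smooth_curve(curve, smooth_window)
    return curve


def extract_vessel(
    image: np.ndarray,
    hand_line: np.ndarray,
    tentative_endpoints: np.ndarray | None = None,
    pad: int = 20,
    binarizer: Callable[[np.ndarray], np.ndarray] | None = None,
    closing_radius: int = 7,
    smooth_window: int = 3,
) -> VesselCurve:
    """Convenience chain: ROI -> binarize -> skeletonize -> prune -> curve."""
    roi = build_vessel_roi(image, hand_line, tentative_endpoints, pad)
    mask = binarize_and_close(roi, binarizer, closing_radius)
    skel = skeletonize_mask(mask)
    skel = select_principal_endpoints(skel, roi.tentative_endpoints)
    skel = prune_needle_branches(skel)
    return extract_curve(skel, offset=roi.offset, smooth_window=smooth_window)
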