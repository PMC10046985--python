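"""Landmark localization and M/D frame alignment.

An eye's two retinographies -- one centered on the macula (M), one on the
optic disc (D) -- image overlapping retinal regions.  To compare a vessel
across the two framings, the frames are aligned on the optic-disc center
and reduced to their common field of view, with the disc itself masked
out.  Landmarks are found on a median-smoothed copy of each frame: the
disc is the brightest region of the fundus, the macula the darkest.
Alignment is a pure integer-pixel translation, so every retained pixel is
an unmodified copy of its source -- interpolation would alter intensity
values and, with them, the measured vessel geometry.

Image coordinates are 0-based ``(row, col)``, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import rank
from skimage.measure import label as cc_label
from skimage.morphology import footprint_rectangle

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "FundusImage",
    "LandmarkSet",
    "RoiPair",
    "median_smooth_rgb",
    "locate_extremum",
    "estimate_disc_radius",
    "field_of_view_mask",
    "align_and_mask_pair",
    "locate_landmarks",
]


@dataclass
class FundusImage:
    """An RGB retinography with its study labels.

    ``frame_center`` records whether the acquisition was centered on the
    macula ("M") or the optic disc ("D"); together with ``subject`` and
    ``eye`` this reproduces the study's labeling scheme (MR1, DL2, ...).
    """

    pixels: np.ndarray
    subject: str = "?"
    eye: Literal["L", "R", "?"] = "?"
    frame_center: Literal["M", "D", "?"] = "?"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError("expected an RGB raster (H, W, 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("image has non-positive dimensions")
        self.pixels = px

    @property
    def label(self) -> str:
        return f"{self.frame_center}{self.eye}{self.subject}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LandmarkSet:
    """Disc center, optional macula center (fractional (row, col)) and disc radius."""

    disc_center: tuple[float, float]
    macula_center: tuple[float, float] | None = None
    disc_radius: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "disc_center": list(self.disc_center),
                "macula_center": list(self.macula_center)
                if self.macula_center is not None
                else None,
                "disc_radius": self.disc_radius,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet":
        d = json.loads(text)
        mac = d.get("macula_center")
        return cls(
            disc_center=tuple(d["disc_center"]),
            macula_center=tuple(mac) if mac is not None else None,
            disc_radius=d.get("disc_radius"),
        )


@dataclass
class RoiPair:
    """Aligned common ROIs of a D/M frame pair.

    Both ROIs live on the D frame's pixel grid; the M frame was shifted
    by the integer ``offset`` (row, col).  ``overlap`` marks the common
    field of view minus the disc disk; pixels outside it are cleared,
    pixels inside are verbatim copies.  ``residual`` is the sub-pixel
    part of the disc-center displacement lost to rounding.
    """

    roi_d: np.ndarray
    roi_m: np.ndarray
    overlap: np.ndarray
    offset: tuple[int, int]
    residual: tuple[float, float]
    disc_center: tuple[float, float]
    disc_radius: float

    def to_frame_m(self, points: np.ndarray) -> np.ndarray:
        """Map (row, col) points on the aligned grid back to M-frame coords."""
        return np.asarray(points, dtype=float) + np.array(self.offset, dtype=float)


def median_smooth_rgb(img: FundusImage, window: int = 21) -> FundusImage:
    """Median-filter each RGB channel (replicate border padding).

    A 21 x 21 window (about three times the thickest vessel diameter)
    removes impulse noise and fine detail before landmark search.  The
    smoothed image is used only to locate landmarks, never to measure.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("median window must be an odd integer >= 3")
    px = img.pixels
    if px.min() >= 0 and px.max() <= 255 and np.array_equal(px, np.rint(px)):
        # exact uint8 rank-median path (much faster than the float filter)
        pad = window // 2
        fp = footprint_rectangle((window, window))
        chans = []
        for c in range(3):
            padded = np.pad(px[..., c].astype(np.uint8), pad, mode="edge")
            chans.append(rank.median(padded, fp)[pad:-pad, pad:-pad])
        out = np.stack(chans, axis=-1).astype(float)
    else:
        out = np.stack(
            [
                median_filter(px[..., c], size=window, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
    return FundusImage(out, img.subject, img.eye, img.frame_center)


def locate_extremum(
    img: FundusImage, mode: Literal["brightest", "darkest"] = "brightest"
) -> tuple[float, float]:
    """Locate the brightest (or darkest) point as a midpoint of channel extrema.

    Per channel, all pixels attaining the channel extremum are reduced to
    their coordinate midpoint; the result is the midpoint of the three
    channel midpoints.  Fractional coordinates are kept.
    """
    if mode not in ("brightest", "darkest"):
        raise ParameterError("mode must be 'brightest' or 'darkest'")
    mids = []
    for c in range(3):
        ch = img.pixels[..., c]
        val = ch.max() if mode == "brightest" else ch.min()
        rr, cc = np.nonzero(ch == val)
        mids.append((rr.mean(), cc.mean()))
    mids_arr = np.array(mids)
    return (float(mids_arr[:, 0].mean()), float(mids_arr[:, 1].mean()))


def estimate_disc_radius(
    disc: tuple[float, float], macula: tuple[float, float]
) -> float:
    """Optic-disc radius as one fifth of the disc-macula distance."""
    d = np.hypot(disc[0] - macula[0], disc[1] - macula[1])
    if d == 0:
        raise DegenerateInputError("disc and macula centers coincide")
    return float(d) / 5.0


def locate_landmarks(
    img: FundusImage, window: int = 21, with_macula: bool = True
) -> LandmarkSet:
    """Median-smooth then locate disc (and optionally macula) centers.

    Detection only: intensities are quantized to 8 bits before smoothing
    (landmark search does not need sub-level precision, and the integer
    median is exact and fast); measurements never touch this copy.
    """
    px = img.pixels
    if px.min() >= 0 and px.max() <= 255:
        img = FundusImage(np.rint(px), img.subject, img.eye, img.frame_center)
    sm = median_smooth_rgb(img, window)
    disc = locate_extremum(sm, "brightest")
    mac = locate_extremum(sm, "darkest") if with_macula else None
    radius = estimate_disc_radius(disc, mac) if mac is not None else None
    return LandmarkSet(disc_center=disc, macula_center=mac, disc_radius=radius)


def field_of_view_mask(img: FundusImage, threshold: float = 10.0) -> np.ndarray:
    """Field-of-view mask: the largest connected region of non-black pixels.

    Fundus photographs have black corners outside the circular field;
    those are excluded by thresholding near-zero luminance and keeping
    the largest connected component.  Frames with no black border (e.g.
    phantoms) yield a full-frame mask.
    """
    lum = img.pixels.mean(axis=-1)
    fg = lum > threshold
    if not fg.any():
        return fg
    lab = cc_label(fg, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


def align_and_mask_pair(
    frame_d: FundusImage,
    frame_m: FundusImage,
    landmarks_d: LandmarkSet,
    landmarks_m: LandmarkSet,
    fov_threshold: float = 10.0,
) -> RoiPair:
    """Align an M frame onto a D frame by their disc centers and mask ROIs.

    The M frame is translated by the integer-rounded disc-center
    displacement (no interpolation, so pixel values are preserved); the
    overlap is the intersection of the two fields of view, and the
    estimated optic-disc disk is cleared in both ROIs.  The disc radius
    is taken from the D-frame landmarks when present there.
    """
    if landmarks_d.disc_center is None or landmarks_m.disc_center is None:
        raise ParameterError("both landmark sets must carry disc centers")
    radius = landmarks_d.disc_radius
    if radius is None:
        radius = landmarks_m.disc_radius
    if radius is None:
        raise ParameterError("no disc radius available in either landmark set")

    dd = np.array(landmarks_d.disc_center, dtype=float)
    dm = np.array(landmarks_m.disc_center, dtype=float)
    disp = dm - dd  # position of the D disc inside the M frame, relative shift
    offset = np.rint(disp).astype(int)
    residual = disp - offset

    h, w = frame_d.shape
    hm, wm = frame_m.shape
    roi_d = frame_d.pixels.copy()
    roi_m = np.zeros((h, w, 3), dtype=frame_m.pixels.dtype)
    valid_m = np.zeros((h, w), dtype=bool)

    # M-frame pixel (r + offset) lands on aligned-grid pixel r
    r0 = max(0, -offset[0])
    c0 = max(0, -offset[1])
    r1 = min(h, hm - offset[0])
    c1 = min(w, wm - offset[1])
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError("frames do not overlap after alignment")
    roi_m[r0:r1, c0:c1] = frame_m.pixels[
        r0 + offset[0] : r1 + offset[0], c0 + offset[1] : c1 + offset[1]
    ]
    valid_m[r0:r1, c0:c1] = True

    fov_d = field_of_view_mask(frame_d, fov_threshold)
    fov_m_full = field_of_view_mask(frame_m, fov_threshold)
    fov_m = np.zeros((h, w), dtype=bool)
    fov_m[r0:r1, c0:c1] = fov_m_full[
        r0 + offset[0] : r1 + offset[0], c0 + offset[1] : c1 + offset[1]
    ]

    overlap = fov_d & fov_m & valid_m
    if not overlap.any():
        raise DegenerateInputError("empty overlap between the two fields of view")

    yy, xx = np.ogrid[0:h, 0:w]
    disc_disk = (yy - dd[0]) ** 2 + (xx - dd[1]) ** 2 <= radius**2
    overlap &= ~disc_disk

    roi_d[~overlap] = 0
    roi_m[~overlap] = 0
    return RoiPair(
        roi_d=roi_d,
        roi_m=roi_m,
        overlap=overlap,
        offset=(int(offset[0]), int(offset[1])),
        residual=(float(residual[0]), float(residual[1])),
        disc_center=(float(dd[0]), float(dd[1])),
        disc_radius=float(radius),
    )
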