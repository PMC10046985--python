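"""Synthetic vessels and fundus phantoms with known ground truth.

Clinical retinographies are not redistributable, so every stage of the
pipeline is exercised against generated data whose geometry is known in
closed form (or by high-accuracy quadrature, computed independently of
the estimators under test):

* analytic centerlines (lines, circular arcs, sinusoids, random smooth
  composites) with exact chord/arc length and total (squared) curvature;
* rasterized vessel tubes: dark tubes of known width on a lighter
  background, with seeded additive noise;
* paired fundus phantoms: one synthetic eye-fundus scene (bright optic
  disc, dark macula, dark vessel tree) cropped twice, once centered on
  the macula and once on the disc, mimicking the M/D frame-center change;
* paired per-vessel index tables with a prescribed bias and a
  magnitude-dependent ("funnel") difference variance, the structure the
  concordance suite assumes.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation as _dilate, disk

from .curve_geometry import GeometricParams, VesselCurve
from .errors import ParameterError

__all__ = [
    "AnalyticCurve",
    "RasterizedVessel",
    "FundusPhantom",
    "PairedDifferencesSpec",
    "gen_analytic_curve",
    "pixelate_curve",
    "rasterize_vessel",
    "gen_fundus_phantom_pair",
    "gen_paired_differences",
]

#: Default arc-length spacing (px) of analytic curve samples.  Fine
#: sampling keeps the Taylor-stencil span short relative to the curve's
#: radius of curvature, so analytic truth is recovered to ~0.1%.
ANALYTIC_STEP = 0.1


@dataclass
class AnalyticCurve:
    """Sampled analytic centerline plus its ground-truth geometry."""

    kind: str
    params: dict[str, Any]
    points: np.ndarray  # (N, 2), columns (x, y)
    truth: GeometricParams

    def as_curve(self) -> VesselCurve:
        return VesselCurve(self.points.copy())

    @property
    def endpoints(self) -> np.ndarray:
        return self.points[[0, -1]]


def _n_samples_for(length: float, n_samples: int | None) -> int:
    if n_samples is not None:
        if n_samples < 21:
            raise ParameterError("n_samples must be at least 21")
        return int(n_samples)
    return max(21, int(math.ceil(length / ANALYTIC_STEP)) + 1)


def _line_curve(params: dict[str, Any], n_samples: int | None) -> AnalyticCurve:
    p0 = np.asarray(params.get("p0", (0.0, 0.0)), dtype=float)
    p1 = np.asarray(params["p1"], dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ParameterError("line endpoints coincide")
    n = _n_samples_for(length, n_samples)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0[None, :] * (1 - t) + p1[None, :] * t
    truth = GeometricParams(D=length, L=length, TK=0.0, TSK=0.0)
    return AnalyticCurve("line", dict(params), pts, truth)


def _arc_curve(params: dict[str, Any], n_samples: int | None) -> AnalyticCurve:
    R = float(params["radius"])
    theta = float(params["angle"])
    if R <= 0 or theta <= 0:
        raise ParameterError("circular arc needs positive radius and angle")
    cx, cy = params.get("center", (0.0, 0.0))
    phase = float(params.get("phase", 0.0))
    n = _n_samples_for(R * theta, n_samples)
    a = phase + np.linspace(0.0, theta, n)
    pts = np.column_stack([cx + R * np.cos(a), cy + R * np.sin(a)])
    truth = GeometricParams(
        D=2.0 * R * math.sin(theta / 2.0), L=R * theta, TK=theta, TSK=theta / R
    )
    return AnalyticCurve("circular_arc", dict(params), pts, truth)


def _sine_sum_truth(
    amps: np.ndarray, omegas: np.ndarray, phases: np.ndarray, length: float
) -> GeometricParams:
    """Truth for y(x) = sum_i a_i sin(w_i x + phi_i), x in [0, length].

    Uses adaptive quadrature (independent of the WLS estimator) for L, TK
    and TSK:  ds = sqrt(1 + y'^2) dx,  |kappa| ds = |y''|/(1+y'^2) dx,
    kappa^2 ds = y''^2 / (1+y'^2)^(5/2) dx.
    """

    def d1(x):
        return np.sum(amps * omegas * np.cos(omegas * x + phases))

    def d2(x):
        return -np.sum(amps * omegas**2 * np.sin(omegas * x + phases))

    def y(x):
        return np.sum(amps * np.sin(omegas * x + phases))

    kw = dict(epsabs=1e-12, epsrel=1e-10, limit=400)
    L = integrate.quad(lambda x: math.hypot(1.0, d1(x)), 0, length, **kw)[0]
    TK = integrate.quad(lambda x: abs(d2(x)) / (1.0 + d1(x) ** 2), 0, length, **kw)[0]
    TSK = integrate.quad(
        lambda x: d2(x) ** 2 / (1.0 + d1(x) ** 2) ** 2.5, 0, length, **kw
    )[0]
    D = math.hypot(length, y(length) - y(0.0))
    return GeometricParams(D=D, L=float(L), TK=float(TK), TSK=float(TSK))


def _sample_sine_sum(
    amps: np.ndarray,
    omegas: np.ndarray,
    phases: np.ndarray,
    length: float,
    n: int,
) -> np.ndarray:
    """Sample y(x) = sum a_i sin(w_i x + phi_i) at n equal arc-length steps."""
    xf = np.linspace(0.0, length, max(20 * n, 4000))
    yf = np.sum(
        amps[:, None] * np.sin(omegas[:, None] * xf[None, :] + phases[:, None]), axis=0
    )
    s = np.concatenate(
        ([0.0], np.cumsum(np.hypot(np.diff(xf), np.diff(yf))))
    )
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, xf), np.interp(si, s, yf)])


def _sinusoid_curve(params: dict[str, Any], n_samples: int | None) -> AnalyticCurve:
    amp = float(params["amplitude"])
    wav = float(params["wavelength"])
    length = float(params["length"])
    phase = float(params.get("phase", 0.0))
    if length <= 0 or wav <= 0 or amp < 0:
        raise ParameterError("sinusoid needs positive length/wavelength, amplitude >= 0")
    amps = np.array([amp])
    omegas = np.array([2.0 * math.pi / wav])
    phases = np.array([phase])
    truth = _sine_sum_truth(amps, omegas, phases, length)
    n = _n_samples_for(truth.L, n_samples)
    pts = _sample_sine_sum(amps, omegas, phases, length, n)
    return AnalyticCurve("sinusoid", dict(params), pts, truth)


def _composite_curve(
    params: dict[str, Any], n_samples: int | None, seed: int | None
) -> AnalyticCurve:
    """Random smooth sum-of-sines curve; truth by adaptive quadrature."""
    rng = np.random.default_rng(seed)
    length = float(params.get("length", 200.0))
    k = int(params.get("n_components", 3))
    amp_range = params.get("amplitude_range", (2.0, 12.0))
    wav_range = params.get("wavelength_range", (60.0, 220.0))
    if length <= 0 or k < 1:
        raise ParameterError("composite needs positive length and >= 1 component")
    amps = rng.uniform(*amp_range, size=k)
    wavs = rng.uniform(*wav_range, size=k)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=k)
    omegas = 2.0 * math.pi / wavs
    truth = _sine_sum_truth(amps, omegas, phases, length)
    n = _n_samples_for(truth.L, n_samples)
    pts = _sample_sine_sum(amps, omegas, phases, length, n)
    p = dict(params)
    p.update(amplitudes=amps.tolist(), wavelengths=wavs.tolist(), phases=phases.tolist())
    return AnalyticCurve("composite", p, pts, truth)


def gen_analytic_curve(
    kind: str,
    params: dict[str, Any],
    n_samples: int | None = None,
    seed: int | None = None,
) -> AnalyticCurve:
    """Generate an analytic centerline with ground-truth (D, L, TK, TSK).

    ``kind`` is one of ``line``, ``circular_arc``, ``sinusoid`` or
    ``composite``.  Line and arc truth is closed-form; sinusoid and
    composite truth comes from adaptive quadrature refined well beyond
    the comparison tolerances.  ``n_samples`` defaults to one sample per
    ``ANALYTIC_STEP`` pixels of arc length (minimum 21).
    """
    if kind == "line":
        return _line_curve(params, n_samples)
    if kind == "circular_arc":
        return _arc_curve(params, n_samples)
    if kind == "sinusoid":
        return _sinusoid_curve(params, n_samples)
    if kind == "composite":
        return _composite_curve(params, n_samples, seed)
    raise ParameterError(f"unknown curve kind: {kind!r}")


def pixelate_curve(points: np.ndarray) -> np.ndarray:
    """Round a densely sampled curve to a deduplicated integer pixel path.

    Input points are (x, y); output is an (M, 2) integer array of (row,
    col) pixels, consecutive pixels 8-connected, as a rasterized
    centerline would appear.
    """
    pts = np.asarray(points, dtype=float)
    # densify so that rounding cannot skip a pixel
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps > 0.5):
        k = int(np.ceil(steps.max() / 0.5))
        t = np.arange(len(pts))
        ti = np.linspace(0, len(pts) - 1, (len(pts) - 1) * k + 1)
        pts = np.column_stack([np.interp(ti, t, pts[:, 0]), np.interp(ti, t, pts[:, 1])])
    rc = np.column_stack([np.rint(pts[:, 1]), np.rint(pts[:, 0])]).astype(int)
    keep = np.ones(len(rc), dtype=bool)
    keep[1:] = np.any(rc[1:] != rc[:-1], axis=1)
    rc = rc[keep]
    if len(rc) < 3:
        return rc
    # drop staircase corner pixels (prev and next already 8-neighbors), as
    # topology-preserving thinning would: the chain becomes 8-connected
    out = [rc[0]]
    i = 1
    while i < len(rc) - 1:
        a, c = out[-1], rc[i + 1]
        if max(abs(int(c[0]) - int(a[0])), abs(int(c[1]) - int(a[1]))) == 1:
            i += 1
            continue
        out.append(rc[i])
        i += 1
    out.append(rc[-1])
    return np.array(out)


@dataclass
class RasterizedVessel:
    """A vessel tube drawn into an image, with its ground truth."""

    image: np.ndarray  # 2D float
    mask: np.ndarray  # true tube pixels
    centerline_px: np.ndarray  # (M, 2) int (row, col)
    tentative_endpoints: np.ndarray  # (2, 2) int (row, col)
    curve: AnalyticCurve
    width_px: int


def rasterize_vessel(
    curve: AnalyticCurve,
    width_px: int = 7,
    image_shape: tuple[int, int] = (512, 512),
    contrast: float = 80.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background: float = 200.0,
) -> RasterizedVessel:
    """Draw the curve as a dark tube of ``width_px`` on a lighter background.

    The tube is the dilation of the rasterized centerline by a discrete
    disk of radius ``width_px // 2`` (round end caps).  Additive Gaussian
    noise with ``noise_sd`` is seeded and reproducible.  Returns the true
    centerline pixels and the two end pixels as tentative endpoints.
    """
    if width_px < 1:
        raise ParameterError("width_px must be >= 1")
    rc = pixelate_curve(curve.points)
    h, w = image_shape
    r_tube = width_px // 2
    if (
        rc[:, 0].min() < r_tube
        or rc[:, 1].min() < r_tube
        or rc[:, 0].max() >= h - r_tube
        or rc[:, 1].max() >= w - r_tube
    ):
        raise ParameterError("curve (plus tube radius) exits the image bounds")
    mask = np.zeros(image_shape, dtype=bool)
    mask[rc[:, 0], rc[:, 1]] = True
    if r_tube > 0:
        mask = _dilate(mask, disk(r_tube))
    img = np.full(image_shape, float(background))
    img[mask] -= float(contrast)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=image_shape)
    return RasterizedVessel(
        image=img,
        mask=mask,
        centerline_px=rc,
        tentative_endpoints=rc[[0, -1]].copy(),
        curve=curve,
        width_px=width_px,
    )


@dataclass
class FundusPhantom:
    """A synthetic eye-fundus scene and its M- and D-centered croppings.

    ``scene`` is an RGB raster with a bright optic-disc blob (the unique
    brightest region in every channel), a dark macula blob (the unique
    darkest), and a set of dark vessel tubes.  ``frame_m`` / ``frame_d``
    are croppings of the scene centered on the macula and disc truth.
    ``truth`` holds scene- and frame-coordinate landmarks, crop offsets
    (row, col), per-vessel analytic curves and endpoints, and the seed.
    """

    scene: np.ndarray
    frame_m: np.ndarray
    frame_d: np.ndarray
    truth: dict[str, Any]
    seed: int


def _largest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Start/end (inclusive) indices of the longest run of True values."""
    best = None
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0] + 1:
                best = (start, i - 1)
            start = None
    if start is not None and (best is None or len(mask) - start > best[1] - best[0] + 1):
        best = (start, len(mask) - 1)
    return best


def _scene_vessels(
    rng: np.random.Generator,
    n_vessels: int,
    valid_box: tuple[float, float, float, float],
    disc: np.ndarray,
    macula: np.ndarray,
    min_arc_len: float = 140.0,
    disc_clear: float = 90.0,
    macula_clear: float = 75.0,
    max_tries: int = 400,
) -> list[AnalyticCurve]:
    """Circular-arc vessels inside the M/D overlap region.

    Random arcs are drawn around the disc-macula midline and trimmed, in
    the analytic parameter domain, to their longest run inside the valid
    box and clear of both landmarks -- so each kept vessel still has exact
    closed-form truth.
    """
    r0, r1, c0, c1 = valid_box
    mid = 0.5 * (disc + macula)
    vessels: list[AnalyticCurve] = []
    for _ in range(max_tries):
        if len(vessels) >= n_vessels:
            break
        R = float(rng.uniform(90.0, 220.0))
        theta = float(rng.uniform(1.0, 2.2))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = rng.uniform(30.0, 110.0)
        cx = mid[1] + rad * math.cos(ang)
        cy = mid[0] + rad * math.sin(ang)
        n = max(64, int(R * theta / 2.0))
        t = np.linspace(0.0, theta, n)
        xs = cx + R * np.cos(phase + t)
        ys = cy + R * np.sin(phase + t)
        ok = (ys > r0) & (ys < r1) & (xs > c0) & (xs < c1)
        ok &= np.hypot(ys - disc[0], xs - disc[1]) > disc_clear
        ok &= np.hypot(ys - macula[0], xs - macula[1]) > macula_clear
        run = _largest_true_run(ok)
        if run is None:
            continue
        i0, i1 = run
        theta_kept = float(t[i1] - t[i0])
        if R * theta_kept < min_arc_len:
            continue
        vessels.append(
            gen_analytic_curve(
                "circular_arc",
                {
                    "radius": R,
                    "angle": theta_kept,
                    "center": (cx, cy),
                    "phase": phase + float(t[i0]),
                },
            )
        )
    return vessels


def gen_fundus_phantom_pair(
    seed: int = 0,
    distortion: float = 0.0,
    frame_shape: tuple[int, int] = (768, 806),
    n_vessels: int = 6,
    vessel_width: int = 5,
    noise_sd: float = 2.0,
    frame_noise_sd: float = 1.5,
) -> FundusPhantom:
    """Build one fundus scene and crop it twice (macula- and disc-centered).

    The disc-macula distance is about one third of the frame width.  The
    two frames are pure re-croppings of one scene (integer translation,
    no resampling); a small per-frame noise field emulates re-imaging so
    paired measurements differ slightly.  Set ``distortion > 0`` for an
    additional mild per-frame radial distortion.
    """
    rng = np.random.default_rng(seed)
    fh, fw = frame_shape
    dm_dist = fw / 3.0
    margin = 60
    sh = fh + 2 * margin
    sw = int(fw + dm_dist + 2 * margin)
    # landmarks on a horizontal line through the scene center
    cy = sh / 2.0
    macula = np.array([cy, (sw - dm_dist) / 2.0])  # (row, col)
    disc = np.array([cy, (sw + dm_dist) / 2.0])

    # crop origins are known up front; vessels must live in the overlap of
    # the two croppings (and clear of both landmarks)
    off_m_pre = np.array(
        [int(round(cy - fh / 2.0)), int(round(macula[1] - fw / 2.0))]
    )
    off_d_pre = np.array(
        [int(round(cy - fh / 2.0)), int(round(disc[1] - fw / 2.0))]
    )
    valid_box = (
        float(off_m_pre[0] + 12),
        float(off_m_pre[0] + fh - 12),
        float(off_d_pre[1] + 12),
        float(off_m_pre[1] + fw - 12),
    )

    yy, xx = np.mgrid[0:sh, 0:sw].astype(float)
    base = 120.0 + 10.0 * (xx / sw)  # mild illumination gradient
    disc_blob = 100.0 * np.exp(
        -(((yy - disc[0]) ** 2 + (xx - disc[1]) ** 2) / (2 * 38.0**2))
    )
    mac_blob = 90.0 * np.exp(
        -(((yy - macula[0]) ** 2 + (xx - macula[1]) ** 2) / (2 * 48.0**2))
    )

    vessels = _scene_vessels(rng, n_vessels, valid_box, disc, macula)
    vmask = np.zeros((sh, sw), dtype=bool)
    kept = []
    r_tube = vessel_width // 2
    for cv in vessels:
        rc = pixelate_curve(cv.points)
        m = np.zeros((sh, sw), dtype=bool)
        m[rc[:, 0], rc[:, 1]] = True
        vmask |= _dilate(m, disk(r_tube)) if r_tube else m
        kept.append((cv, rc))

    field = base + disc_blob - mac_blob
    field = field - 55.0 * vmask
    # soften tube edges slightly, as in a defocused fundus photograph
    field = gaussian_filter(field, 1.0)
    scene = np.stack(
        [
            field + 35.0,  # R: fundus is reddish
            field,
            field - 35.0,
        ],
        axis=-1,
    )
    scene += rng.normal(0.0, noise_sd, size=scene.shape)
    scene = np.clip(scene, 0.0, 255.0)

    def crop(center: np.ndarray, frame_seed: int) -> tuple[np.ndarray, np.ndarray]:
        r0 = int(round(center[0] - fh / 2.0))
        c0 = int(round(center[1] - fw / 2.0))
        r0 = min(max(r0, 0), sh - fh)
        c0 = min(max(c0, 0), sw - fw)
        frame = scene[r0 : r0 + fh, c0 : c0 + fw].copy()
        frng = np.random.default_rng(frame_seed)
        if frame_noise_sd > 0:
            frame = np.clip(
                frame + frng.normal(0.0, frame_noise_sd, size=frame.shape), 0, 255
            )
        if distortion > 0:
            frame = _radial_distort(frame, distortion)
        return frame, np.array([r0, c0])

    # derive per-frame seeds from the master seed, kept below 2**31
    frame_m, off_m = crop(macula, (seed * 2 + 1) % (2**31))
    frame_d, off_d = crop(disc, (seed * 2 + 2) % (2**31))

    truth: dict[str, Any] = {
        "seed": seed,
        "scene_shape": (sh, sw),
        "disc_scene": disc.tolist(),
        "macula_scene": macula.tolist(),
        "offset_m": off_m.tolist(),
        "offset_d": off_d.tolist(),
        "disc_m": (disc - off_m).tolist(),
        "disc_d": (disc - off_d).tolist(),
        "macula_m": (macula - off_m).tolist(),
        "macula_d": (macula - off_d).tolist(),
        "vessel_width": vessel_width,
        "vessels": [
            {
                "id": i,
                "curve": cv,
                "centerline_scene": rc,
                "endpoints_scene": rc[[0, -1]],
            }
            for i, (cv, rc) in enumerate(kept)
        ],
    }
    return FundusPhantom(
        scene=scene, frame_m=frame_m, frame_d=frame_d, truth=truth, seed=seed
    )


def _radial_distort(frame: np.ndarray, k: float) -> np.ndarray:
    """Mild barrel distortion about the frame center (k ~ 1e-2 is already strong)."""
    from skimage.transform import warp

    h, w = frame.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rmax = math.hypot(cy, cx)

    def inv(coords):
        y = coords[:, 1] - cy
        x = coords[:, 0] - cx
        r = np.hypot(x, y) / rmax
        f = 1.0 + k * r**2
        return np.column_stack([x * f + cx, y * f + cy])

    return warp(frame, inverse_map=inv, preserve_range=True)


@dataclass(frozen=True)
class PairedDifferencesSpec:
    """Structure of a simulated paired (M, D) index table.

    ``magnitude_range`` is the uniform range of the M-frame values; the
    paired D-frame value adds ``bias`` plus Gaussian noise whose sd grows
    linearly with the magnitude (``baseline_sd + funnel * magnitude``),
    the funnel shape seen in the study's Bland-Altman plots.
    """

    n_pairs: int
    bias: float = 0.0
    baseline_sd: float = 0.01
    funnel: float = 0.0
    magnitude_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ParameterError("need at least 2 pairs")
        if self.baseline_sd < 0 or self.funnel < 0:
            raise ParameterError("sd parameters must be non-negative")


_EYE_LABELS = ("R1", "L1", "R2", "L2")


def gen_paired_differences(spec: PairedDifferencesSpec) -> pd.DataFrame:
    """Simulate a per-vessel paired index table.

    Returns a DataFrame with columns ``vessel_id``, ``eye``, ``value_M``,
    ``value_D``; rows are labeled cyclically across the four eye groups.
    """
    rng = np.random.default_rng(spec.seed)
    mag = rng.uniform(*spec.magnitude_range, size=spec.n_pairs)
    sd = spec.baseline_sd + spec.funnel * mag
    d = mag + spec.bias + rng.normal(0.0, 1.0, size=spec.n_pairs) * sd
    return pd.DataFrame(
        {
            "vessel_id": np.arange(spec.n_pairs),
            "eye": [_EYE_LABELS[i % 4] for i in range(spec.n_pairs)],
            "value_M": mag,
            "value_D": d,
        }
    )
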