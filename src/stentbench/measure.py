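"""Quantitative stent metrics from HU line profiles on axial slices.

Three metrics, each replicated at several axial locations per stent and
reported as mean +/- SD:

* **diameter** — peak-to-peak: on each diametral line through the stent
  center, the distance between the two outermost opposing strut peaks.
* **blooming** — apparent strut-band widening: on radial profiles, the
  inner and outer half-maximum crossing radii of the strut peak (half-max
  relative to the local background on that side) define apparent inner and
  outer areas A_in = pi*r_in^2, A_out = pi*r_out^2; blooming is
  (A_out - A_in) / A_out * 100.
* **inter-stent distinction** — on a profile crossing one strut of each of
  two adjacent stents: distinction = (peak - trough) / (peak - minimum)
  * 100, where peak is the mean height of the two strut peaks, trough the
  HU minimum between them, and minimum the background HU far from the
  stent (soft-tissue reference), clamped to [0, 100].

All three are position- or ratio-based, so they are invariant under any
positive affine rescaling of the HU values; thresholds used internally
(peak prominence, centroid threshold, half-max levels) are defined relative
to profile statistics, never as absolute HU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .errors import (
    InvalidParameterError,
    MeasurementFailureError,
    OutOfBoundsError,
)
from .phantom import ImageVolume, StentSpec

__all__ = [
    "LineProfile",
    "Summary",
    "StentMeasurement",
    "extract_profile",
    "radial_profile",
    "find_peaks_subpixel",
    "estimate_center",
    "measure_diameter",
    "mean_abs_error",
    "blooming_percent",
    "distinction_percent",
    "measure_blooming",
    "measure_distinction",
]


@dataclass
class LineProfile:
    """HU sampled along a straight line in one axial slice.

    ``position_mm`` is the signed distance along the line (strictly
    increasing); ``origin_xy_mm`` and ``angle_rad`` record where the line
    lies so results can be mapped back to the image.
    """

    position_mm: np.ndarray
    hu: np.ndarray
    origin_xy_mm: tuple[float, float] = (0.0, 0.0)
    angle_rad: float = 0.0

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.hu = np.asarray(self.hu, dtype=float)
        if self.position_mm.ndim != 1 or self.position_mm.shape != self.hu.shape:
            raise InvalidParameterError("position_mm and hu must be equal-length 1-D")
        if self.position_mm.size >= 2 and not np.all(np.diff(self.position_mm) > 0):
            raise InvalidParameterError("position_mm must be strictly increasing")

    @property
    def step_mm(self) -> float:
        return float(self.position_mm[1] - self.position_mm[0])


@dataclass
class Summary:
    """Mean +/- SD over replicate measurements (SD with ddof=1, 0 if n==1)."""

    mean: float
    sd: float
    n: int
    values: np.ndarray

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "Summary":
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise InvalidParameterError("cannot summarize zero measurements")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls(mean=float(np.mean(v)), sd=sd, n=int(v.size), values=v)


@dataclass
class StentMeasurement:
    """All per-stent results with per-location replicates and intermediates."""

    stent_key: str
    true_diameter_mm: float | None
    diameter: Summary | None
    abs_error: Summary | None
    blooming: Summary | None
    distinction: Summary | None = None
    n_locations: int = 0
    detail_rows: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------------
# profile extraction


def _sample_slice(image: ImageVolume, slice_index: int, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    nz, ny, nx = image.voxels.shape
    if not 0 <= slice_index < nz:
        raise OutOfBoundsError(f"slice_index {slice_index} outside [0, {nz})")
    ix = (xs - image.origin_mm[0]) / image.spacing_mm[0]
    iy = (ys - image.origin_mm[1]) / image.spacing_mm[1]
    eps = 1e-6
    if ix.min() < -eps or ix.max() > nx - 1 + eps or iy.min() < -eps or iy.max() > ny - 1 + eps:
        raise OutOfBoundsError("sampling line exits the image slice")
    sl = image.voxels[slice_index]
    return map_coordinates(sl, np.vstack([iy, ix]), order=1, mode="nearest")


def extract_profile(
    image: ImageVolume,
    slice_index: int,
    center_mm: Sequence[float],
    angle_rad: float,
    half_length_mm: float,
    step_mm: float,
) -> LineProfile:
    """Bilinearly sample HU along a diametral line through ``center_mm``.

    The line runs from -half_length to +half_length at uniform ``step_mm``;
    position 0 is the center point.
    """
    if half_length_mm <= 0 or step_mm <= 0:
        raise InvalidParameterError("half_length_mm and step_mm must be > 0")
    nh = int(round(half_length_mm / step_mm))
    s = (np.arange(2 * nh + 1) - nh) * step_mm
    cx, cy = float(center_mm[0]), float(center_mm[1])
    xs = cx + s * math.cos(angle_rad)
    ys = cy + s * math.sin(angle_rad)
    hu = _sample_slice(image, slice_index, xs, ys)
    return LineProfile(s, hu, origin_xy_mm=(cx, cy), angle_rad=angle_rad)


def radial_profile(
    image: ImageVolume,
    slice_index: int,
    center_mm: Sequence[float],
    angle_rad: float,
    r_max_mm: float,
    step_mm: float,
) -> LineProfile:
    """HU along an outward ray from ``center_mm`` (position = radius >= 0)."""
    if r_max_mm <= 0 or step_mm <= 0:
        raise InvalidParameterError("r_max_mm and step_mm must be > 0")
    r = np.arange(int(round(r_max_mm / step_mm)) + 1) * step_mm
    cx, cy = float(center_mm[0]), float(center_mm[1])
    xs = cx + r * math.cos(angle_rad)
    ys = cy + r * math.sin(angle_rad)
    hu = _sample_slice(image, slice_index, xs, ys)
    return LineProfile(r, hu, origin_xy_mm=(cx, cy), angle_rad=angle_rad)


# --------------------------------------------------------------------------
# peaks


def _default_prominence(hu: np.ndarray, fraction: float = 0.2) -> float:
    return fraction * float(hu.max() - np.median(hu))


def find_peaks_subpixel(
    profile: LineProfile, min_prominence_hu: float | None = None
) -> list[tuple[float, float]]:
    """Local maxima above a prominence threshold, refined sub-sample.

    Position is refined by fitting a parabola through the three samples
    around each discrete maximum; the refined height is the parabola vertex.
    Returns (position_mm, height_hu) pairs sorted by position; may be empty.
    """
    hu = profile.hu
    if hu.size < 3:
        raise InvalidParameterError("profile needs at least 3 samples")
    if min_prominence_hu is None:
        min_prominence_hu = _default_prominence(hu)
    idx, _ = find_peaks(hu, prominence=min_prominence_hu)
    out: list[tuple[float, float]] = []
    for i in idx:
        y0, y1, y2 = hu[i - 1], hu[i], hu[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom >= 0:  # flat or degenerate; keep the sample itself
            delta = 0.0
        else:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        step = profile.position_mm[i] - profile.position_mm[i - 1]
        pos = float(profile.position_mm[i] + delta * step)
        height = float(y1 - 0.25 * (y0 - y2) * delta)
        out.append((pos, height))
    return sorted(out)


# --------------------------------------------------------------------------
# center estimation


def estimate_center(
    image: ImageVolume,
    slice_index: int,
    approx_center_mm: Sequence[float],
    window_mm: float,
    n_iter: int = 2,
) -> tuple[float, float]:
    """Intensity-weighted centroid of the bright stent ring.

    Within a square window around the approximate center, voxels above the
    midpoint between the window background (median) and the window maximum
    are weighted by their excess over background; the centroid is refined by
    repeating once around the new estimate.
    """
    cx, cy = float(approx_center_mm[0]), float(approx_center_mm[1])
    nz, ny, nx = image.voxels.shape
    if not 0 <= slice_index < nz:
        raise OutOfBoundsError(f"slice_index {slice_index} outside [0, {nz})")
    sl = image.voxels[slice_index]
    xc = image.x_coords()
    yc = image.y_coords()
    for _ in range(n_iter):
        mx = (xc >= cx - window_mm) & (xc <= cx + window_mm)
        my = (yc >= cy - window_mm) & (cy + window_mm >= yc)
        if not mx.any() or not my.any():
            raise OutOfBoundsError("centroid window exits the image")
        crop = sl[np.ix_(my, mx)]
        bg = float(np.median(crop))
        peak = float(crop.max())
        if peak <= bg:
            raise MeasurementFailureError("no bright structure in centroid window")
        thr = bg + 0.5 * (peak - bg)
        w = np.where(crop > thr, crop - bg, 0.0)
        tot = w.sum()
        if tot <= 0:
            raise MeasurementFailureError("centroid threshold left no voxels")
        cx = float((w * xc[mx][np.newaxis, :]).sum() / tot)
        cy = float((w * yc[my][:, np.newaxis]).sum() / tot)
    return cx, cy


# --------------------------------------------------------------------------
# metric formulas (pure arithmetic, exposed for oracle checks)


def mean_abs_error(measured: Sequence[float], true_d: float) -> float:
    """Mean absolute deviation of measured diameters from the true diameter."""
    m = np.asarray(list(measured), dtype=float)
    if m.size == 0:
        raise InvalidParameterError("need at least one measurement")
    return float(np.mean(np.abs(m - true_d)))


def blooming_percent(inner_area_mm2: float, outer_area_mm2: float) -> float:
    """Relative inner/outer area difference as a percentage of the outer area."""
    if inner_area_mm2 < 0 or outer_area_mm2 <= 0:
        raise InvalidParameterError("areas must be positive")
    if inner_area_mm2 > outer_area_mm2:
        raise InvalidParameterError("inner area cannot exceed outer area")
    return (outer_area_mm2 - inner_area_mm2) / outer_area_mm2 * 100.0


def distinction_percent(peak_hu: float, trough_hu: float, minimum_hu: float) -> float:
    """Relative peak-to-trough depth, clamped to [0, 100].

    100 means the profile between two struts falls all the way to the
    background level; 0 means no dip at all (fully merged struts).
    """
    denom = peak_hu - minimum_hu
    if denom <= 0:
        return 0.0
    val = (peak_hu - trough_hu) / denom * 100.0
    return float(np.clip(val, 0.0, 100.0))


# --------------------------------------------------------------------------
# diameter


def _center_window_mm(stent: StentSpec) -> float:
    return 0.75 * stent.diameter_mm + 1.0


def measure_diameter(
    image: ImageVolume,
    stent: StentSpec,
    slice_indices: Sequence[int],
    n_angles: int = 8,
    step_mm: float | None = None,
    min_prominence_hu: float | None = None,
) -> tuple[Summary, list[dict]]:
    """Peak-to-peak stent diameter, replicated over slices and angles.

    For each slice the ring center is re-estimated, then ``n_angles``
    equally spaced diametral lines are profiled; on each line the diameter
    is the distance between the outermost peak on either side of the
    center.  Lines with fewer than two opposing peaks are excluded; if more
    than half of all lines are excluded the measurement fails.

    Returns a per-slice :class:`Summary` (each slice's value is the mean
    over its usable angles) and tidy per-line detail rows.
    """
    if n_angles < 1:
        raise InvalidParameterError("n_angles must be >= 1")
    step = step_mm if step_mm is not None else image.spacing_mm[0] / 4.0
    half_len = 0.8 * stent.diameter_mm
    rows: list[dict] = []
    per_slice: list[float] = []
    n_total = 0
    n_excluded = 0
    for k in slice_indices:
        cx, cy = estimate_center(image, k, stent.center_offset_mm, _center_window_mm(stent))
        vals = []
        for a in range(n_angles):
            theta = math.pi * a / n_angles
            n_total += 1
            prof = extract_profile(image, k, (cx, cy), theta, half_len, step)
            peaks = find_peaks_subpixel(prof, min_prominence_hu)
            left = [p for p in peaks if p[0] < 0]
            right = [p for p in peaks if p[0] > 0]
            if not left or not right:
                n_excluded += 1
                continue
            p_l = min(left)[0]
            p_r = max(right)[0]
            d = p_r - p_l
            vals.append(d)
            rows.append(
                {
                    "slice": int(k),
                    "angle_deg": math.degrees(theta),
                    "diameter_mm": d,
                    "center_x_mm": cx,
                    "center_y_mm": cy,
                }
            )
        if vals:
            per_slice.append(float(np.mean(vals)))
    if n_excluded * 2 > n_total or not per_slice:
        raise MeasurementFailureError(
            f"too few usable diametral lines ({n_total - n_excluded}/{n_total})"
        )
    return Summary.from_values(per_slice), rows


# --------------------------------------------------------------------------
# blooming


def _half_max_crossings(
    prof: LineProfile,
    peak_pos: float,
    peak_height: float,
    inner_window: tuple[float, float],
    outer_window: tuple[float, float],
) -> tuple[float, float] | None:
    """Inner/outer radii where the strut peak falls to half height.

    Half level on each side is relative to that side's local background
    (median HU in a radius window well away from the strut band).
    """
    r = prof.position_mm
    hu = prof.hu
    i_peak = int(np.argmin(np.abs(r - peak_pos)))

    def _baseline(window: tuple[float, float]) -> float | None:
        m = (r >= window[0]) & (r <= window[1])
        if not m.any():
            return None
        return float(np.median(hu[m]))

    b_in = _baseline(inner_window)
    b_out = _baseline(outer_window)
    if b_in is None or b_out is None:
        return None
    if peak_height <= max(b_in, b_out):
        return None

    def _cross(level: float, direction: int) -> float | None:
        i = i_peak
        while 0 < i < len(r) - 1:
            j = i + direction
            if j < 0 or j >= len(r):
                return None
            if hu[j] < level:
                # linear interpolation between samples i and j
                t = (hu[i] - level) / (hu[i] - hu[j])
                return float(r[i] + t * (r[j] - r[i]))
            i = j
        return None

    r_in = _cross(b_in + 0.5 * (peak_height - b_in), -1)
    r_out = _cross(b_out + 0.5 * (peak_height - b_out), +1)
    if r_in is None or r_out is None or r_in <= 0:
        return None
    return r_in, r_out


def measure_blooming(
    image: ImageVolume,
    stent: StentSpec,
    slice_indices: Sequence[int],
    n_angles: int = 8,
    step_mm: float | None = None,
    min_prominence_hu: float | None = None,
) -> tuple[Summary, list[dict]]:
    """Apparent strut-band blooming percentage, replicated over slices.

    Per slice: radial rays from the re-estimated center give, per angle,
    the strut peak and its half-maximum crossing radii.  The mean inner and
    outer crossing radii define apparent areas A_in and A_out and
    blooming = (A_out - A_in) / A_out * 100.  Rays whose crossings are not
    bracketed are excluded; a slice with no usable ray fails.
    """
    if n_angles < 1:
        raise InvalidParameterError("n_angles must be >= 1")
    step = step_mm if step_mm is not None else image.spacing_mm[0] / 4.0
    r_nominal = stent.radius_mm
    r_max = 2.7 * r_nominal
    rows: list[dict] = []
    per_slice: list[float] = []
    for k in slice_indices:
        cx, cy = estimate_center(image, k, stent.center_offset_mm, _center_window_mm(stent))
        r_ins: list[float] = []
        r_outs: list[float] = []
        peak_hts: list[float] = []
        for a in range(n_angles):
            theta = 2.0 * math.pi * a / n_angles
            prof = radial_profile(image, k, (cx, cy), theta, r_max, step)
            peaks = find_peaks_subpixel(prof, min_prominence_hu)
            if not peaks:
                continue
            r_p, h_p = max(peaks, key=lambda p: p[1])  # metal dominates
            crossings = _half_max_crossings(
                prof,
                r_p,
                h_p,
                inner_window=(0.25 * r_p, 0.6 * r_p),
                outer_window=(min(1.6 * r_p, r_max - step), min(2.4 * r_p, r_max)),
            )
            if crossings is None:
                continue
            r_ins.append(crossings[0])
            r_outs.append(crossings[1])
            peak_hts.append(h_p)
        if not r_ins:
            raise MeasurementFailureError(
                f"no usable blooming ray on slice {k} (all half-max crossings unbracketed)"
            )
        r_in = float(np.mean(r_ins))
        r_out = float(np.mean(r_outs))
        a_in = math.pi * r_in**2
        a_out = math.pi * r_out**2
        val = blooming_percent(a_in, a_out)
        per_slice.append(val)
        rows.append(
            {
                "slice": int(k),
                "r_inner_mm": r_in,
                "r_outer_mm": r_out,
                "inner_area_mm2": a_in,
                "outer_area_mm2": a_out,
                "blooming_pct": val,
                "peak_hu": float(np.mean(peak_hts)),
                "n_rays": len(r_ins),
            }
        )
    return Summary.from_values(per_slice), rows


# --------------------------------------------------------------------------
# inter-stent distinction


def measure_distinction(
    image: ImageVolume,
    stents: Sequence[StentSpec],
    slice_indices: Sequence[int],
    step_mm: float | None = None,
    min_prominence_fraction: float = 0.08,
) -> tuple[Summary, list[dict]]:
    """Peak-to-trough distinction between two adjacent stents.

    Per slice, a ray from the midpoint between the two stent axes is cast
    along the direction where the ring gap is widest (away from the inner
    stent's offset).  The two outermost peaks on the ray are the adjacent
    struts of the two stents; the HU minimum between them is the trough and
    the soft-tissue background far outside the outer stent is the minimum.
    Unresolvable struts (fewer than two peaks) score 0 for that location
    and are flagged.
    """
    if len(stents) != 2:
        raise InvalidParameterError("distinction requires exactly two stents")
    s_out, s_in = sorted(stents, key=lambda s: -s.diameter_mm)
    c_out = np.asarray(s_out.center_offset_mm, dtype=float)
    c_in = np.asarray(s_in.center_offset_mm, dtype=float)
    d_vec = c_out - c_in
    norm = float(np.hypot(*d_vec))
    theta = math.atan2(d_vec[1], d_vec[0]) if norm > 1e-9 else 0.0
    mid = (c_out + c_in) / 2.0
    step = step_mm if step_mm is not None else image.spacing_mm[0] / 4.0
    r_ref = s_out.radius_mm
    r_max = 3.0 * r_ref
    rows: list[dict] = []
    per_slice: list[float] = []
    for k in slice_indices:
        prof = radial_profile(image, k, tuple(mid), theta, r_max, step)
        prom = min_prominence_fraction * float(prof.hu.max() - np.median(prof.hu))
        peaks = find_peaks_subpixel(prof, prom)
        # background reference well outside the outer stent
        m_bg = prof.position_mm >= 2.2 * r_ref
        minimum = float(np.median(prof.hu[m_bg])) if m_bg.any() else float(prof.hu[-1])
        if len(peaks) < 2:
            per_slice.append(0.0)
            rows.append(
                {
                    "slice": int(k),
                    "peak_hu": float("nan"),
                    "trough_hu": float("nan"),
                    "minimum_hu": minimum,
                    "distinction_pct": 0.0,
                    "flagged_unresolved": True,
                }
            )
            continue
        (p1, h1), (p2, h2) = peaks[-2], peaks[-1]  # two outermost
        between = (prof.position_mm > p1) & (prof.position_mm < p2)
        trough = float(prof.hu[between].min()) if between.any() else float(min(h1, h2))
        peak = 0.5 * (h1 + h2)
        val = distinction_percent(peak, trough, minimum)
        per_slice.append(val)
        rows.append(
            {
                "slice": int(k),
                "peak_hu": peak,
                "trough_hu": trough,
                "minimum_hu": minimum,
                "distinction_pct": val,
                "flagged_unresolved": False,
            }
        )
    return Summary.from_values(per_slice), rows
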