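"""Chromatographic peak tracing and quantification.

A rectangular query region (m/z ppm window x RT interval [x IM interval]) of
a run's peak map is turned into a quantified :class:`TracedFeature`: the
monoisotopic trace is resampled onto a uniform time grid, Savitzky-Golay
smoothed, peak boundaries are found by descending from the apex, a linear
background between the boundary intensities is subtracted, and the area is
integrated by the trapezoid rule.  The +1 and +2 isotope peaks are traced
within the same bounds.  Peak boundaries may extend beyond the query
region's RT bounds.
"""
from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.signal import savgol_coeffs

from .model import ISOTOPE_SPACING, RunPeakMap, TracedFeature

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Too few raw points to build a chromatogram."""


@dataclasses.dataclass
class Chromatogram:
    """A uniformly resampled extracted-ion chromatogram."""

    times: np.ndarray
    intensities: np.ndarray
    resample_interval: float

    def __len__(self) -> int:
        return int(self.times.size)


def _aggregate_duplicates(times: np.ndarray, intensities: np.ndarray):
    """Sort by time and sum intensities at identical times (one value/scan)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    y = intensities[order]
    if t.size > 1:
        uniq, start = np.unique(t, return_index=True)
        if uniq.size != t.size:
            y = np.add.reduceat(y, start)
            t = uniq
    return t, y


def resample(
    times: np.ndarray,
    intensities: np.ndarray,
    interval: float | None = None,
) -> Chromatogram:
    """Resample raw (time, intensity) points onto a uniform grid.

    Linear interpolation between raw points; the grid spans [min time,
    max time].  ``interval`` defaults to the median raw spacing.  Raises
    :class:`DegenerateInputError` for fewer than two distinct time points.
    """
    times = np.asarray(times, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    t, y = _aggregate_duplicates(times, intensities)
    if t.size < 2:
        raise DegenerateInputError(
            f"resampling requires >= 2 distinct time points, got {t.size}"
        )
    if interval is None:
        interval = float(np.median(np.diff(t)))
    if interval <= 0:
        raise ValueError(f"resample interval must be positive, got {interval}")
    n = int(math.floor((t[-1] - t[0]) / interval + 0.5)) + 1
    grid = t[0] + np.arange(n) * interval
    vals = np.interp(grid, t, y)
    return Chromatogram(times=grid, intensities=vals, resample_interval=interval)


_SG_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _sg_matrices(window: int, polyorder: int):
    """Cached SG convolution kernel and edge-window hat matrix."""
    key = (window, polyorder)
    if key not in _SG_CACHE:
        c = savgol_coeffs(window, polyorder)
        x = np.arange(window, dtype=float)
        A = np.vander(x, polyorder + 1, increasing=True)
        H = A @ np.linalg.pinv(A)
        _SG_CACHE[key] = (c, H)
    return _SG_CACHE[key]


def _savgol(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay filtering with polynomial fits over the edge windows."""
    c, H = _sg_matrices(window, polyorder)
    h = window // 2
    out = np.convolve(y, c, mode="same")
    out[:h] = (H @ y[:window])[:h]
    out[-h:] = (H @ y[-window:])[-h:]
    return out


def smooth(chrom: Chromatogram, window: int = 7, polyorder: int = 2) -> Chromatogram:
    """Savitzky-Golay smoothing; edges use polynomial fits on truncated windows.

    A window not smaller than the series falls back to no smoothing with a
    logged warning.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    n = len(chrom)
    if window >= n:
        log.warning("smoothing window %d >= series length %d; skipping", window, n)
        return Chromatogram(chrom.times.copy(), chrom.intensities.copy(),
                            chrom.resample_interval)
    vals = _savgol(chrom.intensities, window, polyorder)
    return Chromatogram(chrom.times.copy(), vals, chrom.resample_interval)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau contributes its earliest index."""
    n = y.size
    if n == 1:
        return np.array([0])
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok:
            idx.append(i)
        i = j + 1
    return np.asarray(idx, dtype=np.intp)


def find_boundaries(
    chrom: Chromatogram,
    apex_hint: float,
    boundary_fraction: float = 0.01,
    search_lo: float | None = None,
    search_hi: float | None = None,
) -> tuple[float, float, float] | None:
    """Locate (rt_start, rt_apex, rt_end) around the apex nearest ``apex_hint``.

    The apex is the local maximum (within [search_lo, search_hi] when given)
    nearest the hint; plateaus resolve to their earliest time, and exact
    distance ties also prefer the earlier time.  Boundaries descend from the
    apex until a local minimum or until intensity drops to
    ``boundary_fraction`` of the apex; they may extend beyond the search
    window.  Returns ``None`` for an all-zero chromatogram (no peak).
    """
    y = chrom.intensities
    t = chrom.times
    if y.size == 0 or np.max(y) <= 0:
        return None
    cands = _local_maxima(y)
    if search_lo is not None or search_hi is not None:
        lo = -np.inf if search_lo is None else search_lo
        hi = np.inf if search_hi is None else search_hi
        inside = cands[(t[cands] >= lo) & (t[cands] <= hi)]
        if inside.size:
            cands = inside
    cands = cands[y[cands] > 0]
    if cands.size == 0:
        return None
    dist = np.abs(t[cands] - apex_hint)
    apex = int(cands[np.lexsort((t[cands], dist))[0]])
    floor = boundary_fraction * y[apex]

    i = apex
    while i > 0:
        if y[i - 1] > y[i]:
            break
        i -= 1
        if y[i] <= floor:
            break
    j = apex
    while j < y.size - 1:
        if y[j + 1] > y[j]:
            break
        j += 1
        if y[j] <= floor:
            break
    return float(t[i]), float(t[apex]), float(t[j])


@dataclasses.dataclass
class TraceParams:
    """Numerical knobs of the tracer (see each field's unit in the docs)."""

    ppm_tolerance: float = 10.0
    boundary_fraction: float = 0.01
    smooth_window: int = 7
    smooth_polyorder: int = 2
    resample_interval: float | None = None
    rt_pad: float = 0.3
    min_rt_halfwidth: float = 0.1
    min_im_halfwidth: float = 0.025


def _integrate(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of a uniform-grid series restricted to [lo, hi]."""
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[mask], t[mask]))


def quantify_feature(
    pmap: RunPeakMap,
    mz: float,
    charge: int,
    rt_lo: float,
    rt_hi: float,
    im_lo: float | None = None,
    im_hi: float | None = None,
    apex_hint: float | None = None,
    params: TraceParams | None = None,
) -> TracedFeature | None:
    """Trace and quantify the feature seeded by a query region.

    Returns ``None`` when the monoisotopic window holds no usable signal.
    The intensity is a background-subtracted area (volume when IM bounds are
    given: scans inside the IM window are collapsed before integration,
    equivalent to summing per-IM-slice areas on the shared scan grid).
    """
    if params is None:
        params = TraceParams()
    if not pmap.single_cv:
        raise ValueError("quantify_feature requires a single-CV peak map")
    if rt_hi < rt_lo:
        raise ValueError("malformed RT region")

    center = 0.5 * (rt_lo + rt_hi)
    half = max(0.5 * (rt_hi - rt_lo), params.min_rt_halfwidth)
    q_lo, q_hi = center - half, center + half
    ext_lo, ext_hi = q_lo - params.rt_pad, q_hi + params.rt_pad
    if apex_hint is None:
        apex_hint = center

    use_im = im_lo is not None and im_hi is not None and pmap.im is not None
    if use_im:
        im_c = 0.5 * (im_lo + im_hi)
        im_h = max(0.5 * (im_hi - im_lo), params.min_im_halfwidth)
        im_lo_eff, im_hi_eff = im_c - im_h, im_c + im_h

    def extract(mz_center: float):
        tol = mz_center * params.ppm_tolerance * 1e-6
        i0, i1 = pmap.mz_slice(mz_center - tol, mz_center + tol)
        if i1 - i0 < 1:
            return None
        rt = pmap.rt[i0:i1]
        mask = (rt >= ext_lo) & (rt <= ext_hi)
        if use_im:
            mask &= (pmap.im[i0:i1] >= im_lo_eff) & (pmap.im[i0:i1] <= im_hi_eff)
        if mask.sum() < 2:
            return None
        sl = slice(i0, i1)
        return (pmap.rt[sl][mask], pmap.intensity[sl][mask], pmap.mz[sl][mask],
                pmap.im[sl][mask] if use_im else None)

    mono = extract(mz)
    if mono is None:
        return None
    t_raw, y_raw, mz_raw, im_raw = mono
    try:
        chrom = resample(t_raw, y_raw, params.resample_interval)
    except DegenerateInputError:
        return None
    raw_resampled = np.maximum(chrom.intensities, 0.0)
    if len(chrom) > params.smooth_window:
        chrom.intensities = _savgol(chrom.intensities, params.smooth_window,
                                    params.smooth_polyorder)
    np.maximum(chrom.intensities, 0.0, out=chrom.intensities)
    bounds = find_boundaries(chrom, apex_hint, params.boundary_fraction,
                             search_lo=q_lo, search_hi=q_hi)
    if bounds is None:
        return None
    rt_start, rt_apex, rt_end = bounds

    t, y = chrom.times, chrom.intensities
    in_peak = (t >= rt_start - 1e-12) & (t <= rt_end + 1e-12)
    if in_peak.sum() < 2:
        return None
    tp, yp = t[in_peak], y[in_peak]
    background = np.interp(tp, [tp[0], tp[-1]], [yp[0], yp[-1]])
    area = float(np.trapezoid(np.maximum(yp - background, 0.0), tp))
    if area <= 0:
        return None
    # isotope envelope areas share one scheme: unsmoothed resampled signal,
    # no background, integrated within the monoisotopic bounds
    area_nobg = float(np.trapezoid(raw_resampled[in_peak], tp))

    # mass error from the raw points inside the peak bounds, intensity-weighted
    sel = (t_raw >= rt_start - 1e-12) & (t_raw <= rt_end + 1e-12)
    if sel.any() and y_raw[sel].sum() > 0:
        w = y_raw[sel]
        measured_mz = float(np.average(mz_raw[sel], weights=w))
        im_center = float(np.average(im_raw[sel], weights=w)) if use_im else None
    else:
        measured_mz = mz
        im_center = 0.5 * (im_lo_eff + im_hi_eff) if use_im else None
    ppm = (measured_mz - mz) / mz * 1e6

    iso = [area_nobg]
    for k in (1, 2):
        mz_k = mz + k * ISOTOPE_SPACING / charge
        raw_k = extract(mz_k)
        if raw_k is None:
            iso.append(0.0)
            continue
        tk, yk, _, _ = raw_k
        try:
            ck = resample(tk, yk, params.resample_interval)
        except DegenerateInputError:
            iso.append(0.0)
            continue
        iso.append(max(_integrate(ck.times, np.maximum(ck.intensities, 0.0),
                                  rt_start, rt_end), 0.0))

    return TracedFeature(
        mono_mz=measured_mz,
        charge=charge,
        rt_apex=rt_apex,
        rt_start=rt_start,
        rt_end=rt_end,
        intensity=area,
        isotope_intensities=(iso[0], iso[1], iso[2]),
        mass_error_ppm=ppm,
        im_center=im_center,
    )
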