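"""RR quality filtering, 4 Hz resampling and windowed RMSSD.

RMSSD (root mean square of successive differences of R-R intervals) is
computed from 5-min segments on a 2.5-min sliding grid, both on the beat-exact
tachogram and on the tachogram resampled to a uniform 4 Hz grid by
shape-preserving piecewise cubic Hermite interpolation (the sampling rate of
clinical ultrasound-based fetal monitors).  Window quality is a weighted sum
of three fractions (physiologic time, connected time, high-quality time);
low-quality windows are masked, not deleted, so the time axis is preserved.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .simulate import BeatSeries, RR_PHYSIOLOGIC_MS

__all__ = [
    "QualityReport", "UniformRRSeries", "RMSSDSeries",
    "assess_quality", "resample_rr_4hz", "rmssd", "rmssd_series",
    "window_grid", "write_rmssd_csv",
]

WINDOW_LENGTH_S = 300.0
WINDOW_STEP_S = 150.0
RESAMPLE_HZ = 4.0
CONNECTION_GAP_S = 2.0
#: beats this close to a non-physiologic episode count as unreliable
QUALITY_HALO_S = 60.0
DEFAULT_QUALITY_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
DEFAULT_QUALITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class QualityReport:
    window_start: float
    window_length: float
    pct_physiologic: float
    pct_connected: float
    pct_high_quality: float
    composite: float
    retained: bool


@dataclass(frozen=True)
class UniformRRSeries:
    """RR values interpolated on a uniform 4 Hz grid."""

    sample_times: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times, float)
        rr = np.asarray(self.rr_ms, float)
        if len(t) != len(rr):
            raise ValueError("sample_times and rr_ms must align")
        if len(t) >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / RESAMPLE_HZ, atol=1e-9):
                raise ValueError("grid spacing must be exactly 0.25 s")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "rr_ms", rr)


@dataclass(frozen=True)
class RMSSDSeries:
    """Windowed RMSSD with quality mask.

    ``window_centers`` are centers of the 5-min windows on the 2.5-min grid;
    ``retained_mask`` marks windows that passed quality filtering and have
    enough usable successive differences.  ``source`` is ``beat_exact`` or
    ``resampled_4hz``.
    """

    window_centers: np.ndarray
    rmssd_ms: np.ndarray
    source: str
    retained_mask: np.ndarray

    def __post_init__(self):
        if self.source not in ("beat_exact", "resampled_4hz"):
            raise ValueError(f"unknown source {self.source!r}")
        c = np.asarray(self.window_centers, float)
        v = np.asarray(self.rmssd_ms, float)
        m = np.asarray(self.retained_mask, bool)
        if not (len(c) == len(v) == len(m)):
            raise ValueError("window arrays must align")
        if np.any(v[m] < 0):
            raise ValueError("RMSSD must be non-negative")
        object.__setattr__(self, "window_centers", c)
        object.__setattr__(self, "rmssd_ms", v)
        object.__setattr__(self, "retained_mask", m)

    def __len__(self) -> int:
        return len(self.window_centers)

    @property
    def window_starts(self) -> np.ndarray:
        return self.window_centers - WINDOW_LENGTH_S / 2.0


def window_grid(t_start: float, t_end: float) -> np.ndarray:
    """Start times of full 5-min windows stepped by 2.5 min from ``t_start``.

    The final partial window is dropped; a record spanning 6 h yields
    ``floor((21600 - 300) / 150) + 1 = 143`` windows.
    """
    span = t_end - t_start
    if span < WINDOW_LENGTH_S:
        raise ValueError(
            f"record spans {span:.0f} s < one {WINDOW_LENGTH_S:.0f} s window"
        )
    n = int(np.floor((span - WINDOW_LENGTH_S) / WINDOW_STEP_S)) + 1
    return t_start + WINDOW_STEP_S * np.arange(n)


def rmssd(values) -> float:
    """Root mean square of successive differences, in the units of `values`."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("rmssd needs at least 2 values")
    d = np.diff(v)
    return float(np.sqrt(np.mean(d * d)))


def _overlap(starts: np.ndarray, ends: np.ndarray, w0: float, w1: float) -> float:
    """Total overlap of [starts, ends] intervals with window [w0, w1]."""
    if len(starts) == 0:
        return 0.0
    lo = np.maximum(starts, w0)
    hi = np.minimum(ends, w1)
    return float(np.sum(np.maximum(hi - lo, 0.0)))


def _merge_intervals(iv: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if not iv:
        return np.empty(0), np.empty(0)
    iv = sorted(iv)
    merged = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    arr = np.array(merged)
    return arr[:, 0], arr[:, 1]


def assess_quality(
    beats: BeatSeries,
    weights: tuple[float, float, float] = DEFAULT_QUALITY_WEIGHTS,
    threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> list[QualityReport]:
    """One quality report per 5-min window (2.5-min step).

    * ``pct_physiologic`` — fraction of window time not covered by flagged or
      out-of-bounds RR intervals;
    * ``pct_connected`` — fraction of window time not inside inter-beat gaps
      longer than 2 s;
    * ``pct_high_quality`` — fraction of window time outside a ±60 s halo
      around non-physiologic episodes (beat detection near noise is unreliable).

    The composite is the weighted sum; a window is retained iff
    ``composite >= threshold``.
    """
    w = np.asarray(weights, float)
    if w.size != 3 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("quality weights must be three fractions summing to 1")
    t = beats.beat_times
    rr = beats.rr_ms
    lo, hi = RR_PHYSIOLOGIC_MS
    bad = beats.artifact_flags | (rr < lo) | (rr > hi)

    # non-physiologic time: the RR interval ending at each bad beat
    iv_bad = [(t[i] - rr[i] / 1000.0, t[i]) for i in np.where(bad)[0]]
    bad_s, bad_e = _merge_intervals(iv_bad)
    halo_s, halo_e = _merge_intervals(
        [(a - QUALITY_HALO_S, b + QUALITY_HALO_S) for a, b in zip(bad_s, bad_e)]
    )
    gaps = np.diff(t)
    gap_idx = np.where(gaps > CONNECTION_GAP_S)[0]
    gap_s, gap_e = t[gap_idx], t[gap_idx + 1]

    reports = []
    for w0 in window_grid(t[0], t[-1]):
        w1 = w0 + WINDOW_LENGTH_S
        p_phys = 1.0 - _overlap(bad_s, bad_e, w0, w1) / WINDOW_LENGTH_S
        p_conn = 1.0 - _overlap(gap_s, gap_e, w0, w1) / WINDOW_LENGTH_S
        p_hq = 1.0 - _overlap(halo_s, halo_e, w0, w1) / WINDOW_LENGTH_S
        comp = float(w @ [p_phys, p_conn, p_hq])
        reports.append(QualityReport(float(w0), WINDOW_LENGTH_S, p_phys,
                                     p_conn, p_hq, comp, comp >= threshold))
    return reports


def resample_rr_4hz(beats: BeatSeries) -> UniformRRSeries:
    """Shape-preserving (PCHIP) interpolation of clean RR onto a 4 Hz grid.

    Flagged / non-physiologic beats are excluded before interpolation; the
    interpolant passes through the remaining samples exactly and never
    overshoots the values of its bracketing beats.
    """
    tc, rc = beats.clean()
    lo, hi = RR_PHYSIOLOGIC_MS
    ok = (rc >= lo) & (rc <= hi)
    tc, rc = tc[ok], rc[ok]
    if len(tc) < 4:
        raise ValueError("resampling needs at least 4 clean beats")
    interp = PchipInterpolator(tc, rc)
    step = 1.0 / RESAMPLE_HZ
    n = int(np.floor((tc[-1] - tc[0]) / step)) + 1
    grid = tc[0] + step * np.arange(n)
    return UniformRRSeries(grid, interp(grid))


def _beat_window_rmssd(beats: BeatSeries, w0: float, w1: float) -> float:
    """Beat-exact window RMSSD over clean beats; differences never bridge
    exclusions or gaps longer than the connection threshold."""
    tc, rc = beats.clean()
    sel = (tc >= w0) & (tc < w1)
    tcw, rcw = tc[sel], rc[sel]
    if len(tcw) < 3:
        return np.nan
    d = np.diff(rcw)
    ok = np.diff(tcw) <= CONNECTION_GAP_S
    d = d[ok]
    if d.size < 2:
        return np.nan
    return float(np.sqrt(np.mean(d * d)))


def rmssd_series(
    data: BeatSeries | UniformRRSeries,
    quality: list[QualityReport],
) -> RMSSDSeries:
    """Windowed RMSSD series at either precision, masked by window quality.

    Masked windows keep their timestamps (NaN value, ``retained_mask`` False)
    so downstream consumers preserve causal timing.
    """
    if not quality:
        raise ValueError("quality reports required (empty input)")
    starts = np.array([q.window_start for q in quality])
    retained = np.array([q.retained for q in quality], dtype=bool)

    if isinstance(data, BeatSeries):
        source = "beat_exact"
        vals = np.array([
            _beat_window_rmssd(data, w0, w0 + WINDOW_LENGTH_S) if keep else np.nan
            for w0, keep in zip(starts, retained)
        ])
    elif isinstance(data, UniformRRSeries):
        source = "resampled_4hz"
        t, rr = data.sample_times, data.rr_ms
        vals = np.full(len(starts), np.nan)
        for i, (w0, keep) in enumerate(zip(starts, retained)):
            if not keep:
                continue
            sel = (t >= w0) & (t < w0 + WINDOW_LENGTH_S)
            if sel.sum() >= 3:
                vals[i] = rmssd(rr[sel])
    else:
        raise TypeError(f"unsupported input type {type(data)!r}")

    mask = retained & np.isfinite(vals)
    return RMSSDSeries(starts + WINDOW_LENGTH_S / 2.0, vals, source, mask)


def write_rmssd_csv(path: str | Path, series: RMSSDSeries) -> None:
    """Write `window_center_s, rmssd_ms, source, retained`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["window_center_s", "rmssd_ms", "source", "retained"])
        for c, v, m in zip(series.window_centers, series.rmssd_ms,
                           series.retained_mask):
            w.writerow([f"{c:.1f}", "" if np.isnan(v) else f"{v:.6f}",
                        series.source, int(m)])
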