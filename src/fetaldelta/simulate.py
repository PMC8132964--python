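"""Synthetic RR-interval tachograms with the regime structure of a
graded umbilical-cord-occlusion (UCO) labor experiment.

A record consists of a baseline period followed by mild, moderate and severe
series of repetitive occlusions (1 min every 2.5 min).  Each occlusion produces
a variable FHR deceleration of stage-dependent depth.  At a hidden, per-subject
decompensation time (the synthetic analogue of the expert-annotated ABP
"sentinel") the beat-to-beat variability begins a sustained rise: an onset
surge followed by a linear trend.  A configurable fraction of beats is replaced
by flagged non-physiologic outliers occurring in bursts, emulating episodes of
ECG noise / disconnection that window-level quality filtering must catch.

The generator is calibrated so that the windowed RMSSD of a pure-baseline
simulation equals ``baseline_rmssd``: the beat noise is an AR(1) sequence whose
successive-difference RMS is set analytically to the target, slowly modulated
in amplitude by a smooth stochastic process (the autonomic-state modulation
that gives real RMSSD tracings their window-to-window variability).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "UCOProtocol", "SubjectParams", "BeatSeries", "SimulatedRecord",
    "make_protocol", "simulate_beats", "simulate_baseline", "simulate_cohort",
    "draw_decomp_times",
    "write_tachogram_csv", "read_tachogram_csv",
    "write_annotation_csv", "read_annotation_csv",
]

RR_PHYSIOLOGIC_MS = (200.0, 1500.0)

_STAGES = ("baseline", "mild", "moderate", "severe")


@dataclass(frozen=True)
class UCOProtocol:
    """Timing and depth parameters of the occlusion protocol.

    Durations are seconds.  ``fhr_drop_bpm`` holds the target deceleration
    depth of the mild / moderate / severe stages; the severe target is clipped
    so FHR never falls below ``severe_floor_bpm`` (a complete occlusion drives
    the heart rate toward a deep deceleration floor, not a fixed decrement).
    Severe decelerations deepen progressively from the moderate depth to the
    severe target over the first ``severe_deepening_occlusions`` occlusions,
    reflecting the gradual loss of cardiovascular compensation.
    """

    baseline_duration: float = 5400.0
    stage_durations: tuple[float, float, float] = (3600.0, 3600.0, 7200.0)
    occlusion_duration: float = 60.0
    occlusion_period: float = 150.0
    fhr_drop_bpm: tuple[float, float, float] = (30.0, 60.0, 120.0)
    severe_floor_bpm: float = 65.0
    severe_deepening_occlusions: int = 12
    # variable-deceleration shape: descent during occlusion, nadir, recovery
    decel_descent_s: float = 45.0
    decel_nadir_s: float = 15.0
    decel_recovery_s: float = 40.0

    @property
    def stage_starts(self) -> tuple[float, float, float, float]:
        """Start times of (baseline, mild, moderate, severe)."""
        b = self.baseline_duration
        m, mo, _ = self.stage_durations
        return (0.0, b, b + m, b + m + mo)

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + sum(self.stage_durations)

    def stage_of(self, t: float) -> str:
        starts = self.stage_starts
        for name, s0, s1 in zip(_STAGES, starts, (*starts[1:], self.total_duration)):
            if s0 <= t < s1:
                return name
        return "severe" if t >= starts[-1] else "baseline"


def make_protocol(
    baseline_duration: float = 5400.0,
    stage_durations: tuple[float, float, float] = (3600.0, 3600.0, 7200.0),
    occlusion_duration: float = 60.0,
    occlusion_period: float = 150.0,
    fhr_drop_bpm: tuple[float, float, float] = (30.0, 60.0, 120.0),
    **kwargs,
) -> UCOProtocol:
    """Validate and build a :class:`UCOProtocol`.

    Raises
    ------
    ValueError
        for non-positive durations or an occlusion longer than its period.
    """
    if baseline_duration <= 0:
        raise ValueError("baseline_duration must be > 0")
    if any(d < 0 for d in stage_durations) or sum(stage_durations) < 0:
        raise ValueError("stage durations must be >= 0")
    if occlusion_duration <= 0 or occlusion_period <= 0:
        raise ValueError("occlusion parameters must be > 0")
    if occlusion_duration >= occlusion_period:
        raise ValueError(
            f"occlusion_duration ({occlusion_duration}) must be shorter than "
            f"occlusion_period ({occlusion_period})"
        )
    if len(stage_durations) != 3 or len(fhr_drop_bpm) != 3:
        raise ValueError("three UCO stages expected (mild, moderate, severe)")
    if any(d <= 0 for d in fhr_drop_bpm):
        raise ValueError("FHR drop targets must be > 0")
    return UCOProtocol(
        baseline_duration=float(baseline_duration),
        stage_durations=tuple(float(d) for d in stage_durations),
        occlusion_duration=float(occlusion_duration),
        occlusion_period=float(occlusion_period),
        fhr_drop_bpm=tuple(float(d) for d in fhr_drop_bpm),
        **kwargs,
    )


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology and ground truth.

    ``decomp_time`` is the hidden decompensation onset (seconds from record
    start), the synthetic analogue of the expert ABP sentinel: from this time
    the beat-to-beat variability surges by ``onset_surge_ms`` (with a transient
    ``surge_overshoot`` fraction decaying over ``surge_tau_s``) and then grows
    linearly by ``rmssd_growth`` per hour.  Set ``decomp_time`` to ``None`` for
    a record without a decompensation event.
    """

    baseline_fhr: float = 160.0           # bpm
    baseline_rmssd: float = 3.0           # ms
    decomp_time: float | None = None      # s from record start
    rmssd_growth: float = 6.0             # ms per hour after onset
    onset_surge_ms: float = 4.0           # step component of the onset
    surge_overshoot: float = 0.5          # transient fraction of the surge
    surge_tau_s: float = 400.0            # overshoot decay time constant
    artifact_rate: float = 0.02           # expected fraction of artifact beats
    rng_seed: int = 0
    # beat-noise structure
    ar_phi: float = 0.3                   # AR(1) coefficient of beat noise
    modulation_cv: float = 0.10           # sd of slow amplitude modulation
    modulation_time_s: float = 450.0      # smoothing timescale of modulation

    def __post_init__(self):
        if self.baseline_rmssd <= 0:
            raise ValueError("baseline_rmssd must be > 0")
        if not (0 <= self.artifact_rate < 0.2):
            raise ValueError("artifact_rate must be in [0, 0.2)")
        if self.baseline_fhr <= 0:
            raise ValueError("baseline_fhr must be > 0")
        if not (-1 < self.ar_phi < 1):
            raise ValueError("ar_phi must be in (-1, 1)")


@dataclass(frozen=True)
class BeatSeries:
    """A tachogram: beat times (s), RR intervals (ms) and artifact flags.

    ``rr_ms[i]`` is the interval ending at ``beat_times[i]``, so
    ``rr_ms[i] == (beat_times[i] - beat_times[i-1]) * 1000`` for ``i >= 1``.
    Flagged beats are non-physiologic (ectopy-like outliers, noise); they are
    excluded from HRV computation downstream and degrade window quality.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    artifact_flags: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, float)
        rr = np.asarray(self.rr_ms, float)
        fl = np.asarray(self.artifact_flags, bool)
        if not (len(t) == len(rr) == len(fl)):
            raise ValueError("beat_times, rr_ms, artifact_flags must align")
        if len(t) < 2:
            raise ValueError("a BeatSeries needs at least 2 beats")
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        object.__setattr__(self, "beat_times", t)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "artifact_flags", fl)
        err = np.abs(rr[1:] - np.diff(t) * 1000.0)
        if np.max(err) > 1.0:
            raise ValueError("rr_ms inconsistent with beat_times (> 1 ms)")
        lo, hi = RR_PHYSIOLOGIC_MS
        bad = (rr < lo) | (rr > hi)
        if np.any(bad & ~fl):
            raise ValueError("unflagged RR interval outside physiologic bounds")

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def clean(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and RR of non-flagged beats."""
        keep = ~self.artifact_flags
        return self.beat_times[keep], self.rr_ms[keep]


@dataclass(frozen=True)
class SimulatedRecord:
    record_id: str
    beats: BeatSeries
    protocol: UCOProtocol
    subject: SubjectParams

    @property
    def sentinel_time(self) -> float | None:
        return self.subject.decomp_time


# ---------------------------------------------------------------------------
# generation internals

def _deceleration_depth_profile(protocol: UCOProtocol, grid: np.ndarray) -> np.ndarray:
    """FHR decrement (bpm) on a uniform time grid, one trapezoid per occlusion."""
    drop = np.zeros_like(grid)
    dt = grid[1] - grid[0]
    starts = protocol.stage_starts
    stage_spans = list(zip(starts[1:], (*starts[2:], protocol.total_duration)))
    for stage_i, (s0, s1) in enumerate(stage_spans):
        n_occ = int(np.floor((s1 - s0) / protocol.occlusion_period))
        for k in range(n_occ):
            o = s0 + k * protocol.occlusion_period
            depth = protocol.fhr_drop_bpm[stage_i]
            if stage_i == 2 and protocol.severe_deepening_occlusions > 0:
                # progressive deepening from the moderate depth
                f = min(1.0, k / protocol.severe_deepening_occlusions)
                depth = protocol.fhr_drop_bpm[1] + f * (depth - protocol.fhr_drop_bpm[1])
            d, nadir, r = (protocol.decel_descent_s, protocol.decel_nadir_s,
                           protocol.decel_recovery_s)
            tau = grid - o
            shape = np.zeros_like(grid)
            sel = (tau >= 0) & (tau < d)
            shape[sel] = tau[sel] / d
            sel = (tau >= d) & (tau < d + nadir)
            shape[sel] = 1.0
            sel = (tau >= d + nadir) & (tau < d + nadir + r)
            shape[sel] = 1.0 - (tau[sel] - d - nadir) / r
            drop = np.maximum(drop, depth * shape)
    return drop


def _target_noise_rmssd(subject: SubjectParams, t: np.ndarray) -> np.ndarray:
    """Per-beat target of the noise-component RMSSD (ms) along the record."""
    m = np.full_like(t, subject.baseline_rmssd, dtype=float)
    if subject.decomp_time is not None:
        dt = t - subject.decomp_time
        post = dt > 0
        surge = subject.onset_surge_ms * (
            1.0 + subject.surge_overshoot * np.exp(-dt[post] / subject.surge_tau_s)
        )
        m[post] += surge + subject.rmssd_growth * dt[post] / 3600.0
    return m


def _smooth_modulation(rng: np.random.Generator, grid_dt: float, n: int,
                       cv: float, timescale_s: float) -> np.ndarray:
    """Smooth unit-mean amplitude modulation (Gaussian-filtered white noise)."""
    if cv <= 0:
        return np.ones(n)
    sigma = max(timescale_s / grid_dt, 1.0)
    pad = int(4 * sigma)
    w = rng.normal(0.0, 1.0, n + 2 * pad)
    s = gaussian_filter1d(w, sigma, mode="nearest")[pad:pad + n]
    # smoothed white noise has variance 1/(2 sqrt(pi) sigma); renormalize
    s = s / np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * sigma))
    return np.maximum(1.0 + cv * s, 0.3)


def _artifact_bursts(rng: np.random.Generator, total: float, rate: float,
                     mean_burst_s: float = 450.0,
                     within_burst_p: float = 0.7) -> list[tuple[float, float]]:
    """Burst intervals such that the expected artifact beat fraction is `rate`."""
    if rate <= 0:
        return []
    n = rng.poisson(rate * total / (within_burst_p * mean_burst_s))
    bursts = []
    for _ in range(n):
        dur = float(np.exp(rng.normal(np.log(mean_burst_s), 0.3)))
        start = float(rng.uniform(0.0, max(total - dur, 1.0)))
        bursts.append((start, start + dur))
    return sorted(bursts)


def _simulate_rr(total: float, fhr_grid: np.ndarray, grid_dt: float,
                 subject: SubjectParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential beat generation.  Returns beat times, rr (ms), flags."""
    phi = subject.ar_phi
    # AR(1) with unit variance has successive-difference RMS sqrt(2 (1-phi));
    # scale so the noise diff RMS equals the target RMSSD exactly.
    diff_scale = 1.0 / np.sqrt(2.0 * (1.0 - phi))

    n_grid = len(fhr_grid)
    mod = _smooth_modulation(rng, grid_dt, n_grid,
                             subject.modulation_cv, subject.modulation_time_s)
    grid_t = np.arange(n_grid) * grid_dt
    m_target = _target_noise_rmssd(subject, grid_t)

    bursts = _artifact_bursts(rng, total, subject.artifact_rate)
    burst_starts = np.array([b[0] for b in bursts])
    burst_ends = np.array([b[1] for b in bursts])

    n_max = int(total / 0.18) + 2
    eps = rng.normal(0.0, 1.0, n_max)
    art_u = rng.uniform(0.0, 1.0, n_max)
    art_kind = rng.uniform(0.0, 1.0, n_max) < 0.5

    times = np.empty(n_max)
    rrs = np.empty(n_max)
    flags = np.zeros(n_max, dtype=bool)

    t = 0.0
    u = eps[0]  # stationary start
    lo, hi = RR_PHYSIOLOGIC_MS
    i = 0
    sq = np.sqrt(1.0 - phi ** 2)
    while True:
        gi = min(int(t / grid_dt), n_grid - 1)
        rr_clean = 60000.0 / max(fhr_grid[gi], 30.0)
        noise = m_target[gi] * mod[gi] * u * diff_scale
        rr = float(np.clip(rr_clean + noise, lo, hi))
        if len(burst_starts) and np.any((burst_starts <= t) & (t < burst_ends)):
            if art_u[i] < 0.7:
                rr = rr * (0.5 if art_kind[i] else 2.0)
                flags[i] = True
        t += rr / 1000.0
        times[i] = t
        rrs[i] = rr
        if t >= total + 1.0 or i + 1 >= n_max:
            i += 1
            break
        u = phi * u + sq * eps[i + 1]
        i += 1
    return times[:i], rrs[:i], flags[:i]


def simulate_beats(protocol: UCOProtocol, subject: SubjectParams) -> BeatSeries:
    """Generate one beat-level tachogram under a UCO protocol.

    Deterministic for a fixed ``subject.rng_seed``.

    Raises
    ------
    ValueError
        if ``decomp_time`` does not fall inside the moderate or severe stage.
    """
    if subject.decomp_time is not None:
        starts = protocol.stage_starts
        if not (starts[2] <= subject.decomp_time < protocol.total_duration):
            raise ValueError(
                f"decomp_time {subject.decomp_time:.0f} s outside the "
                f"moderate/severe span [{starts[2]:.0f}, {protocol.total_duration:.0f})"
            )
    rng = np.random.default_rng(subject.rng_seed)
    total = protocol.total_duration
    grid_dt = 0.25
    grid = np.arange(0.0, total + grid_dt, grid_dt)
    drop = _deceleration_depth_profile(protocol, grid)
    fhr = np.maximum(subject.baseline_fhr - drop, protocol.severe_floor_bpm)
    times, rrs, flags = _simulate_rr(total, fhr, grid_dt, subject, rng)
    return BeatSeries(times, rrs, flags)


def simulate_baseline(duration: float, subject: SubjectParams) -> BeatSeries:
    """A stationary baseline-only tachogram (no occlusions, no decompensation).

    Used for calibration and resampling-bias studies.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    subj = replace(subject, decomp_time=None)
    rng = np.random.default_rng(subj.rng_seed)
    grid_dt = 0.25
    n = int(duration / grid_dt) + 2
    fhr = np.full(n, subj.baseline_fhr)
    times, rrs, flags = _simulate_rr(duration, fhr, grid_dt, subj, rng)
    return BeatSeries(times, rrs, flags)


def draw_decomp_times(n: int, rng: np.random.Generator,
                      protocol: UCOProtocol) -> np.ndarray:
    """Decompensation onsets: uniform over the moderate stage plus the first
    quarter of the severe stage."""
    starts = protocol.stage_starts
    lo = starts[2]
    hi = starts[3] + protocol.stage_durations[2] / 4
    return rng.uniform(lo, hi, size=n)


def simulate_cohort(
    n: int,
    master_seed: int,
    protocol: UCOProtocol | None = None,
    subject_defaults: SubjectParams | None = None,
) -> list[SimulatedRecord]:
    """Simulate a cohort of subjects with hidden decompensation times.

    Per-subject seeds derive deterministically from ``master_seed``; each
    decompensation time is drawn uniformly over the moderate stage plus the
    first quarter of the severe stage.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    protocol = protocol or make_protocol()
    subject_defaults = subject_defaults or SubjectParams()
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    decomps = draw_decomp_times(n, rng, protocol)
    records = []
    for k in range(n):
        subj = replace(subject_defaults, decomp_time=float(decomps[k]),
                       rng_seed=int(seeds[k]))
        beats = simulate_beats(protocol, subj)
        records.append(SimulatedRecord(f"S{k + 1:02d}", beats, protocol, subj))
    return records


# ---------------------------------------------------------------------------
# CSV interchange

def write_tachogram_csv(path: str | Path, beats: BeatSeries) -> None:
    """Write `beat_time_s, rr_ms, artifact` (UTF-8, '.' decimal)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["beat_time_s", "rr_ms", "artifact"])
        for t, rr, fl in zip(beats.beat_times, beats.rr_ms, beats.artifact_flags):
            w.writerow([f"{t:.6f}", f"{rr:.3f}", int(fl)])


def read_tachogram_csv(path: str | Path) -> BeatSeries:
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:3] != ["beat_time_s", "rr_ms", "artifact"]:
            raise ValueError(f"unexpected tachogram header in {path}: {header}")
        rows = [(float(a), float(b), bool(int(c))) for a, b, c in r]
    if not rows:
        raise ValueError(f"empty tachogram: {path}")
    t, rr, fl = map(np.array, zip(*rows))
    return BeatSeries(t, rr, fl.astype(bool))


def write_annotation_csv(path: str | Path, records: list[SimulatedRecord]) -> None:
    """Write ground-truth sentinel times: `record_id, sentinel_time_s`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "sentinel_time_s"])
        for rec in records:
            if rec.sentinel_time is not None:
                w.writerow([rec.record_id, f"{rec.sentinel_time:.3f}"])


def read_annotation_csv(path: str | Path) -> dict[str, float]:
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:2] != ["record_id", "sentinel_time_s"]:
            raise ValueError(f"unexpected annotation header in {path}: {header}")
        return {rid: float(t) for rid, t in r}
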