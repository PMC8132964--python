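"""Detection-performance evaluation against sentinel annotations.

A detection is a true positive when it is no more than 2 min later and no more
than 25 min (one Delta-point sampling interval) earlier than the expert
sentinel; later detections are false negatives, earlier ones false positives
(boundaries inclusive for TP).  Aggregates are

    accuracy    = successful detections / number of examples
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)

plus summaries of the absolute sentinel-detection differences (median, IQR,
mean, SD) and an exact Wilcoxon signed-rank comparison of the paired absolute
differences between the two sampling precisions.

A bundled fixture (``data/table2_fixture.csv``) transcribes the per-animal
sentinel and detection clock times of the published fetal-sheep UCO study;
evaluating it reproduces every printed performance number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "SentinelAnnotation", "DetectionOutcome", "ConfusionMatrix",
    "PerformanceMetrics", "DeltaSummary", "PairedDetectionTable",
    "CohortReport", "classify_detection", "confusion", "metrics",
    "summarize_deltas", "wilcoxon_signed_rank", "evaluate_cohort",
    "load_reference_table", "parse_clock",
]

LATE_LIMIT_MIN = 2.0    # TP may be at most this late
EARLY_LIMIT_MIN = 25.0  # TP may be at most this early (one sampling interval)

SOURCES = ("beat_exact", "resampled_4hz")


@dataclass(frozen=True)
class SentinelAnnotation:
    record_id: str
    sentinel_time: float  # seconds


@dataclass(frozen=True)
class DetectionOutcome:
    record_id: str
    source: str
    lead_minutes: float | None   # sentinel - detection; positive = early
    outcome: str                 # TP / FP / FN

    @property
    def abs_delta_minutes(self) -> float | None:
        return None if self.lead_minutes is None else abs(self.lead_minutes)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: float
    accuracy: float
    precision: float


@dataclass(frozen=True)
class DeltaSummary:
    median_min: float
    iqr_min: float
    mean_min: float
    sd_min: float


@dataclass(frozen=True)
class PairedDetectionTable:
    """Per-record sentinel and detection times (seconds) at both precisions."""

    record_ids: list[str]
    sentinel: np.ndarray
    detection_beat_exact: np.ndarray
    detection_4hz: np.ndarray

    def deltas(self, source: str) -> np.ndarray:
        det = (self.detection_beat_exact if source == "beat_exact"
               else self.detection_4hz)
        return np.abs(self.sentinel - det) / 60.0

    def outcomes(self, source: str) -> list[DetectionOutcome]:
        det = (self.detection_beat_exact if source == "beat_exact"
               else self.detection_4hz)
        return [classify_detection(s, d, record_id=r, source=source)
                for r, s, d in zip(self.record_ids, self.sentinel, det)]


@dataclass(frozen=True)
class CohortReport:
    confusion: dict[str, ConfusionMatrix]
    metrics: dict[str, PerformanceMetrics]
    deltas: dict[str, DeltaSummary]
    outcomes: dict[str, list[DetectionOutcome]]
    wilcoxon_w: float | None
    wilcoxon_p: float | None
    n_records: int


def parse_clock(hms: str) -> float:
    """HH:MM:SS clock time to seconds of day (single experiment day)."""
    h, m, s = (int(p) for p in hms.strip().split(":"))
    return 3600.0 * h + 60.0 * m + float(s)


def classify_detection(
    sentinel_time: float,
    detection_time: float | None,
    late_limit_min: float = LATE_LIMIT_MIN,
    early_limit_min: float = EARLY_LIMIT_MIN,
    record_id: str = "",
    source: str = "beat_exact",
) -> DetectionOutcome:
    """Classify one detection against its sentinel.

    Lead = sentinel - detection (minutes; positive = detection earlier).
    TP iff -late_limit <= lead <= early_limit (inclusive); a later detection
    or no detection at all is a FN; an earlier one a FP.
    """
    if detection_time is None:
        return DetectionOutcome(record_id, source, None, "FN")
    lead = (sentinel_time - detection_time) / 60.0
    if -late_limit_min <= lead <= early_limit_min:
        cls = "TP"
    elif lead < -late_limit_min:
        cls = "FN"
    else:
        cls = "FP"
    return DetectionOutcome(record_id, source, lead, cls)


def confusion(outcomes: list[DetectionOutcome]) -> ConfusionMatrix:
    if not outcomes:
        raise ValueError("no outcomes to aggregate")
    counts = {"TP": 0, "FP": 0, "FN": 0}
    for o in outcomes:
        counts[o.outcome] += 1
    return ConfusionMatrix(counts["TP"], counts["FP"], counts["FN"], tn=0)


def metrics(cm: ConfusionMatrix, n_examples: int) -> PerformanceMetrics:
    """Sensitivity, accuracy and precision; zero-denominator ratios are NaN."""
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return PerformanceMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        accuracy=cm.tp / n_examples,
        precision=ratio(cm.tp, cm.tp + cm.fp),
    )


def summarize_deltas(deltas_min) -> DeltaSummary:
    """Median, IQR, mean and sample SD of absolute deltas (minutes).

    Quantiles use linear interpolation between order statistics
    (position 1 + p (n - 1)).
    """
    d = np.abs(np.asarray(deltas_min, float))
    if d.size < 2:
        raise ValueError("need at least 2 deltas")
    q1, q3 = np.percentile(d, [25, 75])
    return DeltaSummary(
        median_min=float(np.median(d)),
        iqr_min=float(q3 - q1),
        mean_min=float(np.mean(d)),
        sd_min=float(np.std(d, ddof=1)),
    )


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2*W+ over uniform sign assignments.

    ``ranks2`` are doubled (hence integral) ranks; returns counts indexed by
    the doubled positive-rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    W is the smaller of the positive/negative rank sums.  Zero differences are
    dropped; ties get average ranks.  The two-sided p is exact (full
    enumeration of sign assignments via the rank-sum distribution) for
    n <= 20 after dropping zeros, otherwise a normal approximation with tie
    correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("paired samples of equal length >= 5 required")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n <= 20:
        ranks2 = np.round(2 * ranks).astype(int)
        dist = _signed_rank_distribution(ranks2)
        total = 2.0 ** n
        w2 = int(round(2 * w))
        p = min(1.0, 2.0 * float(dist[: w2 + 1].sum()) / total)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        from scipy.stats import norm as _norm
        z = (w - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * float(_norm.cdf(z)))
    return w, p


def evaluate_cohort(
    detections: dict[str, dict[str, float | None]],
    annotations: list[SentinelAnnotation],
) -> CohortReport:
    """Score a cohort of detections at both precisions.

    ``detections`` maps source -> {record_id: detection time (s) or None}.
    Every detected record must have an annotation; records are processed in
    sorted id order so the report is order-invariant.
    """
    ann = {a.record_id: a.sentinel_time for a in annotations}
    outcomes: dict[str, list[DetectionOutcome]] = {}
    for source, dets in detections.items():
        missing = sorted(set(dets) - set(ann))
        if missing:
            raise ValueError(f"records without annotation: {', '.join(missing)}")
        outcomes[source] = [
            classify_detection(ann[rid], dets[rid], record_id=rid, source=source)
            for rid in sorted(dets)
        ]
    cms = {s: confusion(o) for s, o in outcomes.items()}
    mets = {s: metrics(cm, cm.n) for s, cm in cms.items()}
    deltas = {}
    for s, outs in outcomes.items():
        d = [o.abs_delta_minutes for o in outs if o.abs_delta_minutes is not None]
        if len(d) >= 2:
            deltas[s] = summarize_deltas(d)
    w = p = None
    if set(SOURCES) <= set(outcomes):
        d_by = {
            s: {o.record_id: o.abs_delta_minutes for o in outcomes[s]
                if o.abs_delta_minutes is not None}
            for s in SOURCES
        }
        common = sorted(set(d_by[SOURCES[0]]) & set(d_by[SOURCES[1]]))
        if len(common) >= 5:
            w, p = wilcoxon_signed_rank(
                [d_by[SOURCES[1]][r] for r in common],
                [d_by[SOURCES[0]][r] for r in common],
            )
    n_records = max((cm.n for cm in cms.values()), default=0)
    return CohortReport(cms, mets, deltas, outcomes, w, p, n_records)


def load_reference_table(path: str | None = None) -> PairedDetectionTable:
    """The bundled per-animal sentinel/detection clock-time table (n = 14).

    ``path`` overrides the packaged file (e.g. for validation tests).
    """
    if path is None:
        ref = resources.files("fetaldelta.data").joinpath("table2_fixture.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    header = lines[0].split(",")
    if header != ["group", "animal", "sentinel", "detection_1000hz", "detection_4hz"]:
        raise ValueError(f"unexpected fixture header: {header}")
    ids, sen, d1k, d4 = [], [], [], []
    for line in lines[1:]:
        _, animal, s, a, b = line.split(",")
        ids.append(animal)
        sen.append(parse_clock(s))
        d1k.append(parse_clock(a))
        d4.append(parse_clock(b))
    if len(ids) != 14:
        raise ValueError(f"reference table must have 14 rows, found {len(ids)}")
    return PairedDetectionTable(ids, np.array(sen), np.array(d1k), np.array(d4))
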