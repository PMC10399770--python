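"""Reference-signal matched-filter click detection.

A single click, chosen by ear (or from ground truth), serves as the
reference template.  The filter slides the template over the recording and
computes, at every lag, the zero-mean, energy-normalized correlation
coefficient between the template and the recording window; correlation
maxima mark candidate event onsets.  A supervised tuning step sweeps the
classification threshold on an annotated segment until the chosen criterion
(by default: at least ``target`` of the reported signals are true) is met.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, oaconvolve, resample_poly
from fractions import Fraction

from .audio_io import AnnotationSet, Recording

__all__ = [
    "ClickTemplate",
    "CorrelationTrace",
    "Detection",
    "DetectionMetrics",
    "TunedDetector",
    "TuningError",
    "matched_filter",
    "detect_events",
    "score_detections",
    "tune_threshold",
]

#: Default minimum separation between detections (s): one maximum
#: Single-Click duration, so a click never yields two detections.
DEFAULT_MIN_SEPARATION = 0.020
#: Default detection-to-truth matching tolerance (s).
DEFAULT_TOLERANCE = 0.010


@dataclass
class ClickTemplate:
    """The reference click waveform used by the matched filter."""

    waveform: np.ndarray
    sample_rate: float
    source: str = ""

    MAX_DURATION = 0.100  # s; a click template longer than this is suspect

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.waveform.size < 2 or not np.any(self.waveform):
            raise ValueError("template must have nonzero energy")
        if self.waveform.size / self.sample_rate > self.MAX_DURATION:
            raise ValueError(
                f"template longer than {self.MAX_DURATION * 1e3:.0f} ms")

    @classmethod
    def from_recording(cls, rec: Recording, start: float,
                       duration: float) -> "ClickTemplate":
        """Cut a template out of a recording (e.g. a click chosen by ear)."""
        piece = rec.slice(start, start + duration)
        return cls(waveform=piece.samples, sample_rate=rec.sample_rate,
                   source=f"{rec.label}@{start:.4f}s+{duration * 1e3:.1f}ms")

    @property
    def duration(self) -> float:
        return self.waveform.size / self.sample_rate

    def resampled(self, target_rate: float) -> "ClickTemplate":
        if target_rate == self.sample_rate:
            return self
        ratio = Fraction(target_rate / self.sample_rate).limit_denominator(10_000)
        wave = resample_poly(self.waveform, ratio.numerator, ratio.denominator)
        return ClickTemplate(waveform=wave, sample_rate=target_rate,
                             source=self.source)


@dataclass
class CorrelationTrace:
    """Normalized correlation coefficient at every candidate onset lag.

    ``values[i]`` is the correlation for the window starting at time
    ``alignment + i / sample_rate`` (seconds).
    """

    values: np.ndarray
    sample_rate: float
    alignment: float = 0.0

    def time_of(self, index: int | np.ndarray):
        return self.alignment + np.asarray(index) / self.sample_rate


@dataclass(frozen=True)
class Detection:
    """One detected event: onset estimate (s) and its correlation score."""

    time: float
    score: float


@dataclass
class DetectionMetrics:
    """Detection-vs-truth counts at a given matching tolerance.

    ``precision_defined`` / ``recall_defined`` flag the degenerate cases
    (no detections / no truths) where the fraction is reported as 0.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    matching_tolerance: float
    precision: float = field(init=False)
    recall: float = field(init=False)
    precision_defined: bool = field(init=False, default=True)
    recall_defined: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        tp, fp, fn = self.true_positives, self.false_positives, self.false_negatives
        if tp + fp > 0:
            self.precision = tp / (tp + fp)
        else:
            self.precision, self.precision_defined = 0.0, False
        if tp + fn > 0:
            self.recall = tp / (tp + fn)
        else:
            self.recall, self.recall_defined = 0.0, False


class TuningError(RuntimeError):
    """No threshold attains the tuning target; carries the best metrics."""

    def __init__(self, message: str, best: Optional[DetectionMetrics] = None):
        super().__init__(message)
        self.best_metrics = best


def matched_filter(rec: Recording, template: ClickTemplate) -> CorrelationTrace:
    """Sliding zero-mean, energy-normalized cross-correlation.

    The value at index ``i`` is the Pearson correlation between the template
    and the recording window starting at sample ``i``; an exact noise-free
    copy of the template scores 1.0 at its onset and the trace is invariant
    to any positive rescaling of the recording.  Zero-energy windows are
    assigned a coefficient of 0.
    """
    if template.sample_rate != rec.sample_rate:
        template = template.resampled(rec.sample_rate)
    x = rec.samples
    t = template.waveform
    m = t.size
    if m > x.size:
        raise ValueError("template longer than recording")
    t0 = t - t.mean()
    t_norm = float(np.linalg.norm(t0))
    if t_norm == 0:
        raise ValueError("template has zero variance")

    # numerator: sum over window of x * (t - mean(t)); the window mean drops
    # out because t0 sums to zero
    num = oaconvolve(x, t0[::-1], mode="valid")

    # per-window energy about the window mean, via running sums
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[m:] - c1[:-m]
    s2 = c2[m:] - c2[:-m]
    del c1, c2
    var = s2 - s1 * s1 / m
    np.maximum(var, 0.0, out=var)
    denom = np.sqrt(var) * t_norm
    del s1, s2, var

    eps = np.finfo(float).tiny
    values = np.where(denom > eps, num / np.where(denom > eps, denom, 1.0), 0.0)
    np.clip(values, -1.0, 1.0, out=values)
    return CorrelationTrace(values=values, sample_rate=rec.sample_rate,
                            alignment=rec.start_offset)


def _suppressed_peaks(trace: CorrelationTrace,
                      min_separation: float) -> tuple[np.ndarray, np.ndarray]:
    """All local maxima after greedy higher-peak-wins suppression at
    ``min_separation`` (no height filter, so thresholding afterwards is
    monotone: raising the threshold never adds a detection)."""
    distance = max(int(round(min_separation * trace.sample_rate)), 1)
    idx, _ = find_peaks(trace.values, distance=distance)
    return idx, trace.values[idx]


def detect_events(trace: CorrelationTrace, threshold: float,
                  min_separation: float = DEFAULT_MIN_SEPARATION
                  ) -> list[Detection]:
    """Local maxima of the trace above ``threshold``, with the higher peak
    winning whenever two maxima fall within ``min_separation`` seconds.
    Sorted by time; an empty list is a valid result."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    idx, scores = _suppressed_peaks(trace, min_separation)
    keep = scores >= threshold
    times = trace.time_of(idx[keep])
    return [Detection(time=float(t), score=float(s))
            for t, s in zip(times, scores[keep])]


def score_detections(dets: Sequence[Detection], truth: AnnotationSet,
                     tolerance: float = DEFAULT_TOLERANCE) -> DetectionMetrics:
    """Greedy one-to-one matching of detections to ground-truth events.

    A truth event covers ``[time, time + duration]`` (duration 0 for single
    clicks); detections within ``tolerance`` seconds of that span are
    candidates and are matched in ascending order of time distance.  Extra
    detections falling inside an already-matched event's span (e.g. the
    later pulses of a serial train) belong to that event and count neither
    as hits nor as false positives.  Detections outside every span are
    false positives; unmatched truths are false negatives.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    det_times = np.array([d.time for d in dets], dtype=float)
    starts = truth.times
    durations = np.array([a.duration for a in truth.entries], dtype=float)
    ends = starts + durations
    pairs = []
    candidate = np.zeros(det_times.size, dtype=bool)
    for i, td in enumerate(det_times):
        j0 = np.searchsorted(ends, td - tolerance)
        j1 = np.searchsorted(starts, td + tolerance, side="right")
        for j in range(j0, j1):
            dist = max(0.0, starts[j] - td, td - ends[j])
            if dist <= tolerance:
                pairs.append((dist, i, j))
                candidate[i] = True
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
    tp = len(used_t)
    # unmatched candidates sit inside (or within tolerance of) an already
    # matched event's span — typically later pulses of a serial train — and
    # are neither hits nor false alarms
    fp = int(np.sum(~candidate))
    return DetectionMetrics(
        true_positives=tp,
        false_positives=fp,
        false_negatives=starts.size - tp,
        matching_tolerance=tolerance,
    )


@dataclass
class TunedDetector:
    """A matched-filter detector with a supervised, tuned threshold."""

    template: ClickTemplate
    threshold: float
    min_separation: float
    tuning_metrics: DetectionMetrics
    criterion: str = "precision"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    def detect(self, rec: Recording) -> list[Detection]:
        trace = matched_filter(rec, self.template)
        return detect_events(trace, self.threshold, self.min_separation)


def _filter_truth(truth: AnnotationSet, start: float, end: float) -> AnnotationSet:
    entries = [a for a in truth.entries if start <= a.time < end]
    return AnnotationSet(entries=entries, recording_id=truth.recording_id)


def tune_threshold(rec: Recording, template: ClickTemplate,
                   truth: AnnotationSet,
                   target: float = 0.95,
                   segment: Optional[tuple[float, float]] = None,
                   criterion: str = "precision",
                   min_separation: float = DEFAULT_MIN_SEPARATION,
                   tolerance: float = DEFAULT_TOLERANCE,
                   max_coarse: int = 256) -> TunedDetector:
    """Supervised threshold refinement on an annotated segment.

    Candidate thresholds are the sorted unique suppressed-peak scores in the
    segment (every achievable operating point), swept in descending order.
    For ``criterion='precision'`` (default) the lowest threshold whose
    precision meets ``target`` is returned — accepting as many signals as
    possible while at least ``target`` of the reported signals are true; for
    ``criterion='recall'`` the highest threshold whose recall meets
    ``target`` — losing as few true signals as tolerable while rejecting the
    most noise.  When there are more than ``max_coarse`` candidates, a
    coarse strided sweep brackets the criterion boundary before the exact
    sweep refines inside it.

    Raises :class:`TuningError`, carrying the best metrics achieved, if no
    threshold attains the target.
    """
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    if criterion not in ("precision", "recall"):
        raise ValueError("criterion must be 'precision' or 'recall'")
    if segment is not None:
        start, end = segment
        rec = rec.slice(start, end)
        truth = _filter_truth(truth, start, end)
    if len(truth) == 0:
        raise ValueError("no ground-truth events in the tuning segment")

    trace = matched_filter(rec, template)
    idx, scores = _suppressed_peaks(trace, min_separation)
    times = trace.time_of(idx)
    order = np.argsort(scores)[::-1]
    times, scores = times[order], scores[order]
    truth_times = truth.times

    def metrics_at(k: int) -> DetectionMetrics:
        """Metrics keeping the k highest-scoring suppressed peaks."""
        dets = [Detection(time=float(t), score=float(s))
                for t, s in zip(times[:k], scores[:k])]
        return score_detections(dets, truth, tolerance)

    uniq_scores = np.unique(scores)[::-1]  # descending
    # ks[i]: number of peaks with score >= uniq_scores[i]
    ks = np.searchsorted(-scores, -uniq_scores, side="right")

    def satisfied(m: DetectionMetrics) -> bool:
        value = m.precision if criterion == "precision" else m.recall
        return value >= target

    n_cand = uniq_scores.size
    eval_idx = np.arange(n_cand)
    if n_cand > max_coarse:
        eval_idx = np.unique(np.linspace(0, n_cand - 1, max_coarse).astype(int))

    results: dict[int, DetectionMetrics] = {}
    for i in eval_idx:
        results[i] = metrics_at(int(ks[i]))

    # refine around the boundary between satisfying and non-satisfying
    if n_cand > max_coarse:
        flags = [satisfied(results[i]) for i in eval_idx]
        for a, b, fa, fb in zip(eval_idx, eval_idx[1:], flags, flags[1:]):
            if fa != fb:
                for i in range(a + 1, b):
                    results[i] = metrics_at(int(ks[i]))

    satisfying = [i for i in sorted(results) if satisfied(results[i])]
    if not satisfying:
        best = max(
            results.values(),
            key=lambda m: m.precision if criterion == "precision" else m.recall)
        raise TuningError(
            f"no threshold reaches {criterion} >= {target}", best=best)
    # precision: lowest satisfying threshold (maximize accepted signals);
    # recall: highest satisfying threshold (maximize rejected noise)
    pick = satisfying[-1] if criterion == "precision" else satisfying[0]
    thr = float(min(uniq_scores[pick], 1.0 - 1e-12))
    return TunedDetector(template=template, threshold=thr,
                         min_separation=min_separation,
                         tuning_metrics=results[pick], criterion=criterion)
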