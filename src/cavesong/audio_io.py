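"""Audio and annotation I/O.

Reads hydrophone recordings from WAV files into :class:`Recording` objects
(float samples in [-1, 1]) and ground-truth event annotations from CSV into
:class:`AnnotationSet` objects.  All times are seconds from recording start,
0-based; windows are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Recording",
    "Annotation",
    "AnnotationSet",
    "read_wav",
    "write_wav",
    "resample",
    "read_annotations",
    "write_annotations",
    "DEFAULT_SAMPLE_RATE",
]

#: Canonical internal sample rate (Hz).  The hydrophone band of interest is
#: flat to ~4.5 kHz and the sounds span 500-10,000 Hz; 44.1 kHz covers this
#: with margin.  Cross-recording operations resample to a common rate.
DEFAULT_SAMPLE_RATE = 44_100

EVENT_TYPES = ("single", "serial")


@dataclass
class Recording:
    """A uniformly sampled amplitude waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes, nominally in [-1, 1].
    sample_rate : float
        Samples per second (Hz), > 0.
    label : str
        Free-text site / lab-line identifier.
    start_offset : float
        Seconds from the origin of the source file.
    """

    samples: np.ndarray
    sample_rate: float
    label: str = ""
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be one-dimensional")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate

    def time_to_index(self, t: float) -> int:
        return int(round(t * self.sample_rate))

    def slice(self, start: float, end: float) -> "Recording":
        """Sub-recording over the half-open window [start, end) seconds."""
        i0 = max(self.time_to_index(start), 0)
        i1 = min(self.time_to_index(end), self.samples.size)
        if i1 <= i0:
            raise ValueError(f"empty or inverted window [{start}, {end})")
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_offset=self.start_offset + i0 / self.sample_rate,
        )


@dataclass(frozen=True)
class Annotation:
    """One ground-truth event: onset time (s), type, optional pulse count.

    ``duration`` is the event's span in seconds (0 for a point-like single
    click); a serial event covers [time, time + duration], and any detection
    inside that span belongs to the event when scoring.
    """

    time: float
    event_type: str
    pulse_count: Optional[int] = None
    duration: float = 0.0


@dataclass
class AnnotationSet:
    """Ground-truth event times and types for one recording.

    ``entries`` are kept sorted by time.  ``details`` optionally carries a
    per-event DataFrame of effective (measurable) feature values recorded by
    the synthetic-soundscape generator.
    """

    entries: list[Annotation] = field(default_factory=list)
    recording_id: str = ""
    details: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda a: a.time)
        for a in self.entries:
            if a.event_type not in EVENT_TYPES:
                raise ValueError(f"unknown event_type {a.event_type!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def times(self) -> np.ndarray:
        return np.array([a.time for a in self.entries], dtype=float)


class AudioFormatError(ValueError):
    """Unsupported or corrupt audio file."""


def read_wav(path: os.PathLike | str, channel: int | str = "mix",
             label: str = "") -> Recording:
    """Read a WAV file into a :class:`Recording`.

    Integer PCM is rescaled to [-1, 1] by the full-scale value of its bit
    depth; float data is taken as-is.  For multichannel files ``channel``
    selects one channel by index, or ``"mix"`` (default) averages channels.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except ValueError as exc:
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path}: zero-length audio")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        if channel == "mix":
            samples = samples.mean(axis=1)
        else:
            idx = int(channel)
            if not 0 <= idx < samples.shape[1]:
                raise AudioFormatError(
                    f"channel {idx} out of range for {samples.shape[1]}-channel file")
            samples = samples[:, idx]
    return Recording(samples=samples, sample_rate=float(rate), label=label)


def write_wav(path: os.PathLike | str, rec: Recording,
              subtype: str = "float32") -> None:
    """Write a :class:`Recording` to WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(os.fspath(path), int(rec.sample_rate),
                      rec.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(rec.samples, -1.0, 1.0)
        wavfile.write(os.fspath(path), int(rec.sample_rate),
                      np.round(clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def resample(rec: Recording, target_rate: float) -> Recording:
    """Band-limited resampling to ``target_rate`` (polyphase filtering).

    Duration is preserved to within one sample period; content below the
    target Nyquist is preserved without aliasing.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == rec.sample_rate:
        return replace(rec, samples=rec.samples.copy())
    ratio = Fraction(target_rate / rec.sample_rate).limit_denominator(10_000)
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return replace(rec, samples=out, sample_rate=float(target_rate))


class AnnotationParseError(ValueError):
    """A malformed annotation row; the message names the offending line."""


def read_annotations(path: os.PathLike | str,
                     recording_id: str = "") -> AnnotationSet:
    """Read an annotation CSV (columns ``time_s``, ``event_type``, optional
    ``pulse_count``; header row required; UTF-8)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "event_type"}
    if not required.issubset(df.columns):
        raise AnnotationParseError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}")
    entries = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            t = float(row["time_s"])
            etype = str(row["event_type"]).strip()
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event_type {etype!r}")
            pc = row.get("pulse_count")
            pulse_count = None if pc is None or pd.isna(pc) else int(pc)
            dur = row.get("duration_s")
            duration = 0.0 if dur is None or pd.isna(dur) else float(dur)
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError(f"{path} line {line_no}: {exc}") from exc
        entries.append(Annotation(time=t, event_type=etype,
                                  pulse_count=pulse_count, duration=duration))
    extra_cols = [c for c in df.columns
                  if c not in ("time_s", "event_type", "pulse_count",
                               "duration_s")]
    details = None
    if extra_cols:
        details = df.sort_values("time_s").reset_index(drop=True)
    return AnnotationSet(entries=entries, recording_id=recording_id, details=details)


def write_annotations(ann: AnnotationSet, path: os.PathLike | str) -> None:
    """Write an :class:`AnnotationSet` to CSV.

    If the set carries a generator-truth ``details`` table, its extra columns
    are written alongside the three canonical ones so that truth sidecars
    survive a round trip.
    """
    base = pd.DataFrame(
        {
            "time_s": [a.time for a in ann.entries],
            "event_type": [a.event_type for a in ann.entries],
            "pulse_count": [a.pulse_count for a in ann.entries],
            "duration_s": [a.duration for a in ann.entries],
        }
    )
    if ann.details is not None and len(ann.details) == len(base):
        extra = ann.details.drop(
            columns=[c for c in ("time_s", "event_type", "pulse_count",
                                 "duration_s")
                     if c in ann.details.columns])
        base = pd.concat([base, extra.reset_index(drop=True)], axis=1)
    # %.17g guarantees float64 round-trip identity through the CSV
    base.to_csv(path, index=False, float_format="%.17g")
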