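"""Acoustic parameters of Single and Serial Clicks.

Single Clicks carry three first-class parameters — duration (ms), dominant
frequency (Hz) and SNR (linear ratio) — and Serial Clicks five: pulse
number, mean pulse duration (ms), mean interpulse duration (ms, the silent
gap between consecutive pulses), pulse rate (s^-1) and total duration (ms).
Feature tables carry one row per event plus a group label (cave or lab
line), and a variable-reduction step enforces the sampling adequacy rule of
at least ten events per retained variable per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import _dsp
from .audio_io import Recording
from .segmentation import SoundEvent

__all__ = [
    "ClickFeatures",
    "SerialFeatures",
    "FeatureTable",
    "click_features",
    "serial_features",
    "build_feature_table",
    "build_feature_tables",
    "reduce_variables",
    "CLICK_FEATURE_NAMES",
    "SERIAL_FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

CLICK_FEATURE_NAMES = ["duration_ms", "dominant_frequency_hz", "snr"]
SERIAL_FEATURE_NAMES = [
    "pulse_number",
    "mean_pulse_duration_ms",
    "mean_interpulse_duration_ms",
    "pulse_rate_hz",
    "total_duration_ms",
]

#: SNR sentinel when the noise window is silent.
SNR_CAP = 1e6
#: Default noise-window length (s) preceding the event for the SNR
#: denominator; long enough for a stable RMS estimate on ~5 ms clicks.
DEFAULT_NOISE_WINDOW = 0.040
#: Spectrum zero-padding floor (points) for dominant-frequency estimation.
MIN_FFT = 4096


@dataclass(frozen=True)
class ClickFeatures:
    duration_ms: float
    dominant_frequency_hz: float
    snr: float
    snr_capped: bool = False


@dataclass(frozen=True)
class SerialFeatures:
    pulse_number: int
    mean_pulse_duration_ms: float
    mean_interpulse_duration_ms: float
    pulse_rate_hz: float
    total_duration_ms: float


@dataclass
class FeatureTable:
    """Rows = sound events, columns = acoustic parameters + group label."""

    df: pd.DataFrame
    event_type: str
    feature_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names + ["group"]
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        if self.df["group"].isna().any():
            raise ValueError("missing group labels")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    def values(self, features: Optional[Sequence[str]] = None) -> np.ndarray:
        return self.df[list(features or self.feature_names)].to_numpy(float)

    def group_values(self, feature: str) -> dict[str, np.ndarray]:
        return {g: sub[feature].to_numpy(float)
                for g, sub in self.df.groupby("group", observed=True)}


def dominant_frequency(x: np.ndarray, sample_rate: float,
                       band: tuple[float, float] = (_dsp.BAND_LOW,
                                                    _dsp.BAND_HIGH)) -> float:
    """Frequency of the maximum of the Hann-windowed magnitude spectrum,
    zero-padded to >= 4096 points and restricted to the analysis band."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window shorter than 2 samples")
    n_fft = max(MIN_FFT, int(2 ** math.ceil(math.log2(x.size))))
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    lo, hi = band
    hi = min(hi, sample_rate / 2)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("analysis band empty at this sample rate")
    return float(freqs[mask][np.argmax(spec[mask])])


def _window_rms(rec: Recording, start: float, end: float,
                band_limited: bool = True,
                context: tuple[float, float] = (0.01, 0.01)) -> float:
    """Band-limited RMS of [start, end); the filter runs over ``context``
    seconds of surrounding audio so its edge transients stay outside the
    measured window.  A zero right context keeps a loud neighbouring event
    from leaking backward through the zero-phase filter."""
    start = max(start, 0.0)
    end = min(end, rec.duration)
    if end <= start:
        return 0.0
    if not band_limited:
        return float(np.sqrt(np.mean(rec.slice(start, end).samples ** 2)))
    c0 = max(start - context[0], 0.0)
    c1 = min(end + context[1], rec.duration)
    x = rec.slice(c0, c1).samples
    if x.size > 30:
        x = _dsp.band_pass(x, rec.sample_rate)
    i0 = int(round((start - c0) * rec.sample_rate))
    i1 = i0 + max(int(round((end - start) * rec.sample_rate)), 1)
    return float(np.sqrt(np.mean(x[i0:i1] ** 2)))


def click_features(event: SoundEvent, rec: Recording,
                   noise_window: float = DEFAULT_NOISE_WINDOW,
                   neighbors: Optional[Sequence[SoundEvent]] = None,
                   snr_in_db: bool = False) -> ClickFeatures:
    """Acoustic parameters of one Single Click.

    Duration comes from the pulse boundaries; dominant frequency from the
    band-passed event window's magnitude spectrum; SNR is the linear ratio
    of event-window RMS to the RMS of a ``noise_window``-second span
    immediately preceding the event (shifted earlier past any overlapping
    neighbouring event).  Amplitude rescaling of the recording leaves all
    three invariant.
    """
    if event.event_type != "single":
        raise ValueError("click_features expects a single-type event")
    pulse = event.pulses[0]
    i0, i1 = rec.time_to_index(pulse.onset), rec.time_to_index(pulse.offset)
    if i1 - i0 < 2:
        raise ValueError("degenerate event: window shorter than 2 samples")

    # band-pass with surrounding context so filter edge transients stay
    # outside the measured window
    c0 = max(pulse.onset - 0.01, 0.0)
    c1 = min(pulse.offset + 0.01, rec.duration)
    ctx = rec.slice(c0, c1).samples
    if ctx.size > 30:
        ctx = _dsp.band_pass(ctx, rec.sample_rate)
    j0 = int(round((pulse.onset - c0) * rec.sample_rate))
    bp = ctx[j0:j0 + (i1 - i0)]
    dom = dominant_frequency(bp, rec.sample_rate)

    sig_rms = float(np.sqrt(np.mean(bp ** 2)))
    noise_end = pulse.onset
    if neighbors:
        for other in neighbors:
            if other is event:
                continue
            w0, w1 = other.window
            if w1 <= noise_end and w1 > noise_end - noise_window:
                noise_end = w0  # skip the overlapping event entirely
    noise_rms = _window_rms(rec, noise_end - noise_window, noise_end,
                            context=(0.01, 0.0))

    if noise_rms == 0:
        snr, capped = SNR_CAP, True
    else:
        snr, capped = sig_rms / noise_rms, False
        if snr > SNR_CAP:
            snr, capped = SNR_CAP, True
    if snr_in_db:
        snr = 20.0 * math.log10(snr) if snr > 0 else -math.inf
    return ClickFeatures(duration_ms=pulse.duration * 1e3,
                         dominant_frequency_hz=dom, snr=snr,
                         snr_capped=capped)


def serial_features(event: SoundEvent,
                    pulse_rate_mode: str = "total") -> SerialFeatures:
    """Acoustic parameters of one Serial Click.

    ``pulse_rate_mode='total'`` (default) defines the pulse rate as pulse
    number over total duration; ``'interpulse'`` as the reciprocal of the
    mean onset-to-onset interval.
    """
    if event.event_type != "serial":
        raise ValueError("serial_features expects a serial-type event")
    pulses = event.pulses
    for a, b in zip(pulses, pulses[1:]):
        if b.onset < a.offset:
            raise ValueError("overlapping pulses")
    n = len(pulses)
    durations = np.array([p.duration for p in pulses])
    gaps = np.array([b.onset - a.offset for a, b in zip(pulses, pulses[1:])])
    onset_gaps = np.array([b.onset - a.onset for a, b in zip(pulses, pulses[1:])])
    total = pulses[-1].offset - pulses[0].onset
    if pulse_rate_mode == "total":
        rate = n / total
    elif pulse_rate_mode == "interpulse":
        rate = 1.0 / float(np.mean(onset_gaps))
    else:
        raise ValueError(f"unknown pulse_rate_mode {pulse_rate_mode!r}")
    return SerialFeatures(
        pulse_number=n,
        mean_pulse_duration_ms=float(np.mean(durations)) * 1e3,
        mean_interpulse_duration_ms=float(np.mean(gaps)) * 1e3,
        pulse_rate_hz=float(rate),
        total_duration_ms=total * 1e3,
    )


def _resolve(mapping: Union[Recording, Mapping[str, Recording], None],
             source_id: str) -> Optional[Recording]:
    if mapping is None or isinstance(mapping, Recording):
        return mapping
    if source_id not in mapping:
        raise KeyError(f"unresolvable source_id {source_id!r}")
    return mapping[source_id]


def build_feature_table(events: Sequence[SoundEvent],
                        recordings: Union[Recording, Mapping[str, Recording], None],
                        group_labels: Union[str, Mapping[str, str]],
                        event_type: str = "single",
                        **kwargs) -> FeatureTable:
    """One feature row per event of the requested type.

    ``recordings`` maps ``source_id`` to its :class:`Recording` (or is a
    single Recording); ``group_labels`` maps ``source_id`` to a group label
    (or is one label for all).  Events whose feature extraction fails are
    dropped with a logged count.
    """
    names = CLICK_FEATURE_NAMES if event_type == "single" else SERIAL_FEATURE_NAMES
    rows, dropped = [], 0
    selected = [e for e in events if e.event_type == event_type]
    for k, ev in enumerate(selected):
        if isinstance(group_labels, str):
            group = group_labels
        elif ev.source_id in group_labels:
            group = group_labels[ev.source_id]
        else:
            raise KeyError(f"unknown group label for source {ev.source_id!r}")
        try:
            if event_type == "single":
                rec = _resolve(recordings, ev.source_id)
                if rec is None:
                    raise ValueError("single-click features need the recording")
                feats = click_features(ev, rec, neighbors=selected, **kwargs)
            else:
                feats = serial_features(ev, **kwargs)
            row = {"event_id": f"{ev.source_id}:{ev.onset:.4f}",
                   "event_type": event_type, "group": group,
                   "onset_s": ev.onset}
            row.update({name: getattr(feats, name) for name in names})
            rows.append(row)
        except (ValueError, KeyError) as exc:
            dropped += 1
            logger.debug("dropping event %d: %s", k, exc)
    if dropped:
        logger.warning("dropped %d/%d %s events with failed features",
                       dropped, len(selected), event_type)
    columns = ["event_id", "event_type", "group", "onset_s"] + names
    df = pd.DataFrame(rows, columns=columns)
    return FeatureTable(df=df, event_type=event_type, feature_names=list(names))


def build_feature_tables(events: Sequence[SoundEvent],
                         recordings, group_labels,
                         **kwargs) -> dict[str, FeatureTable]:
    """Partition mixed events into one table per event type."""
    return {etype: build_feature_table(events, recordings, group_labels,
                                       event_type=etype, **kwargs)
            for etype in ("single", "serial")}


@dataclass
class AdequacyReport:
    """Per-group sampling adequacy: at least ten events per retained
    variable (rows-per-variable rule)."""

    n_variables: int
    group_sizes: dict[str, int]
    required: int = field(init=False)
    flagged_groups: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.required = 10 * self.n_variables
        self.flagged_groups = sorted(
            g for g, n in self.group_sizes.items() if n < self.required)

    @property
    def adequate(self) -> bool:
        return not self.flagged_groups


def reduce_variables(table: FeatureTable,
                     max_abs_correlation: float = 0.9,
                     required: Optional[int] = None
                     ) -> tuple[list[str], AdequacyReport]:
    """Greedy redundancy-pruning variable selection.

    Features are ranked by the magnitude of their loading on the first
    principal axis of the standardized table and retained greedily so that
    no retained pair exceeds ``max_abs_correlation`` in absolute Spearman
    correlation.  The adequacy report flags groups with fewer than ten rows
    per retained variable.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if not 0 < max_abs_correlation <= 1:
        raise ValueError("max_abs_correlation must be in (0, 1]")
    names = list(table.feature_names)
    if required is not None and required > len(names):
        raise ValueError(
            f"required={required} exceeds the {len(names)} available features")
    X = table.values(names)
    sd = X.std(axis=0, ddof=0)
    keep_cols = sd > 0
    names = [n for n, k in zip(names, keep_cols) if k]
    X = X[:, keep_cols]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    # first principal axis of the correlation matrix
    _, _, vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    loading = np.abs(vt[0])
    order = np.argsort(-loading)

    selected: list[int] = []
    for j in order:
        ok = True
        for i in selected:
            rho = spearmanr(X[:, i], X[:, j]).statistic
            if abs(rho) > max_abs_correlation:
                ok = False
                break
        if ok:
            selected.append(j)
    if required is not None:
        selected = selected[:required]
    chosen = [names[j] for j in sorted(selected)]
    sizes = {g: int(n) for g, n in
             table.df.groupby("group", observed=True).size().items()}
    return chosen, AdequacyReport(n_variables=len(chosen), group_sizes=sizes)
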