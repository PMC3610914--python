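"""Event detection and per-neuron quantification of calcium oscillations.

The statistic implemented here is the semi-quantitative F/F0 rule used for
Fluo-4 recordings of spontaneous calcium activity: for each sample F(t), the
local baseline F0(t) is the arithmetic mean of two running minima — the
minimum fluorescence over the trailing ``half_window`` seconds and the
minimum over the leading ``half_window`` seconds (both windows include t and
are truncated at the trace edges).  Any maximal run of samples with
F/F0 strictly above ``threshold`` (1.2 by default) counts as one calcium
oscillation; a trace is summarized by its event frequency (events per second
of recording) and amplitude (mean over events of the peak F/F0 ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "NormalizedTrace",
    "OscillationEvent",
    "DetectionParams",
    "TraceSummary",
    "compute_baseline",
    "normalize_trace",
    "detect_events",
    "summarize_trace",
    "analyze_trace",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the oscillation statistic.

    threshold
        F/F0 ratio above which a sample is part of an oscillation
        (strictly greater; dimensionless).
    half_window
        Half-width, in seconds, of the +/- baseline window used for the
        running minima.
    min_gap
        Minimum sub-threshold duration, in seconds, that separates two
        events; shorter dips are treated as part of a single transient.
    """

    threshold: float = 1.2
    half_window: float = 10.0
    min_gap: float = 2.0

    def __post_init__(self) -> None:
        if not self.threshold > 1.0:
            raise ValueError(f"threshold must be > 1, got {self.threshold}")
        if not self.half_window > 0:
            raise ValueError(f"half_window must be > 0, got {self.half_window}")
        if self.min_gap < 0:
            raise ValueError(f"min_gap must be >= 0, got {self.min_gap}")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One ROI's raw fluorescence time series, uniformly sampled.

    ``values`` are raw indicator fluorescence in arbitrary units (must be
    finite and strictly positive); ``t0`` is the time of the first sample
    and ``dt`` the sampling interval, both in seconds.
    """

    neuron_id: str
    values: np.ndarray
    t0: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("trace must be a 1-D series of length >= 2")
        bad = np.flatnonzero(~np.isfinite(values) | (values <= 0))
        if bad.size:
            raise ValueError(
                f"trace {self.neuron_id!r}: non-positive or non-finite "
                f"fluorescence at sample index {int(bad[0])} "
                f"(value {values[bad[0]]!r})"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples * dt)."""
        return len(self) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))


@dataclass(frozen=True)
class NormalizedTrace:
    """F/F0 ratio series together with the baseline it was divided by."""

    source: FluorescenceTrace
    baseline: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.baseline) == len(self.ratio) == len(self.source)):
            raise ValueError("baseline/ratio lengths must match the source trace")


@dataclass(frozen=True)
class OscillationEvent:
    """One supra-threshold excursion of the F/F0 ratio.

    Indices are sample indices into the normalized trace; ``offset_index``
    is inclusive.  ``amplitude`` is the maximum F/F0 within the event.
    """

    onset_index: int
    offset_index: int
    peak_index: int
    amplitude: float

    def __post_init__(self) -> None:
        if not self.onset_index <= self.peak_index <= self.offset_index:
            raise ValueError("event indices must satisfy onset <= peak <= offset")


@dataclass(frozen=True)
class TraceSummary:
    """Per-neuron oscillation metrics: count, frequency (Hz), amplitude.

    ``amplitude`` is the arithmetic mean of the event peak ratios and is
    ``None`` (missing) when the trace has no events.
    """

    neuron_id: str
    n_events: int
    duration: float
    frequency: float
    amplitude: float | None
    phase: str = ""


def _window_samples(params: DetectionParams, dt: float) -> int:
    w = int(round(params.half_window / dt))
    if w < 1:
        raise ValueError(
            f"half_window {params.half_window} s is below one sample at dt={dt} s"
        )
    return w


def compute_baseline(trace: FluorescenceTrace, params: DetectionParams | None = None) -> np.ndarray:
    """Running two-sided-minimum baseline F0.

    F0(t) = mean( min F over [t - half_window, t], min F over
    [t, t + half_window] ), with both windows truncated at the trace
    boundaries.  Returns an array of the same length as the trace.
    """
    params = params or DetectionParams()
    v = trace.values
    w = _window_samples(params, trace.dt)
    pad = np.full(w, np.inf)
    windows_trail = np.lib.stride_tricks.sliding_window_view(
        np.concatenate([pad, v]), w + 1
    )
    windows_lead = np.lib.stride_tricks.sliding_window_view(
        np.concatenate([v, pad]), w + 1
    )
    return 0.5 * (windows_trail.min(axis=1) + windows_lead.min(axis=1))


def normalize_trace(trace: FluorescenceTrace, params: DetectionParams | None = None) -> NormalizedTrace:
    """Divide the raw trace by its running-minimum baseline.

    The resulting ratio is invariant under rescaling of the raw values by
    any positive constant.
    """
    params = params or DetectionParams()
    baseline = compute_baseline(trace, params)
    return NormalizedTrace(source=trace, baseline=baseline, ratio=trace.values / baseline)


def detect_events(norm: NormalizedTrace, params: DetectionParams | None = None) -> list[OscillationEvent]:
    """Find oscillation events: maximal runs of ratio strictly above threshold.

    Two runs separated by a sub-threshold gap shorter than ``min_gap``
    seconds are merged into one event.  Events are returned in time order
    and never overlap.
    """
    params = params or DetectionParams()
    ratio = norm.ratio
    above = ratio > params.threshold
    if not above.any():
        return []
    # run boundaries of the supra-threshold mask
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))  # inclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(ratio) - 1)

    dt = norm.source.dt
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1] - 1) * dt < params.min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        peak = s + int(np.argmax(ratio[s : e + 1]))
        events.append(
            OscillationEvent(
                onset_index=s,
                offset_index=e,
                peak_index=peak,
                amplitude=float(ratio[peak]),
            )
        )
    return events


def summarize_trace(
    events: list[OscillationEvent], duration: float, neuron_id: str, phase: str = ""
) -> TraceSummary:
    """Reduce an event list to the two reported metrics.

    frequency = n_events / duration (Hz); amplitude = mean of event peak
    ratios, missing (None) when there are no events.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    n = len(events)
    amplitude = float(np.mean([ev.amplitude for ev in events])) if n else None
    return TraceSummary(
        neuron_id=neuron_id,
        n_events=n,
        duration=float(duration),
        frequency=n / duration,
        amplitude=amplitude,
        phase=phase,
    )


def analyze_trace(
    trace: FluorescenceTrace, params: DetectionParams | None = None, phase: str = ""
) -> TraceSummary:
    """Full pipeline on one trace: baseline -> F/F0 -> events -> summary."""
    params = params or DetectionParams()
    norm = normalize_trace(trace, params)
    events = detect_events(norm, params)
    return summarize_trace(events, trace.duration, trace.neuron_id, phase=phase)
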