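"""CPMC event detection and per-phase motility metrics.

Given one 15-min phase of intraluminal pressure, this module estimates the
resting baseline, detects CPMC events by hysteresis thresholding, and
reduces the phase to the five standard motility metrics: event frequency,
mean onset-to-onset interval (TI), time in quiescence (TIQ), mean event
amplitude, and area under the baseline-subtracted pressure curve (AUC).

Conventions (all configurable through :class:`DetectionParams`):

* the baseline is a low percentile of the phase's samples (default 10th),
  robust to the events themselves;
* an event opens when pressure exceeds baseline + ``onset_threshold`` and
  closes when it falls below baseline + ``offset_threshold`` (hysteresis);
  events closer than ``merge_gap`` are merged and events shorter than
  ``min_event_duration`` are discarded; events truncated by the phase edge
  are kept if the visible portion satisfies the duration criterion;
* amplitude is the peak excursion *above baseline*, not absolute pressure;
* TIQ is the total time pressure stays at or below
  baseline + ``quiescence_band``, so TIQ plus time-above-band equals the
  phase duration exactly;
* AUC integrates ``max(pressure - baseline, 0)`` over the full phase
  (trapezoidal rule), which makes it robust to slow baseline drift.

Metrics that need events to exist (mean interval needs >= 2 events, mean
amplitude >= 1) are reported as NaN — an explicit "undefined" marker that
propagates through the relative-change computation instead of silently
becoming zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import ConfigurationError, PressureTrace

__all__ = [
    "DetectionParams",
    "CPMCEvent",
    "PhaseMetrics",
    "estimate_baseline",
    "detect_cpmcs",
    "phase_metrics",
    "quantify_phase",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for baseline estimation and hysteresis event detection.

    Pressures in mmHg above the estimated baseline, durations in seconds.
    The onset threshold must exceed the offset threshold (hysteresis), and
    the quiescence band must not exceed the offset threshold.
    """

    baseline_percentile: float = 10.0
    onset_threshold: float = 10.0
    offset_threshold: float = 5.0
    quiescence_band: float = 5.0
    min_event_duration: float = 5.0
    merge_gap: float = 2.0
    amplitude_above_baseline: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_percentile <= 100:
            raise ConfigurationError("baseline_percentile must be in [0, 100]")
        if not self.onset_threshold > self.offset_threshold > 0:
            raise ConfigurationError(
                "need onset_threshold > offset_threshold > 0"
            )
        if not 0 < self.quiescence_band <= self.offset_threshold:
            raise ConfigurationError(
                "need 0 < quiescence_band <= offset_threshold"
            )
        if self.min_event_duration <= 0:
            raise ConfigurationError("min_event_duration must be > 0")
        if self.merge_gap < 0:
            raise ConfigurationError("merge_gap must be >= 0")


@dataclass(frozen=True)
class CPMCEvent:
    """One detected CPMC; times in seconds relative to phase start."""

    onset: float
    offset: float
    peak_time: float
    amplitude: float  # mmHg above baseline

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ConfigurationError("event onset must precede offset")


@dataclass(frozen=True)
class PhaseMetrics:
    """The five per-phase motility metrics (NaN marks undefined values)."""

    frequency: int
    ti_mean: float  # s; NaN when < 2 events
    tiq: float  # s
    amplitude_mean: float  # mmHg; NaN when no events
    auc: float  # mmHg.s
    phase_label: str = ""


def estimate_baseline(trace: PressureTrace, params: DetectionParams) -> float:
    """Resting-pressure estimate: a low percentile of the phase's samples.

    Emits a warning when fewer than 5% of samples sit within the quiescence
    band of the estimate — the phase is then essentially one long event and
    the baseline (hence every baseline-referenced metric) is suspect.
    """
    if trace.samples.size == 0:
        raise ConfigurationError("cannot estimate baseline of an empty trace")
    baseline = float(
        np.percentile(trace.samples, params.baseline_percentile)
    )
    # a phase that is one long event visits its true baseline only briefly;
    # the percentile estimate is then biased high.  Gauge this by how much
    # of the phase sits near the trace minimum.
    quiescent_frac = float(
        np.mean(
            trace.samples <= trace.samples.min() + params.quiescence_band
        )
    )
    if quiescent_frac < 0.05:
        warnings.warn(
            f"only {quiescent_frac:.1%} of samples within the quiescence "
            "band; baseline estimate is likely biased high",
            stacklevel=2,
        )
    return baseline


def _above_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_cpmcs(
    trace: PressureTrace,
    params: DetectionParams | None = None,
    baseline: float | None = None,
) -> list[CPMCEvent]:
    """Hysteresis detection of CPMC events in one phase.

    Candidate regions are contiguous runs above baseline + offset_threshold;
    a region qualifies as an event only if it also crosses
    baseline + onset_threshold.  The event onset is the first onset-threshold
    crossing, the offset is where pressure falls back below the offset
    threshold.  Regions separated by less than ``merge_gap`` are merged
    before the duration criterion is applied.
    """
    params = params or DetectionParams()
    if baseline is None:
        baseline = estimate_baseline(trace, params)
    s = trace.samples
    rate = trace.sample_rate
    segments = _above_segments(s > baseline + params.offset_threshold)

    # merge candidate regions separated by < merge_gap
    merged: list[list[int]] = []
    gap_samples = params.merge_gap * rate
    for start, stop in segments:
        if merged and start - merged[-1][1] < gap_samples:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events: list[CPMCEvent] = []
    onset_level = baseline + params.onset_threshold
    for start, stop in merged:
        region = s[start:stop]
        above_onset = np.flatnonzero(region > onset_level)
        if above_onset.size == 0:
            continue  # never crossed the onset threshold: not an event
        i_on = start + int(above_onset[0])
        duration = (stop - i_on) / rate
        if duration < params.min_event_duration:
            continue
        i_peak = start + int(np.argmax(region))
        peak = float(s[i_peak])
        amplitude = peak - baseline if params.amplitude_above_baseline else peak
        events.append(
            CPMCEvent(
                onset=i_on / rate,
                offset=stop / rate,
                peak_time=i_peak / rate,
                amplitude=amplitude,
            )
        )
    return events


def phase_metrics(
    trace: PressureTrace,
    events: list[CPMCEvent],
    params: DetectionParams | None = None,
    baseline: float | None = None,
) -> PhaseMetrics:
    """Reduce one phase to the five motility metrics.

    ``events`` must come from :func:`detect_cpmcs` on the same trace (events
    outside the phase window raise an error).  TIQ is computed directly from
    the samples — time at or below baseline + quiescence_band — so that TIQ
    plus time-above-band equals the phase duration by construction.
    """
    params = params or DetectionParams()
    if baseline is None:
        baseline = estimate_baseline(trace, params)
    duration = trace.duration
    for ev in events:
        if ev.onset < 0 or ev.offset > duration + 1e-9:
            raise ConfigurationError(
                "event outside the phase window: trace/event mismatch"
            )

    s = trace.samples
    dt = 1.0 / trace.sample_rate
    frequency = len(events)

    if frequency >= 2:
        onsets = np.array([ev.onset for ev in events])
        ti_mean = float(np.mean(np.diff(onsets)))
    else:
        ti_mean = math.nan

    tiq = float(np.sum(s <= baseline + params.quiescence_band) * dt)

    amplitude_mean = (
        float(np.mean([ev.amplitude for ev in events]))
        if frequency
        else math.nan
    )

    auc = float(np.trapezoid(np.clip(s - baseline, 0.0, None), dx=dt))

    return PhaseMetrics(
        frequency=frequency,
        ti_mean=ti_mean,
        tiq=tiq,
        amplitude_mean=amplitude_mean,
        auc=auc,
        phase_label=trace.phase_label,
    )


def quantify_phase(
    trace: PressureTrace, params: DetectionParams | None = None
) -> PhaseMetrics:
    """Convenience one-shot: baseline -> detection -> metrics for one phase."""
    params = params or DetectionParams()
    baseline = estimate_baseline(trace, params)
    events = detect_cpmcs(trace, params, baseline=baseline)
    return phase_metrics(trace, events, params, baseline=baseline)
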