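"""Synthetic intraluminal-pressure traces with CPMC activity.

Isolated mouse colon, kept in an organ bath and gently pressurised to a few
mmHg, spontaneously generates colonic peristaltic motor complexes (CPMCs):
discrete, regularly recurring waves of contraction that register on a luminal
pressure transducer as large transient pressure excursions above an otherwise
quiet baseline.  This module generates surrogate recordings of that
preparation — one 15-min phase at a time — together with ground-truth event
annotations, so that the downstream event detector and metric pipeline can be
validated against a known truth.

The generative model is deliberately simple:

* event onsets follow a stationary renewal process whose inter-onset
  intervals are ``event_duration + Gamma(interval_shape, scale)`` with mean
  exactly ``mean_interval`` — sub-Poisson regularity, and events can never
  overlap;
* each event contributes a smooth, compactly supported pressure pulse: a
  broad raised-cosine *pedestal* carrying a narrower concentric raised-cosine
  *crest*, peaking at ``event_amplitude`` (jittered by a unit-mean lognormal
  with coefficient of variation ``amplitude_cv``);
* measurement noise is white Gaussian;
* slow deterioration of the preparation ("vehicle drift") multiplies the
  event amplitude by ``(1 + drift_per_phase)**phase_index``;
* drug action rescales generator parameters through a Hill (Emax)
  concentration-response curve.

Default numeric values are calibrated so that the full
simulate -> detect -> quantify pipeline reproduces the baseline CPMC
statistics of the real assay (~5.6 events/900 s, ~161 s inter-event
interval, ~661 s quiescence, ~49 mmHg amplitude, ~6410 mmHg.s AUC); see
docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "DrugEffect",
    "DrugEffectModel",
    "ExperimentDesign",
    "PressureTrace",
    "EventAnnotation",
    "simulate_phase",
    "apply_drug_effect",
    "simulate_experiment",
    "simulate_control_cohort",
]

#: number of warm-up inter-event intervals discarded before the phase window,
#: enough for the renewal process to forget its origin
_BURN_IN_INTERVALS = 20


class ConfigurationError(ValueError):
    """Raised when a generator/design configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Physiological parameters of the synthetic preparation.

    Units: pressures in mmHg, times in seconds.  ``mean_interval`` is
    onset-to-onset; ``event_amplitude`` is the pulse peak above baseline.
    ``pedestal_frac`` is the fraction of the peak carried by the broad
    pedestal component and ``crest_frac`` the crest width as a fraction of
    ``event_duration``.
    """

    baseline_pressure: float = 5.0
    noise_sd: float = 1.0
    mean_interval: float = 161.4
    interval_shape: float = 4.0
    event_duration: float = 59.0
    event_amplitude: float = 45.25
    amplitude_cv: float = 0.10
    pedestal_frac: float = 0.65
    crest_frac: float = 0.31
    drift_per_phase: float = -0.02

    def __post_init__(self) -> None:
        vals = [getattr(self, f.name) for f in fields(self)]
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("all generator parameters must be finite")
        if self.baseline_pressure < 0:
            raise ConfigurationError("baseline_pressure must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (self.mean_interval > self.event_duration > 0):
            raise ConfigurationError(
                "need mean_interval > event_duration > 0 "
                f"(got {self.mean_interval}, {self.event_duration})"
            )
        if self.event_amplitude < 0:
            raise ConfigurationError("event_amplitude must be >= 0")
        if self.amplitude_cv < 0:
            raise ConfigurationError("amplitude_cv must be >= 0")
        if self.interval_shape <= 0:
            raise ConfigurationError("interval_shape must be > 0")
        if not 0 < self.pedestal_frac <= 1:
            raise ConfigurationError("pedestal_frac must be in (0, 1]")
        if not 0 < self.crest_frac <= 1:
            raise ConfigurationError("crest_frac must be in (0, 1]")
        if abs(self.drift_per_phase) >= 1:
            raise ConfigurationError("|drift_per_phase| must be < 1")


@dataclass(frozen=True)
class DrugEffect:
    """Hill (Emax) action of a compound on one generator parameter.

    ``parameter`` names a :class:`GeneratorConfig` field (``event_amplitude``,
    ``mean_interval`` or ``event_duration``).  At concentration ``c`` the
    scaling is ``s(c) = 1 + (emax - 1) * c**n / (c**n + ec50**n)``; excitatory
    effects multiply the parameter by ``s``, inhibitory effects divide by it,
    so the parameter always stays positive for ``emax >= 1``.
    """

    parameter: str
    emax: float
    ec50: float
    hill_n: float
    direction: str = "inhibitory"

    _TARGETS = ("event_amplitude", "mean_interval", "event_duration")

    def __post_init__(self) -> None:
        if self.parameter not in self._TARGETS:
            raise ConfigurationError(
                f"drug effect target must be one of {self._TARGETS}"
            )
        if not (self.ec50 > 0 and math.isfinite(self.ec50)):
            raise ConfigurationError("ec50 must be positive and finite")
        if not (self.hill_n > 0 and math.isfinite(self.hill_n)):
            raise ConfigurationError("hill_n must be positive and finite")
        if not (self.emax >= 1 and math.isfinite(self.emax)):
            raise ConfigurationError("emax must be >= 1 (maximal fold effect)")
        if self.direction not in ("excitatory", "inhibitory"):
            raise ConfigurationError("direction must be excitatory|inhibitory")

    def scaling(self, conc: float) -> float:
        """Hill scaling factor at concentration ``conc`` (uM)."""
        if conc < 0:
            raise ConfigurationError("concentration must be >= 0")
        if conc == 0:
            return 1.0
        cn = conc**self.hill_n
        return 1.0 + (self.emax - 1.0) * cn / (cn + self.ec50**self.hill_n)


@dataclass(frozen=True)
class DrugEffectModel:
    """A compound's concentration-response model: one or more Hill effects."""

    effects: tuple[DrugEffect, ...] = ()

    @classmethod
    def null(cls) -> "DrugEffectModel":
        return cls(())


@dataclass(frozen=True)
class ExperimentDesign:
    """Cumulative concentration-response protocol.

    Successive 15-min perfusion phases: vehicle, then strictly increasing
    drug concentrations, then (optionally) a washout at zero concentration.
    """

    phase_labels: tuple[str, ...] = (
        "vehicle",
        "conc1",
        "conc2",
        "conc3",
        "washout",
    )
    concentrations: tuple[float, ...] = (0.3, 3.0, 30.0)
    phase_duration: float = 900.0
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.phase_duration <= 0:
            raise ConfigurationError("phase_duration must be > 0")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        n_drug = sum(
            1 for lab in self.phase_labels if lab not in ("vehicle", "washout")
        )
        if n_drug != len(self.concentrations):
            raise ConfigurationError(
                f"{n_drug} drug phases but {len(self.concentrations)} "
                "concentrations"
            )
        if any(c <= 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be positive")
        if any(
            b <= a
            for a, b in zip(self.concentrations, self.concentrations[1:])
        ):
            raise ConfigurationError("concentrations must strictly increase")

    def phase_concentration(self, index: int) -> float:
        """Bath concentration (uM) during phase ``index`` (0 for vehicle/washout)."""
        label = self.phase_labels[index]
        if label in ("vehicle", "washout"):
            return 0.0
        n_before = sum(
            1
            for lab in self.phase_labels[:index]
            if lab not in ("vehicle", "washout")
        )
        return self.concentrations[n_before]


@dataclass(frozen=True)
class PressureTrace:
    """One experimental phase of the pressure recording."""

    samples: np.ndarray  # mmHg
    sample_rate: float  # Hz
    phase_label: str = "vehicle"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if self.samples.ndim != 1:
            raise ConfigurationError("trace samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class EventAnnotation:
    """Ground truth for one generated CPMC, times relative to phase start."""

    onset: float
    offset: float
    peak_time: float
    true_amplitude: float

    def __post_init__(self) -> None:
        if not self.onset < self.peak_time < self.offset:
            raise ConfigurationError("need onset < peak_time < offset")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pulse_shape(u: np.ndarray, pedestal_frac: float, crest_frac: float) -> np.ndarray:
    """Unit-peak pulse on u in [0, 1]: raised-cosine pedestal + central crest."""
    shape = pedestal_frac * np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2
    v = (u - (0.5 - crest_frac / 2.0)) / crest_frac
    inside = (v >= 0.0) & (v <= 1.0)
    shape = shape + np.where(
        inside, (1.0 - pedestal_frac) * np.sin(np.pi * np.clip(v, 0.0, 1.0)) ** 2, 0.0
    )
    return shape


def _draw_onsets(
    config: GeneratorConfig, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Onset times of a stationary renewal process restricted to [0, duration)."""
    gamma_mean = config.mean_interval - config.event_duration
    scale = gamma_mean / config.interval_shape
    burn_in = _BURN_IN_INTERVALS * config.mean_interval
    onsets = []
    # draw intervals in blocks until the phase window is covered
    t = -burn_in
    while t < duration:
        n = max(8, int((duration - t) / config.mean_interval * 1.5) + 8)
        intervals = config.event_duration + rng.gamma(
            config.interval_shape, scale, size=n
        )
        for dt in intervals:
            t += dt
            if t >= duration:
                break
            if t >= 0.0:
                onsets.append(t)
    return np.asarray(onsets, dtype=float)


def simulate_phase(
    config: GeneratorConfig,
    duration: float = 900.0,
    rng_seed=0,
    sample_rate: float = 100.0,
    phase_label: str = "vehicle",
    start_time: float = 0.0,
) -> tuple[PressureTrace, list[EventAnnotation]]:
    """Simulate one phase of pressure recording with ground-truth annotations.

    Parameters
    ----------
    config
        Generator parameters (validated on construction).
    duration
        Phase length in seconds; a multiple of ``mean_interval`` is
        recommended so several events are expected.
    rng_seed
        Integer seed or a ``numpy.random.Generator``.

    Returns
    -------
    (trace, annotations)
        The trace has ``round(duration * sample_rate)`` samples; annotations
        list every generated event (onset within the phase; the final event's
        pulse may be truncated at the phase edge, in which case its
        annotated offset is clipped).
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    rng = _as_rng(rng_seed)
    n_samples = int(round(duration * sample_rate))
    t = np.arange(n_samples) / sample_rate

    samples = np.full(n_samples, config.baseline_pressure, dtype=float)
    if config.noise_sd > 0:
        samples += rng.normal(0.0, config.noise_sd, size=n_samples)

    annotations: list[EventAnnotation] = []
    if config.event_amplitude > 0:
        onsets = _draw_onsets(config, duration, rng)
        if config.amplitude_cv > 0:
            sigma = math.sqrt(math.log1p(config.amplitude_cv**2))
            amp_jitter = rng.lognormal(-0.5 * sigma**2, sigma, size=onsets.size)
        else:
            amp_jitter = np.ones(onsets.size)
        for onset, jit in zip(onsets, amp_jitter):
            amp = config.event_amplitude * jit
            d = config.event_duration
            i0 = int(np.ceil(onset * sample_rate))
            i1 = min(int(np.floor((onset + d) * sample_rate)) + 1, n_samples)
            u = (t[i0:i1] - onset) / d
            pulse = amp * _pulse_shape(u, config.pedestal_frac, config.crest_frac)
            samples[i0:i1] += pulse
            peak_time = onset + d / 2.0
            offset = onset + d
            if offset > duration:
                offset = duration
                peak_time = min(peak_time, (onset + duration) / 2.0)
                # truncated tail: true peak is the largest rendered value
                amp = float(pulse.max()) if pulse.size else amp
            annotations.append(
                EventAnnotation(
                    onset=float(onset),
                    offset=float(offset),
                    peak_time=float(peak_time),
                    true_amplitude=float(amp),
                )
            )

    trace = PressureTrace(
        samples=samples,
        sample_rate=sample_rate,
        phase_label=phase_label,
        start_time=start_time,
    )
    return trace, annotations


def apply_drug_effect(
    config: GeneratorConfig, model: DrugEffectModel, conc: float
) -> GeneratorConfig:
    """Return ``config`` with each targeted parameter Hill-scaled at ``conc``.

    Excitatory effects multiply the parameter by the Hill scaling
    ``1 + (emax - 1) c^n / (c^n + ec50^n)``; inhibitory effects divide by it.
    ``conc = 0`` returns the configuration unchanged.
    """
    if conc < 0:
        raise ConfigurationError("concentration must be >= 0")
    new = config
    for eff in model.effects:
        s = eff.scaling(conc)
        value = getattr(new, eff.parameter)
        value = value * s if eff.direction == "excitatory" else value / s
        try:
            new = replace(new, **{eff.parameter: value})
        except ConfigurationError as exc:
            raise ConfigurationError(
                f"drug effect on {eff.parameter} at {conc} uM produced an "
                f"invalid configuration: {exc}"
            ) from exc
    return new


def simulate_experiment(
    design: ExperimentDesign,
    base: GeneratorConfig,
    model: DrugEffectModel,
    rng_seed=0,
) -> list[tuple[PressureTrace, list[EventAnnotation]]]:
    """Simulate a full cumulative concentration-response experiment.

    One trace per design phase.  Vehicle drift is applied multiplicatively to
    the event amplitude in every phase (``(1 + drift)**phase_index``) — the
    time-dependent confound present in drug and control runs alike — and the
    drug model is applied on top at the phase's bath concentration (zero for
    vehicle and washout, i.e. washout is an instantaneous return to vehicle).
    """
    rng = _as_rng(rng_seed)
    out = []
    for i, label in enumerate(design.phase_labels):
        cfg = replace(
            base,
            event_amplitude=base.event_amplitude
            * (1.0 + base.drift_per_phase) ** i,
        )
        cfg = apply_drug_effect(cfg, model, design.phase_concentration(i))
        trace, ann = simulate_phase(
            cfg,
            duration=design.phase_duration,
            rng_seed=rng,
            sample_rate=design.sample_rate,
            phase_label=label,
            start_time=i * design.phase_duration,
        )
        out.append((trace, ann))
    return out


def simulate_control_cohort(
    n: int,
    design: ExperimentDesign,
    base: GeneratorConfig,
    rng_seed=0,
) -> list[list[tuple[PressureTrace, list[EventAnnotation]]]]:
    """Simulate ``n`` time-matched vehicle-control experiments.

    Controls follow the same phase structure as drug runs but perfuse vehicle
    (serial dilutions) throughout, so every phase is at zero concentration
    while the amplitude drift is retained.  At least two experiments are
    required because the downstream control SD is undefined for fewer.
    """
    if n < 2:
        raise ConfigurationError(
            "a control cohort needs n >= 2 (control SD undefined otherwise)"
        )
    rng = _as_rng(rng_seed)
    null = DrugEffectModel.null()
    return [
        simulate_experiment(design, base, null, rng_seed=child)
        for child in rng.spawn(n)
    ]
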