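"""Vehicle-relative changes and the time-matched-control 2-SD decision rule.

A compound run consists of a vehicle phase followed by increasing drug
concentrations (and a washout).  For the two decision metrics — mean CPMC
amplitude and time in quiescence (TIQ) — each drug phase is expressed as a
percentage change relative to the run's own vehicle phase.  The null
distribution of such changes comes from time-matched control experiments
(vehicle throughout), which capture the slow time-dependent drift of the
preparation.  A phase is called positive on a metric when its relative
change deviates from the control mean by strictly more than
``sd_multiplier`` (default 2) control standard deviations, in either
direction; a compound is positive when *either* metric is positive (OR
rule).

Compound-level calls are made at two reference points: the highest
concentration tested, and the highest concentration inside the clinically
relevant exposure window.  A compound none of whose tested concentrations
falls inside the window is called negative at the clinical dose — there is
no admissible evidence of an effect at exposures patients actually see.

Undefined relative changes (NaN, e.g. no events in the vehicle phase)
propagate as not-assessable and never count as positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .quantify import PhaseMetrics
from .simulate import ConfigurationError

__all__ = [
    "DECISION_METRICS",
    "RelativeChange",
    "ControlDistribution",
    "AssayCall",
    "relative_change",
    "build_control_distribution",
    "call_positive",
    "call_compound",
    "needs_dose_lowering",
]

#: metrics entering the positivity rule
DECISION_METRICS = ("amplitude", "tiq")

_METRIC_ATTR = {"amplitude": "amplitude_mean", "tiq": "tiq"}


@dataclass(frozen=True)
class RelativeChange:
    """Percent change of one metric in one phase relative to vehicle."""

    metric: str
    phase_label: str
    value: float  # percent; NaN when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class ControlDistribution:
    """Per (phase index, metric) mean/SD of control relative changes.

    ``stats`` maps ``(phase_index, metric)`` to ``(mean_pct, sd_pct)``;
    ``n`` is the number of control experiments.
    """

    stats: dict[tuple[int, str], tuple[float, float]]
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("control distribution needs n >= 2")

    def mean_sd(self, phase_index: int, metric: str) -> tuple[float, float]:
        try:
            return self.stats[(phase_index, metric)]
        except KeyError:
            raise ConfigurationError(
                f"no control distribution for phase {phase_index}, "
                f"metric {metric!r}"
            ) from None


@dataclass(frozen=True)
class AssayCall:
    """Compound-level outcome of the 2-SD rule.

    ``phase_flags`` maps ``(phase_index, metric)`` to True/False/None
    (None = not assessable).  ``positive_at_clinical_dose`` is None only
    when the relevant phase was not assessable; a compound with no tested
    concentration inside the window is negative-by-window
    (``window_empty`` is then True).
    """

    phase_flags: dict[tuple[int, str], bool | None]
    positive_at_max_dose: bool | None
    positive_at_clinical_dose: bool | None
    window_empty: bool = False
    max_dose_phase: int | None = None
    clinical_dose_phase: int | None = None


def relative_change(
    drug: PhaseMetrics, vehicle: PhaseMetrics, metric: str
) -> RelativeChange:
    """Percent change of ``metric`` in a drug phase vs the vehicle phase.

    Returns an undefined marker (NaN value) when the vehicle metric is
    undefined or zero, rather than a number.
    """
    if metric not in _METRIC_ATTR:
        raise ConfigurationError(
            f"metric must be one of {DECISION_METRICS}, got {metric!r}"
        )
    attr = _METRIC_ATTR[metric]
    v = getattr(vehicle, attr)
    d = getattr(drug, attr)
    if math.isnan(v) or math.isnan(d) or v == 0:
        value = math.nan
    else:
        value = 100.0 * (d - v) / v
    return RelativeChange(
        metric=metric, phase_label=drug.phase_label, value=value
    )


def build_control_distribution(
    cohort: list[list[PhaseMetrics]],
) -> ControlDistribution:
    """Null distribution of relative changes from time-matched controls.

    Each control experiment contributes, for every post-vehicle phase index
    and decision metric, its own vehicle-relative change; the distribution
    stores the across-experiment mean and sample SD (n-1 denominator).
    """
    if len(cohort) < 2:
        raise ConfigurationError("need >= 2 control experiments")
    n_phases = len(cohort[0])
    if any(len(exp) != n_phases for exp in cohort):
        raise ConfigurationError("control experiments differ in phase count")
    if n_phases < 2:
        raise ConfigurationError("experiments need a vehicle + >= 1 phase")

    stats: dict[tuple[int, str], tuple[float, float]] = {}
    for phase_idx in range(1, n_phases):
        for metric in DECISION_METRICS:
            changes = [
                relative_change(exp[phase_idx], exp[0], metric).value
                for exp in cohort
            ]
            arr = np.asarray(changes, dtype=float)
            if np.isnan(arr).any():
                warnings.warn(
                    f"undefined control change(s) for phase {phase_idx} "
                    f"{metric}; excluded from the null distribution",
                    stacklevel=2,
                )
                arr = arr[~np.isnan(arr)]
            if arr.size < 2:
                raise ConfigurationError(
                    f"fewer than 2 defined control changes for phase "
                    f"{phase_idx}, metric {metric!r}"
                )
            stats[(phase_idx, metric)] = (
                float(arr.mean()),
                float(arr.std(ddof=1)),
            )
    return ControlDistribution(stats=stats, n=len(cohort))


def call_positive(
    change: RelativeChange,
    ctrl: ControlDistribution,
    phase_index: int,
    sd_multiplier: float = 2.0,
) -> bool | None:
    """Two-sided 2-SD rule for one metric in one phase.

    Positive iff ``|change - control mean| > sd_multiplier * control SD``
    (strict inequality).  Returns None (not assessable) for undefined
    changes.
    """
    if not change.defined:
        return None
    mean, sd = ctrl.mean_sd(phase_index, change.metric)
    return abs(change.value - mean) > sd_multiplier * sd


def call_compound(
    changes: dict[int, dict[str, RelativeChange]],
    ctrl: ControlDistribution,
    phase_concentrations: dict[int, float],
    admissible_concentrations: set[float] | frozenset[float],
    sd_multiplier: float = 2.0,
) -> AssayCall:
    """Compound-level positivity at the maximum and the clinical dose.

    Parameters
    ----------
    changes
        ``{phase_index: {metric: RelativeChange}}`` for the drug phases.
    phase_concentrations
        Bath concentration (uM) of each drug phase.
    admissible_concentrations
        Tested concentrations inside the clinical exposure window (see
        :func:`cpmcassay.concordance.clinical_window`).  When no phase lies
        in the window the clinical-dose call is negative-by-window.
    """
    if not changes:
        raise ConfigurationError("empty change set for compound call")

    phase_flags: dict[tuple[int, str], bool | None] = {}
    for idx, per_metric in changes.items():
        for metric, change in per_metric.items():
            phase_flags[(idx, metric)] = call_positive(
                change, ctrl, idx, sd_multiplier
            )

    def phase_call(idx: int) -> bool | None:
        flags = [
            phase_flags[(idx, m)]
            for m in DECISION_METRICS
            if (idx, m) in phase_flags
        ]
        defined = [f for f in flags if f is not None]
        if not defined:
            warnings.warn(
                f"phase {idx}: no assessable metric; call not assessable",
                stacklevel=3,
            )
            return None
        return any(defined)  # OR rule over the decision metrics

    max_phase = max(
        changes, key=lambda idx: phase_concentrations.get(idx, -math.inf)
    )
    positive_max = phase_call(max_phase)

    admissible_phases = [
        idx
        for idx in changes
        if phase_concentrations.get(idx) in admissible_concentrations
    ]
    if admissible_phases:
        clin_phase = max(
            admissible_phases, key=lambda idx: phase_concentrations[idx]
        )
        positive_clin = phase_call(clin_phase)
        window_empty = False
    else:
        clin_phase = None
        positive_clin = False  # negative-by-window
        window_empty = True

    return AssayCall(
        phase_flags=phase_flags,
        positive_at_max_dose=positive_max,
        positive_at_clinical_dose=positive_clin,
        window_empty=window_empty,
        max_dose_phase=max_phase,
        clinical_dose_phase=clin_phase,
    )


def needs_dose_lowering(
    changes: dict[int, dict[str, RelativeChange]],
    ctrl: ControlDistribution,
    phase_concentrations: dict[int, float],
    sd_multiplier: float = 2.0,
    factor: float = 10.0,
) -> tuple[bool, tuple[float, ...]]:
    """Dose-lowering planner for the cumulative protocol.

    When a compound is already positive at the lowest concentration tested,
    the concentration-response relationship is left-censored and the run
    should be repeated with the range divided by ``factor``.  Returns
    ``(rerun_required, suggested_concentrations)``; this is a planning
    utility only — it never merges runs.
    """
    lowest = min(
        changes, key=lambda idx: phase_concentrations.get(idx, math.inf)
    )
    flags = [
        call_positive(change, ctrl, lowest, sd_multiplier)
        for change in changes[lowest].values()
    ]
    positive = any(f for f in flags if f is not None)
    if not positive:
        return False, ()
    concs = sorted(
        phase_concentrations[idx] for idx in changes
    )
    return True, tuple(c / factor for c in concs)
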