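"""High-level workflows: published-table reproduction and an end-to-end demo.

``reproduce_paper`` re-derives every compound's TP/FP/TN/FN category — for
the in vitro assay at the maximum and at the highest clinically relevant
dose, and for the charcoal-meal assay — from the packaged fixture inputs
(assay positivity, clinical findings, exposure ranges, tested
concentrations), checks them against the transcribed outcome columns, and
reports the three predictive capacities plus the scheme comparison.

``end_to_end_demo`` exercises the whole synthetic pipeline: simulate a
time-matched control cohort and a panel of synthetic compounds with known
Hill effect models, quantify every phase, apply the 2-SD decision rule, and
score the recovered classifications against the panel's ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
from fractions import Fraction

import numpy as np

from .concordance import (
    classify,
    clinical_window,
    compare_schemes,
    derived_rates,
    summarize,
)
from .decision import (
    DECISION_METRICS,
    build_control_distribution,
    call_compound,
    relative_change,
)
from .io import RunConfig, load_tables
from .quantify import DetectionParams, quantify_phase
from .simulate import (
    ConfigurationError,
    DrugEffect,
    DrugEffectModel,
    ExperimentDesign,
    GeneratorConfig,
    simulate_control_cohort,
    simulate_experiment,
    simulate_phase,
)

__all__ = [
    "reproduce_paper",
    "end_to_end_demo",
    "baseline_cohort_run",
    "DEMO_PANEL",
]

log = logging.getLogger("cpmcassay")


def _scheme_report(result) -> dict:
    counts = result.counts
    sens, spec = derived_rates(counts)
    return {
        "categories": dict(result.categories),
        "counts": counts,
        "n": result.total,
        "predictive_capacity": result.predictive_capacity,
        "predictive_capacity_pct": round(100 * result.predictive_capacity),
        "sensitivity": sens,
        "specificity": spec,
    }


def reproduce_paper(fold: float = 50.0) -> dict:
    """Recompute the published concordance tables from the packaged fixtures.

    For every compound the clinical GADR flag, the exposure window and the
    TP/FP/TN/FN category are re-derived; any disagreement with the
    transcribed outcome columns raises a hard failure naming the offending
    compounds.  Returns a report with the per-compound categories, the three
    predictive capacities, sensitivity/specificity, and the exact-test
    p-value comparing the two in vitro schemes.
    """
    records, invitro, charcoal = load_tables()

    mismatches: list[str] = []
    max_dose: dict[str, str] = {}
    therapeutic: dict[str, str] = {}
    windows: dict[str, tuple[float, ...]] = {}
    for row in invitro.itertuples():
        cid = str(row.compound)
        rec = records[cid]
        gadr = rec.has_motility_gadr
        window = clinical_window(
            rec.tested_concentrations, rec.max_free_exposure, fold
        )
        windows[cid] = window

        cat_max = classify(bool(row.assay_positive_max), gadr)
        # no admissible concentration -> negative-by-window at clinical dose
        positive_clin = bool(row.assay_positive_therapeutic) and bool(window)
        cat_clin = classify(positive_clin, gadr)
        max_dose[cid] = cat_max
        therapeutic[cid] = cat_clin
        if cat_max != row.outcome_max:
            mismatches.append(
                f"{cid}: max-dose {cat_max} != printed {row.outcome_max}"
            )
        if cat_clin != row.outcome_therapeutic:
            mismatches.append(
                f"{cid}: therapeutic {cat_clin} != printed "
                f"{row.outcome_therapeutic}"
            )

    charcoal_cats: dict[str, str] = {}
    for row in charcoal.itertuples():
        cid = str(row.compound)
        positive = (
            str(row.charcoal_effect) != "NC" and bool(row.effect_within_window)
        )
        cat = classify(positive, records[cid].has_motility_gadr)
        charcoal_cats[cid] = cat
        if cat != row.outcome:
            mismatches.append(
                f"{cid}: charcoal {cat} != printed {row.outcome}"
            )

    if mismatches:
        raise ConfigurationError(
            "recomputed categories disagree with the transcribed outcomes:\n"
            + "\n".join(mismatches)
        )

    res_max = summarize(max_dose)
    res_clin = summarize(therapeutic)
    res_charcoal = summarize(charcoal_cats)
    p_schemes = compare_schemes(res_max.counts, res_clin.counts)

    report = {
        "fold_margin": fold,
        "n_compounds": len(records),
        "in_vitro_max_dose": _scheme_report(res_max),
        "in_vitro_therapeutic": _scheme_report(res_clin),
        "charcoal_meal": _scheme_report(res_charcoal),
        "scheme_comparison_p": p_schemes,
        "clinical_windows": {
            cid: list(window) for cid, window in windows.items()
        },
        "total_exposure_compounds": sorted(
            cid for cid, rec in records.items() if rec.exposure_is_total
        ),
    }
    log.info(
        "reproduced tables: capacities %s / %s / %s, scheme p=%.3f",
        Fraction(
            res_clin.counts["TP"] + res_clin.counts["TN"], res_clin.total
        ),
        Fraction(res_max.counts["TP"] + res_max.counts["TN"], res_max.total),
        Fraction(
            res_charcoal.counts["TP"] + res_charcoal.counts["TN"],
            res_charcoal.total,
        ),
        p_schemes,
    )
    return report


def baseline_cohort_run(
    n_phases: int = 99,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    params: DetectionParams | None = None,
    duration: float = 900.0,
) -> dict:
    """Simulate and quantify a cohort of independent baseline phases.

    This is the calibration experiment of the synthetic assay: ``n_phases``
    15-min vehicle phases at the default generator settings, pushed through
    baseline estimation, event detection and metric extraction.  Returns the
    cohort mean and SEM of the five metrics (phases with fewer than two
    events contribute no interval estimate).
    """
    config = config or GeneratorConfig()
    params = params or DetectionParams()
    rng = np.random.default_rng(seed)
    rows = []
    for child in rng.spawn(n_phases):
        trace, _ = simulate_phase(config, duration, rng_seed=child)
        m = quantify_phase(trace, params)
        rows.append((m.frequency, m.ti_mean, m.tiq, m.amplitude_mean, m.auc))
    arr = np.asarray(rows, dtype=float)
    names = ("frequency", "ti_mean", "tiq", "amplitude_mean", "auc")
    out: dict = {"n_phases": n_phases, "metrics": {}}
    for i, name in enumerate(names):
        col = arr[:, i]
        col = col[~np.isnan(col)]
        out["metrics"][name] = {
            "mean": float(col.mean()),
            "sem": float(col.std(ddof=1) / np.sqrt(col.size)),
            "n": int(col.size),
        }
    return out


@dataclasses.dataclass(frozen=True)
class DemoCompound:
    """A synthetic panel member with known effect model and clinical label."""

    name: str
    model: DrugEffectModel
    clinical_gadr: bool
    max_exposure: float  # uM


#: synthetic compound panel: a strong amplitude inhibitor, a frequency
#: stimulant, a null compound, and a potent inhibitor whose clinical
#: exposure makes every tested concentration clinically irrelevant
DEMO_PANEL: tuple[DemoCompound, ...] = (
    DemoCompound(
        "inhibitor",
        DrugEffectModel(
            (DrugEffect("event_amplitude", emax=4.0, ec50=1.0, hill_n=1.0,
                        direction="inhibitory"),)
        ),
        clinical_gadr=True,
        max_exposure=1.0,
    ),
    DemoCompound(
        "stimulant",
        DrugEffectModel(
            (DrugEffect("mean_interval", emax=2.2, ec50=2.0, hill_n=1.0,
                        direction="inhibitory"),)
        ),
        clinical_gadr=True,
        max_exposure=1.0,
    ),
    DemoCompound(
        "null", DrugEffectModel.null(), clinical_gadr=False, max_exposure=1.0
    ),
    DemoCompound(
        "out_of_window",
        DrugEffectModel(
            (DrugEffect("event_amplitude", emax=4.0, ec50=1.0, hill_n=1.0,
                        direction="inhibitory"),)
        ),
        clinical_gadr=False,
        max_exposure=0.001,
    ),
)


def end_to_end_demo(
    config: RunConfig | None = None,
    n_controls: int = 4,
    panel: tuple[DemoCompound, ...] = DEMO_PANEL,
) -> dict:
    """Simulate -> quantify -> call -> classify on a synthetic compound panel.

    Returns a report with the control-distribution summary, per-compound
    relative changes, assay calls at the maximum and clinical dose, and the
    concordance of the recovered calls with the panel's ground-truth labels.
    All randomness flows from ``config.seed``.
    """
    config = config or RunConfig()
    design = ExperimentDesign()
    base = GeneratorConfig()
    params = DetectionParams()
    rng = np.random.default_rng(config.seed)

    cohort = simulate_control_cohort(n_controls, design, base, rng_seed=rng)
    cohort_metrics = [
        [quantify_phase(trace, params) for trace, _ in experiment]
        for experiment in cohort
    ]
    ctrl = build_control_distribution(cohort_metrics)

    drug_phase_idx = [
        i
        for i, lab in enumerate(design.phase_labels)
        if lab not in ("vehicle", "washout")
    ]
    phase_conc = {i: design.phase_concentration(i) for i in drug_phase_idx}

    compounds = {}
    category_map = {}
    for compound in panel:
        run = simulate_experiment(design, base, compound.model, rng_seed=rng)
        metrics = [quantify_phase(trace, params) for trace, _ in run]
        changes = {
            i: {
                metric: relative_change(metrics[i], metrics[0], metric)
                for metric in DECISION_METRICS
            }
            for i in drug_phase_idx
        }
        admissible = clinical_window(
            design.concentrations, compound.max_exposure, config.fold_margin
        )
        call = call_compound(
            changes, ctrl, phase_conc, set(admissible), config.sd_multiplier
        )
        category = classify(
            call.positive_at_clinical_dose, compound.clinical_gadr
        )
        category_map[compound.name] = category
        compounds[compound.name] = {
            "relative_changes_pct": {
                f"phase{i}_{metric}": changes[i][metric].value
                for i in drug_phase_idx
                for metric in DECISION_METRICS
            },
            "positive_at_max_dose": call.positive_at_max_dose,
            "positive_at_clinical_dose": call.positive_at_clinical_dose,
            "window_empty": call.window_empty,
            "clinical_gadr": compound.clinical_gadr,
            "category": category,
        }

    result = summarize(category_map)
    return {
        "seed": config.seed,
        "n_controls": n_controls,
        "control_distribution": {
            f"phase{idx}_{metric}": {"mean_pct": mu, "sd_pct": sd}
            for (idx, metric), (mu, sd) in sorted(ctrl.stats.items())
        },
        "compounds": compounds,
        "counts": result.counts,
        "predictive_capacity": result.predictive_capacity,
    }
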