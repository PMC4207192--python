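"""Readers/writers for traces, metrics, calls, configs and packaged tables.

All artifact formats are plain text: two-column CSV traces with a JSON
sidecar (sample rate, phase boundaries, generator config, seed), annotation
and per-phase metrics CSVs, YAML/JSON configuration files mirroring the
dataclass field names, and the packaged clinical/assay fixture tables.
Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import CompoundRecord
from .quantify import DetectionParams, PhaseMetrics
from .simulate import (
    ConfigurationError,
    DrugEffect,
    DrugEffectModel,
    EventAnnotation,
    ExperimentDesign,
    GeneratorConfig,
    PressureTrace,
)

__all__ = [
    "RunConfig",
    "write_trace_csv",
    "read_trace_csv",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "load_generator_config",
    "load_drug_model",
    "load_design",
    "load_tables",
    "packaged_table",
]

log = logging.getLogger("cpmcassay")

_FINDING_CODES = {"D": True, "C": True, "NE": False}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Global knobs of a pipeline run.

    ``fold_margin`` is the clinical exposure window (default 50x maximum
    plasma exposure), ``sd_multiplier`` the positivity threshold in control
    SDs (default 2), ``alpha`` the significance level of the transit test.
    """

    seed: int = 0
    fold_margin: float = 50.0
    sd_multiplier: float = 2.0
    alpha: float = 0.05
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.fold_margin <= 0:
            raise ConfigurationError("fold_margin must be > 0")
        if self.sd_multiplier <= 0:
            raise ConfigurationError("sd_multiplier must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


# ---------------------------------------------------------------- traces

def write_trace_csv(
    path, trace: PressureTrace, config: GeneratorConfig | None = None, seed=None
) -> None:
    """Write a trace as (time_s, pressure_mmHg) CSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.times, "pressure_mmHg": trace.samples}
    )
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "sample_rate": trace.sample_rate,
        "phase_label": trace.phase_label,
        "start_time": trace.start_time,
        "n_samples": int(trace.samples.size),
        "seed": seed,
        "generator_config": dataclasses.asdict(config) if config else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    log.info("wrote trace %s (%d samples)", path, trace.samples.size)


def read_trace_csv(path) -> PressureTrace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return PressureTrace(
        samples=df["pressure_mmHg"].to_numpy(),
        sample_rate=float(sidecar["sample_rate"]),
        phase_label=sidecar["phase_label"],
        start_time=float(sidecar["start_time"]),
    )


def write_annotations_csv(path, annotations: list[EventAnnotation]) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": a.onset,
                "offset_s": a.offset,
                "peak_s": a.peak_time,
                "amplitude_mmHg": a.true_amplitude,
            }
            for a in annotations
        ],
        columns=["onset_s", "offset_s", "peak_s", "amplitude_mmHg"],
    ).to_csv(path, index=False, float_format="%.6f")


def read_annotations_csv(path) -> list[EventAnnotation]:
    df = pd.read_csv(path)
    return [
        EventAnnotation(
            onset=row.onset_s,
            offset=row.offset_s,
            peak_time=row.peak_s,
            true_amplitude=row.amplitude_mmHg,
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------- metrics

_METRIC_COLUMNS = [
    "phase_label",
    "frequency",
    "ti_mean_s",
    "tiq_s",
    "amplitude_mmHg",
    "auc_mmHg_s",
]


def write_metrics_csv(path, metrics: list[PhaseMetrics]) -> None:
    """One row per phase; NaN encodes the undefined-metric marker."""
    pd.DataFrame(
        [
            {
                "phase_label": m.phase_label,
                "frequency": m.frequency,
                "ti_mean_s": m.ti_mean,
                "tiq_s": m.tiq,
                "amplitude_mmHg": m.amplitude_mean,
                "auc_mmHg_s": m.auc,
            }
            for m in metrics
        ],
        columns=_METRIC_COLUMNS,
    ).to_csv(path, index=False)


def read_metrics_csv(path) -> list[PhaseMetrics]:
    df = pd.read_csv(path)
    return [
        PhaseMetrics(
            frequency=int(row.frequency),
            ti_mean=float(row.ti_mean_s),
            tiq=float(row.tiq_s),
            amplitude_mean=float(row.amplitude_mmHg),
            auc=float(row.auc_mmHg_s),
            phase_label=str(row.phase_label),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------- configs

def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    return data


def load_generator_config(path) -> GeneratorConfig:
    return GeneratorConfig(**_load_mapping(path))


def load_drug_model(path) -> DrugEffectModel:
    data = _load_mapping(path)
    effects = tuple(DrugEffect(**e) for e in data.get("effects", []))
    return DrugEffectModel(effects=effects)


def load_design(path) -> ExperimentDesign:
    data = _load_mapping(path)
    for key in ("phase_labels", "concentrations"):
        if key in data:
            data[key] = tuple(data[key])
    return ExperimentDesign(**data)


def load_detection_params(path) -> DetectionParams:
    return DetectionParams(**_load_mapping(path))


# ---------------------------------------------------------------- tables

def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged fixture tables by file name."""
    with resources.files("cpmcassay.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _parse_conc_list(text: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in str(text).split(";"))


def load_tables(
    clinical_path=None, invitro_path=None, charcoal_path=None
) -> tuple[dict[str, CompoundRecord], pd.DataFrame, pd.DataFrame]:
    """Load and validate the compound tables (packaged fixtures by default).

    Returns ``(records, invitro, charcoal)`` where ``records`` maps compound
    id to :class:`CompoundRecord` and the two data frames carry the in vitro
    and charcoal-meal summaries.  Compound ids must be unique, consistent
    across the three tables, and number 15 for the packaged set.
    """
    clinical = (
        pd.read_csv(clinical_path)
        if clinical_path
        else packaged_table("table1_clinical.csv")
    )
    invitro = (
        pd.read_csv(invitro_path)
        if invitro_path
        else packaged_table("table2_invitro.csv")
    )
    charcoal = (
        pd.read_csv(charcoal_path)
        if charcoal_path
        else packaged_table("table3_charcoal.csv")
    )

    if clinical["compound"].duplicated().any():
        dupes = clinical.loc[
            clinical["compound"].duplicated(), "compound"
        ].tolist()
        raise ConfigurationError(f"duplicated compound id(s): {dupes}")

    conc_by_compound = dict(
        zip(invitro["compound"], invitro["concentrations_uM"].map(_parse_conc_list))
    )
    records: dict[str, CompoundRecord] = {}
    for row in clinical.itertuples():
        cid = str(row.compound)
        records[cid] = CompoundRecord(
            compound_id=cid,
            clinical_finding=str(row.clinical_finding),
            pct_subjects_affected=float(row.pct_subjects_affected),
            min_free_exposure=float(row.min_free_exposure_uM),
            max_free_exposure=float(row.max_free_exposure_uM),
            tested_concentrations=conc_by_compound.get(cid, ()),
            exposure_is_total=bool(row.exposure_is_total),
            finding_verbatim=str(row.finding_verbatim),
        )

    for name, df in (("in vitro", invitro), ("charcoal", charcoal)):
        missing = set(df["compound"]) ^ set(records)
        if missing:
            raise ConfigurationError(
                f"{name} table ids inconsistent with clinical table: {missing}"
            )
    log.info("loaded %d compound records", len(records))
    return records, invitro, charcoal
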