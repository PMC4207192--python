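"""Translational concordance: assay calls vs clinical GADR labels.

The assay (in vitro CPMC bioassay or in vivo charcoal-meal transit test) is
treated as a binary classifier of motility-related gastrointestinal adverse
drug reactions (GADRs: diarrhea, constipation, loose stools).  Each compound
carries a clinical label and an exposure range from phase I trials; only
assay concentrations within a ``fold`` (default 50x) margin of the maximum
free plasma exposure count as clinically relevant evidence.

Compounds are cross-classified as TP / FP / TN / FN, and the headline
statistic is the predictive capacity (TP + TN) / total — the fraction of
compounds whose clinical motility outcome the assay called correctly.
Sensitivity and specificity, and an exact conditional (Fisher) comparison
of two classification schemes, are provided as supporting measures.
Nausea is *not* a motility GADR: a nausea-only compound counts as clinically
negative here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy import stats as _stats

from .simulate import ConfigurationError

__all__ = [
    "MOTILITY_FINDINGS",
    "NON_MOTILITY_FINDINGS",
    "CompoundRecord",
    "ConcordanceResult",
    "clinical_window",
    "is_motility_gadr",
    "classify",
    "summarize",
    "predictive_capacity",
    "compare_schemes",
    "derived_rates",
]

MOTILITY_FINDINGS = frozenset({"diarrhea", "constipation", "loose_stools"})
NON_MOTILITY_FINDINGS = frozenset({"nausea", "none"})

_CATEGORIES = ("TP", "FP", "TN", "FN")


@dataclass(frozen=True)
class CompoundRecord:
    """Clinical profile and tested concentrations of one compound.

    ``min_free_exposure``/``max_free_exposure`` are the mean free plasma
    exposures at the lowest and highest clinical dose (uM).  For compounds
    whose protein binding was unknown, ``exposure_is_total`` flags that the
    stated values are total rather than free plasma exposure; the window
    logic uses them unchanged but reports should flag the caveat.
    """

    compound_id: str
    clinical_finding: str
    pct_subjects_affected: float
    min_free_exposure: float
    max_free_exposure: float
    tested_concentrations: tuple[float, ...]
    exposure_is_total: bool = False
    finding_verbatim: str = ""

    def __post_init__(self) -> None:
        if self.clinical_finding not in MOTILITY_FINDINGS | NON_MOTILITY_FINDINGS:
            raise ConfigurationError(
                f"unknown clinical finding {self.clinical_finding!r}"
            )
        if not 0 < self.min_free_exposure <= self.max_free_exposure:
            raise ConfigurationError(
                f"{self.compound_id}: invalid exposure range "
                f"{self.min_free_exposure}-{self.max_free_exposure}"
            )
        if any(c <= 0 for c in self.tested_concentrations):
            raise ConfigurationError(
                f"{self.compound_id}: tested concentrations must be positive"
            )
        if list(self.tested_concentrations) != sorted(
            self.tested_concentrations
        ):
            raise ConfigurationError(
                f"{self.compound_id}: tested concentrations must be sorted"
            )

    @property
    def has_motility_gadr(self) -> bool:
        return is_motility_gadr(self.clinical_finding)


@dataclass
class ConcordanceResult:
    """Per-compound categories, the 2x2 counts, and predictive capacity."""

    categories: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in _CATEGORIES}
        for cat in self.categories.values():
            out[cat] += 1
        return out

    @property
    def total(self) -> int:
        return len(self.categories)

    @property
    def predictive_capacity(self) -> float:
        return predictive_capacity(self.counts)


def clinical_window(
    tested: tuple[float, ...] | list[float],
    max_exposure: float,
    fold: float = 50.0,
) -> tuple[float, ...]:
    """Tested concentrations within ``fold`` of the maximum clinical exposure.

    Returns the (possibly empty) subset ``{c : c <= fold * max_exposure}``.
    An empty window means the compound was only ever tested at exposures far
    beyond anything seen in patients.
    """
    if not (max_exposure > 0 and math.isfinite(max_exposure)):
        raise ConfigurationError("max_exposure must be positive and finite")
    if fold <= 0:
        raise ConfigurationError("fold margin must be positive")
    return tuple(c for c in tested if c <= fold * max_exposure)


def is_motility_gadr(finding: str) -> bool:
    """True for motility-related GADR labels (diarrhea/constipation/loose stools)."""
    if finding in MOTILITY_FINDINGS:
        return True
    if finding in NON_MOTILITY_FINDINGS:
        return False
    raise ConfigurationError(f"unknown clinical finding {finding!r}")


def classify(assay_positive: bool | None, clinical_gadr: bool) -> str | None:
    """Cross-classify one compound: (assay call, clinical label) -> category.

    A not-assessable assay call (None) yields None — the compound is to be
    excluded from the counts, with a warning.
    """
    if assay_positive is None:
        warnings.warn(
            "not-assessable assay call; compound excluded from concordance",
            stacklevel=2,
        )
        return None
    if clinical_gadr:
        return "TP" if assay_positive else "FN"
    return "FP" if assay_positive else "TN"


def summarize(category_map: dict[str, str | None]) -> ConcordanceResult:
    """Collect per-compound categories into a ConcordanceResult."""
    result = ConcordanceResult()
    for compound, cat in category_map.items():
        if cat is None:
            result.excluded.append(compound)
        elif cat in _CATEGORIES:
            result.categories[compound] = cat
        else:
            raise ConfigurationError(f"unknown category {cat!r}")
    return result


def predictive_capacity(counts: dict[str, int]) -> float:
    """(TP + TN) / total classified compounds, as a fraction in [0, 1]."""
    total = sum(counts.get(c, 0) for c in _CATEGORIES)
    if total == 0:
        raise ConfigurationError("predictive capacity undefined for 0 compounds")
    return (counts.get("TP", 0) + counts.get("TN", 0)) / total


def compare_schemes(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> float:
    """Exact conditional test comparing two classification schemes.

    Builds the 2x2 table of correct (TP+TN) vs incorrect (FP+FN) calls per
    scheme and returns the two-sided Fisher exact p-value.  Both schemes
    must classify the same number of compounds.
    """
    totals = [sum(c.get(k, 0) for k in _CATEGORIES) for c in (counts_a, counts_b)]
    if totals[0] != totals[1]:
        raise ConfigurationError(
            f"schemes classify different totals: {totals[0]} vs {totals[1]}"
        )
    if totals[0] == 0:
        raise ConfigurationError("cannot compare empty schemes")
    table = [
        [
            c.get("TP", 0) + c.get("TN", 0),
            c.get("FP", 0) + c.get("FN", 0),
        ]
        for c in (counts_a, counts_b)
    ]
    return float(_stats.fisher_exact(table, alternative="two-sided").pvalue)


def derived_rates(counts: dict[str, int]) -> tuple[float, float]:
    """(sensitivity, specificity); NaN when a denominator is zero."""
    tp, fn = counts.get("TP", 0), counts.get("FN", 0)
    tn, fp = counts.get("TN", 0), counts.get("FP", 0)
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return sens, spec
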