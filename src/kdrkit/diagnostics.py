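"""Evaluation of the Vgsc-1014 genotype as a diagnostic for resistance.

Treats a kdr-only genotype (no wild-type leucine allele, i.e. groups
Ser/Ser, Ser/Phe, Phe/Phe) as a positive test and survival of the
bioassay as the positive condition, yielding confusion counts per
insecticide, sensitivity/specificity with continuity-corrected Wilson
CIs, and per-genotype-group positive/negative predictive values at the
sample's own prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from .genotypes import GenotypeGroup, KDR_ONLY_GROUPS
from .stats import (
    ContingencyTable,
    ProportionEstimate,
    genotype_group_table,
    survival_proportion_ci,
)

__all__ = [
    "ConfusionCounts",
    "DiagnosticSummary",
    "GroupPredictiveValues",
    "UndefinedMetricError",
    "confusion_counts",
    "confusion_from_group_table",
    "sensitivity_specificity",
    "predictive_values",
]


class UndefinedMetricError(ValueError):
    """A diagnostic metric has a zero denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN under the kdr-diagnostic definitions.

    TP: alive with a kdr-only genotype; FP: dead with a kdr-only genotype;
    TN: dead with a leucine-carrying genotype; FN: alive with a
    leucine-carrying genotype.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity and specificity, in percent, with 95% CIs."""

    sensitivity: ProportionEstimate
    specificity: ProportionEstimate

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.sensitivity.estimate

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.specificity.estimate


@dataclass(frozen=True)
class GroupPredictiveValues:
    """PPV/NPV of one genotype group (``None`` when the group is empty)."""

    group: str
    n: int
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]

    @property
    def available(self) -> bool:
        return self.ppv is not None


def confusion_from_group_table(
    group_table: ContingencyTable,
    positive_groups: Sequence[GenotypeGroup] = KDR_ONLY_GROUPS,
) -> ConfusionCounts:
    """Confusion counts from an alive/dead x group table."""
    pos = [g.label for g in positive_groups if g.label in group_table.table.columns]
    neg = [c for c in group_table.table.columns if c not in pos]
    t = group_table.table
    return ConfusionCounts(
        tp=int(t.loc["alive", pos].sum()),
        fp=int(t.loc["dead", pos].sum()),
        tn=int(t.loc["dead", neg].sum()),
        fn=int(t.loc["alive", neg].sum()),
    )


def confusion_counts(
    specimens: pd.DataFrame,
    insecticide: Optional[str] = None,
    positive_groups: Sequence[GenotypeGroup] = KDR_ONLY_GROUPS,
) -> ConfusionCounts:
    """Confusion counts for one insecticide from the specimen table.

    The positivity rule (which genotype groups count as a positive test)
    defaults to kdr-only genotypes but is a parameter so alternative
    cut-points, e.g. Phe-carrying genotypes only, can be evaluated.
    """
    table = genotype_group_table(specimens, insecticide)
    return confusion_from_group_table(table, positive_groups)


def sensitivity_specificity(
    counts: ConfusionCounts, level: float = 0.95
) -> DiagnosticSummary:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with Wilson-cc CIs."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no alive specimens")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no dead specimens")
    return DiagnosticSummary(
        sensitivity=survival_proportion_ci(counts.tp, counts.tp + counts.fn, level),
        specificity=survival_proportion_ci(counts.tn, counts.tn + counts.fp, level),
    )


def predictive_values(
    specimens: pd.DataFrame,
    insecticide: Optional[str] = None,
    level: float = 0.95,
) -> Dict[str, GroupPredictiveValues]:
    """Per-group PPV (P(alive | group)) and NPV (P(dead | group)) with CIs.

    Computed at the sample's own prevalence, as appropriate for bioassay
    panels; an empty group is marked unavailable rather than zero.  Point
    estimates satisfy PPV + NPV = 1 within each group.
    """
    table = genotype_group_table(specimens, insecticide)
    out: Dict[str, GroupPredictiveValues] = {}
    for group in table.table.columns:
        alive = int(table.table.loc["alive", group])
        dead = int(table.table.loc["dead", group])
        n = alive + dead
        if n == 0:
            out[group] = GroupPredictiveValues(group=group, n=0, ppv=None, npv=None)
            continue
        out[group] = GroupPredictiveValues(
            group=group,
            n=n,
            ppv=survival_proportion_ci(alive, n, level),
            npv=survival_proportion_ci(dead, n, level),
        )
    return out
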