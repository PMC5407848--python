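"""Model/Results interface over the association and diagnostics toolkit.

``KdrAssociation`` is built from a specimen table; ``fit()`` runs, per
insecticide, the full genotype-phenotype analysis — allele and
genotype-group tables, the group chi-square, pairwise allele Fisher
tests with cross-product odds ratios and Holm correction, per-group
survival proportions with continuity-corrected Wilson CIs,
Marascuilo-McSweeney pairwise survival comparisons, and the diagnostic
evaluation (confusion counts, sensitivity/specificity, predictive
values) — returning a ``KdrAssociationResults`` whose ``summary()``
renders the familiar three-table report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .diagnostics import (
    ConfusionCounts,
    DiagnosticSummary,
    GroupPredictiveValues,
    confusion_from_group_table,
    predictive_values,
    sensitivity_specificity,
)
from .genotypes import GenotypeGroup, KDR_ONLY_GROUPS
from .io import read_specimen_table
from .stats import (
    ContingencyTable,
    HolmDecision,
    MarascuiloComparison,
    OddsRatioResult,
    ProportionEstimate,
    TestResult,
    allele_count_table,
    chi_square_rxc,
    fisher_exact_2x2,
    genotype_group_table,
    marascuilo_pairwise,
    odds_ratio,
    sequential_bonferroni,
    survival_proportion_ci,
)

__all__ = ["KdrAssociation", "KdrAssociationResults", "InsecticideResult"]

#: allele contrasts reported per insecticide, as (variant, reference).
ALLELE_CONTRASTS: Tuple[Tuple[str, str], ...] = (
    ("Ser", "Leu"),
    ("Phe", "Leu"),
    ("Phe", "Ser"),
)


@dataclass
class InsecticideResult:
    """Per-insecticide association and diagnostic results."""

    insecticide: str
    allele_table: ContingencyTable
    group_table: ContingencyTable
    fine_table: ContingencyTable
    group_chi_square: TestResult
    allele_tests: Dict[Tuple[str, str], TestResult]
    allele_odds_ratios: Dict[Tuple[str, str], OddsRatioResult]
    holm: Dict[Tuple[str, str], HolmDecision]
    survival: Dict[str, ProportionEstimate]
    marascuilo: List[MarascuiloComparison]
    confusion: ConfusionCounts
    diagnostics: DiagnosticSummary
    predictive: Dict[str, GroupPredictiveValues]


class KdrAssociation:
    """Genotype-phenotype association model for kdr bioassay data.

    Parameters
    ----------
    specimens : pandas.DataFrame
        Specimen table (see :mod:`kdrkit.io` for the schema).
    insecticides : sequence of str, optional
        Restrict the analysis; defaults to every insecticide present.
    alpha : float
        Family-wise significance level (default 0.05).
    ci_level : float
        Confidence level of all intervals (default 0.95).
    positive_groups : sequence of GenotypeGroup
        Diagnostic positivity rule; defaults to the kdr-only groups.
    """

    def __init__(
        self,
        specimens: pd.DataFrame,
        insecticides: Optional[Sequence[str]] = None,
        alpha: float = 0.05,
        ci_level: float = 0.95,
        positive_groups: Sequence[GenotypeGroup] = KDR_ONLY_GROUPS,
    ) -> None:
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.specimens = specimens
        self.insecticides = list(
            insecticides
            if insecticides is not None
            else pd.unique(specimens["insecticide"].dropna())
        )
        self.alpha = alpha
        self.ci_level = ci_level
        self.positive_groups = tuple(positive_groups)

    @classmethod
    def from_table(cls, path, sep: str = "\t", **kwargs) -> "KdrAssociation":
        """Build the model from a delimited specimen file."""
        return cls(read_specimen_table(path, sep=sep), **kwargs)

    def fit(self) -> "KdrAssociationResults":
        per_ins: Dict[str, InsecticideResult] = {}
        for ins in self.insecticides:
            per_ins[ins] = self._fit_one(ins)
        return KdrAssociationResults(
            model=self, results=per_ins, alpha=self.alpha, ci_level=self.ci_level
        )

    def _fit_one(self, insecticide: str) -> InsecticideResult:
        allele = allele_count_table(self.specimens, insecticide)
        group = genotype_group_table(self.specimens, insecticide)
        fine = genotype_group_table(self.specimens, insecticide, leu_split=True)

        chi2 = chi_square_rxc(group)

        tests: Dict[Tuple[str, str], TestResult] = {}
        ors: Dict[Tuple[str, str], OddsRatioResult] = {}
        for variant, ref in ALLELE_CONTRASTS:
            sub = allele.table[[variant, ref]]
            tests[(variant, ref)] = fisher_exact_2x2(sub)
            ors[(variant, ref)] = odds_ratio(sub, level=self.ci_level)
        decisions = sequential_bonferroni(
            [tests[c].pvalue for c in ALLELE_CONTRASTS], alpha=self.alpha
        )
        holm = dict(zip(ALLELE_CONTRASTS, decisions))

        survival: Dict[str, ProportionEstimate] = {}
        groups_kn: List[Tuple[int, int]] = []
        labels: List[str] = []
        for col in group.table.columns:
            alive = int(group.table.loc["alive", col])
            n = int(group.table[col].sum())
            if n > 0:
                survival[col] = survival_proportion_ci(alive, n, self.ci_level)
                groups_kn.append((alive, n))
                labels.append(col)
        marascuilo = (
            marascuilo_pairwise(groups_kn, alpha=self.alpha, labels=labels)
            if len(groups_kn) >= 2
            else []
        )

        confusion = confusion_from_group_table(group, self.positive_groups)
        diag = sensitivity_specificity(confusion, self.ci_level)
        pred = predictive_values(self.specimens, insecticide, self.ci_level)

        return InsecticideResult(
            insecticide=insecticide,
            allele_table=allele,
            group_table=group,
            fine_table=fine,
            group_chi_square=chi2,
            allele_tests=tests,
            allele_odds_ratios=ors,
            holm=holm,
            survival=survival,
            marascuilo=marascuilo,
            confusion=confusion,
            diagnostics=diag,
            predictive=pred,
        )


@dataclass
class KdrAssociationResults:
    """Fitted results; display rounding is 1 d.p. for chi-squares and
    percentages, 2 d.p. for odds ratios, while the stored objects keep
    full precision."""

    model: KdrAssociation
    results: Dict[str, InsecticideResult]
    alpha: float
    ci_level: float

    def __getitem__(self, insecticide: str) -> InsecticideResult:
        return self.results[insecticide]

    @property
    def insecticides(self) -> List[str]:
        return list(self.results)

    def summary(self) -> str:
        lines: List[str] = []
        lines.append("Vgsc-1014 genotype-phenotype association summary")
        lines.append(
            f"kdrkit {__version__} | alpha = {self.alpha} | "
            f"CI level = {self.ci_level} (Wilson, continuity-corrected) | "
            f"OR estimator = cross-product (Haldane +0.5 on zero cells)"
        )
        for ins, res in self.results.items():
            lines.append("")
            lines.append(f"=== {ins} ===")
            lines.append("Allele counts (alive/dead x Leu/Ser/Phe):")
            lines.append(res.allele_table.table.to_string())
            for contrast in res.allele_tests:
                t = res.allele_tests[contrast]
                o = res.allele_odds_ratios[contrast]
                h = res.holm[contrast]
                lines.append(
                    f"  {contrast[0]} vs {contrast[1]}: OR = {o.oddsratio:.2f} "
                    f"({o.ci_low:.2f}-{o.ci_high:.2f}), Fisher P = {t.pvalue:.3g}"
                    f"{' *' if h.reject else ''}"
                )
            lines.append("Genotype-group counts:")
            lines.append(res.group_table.table.to_string())
            chi = res.group_chi_square
            lines.append(
                f"  group chi-square: chi2_{chi.df} = {chi.statistic:.1f}, "
                f"P = {chi.pvalue:.3g}"
            )
            lines.append("Survival proportions (95% CI):")
            for label, est in res.survival.items():
                lines.append(
                    f"  {label}: {est.k}/{est.n} = {est.estimate:.2f} "
                    f"({est.ci_low:.2f}-{est.ci_high:.2f})"
                )
            c = res.confusion
            d = res.diagnostics
            lines.append(
                f"Diagnostics (kdr-only positive): TP={c.tp} FP={c.fp} "
                f"TN={c.tn} FN={c.fn}"
            )
            lines.append(
                f"  sensitivity = {d.sensitivity_pct:.1f}% "
                f"({100 * d.sensitivity.ci_low:.0f}-{100 * d.sensitivity.ci_high:.0f}), "
                f"specificity = {d.specificity_pct:.1f}% "
                f"({100 * d.specificity.ci_low:.0f}-{100 * d.specificity.ci_high:.0f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> Dict[str, dict]:
        """Machine-readable nested summary (full precision)."""
        out: Dict[str, dict] = {
            "config": {
                "alpha": self.alpha,
                "ci_level": self.ci_level,
                "ci_method": "wilson-cc",
                "or_estimator": "cross-product",
                "version": __version__,
            }
        }
        for ins, res in self.results.items():
            out[ins] = {
                "allele_table": res.allele_table.table.to_dict(),
                "group_table": res.group_table.table.to_dict(),
                "group_chi_square": {
                    "statistic": res.group_chi_square.statistic,
                    "df": res.group_chi_square.df,
                    "pvalue": res.group_chi_square.pvalue,
                },
                "odds_ratios": {
                    f"{v}_vs_{r}": {
                        "or": o.oddsratio,
                        "ci": [o.ci_low, o.ci_high],
                        "estimator": o.estimator,
                        "fisher_p": res.allele_tests[(v, r)].pvalue,
                        "holm_reject": res.holm[(v, r)].reject,
                    }
                    for (v, r), o in res.allele_odds_ratios.items()
                },
                "survival": {
                    label: {
                        "k": e.k, "n": e.n, "estimate": e.estimate,
                        "ci": [e.ci_low, e.ci_high],
                    }
                    for label, e in res.survival.items()
                },
                "diagnostics": {
                    "tp": res.confusion.tp, "fp": res.confusion.fp,
                    "tn": res.confusion.tn, "fn": res.confusion.fn,
                    "sensitivity_pct": res.diagnostics.sensitivity_pct,
                    "sensitivity_ci_pct": [
                        100 * res.diagnostics.sensitivity.ci_low,
                        100 * res.diagnostics.sensitivity.ci_high,
                    ],
                    "specificity_pct": res.diagnostics.specificity_pct,
                    "specificity_ci_pct": [
                        100 * res.diagnostics.specificity.ci_low,
                        100 * res.diagnostics.specificity.ci_high,
                    ],
                },
                "predictive_values": {
                    label: (
                        None
                        if not pv.available
                        else {
                            "n": pv.n,
                            "ppv": pv.ppv.estimate,
                            "ppv_ci": [pv.ppv.ci_low, pv.ppv.ci_high],
                            "npv": pv.npv.estimate,
                            "npv_ci": [pv.npv.ci_low, pv.npv.ci_high],
                        }
                    )
                    for label, pv in res.predictive.items()
                },
            }
        return out
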