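"""Bioassay association statistics for outcome x genotype data.

Implements the statistical toolkit used to relate Vgsc-1014 genotypes to
insecticide bioassay outcome: Abbott control-mortality correction,
outcome x allele and outcome x genotype-group contingency tables, Pearson
chi-square and Fisher exact tests, cross-product odds ratios with Woolf
confidence intervals, continuity-corrected Wilson score intervals for
survival proportions, Marascuilo-McSweeney pairwise comparison of several
proportions, and Holm's sequential Bonferroni correction.

Specimens enter as a pandas DataFrame with one row per bioassayed sand
fly (columns: ``id``, ``insecticide``, ``outcome`` in {alive, dead},
``role`` in {test, control}, ``genotype`` as ``"TTA/TCA"`` labels, plus
optional site columns).  A live female 24 h post-exposure is classed
resistant (DDT) or tolerant (pyrethroids); a dead one susceptible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import (
    GenotypeGroup,
    KdrGenotype,
    RESIDUE_ORDER,
    classify_group,
    fine_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES",
    "GROUP_LABELS",
    "FINE_LABELS",
    "AbbottResult",
    "ContingencyTable",
    "TestResult",
    "OddsRatioResult",
    "ProportionEstimate",
    "MarascuiloComparison",
    "HolmDecision",
    "DegenerateTableError",
    "abbott_correction",
    "allele_count_table",
    "genotype_group_table",
    "chi_square_rxc",
    "fisher_exact_2x2",
    "odds_ratio",
    "survival_proportion_ci",
    "marascuilo_pairwise",
    "sequential_bonferroni",
    "allele_homogeneity_test",
]

OUTCOMES: Tuple[str, str] = ("alive", "dead")
GROUP_LABELS: Tuple[str, ...] = tuple(g.label for g in GenotypeGroup)
FINE_LABELS: Tuple[str, ...] = (
    "Leu/Leu", "Leu/Ser", "Leu/Phe", "Ser/Ser", "Ser/Phe", "Phe/Phe",
)


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Outcome x category count matrix with derived margins."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.table.to_numpy()
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        self.table = self.table.astype(int)

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def select(self, columns: Sequence[str]) -> "ContingencyTable":
        return ContingencyTable(self.table[list(columns)].copy())

    def relative(self) -> pd.DataFrame:
        """Row-wise relative percentage frequencies."""
        return self.table.div(self.row_totals, axis=0) * 100.0


TableLike = Union[ContingencyTable, pd.DataFrame, np.ndarray, Sequence[Sequence[int]]]


def _as_array(table: TableLike) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    if isinstance(table, pd.DataFrame):
        return table.to_numpy()
    return np.asarray(table, dtype=float)


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom and p-value of one hypothesis test."""

    statistic: Optional[float]
    df: Optional[int]
    pvalue: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.method.startswith("pearson") and (self.df is None or self.df < 1):
            raise ValueError("chi-square test requires df >= 1")


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    estimator: str  # "cross-product" or "cross-product-haldane"

    def __post_init__(self) -> None:
        if self.oddsratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci_low <= self.oddsratio <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class ProportionEstimate:
    """k/n with a continuity-corrected Wilson score interval."""

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError("proportion CI ordering violated")


@dataclass(frozen=True)
class AbbottResult:
    """Outcome of Abbott's control-mortality correction.

    ``verdict`` is one of ``uncorrected`` (control mortality below the
    correction threshold), ``corrected`` (formula applied) or ``discard``
    (control mortality too high; ``value`` is ``None``).
    """

    value: Optional[float]
    verdict: str
    test_mortality: float
    control_mortality: float


@dataclass(frozen=True)
class MarascuiloComparison:
    label_i: str
    label_j: str
    p_i: float
    p_j: float
    difference: float
    critical_range: float
    significant: bool
    pvalue: float
    boundary: bool = False


@dataclass(frozen=True)
class HolmDecision:
    pvalue: float
    threshold: float
    reject: bool


# ---------------------------------------------------------------------------
# Abbott correction
# ---------------------------------------------------------------------------


def abbott_correction(
    test_mortality_pct: float,
    control_mortality_pct: float,
    *,
    no_correction_below: float = 5.0,
    discard_above: float = 20.0,
) -> AbbottResult:
    """Correct a test mortality percentage for control mortality.

    Follows the WHO gating convention: control mortality below
    ``no_correction_below`` leaves the test mortality unchanged; between
    the thresholds the correction ``100*(T-C)/(100-C)`` is applied; above
    ``discard_above`` the assay is discarded.
    """
    for name, v in (
        ("test", test_mortality_pct),
        ("control", control_mortality_pct),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} mortality must be a percentage in [0, 100]")
    t, c = float(test_mortality_pct), float(control_mortality_pct)
    if c < no_correction_below:
        return AbbottResult(t, "uncorrected", t, c)
    if c > discard_above:
        return AbbottResult(None, "discard", t, c)
    if c >= 100.0:
        raise ValueError("Abbott correction undefined at 100% control mortality")
    return AbbottResult(100.0 * (t - c) / (100.0 - c), "corrected", t, c)


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------


def _test_specimens(
    specimens: pd.DataFrame, insecticide: Optional[str]
) -> pd.DataFrame:
    df = specimens
    if insecticide is not None:
        df = df[df["insecticide"] == insecticide]
    if "role" in df.columns:
        df = df[df["role"] == "test"]
    n_missing = int(df["genotype"].isna().sum()) if "genotype" in df.columns else len(df)
    if "genotype" not in df.columns:
        raise ValueError("specimen table lacks a 'genotype' column")
    if n_missing:
        logger.info(
            "excluded %d ungenotyped specimen(s) for insecticide %s",
            n_missing,
            insecticide,
        )
    return df[df["genotype"].notna()]


def allele_count_table(
    specimens: pd.DataFrame, insecticide: Optional[str] = None
) -> ContingencyTable:
    """Alive/dead x Leu/Ser/Phe allele count table (2 alleles per fly).

    The two phenylalanine codons TTT and TTC are pooled.  Ungenotyped or
    control specimens are excluded (logged).
    """
    df = _test_specimens(specimens, insecticide)
    counts = pd.DataFrame(0, index=list(OUTCOMES), columns=list(RESIDUE_ORDER))
    for outcome, label in zip(df["outcome"], df["genotype"]):
        gt = KdrGenotype.from_label(label)
        for residue in gt.residue_pair:
            counts.loc[outcome, residue] += 1
    return ContingencyTable(counts)


def genotype_group_table(
    specimens: pd.DataFrame,
    insecticide: Optional[str] = None,
    leu_split: bool = False,
) -> ContingencyTable:
    """Alive/dead x genotype-group count table.

    With ``leu_split`` the Leu/* group expands into Leu/Leu, Leu/Ser and
    Leu/Phe (needed to expose survival heterogeneity among wild-type
    carriers, e.g. under deltamethrin).
    """
    columns = list(FINE_LABELS) if leu_split else list(GROUP_LABELS)
    df = _test_specimens(specimens, insecticide)
    counts = pd.DataFrame(0, index=list(OUTCOMES), columns=columns)
    for outcome, label in zip(df["outcome"], df["genotype"]):
        gt = KdrGenotype.from_label(label)
        col = fine_label(gt) if leu_split else classify_group(gt).label
        counts.loc[outcome, col] += 1
    return ContingencyTable(counts)


# ---------------------------------------------------------------------------
# Tests and effect sizes
# ---------------------------------------------------------------------------


def chi_square_rxc(table: TableLike) -> TestResult:
    """Pearson chi-square on an R x C table (no continuity correction)."""
    arr = _as_array(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-square requires at least a 2x2 table")
    row_tot = arr.sum(axis=1)
    col_tot = arr.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        labels = _margin_labels(table, row_tot, col_tot)
        raise DegenerateTableError(f"zero margin for level(s): {labels}")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(float(stat), int(df), float(p), "pearson-chi-square")


def _margin_labels(table: TableLike, row_tot, col_tot) -> List[str]:
    if isinstance(table, ContingencyTable):
        frame = table.table
    elif isinstance(table, pd.DataFrame):
        frame = table
    else:
        frame = pd.DataFrame(_as_array(table))
    out = [str(frame.index[i]) for i in np.nonzero(row_tot == 0)[0]]
    out += [str(frame.columns[j]) for j in np.nonzero(col_tot == 0)[0]]
    return out


def fisher_exact_2x2(table: TableLike) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided p sums all hypergeometric outcomes with point probability at
    most that of the observed table (the usual convention; other two-sided
    rules exist, so printed p-values from other software may differ
    slightly).
    """
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    oddsratio, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(oddsratio), None, float(p), "fisher-exact")


def odds_ratio(table: TableLike, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio (ad/bc) with a Woolf logit CI.

    A zero cell triggers the Haldane-Anscombe +0.5 adjustment on all four
    cells (tagged ``cross-product-haldane``).
    """
    arr = _as_array(table).astype(float)
    if arr.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    a, b = arr[0]
    c, d = arr[1]
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: an entire row or column is zero")
    estimator = "cross-product"
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        estimator = "cross-product-haldane"
    or_ = (a * d) / (b * c)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        oddsratio=float(or_),
        ci_low=float(or_ * math.exp(-z * se)),
        ci_high=float(or_ * math.exp(z * se)),
        estimator=estimator,
    )


def survival_proportion_ci(
    k: int, n: int, level: float = 0.95
) -> ProportionEstimate:
    """Proportion k/n with a continuity-corrected Wilson score interval.

    The Newcombe continuity-corrected Wilson interval respects [0, 1],
    collapses to 0 (or 1) at the boundaries k=0 (k=n), and is mildly
    conservative; it is used for survival proportions, sensitivities,
    specificities and predictive values alike.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    z = sps.norm.ppf(1 - (1 - level) / 2)
    z2 = z * z
    denom = 2 * (n + z2)
    if k == 0:
        low = 0.0
    else:
        arg = max(0.0, z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        low = max(0.0, (2 * n * p + z2 - 1 - z * math.sqrt(arg)) / denom)
    if k == n:
        high = 1.0
    else:
        arg = max(0.0, z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        high = min(1.0, (2 * n * p + z2 + 1 + z * math.sqrt(arg)) / denom)
    return ProportionEstimate(k=int(k), n=int(n), estimate=p,
                              ci_low=low, ci_high=high, level=level)


def marascuilo_pairwise(
    groups: Sequence[Tuple[int, int]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
    k: Optional[int] = None,
) -> List[MarascuiloComparison]:
    """Marascuilo-McSweeney pairwise comparison of K proportions.

    For each pair the absolute difference in proportions is compared to the
    critical range ``sqrt(chi2_{1-alpha, K-1}) * sqrt(v_i + v_j)`` where
    ``v = p(1-p)/n``; a per-pair p-value is obtained McSweeney-style as the
    upper chi-square(K-1) tail of the squared standardized difference.  K
    (the number of groups entering the family) defaults to ``len(groups)``
    and may be passed explicitly when pairs are drawn from a larger family.

    When both proportions sit on the {0, 1} boundary (zero variance) and
    differ, the variance of each boundary group is replaced by that of the
    shrunk proportion ``(k+0.5)/(n+1)`` and the comparison is flagged
    ``boundary``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 1 for _, n in groups):
        raise ValueError("all group sizes must be >= 1")
    K = k if k is not None else len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    crit_chi2 = sps.chi2.ppf(1 - alpha, K - 1)
    out: List[MarascuiloComparison] = []
    props = [(ki / ni, ki, ni) for ki, ni in groups]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_i, k_i, n_i = props[i]
            p_j, k_j, n_j = props[j]
            v_i = p_i * (1 - p_i) / n_i
            v_j = p_j * (1 - p_j) / n_j
            diff = abs(p_i - p_j)
            boundary = False
            if v_i + v_j == 0.0:
                if diff == 0.0:
                    out.append(
                        MarascuiloComparison(labels[i], labels[j], p_i, p_j,
                                             0.0, 0.0, False, 1.0)
                    )
                    continue
                boundary = True
                pt_i = (k_i + 0.5) / (n_i + 1)
                pt_j = (k_j + 0.5) / (n_j + 1)
                v_i = pt_i * (1 - pt_i) / n_i
                v_j = pt_j * (1 - pt_j) / n_j
            critical = math.sqrt(crit_chi2) * math.sqrt(v_i + v_j)
            z2 = diff * diff / (v_i + v_j)
            pval = float(sps.chi2.sf(z2, K - 1))
            out.append(
                MarascuiloComparison(
                    label_i=labels[i], label_j=labels[j], p_i=p_i, p_j=p_j,
                    difference=diff, critical_range=critical,
                    significant=bool(diff > critical), pvalue=pval,
                    boundary=boundary,
                )
            )
    return out


def sequential_bonferroni(
    pvalues: Sequence[float], alpha: float = 0.05
) -> List[HolmDecision]:
    """Holm step-down (sequential Bonferroni) decisions, in input order.

    Sorted ascending, p(i) is compared to alpha/(m-i+1); the first failure
    stops all later rejections, so decisions are monotone in sorted order.
    """
    if any(not 0.0 <= p <= 1.0 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvalues)
    decisions: List[Optional[HolmDecision]] = [None] * m
    failed = False
    order = sorted(range(m), key=lambda i: pvalues[i])
    for rank, idx in enumerate(order):
        threshold = alpha / (m - rank)
        reject = (not failed) and pvalues[idx] <= threshold
        if not reject:
            failed = True
        decisions[idx] = HolmDecision(pvalues[idx], threshold, reject)
    return [d for d in decisions if d is not None]


def allele_homogeneity_test(
    per_insecticide_tables: Mapping[str, TableLike],
    alpha: float = 0.05,
) -> Tuple[Dict[str, TestResult], float]:
    """Fisher test of outcome homogeneity between the TTC and TTT codons.

    One 2x2 (alive/dead x TTC/TTT) table per insecticide; returns the
    per-insecticide results and the minimum p across insecticides.  A
    minimum p below ``alpha`` argues against pooling the two phenylalanine
    codons and emits a warning.
    """
    results = {
        ins: fisher_exact_2x2(tab) for ins, tab in per_insecticide_tables.items()
    }
    if not results:
        raise ValueError("no tables supplied")
    min_p = min(r.pvalue for r in results.values())
    if min_p < alpha:
        warnings.warn(
            f"TTC vs TTT outcome distributions differ (min p = {min_p:.3g}); "
            "pooling the phenylalanine codons may be inappropriate",
            stacklevel=2,
        )
    return results, min_p
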