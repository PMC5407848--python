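"""Per-site frequency summaries, differentiation tests and HWE testing.

Works on per-site genotype counts at the multi-allelic Vgsc-1014 locus.
By default alleles are pooled to the residue level (Leu/Ser/Phe, three
alleles) mirroring the phenotypic pooling of the two Phe codons;
codon-level (four-allele) analysis is available via ``level="codon"``.

Hardy-Weinberg testing offers three routes: an asymptotic chi-square, an
exact test by full enumeration of genotype tables conditional on the
allele counts, and a Monte-Carlo test that shuffles the 2n gametes
(Guo-Thompson style) and is reproducible bit-for-bit given (counts,
replicates, seed).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import ALLELE_ORDER, KdrGenotype, RESIDUE_ORDER, classify_group
from .stats import TestResult, chi_square_rxc, survival_proportion_ci

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSample",
    "SiteFrequencies",
    "HweResult",
    "sites_from_specimens",
    "site_frequencies",
    "compare_populations",
    "hwe_test",
]


def _alleles_for(level: str) -> Tuple[str, ...]:
    if level == "residue":
        return RESIDUE_ORDER
    if level == "codon":
        return ALLELE_ORDER
    raise ValueError("level must be 'residue' or 'codon'")


@dataclass
class SiteSample:
    """Genotype counts for one collection site (district/PHC/village)."""

    district: str
    genotype_counts: Dict[str, int] = field(default_factory=dict)
    phc: Optional[str] = None
    village: Optional[str] = None
    level: str = "residue"

    def __post_init__(self) -> None:
        _alleles_for(self.level)
        for label, c in self.genotype_counts.items():
            if c < 0:
                raise ValueError(f"negative count for {label}")
            a, b = label.split("/")
            for allele in (a, b):
                if allele not in _alleles_for(self.level):
                    raise ValueError(f"allele {allele!r} not valid at {self.level} level")

    @property
    def n(self) -> int:
        return sum(self.genotype_counts.values())

    def allele_counts(self) -> Dict[str, int]:
        """Counts over 2n gametes."""
        counts = {a: 0 for a in _alleles_for(self.level)}
        for label, c in self.genotype_counts.items():
            a, b = label.split("/")
            counts[a] += c
            counts[b] += c
        return counts

    def group_counts(self) -> Dict[str, int]:
        """Individual counts over the four dominance groups (residue level)."""
        if self.level != "residue":
            raise ValueError("group counts require residue-level genotypes")
        out: Dict[str, int] = {}
        for label, c in self.genotype_counts.items():
            group = "Leu/*" if "Leu" in label.split("/") else label
            out[group] = out.get(group, 0) + c
        return out


def sites_from_specimens(
    specimens: pd.DataFrame,
    pooling: str = "district",
    level: str = "residue",
) -> List[SiteSample]:
    """Aggregate a specimen table into per-site genotype counts.

    ``pooling`` picks the grouping column (village, phc or district,
    defaulting to district as for the headline between-district tests).
    """
    if pooling not in ("district", "phc", "village"):
        raise ValueError("pooling must be district, phc or village")
    df = specimens[specimens["genotype"].notna()]
    out: List[SiteSample] = []
    for key, sub in df.groupby(pooling, sort=True):
        counts: Dict[str, int] = {}
        for label in sub["genotype"]:
            gt = KdrGenotype.from_label(label)
            glabel = gt.residue_label if level == "residue" else gt.label
            counts[glabel] = counts.get(glabel, 0) + 1
        out.append(
            SiteSample(district=str(key), genotype_counts=counts, level=level)
        )
    return out


@dataclass(frozen=True)
class SiteFrequencies:
    alleles: pd.DataFrame  # count, frequency, ci_low, ci_high per allele
    groups: Optional[pd.DataFrame]  # same per dominance group


def site_frequencies(sample: SiteSample, ci_level: float = 0.95) -> SiteFrequencies:
    """Allele (2n denominator) and group (n denominator) relative frequencies."""
    if sample.n < 1:
        raise ValueError("empty site sample")
    two_n = 2 * sample.n
    rows = []
    for allele, count in sample.allele_counts().items():
        est = survival_proportion_ci(count, two_n, ci_level)
        rows.append(
            {"allele": allele, "count": count, "frequency": est.estimate,
             "ci_low": est.ci_low, "ci_high": est.ci_high}
        )
    alleles = pd.DataFrame(rows).set_index("allele")
    groups = None
    if sample.level == "residue":
        grows = []
        for group, count in sorted(sample.group_counts().items()):
            est = survival_proportion_ci(count, sample.n, ci_level)
            grows.append(
                {"group": group, "count": count, "frequency": est.estimate,
                 "ci_low": est.ci_low, "ci_high": est.ci_high}
            )
        groups = pd.DataFrame(grows).set_index("group")
    return SiteFrequencies(alleles=alleles, groups=groups)


def compare_populations(
    a: SiteSample, b: SiteSample, level: str = "allele"
) -> TestResult:
    """Chi-square comparison of two site samples.

    ``level="allele"`` compares allele counts (2n gametes per site, df =
    number of shared alleles - 1); ``level="genotype-group"`` compares
    individuals across the four dominance groups.  Categories absent from
    both samples are dropped (df reduced, logged).  Symmetric in (a, b).
    """
    if a.n < 1 or b.n < 1:
        raise ValueError("both samples must be non-empty")
    if level == "allele":
        ca, cb = a.allele_counts(), b.allele_counts()
    elif level == "genotype-group":
        ca, cb = a.group_counts(), b.group_counts()
    else:
        raise ValueError("level must be 'allele' or 'genotype-group'")
    cats = sorted(set(ca) | set(cb))
    kept = [c for c in cats if ca.get(c, 0) + cb.get(c, 0) > 0]
    dropped = [c for c in cats if c not in kept]
    if dropped:
        logger.info("dropping categories absent from both samples: %s", dropped)
    table = pd.DataFrame(
        [[ca.get(c, 0) for c in kept], [cb.get(c, 0) for c in kept]],
        index=[a.district, b.district],
        columns=kept,
    )
    return chi_square_rxc(table)


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HweResult:
    observed: Dict[str, int]
    expected: Dict[str, float]
    pvalue: float
    method: str
    statistic: Optional[float] = None
    df: Optional[int] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None


def _counts_matrix(sample: SiteSample) -> Tuple[List[str], np.ndarray]:
    """Observed alleles (in canonical order) and symmetric genotype-count matrix."""
    order = _alleles_for(sample.level)
    observed_alleles = [a for a, c in sample.allele_counts().items() if c > 0]
    alleles = [a for a in order if a in observed_alleles]
    idx = {a: i for i, a in enumerate(alleles)}
    mat = np.zeros((len(alleles), len(alleles)), dtype=int)
    for label, c in sample.genotype_counts.items():
        a, b = label.split("/")
        if c == 0:
            continue
        i, j = sorted((idx[a], idx[b]))
        mat[i, j] += c
    return alleles, mat


def _genotype_label(alleles: List[str], i: int, j: int) -> str:
    return f"{alleles[i]}/{alleles[j]}"


def _log_prob(mat: np.ndarray, allele_counts: np.ndarray) -> float:
    """log P(genotype table | allele counts) under HWE (conditional law)."""
    n = int(mat.sum())
    two_n = int(allele_counts.sum())
    het = int(mat.sum() - np.trace(mat))
    lp = math.lgamma(n + 1) + het * math.log(2)
    for i in range(mat.shape[0]):
        for j in range(i, mat.shape[1]):
            lp -= math.lgamma(mat[i, j] + 1)
    lp += sum(math.lgamma(m + 1) for m in allele_counts)
    lp -= math.lgamma(two_n + 1)
    return lp


def _expected_counts(alleles: List[str], allele_counts: np.ndarray, n: int) -> Dict[str, float]:
    p = allele_counts / allele_counts.sum()
    out: Dict[str, float] = {}
    for i in range(len(alleles)):
        for j in range(i, len(alleles)):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            out[_genotype_label(alleles, i, j)] = float(e)
    return out


def _enumerate_tables(allele_counts: np.ndarray):
    """Yield all genotype-count matrices consistent with the allele counts."""
    A = len(allele_counts)
    pairs = list(itertools.combinations(range(A), 2))

    def rec(k: int, remaining: np.ndarray, het: Dict[Tuple[int, int], int]):
        if k == len(pairs):
            if all(r % 2 == 0 for r in remaining):
                mat = np.zeros((A, A), dtype=int)
                for (i, j), c in het.items():
                    mat[i, j] = c
                for i in range(A):
                    mat[i, i] = remaining[i] // 2
                yield mat
            return
        i, j = pairs[k]
        for c in range(min(remaining[i], remaining[j]) + 1):
            nxt = remaining.copy()
            nxt[i] -= c
            nxt[j] -= c
            het[(i, j)] = c
            yield from rec(k + 1, nxt, het)
        het.pop((i, j), None)

    yield from rec(0, allele_counts.copy(), {})


def _exact_pvalue(mat: np.ndarray, allele_counts: np.ndarray) -> float:
    lp_obs = _log_prob(mat, allele_counts)
    total = 0.0
    psum = 0.0
    for table in _enumerate_tables(allele_counts):
        lp = _log_prob(table, allele_counts)
        p = math.exp(lp)
        total += p
        if lp <= lp_obs + 1e-9:
            psum += p
    return min(1.0, psum / total)  # total ~ 1; normalize against round-off


def _mc_pvalue(
    mat: np.ndarray, allele_counts: np.ndarray, replicates: int, seed: Optional[int]
) -> float:
    rng = np.random.default_rng(seed)
    lp_obs = _log_prob(mat, allele_counts)
    genes = np.repeat(np.arange(len(allele_counts)), allele_counts)
    A = len(allele_counts)
    hits = 0
    for _ in range(replicates):
        rng.shuffle(genes)
        sim = np.zeros((A, A), dtype=int)
        pairs = genes.reshape(-1, 2)
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        np.add.at(sim, (lo, hi), 1)
        if _log_prob(sim, allele_counts) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (replicates + 1)


def hwe_test(
    sample: SiteSample,
    method: str = "auto",
    replicates: int = 10000,
    seed: Optional[int] = None,
) -> HweResult:
    """Multi-allelic Hardy-Weinberg test on one site sample.

    ``method`` is one of ``chi-square``, ``exact-enumeration``,
    ``monte-carlo`` or ``auto`` (exact for n <= 50, Monte-Carlo beyond).
    The exact test enumerates every genotype table conditional on the
    allele counts; the Monte-Carlo test shuffles the 2n gametes and uses
    the conditional probability as orderings statistic, returning
    ``(hits + 1)/(replicates + 1)``.  A monomorphic sample yields p = 1.
    """
    alleles, mat = _counts_matrix(sample)
    n = sample.n
    if n < 1:
        raise ValueError("empty sample")
    allele_counts = np.array(
        [sample.allele_counts()[a] for a in alleles], dtype=int
    )
    observed = {
        _genotype_label(alleles, i, j): int(mat[i, j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
        if mat[i, j] > 0
    }
    if len(alleles) < 2:
        return HweResult(observed=observed, expected=_expected_counts(alleles, allele_counts, n),
                         pvalue=1.0, method="monomorphic")
    expected = _expected_counts(alleles, allele_counts, n)

    if method == "auto":
        method = "exact-enumeration" if n <= 50 else "monte-carlo"

    if method == "chi-square":
        if n < 5:
            warnings.warn("chi-square HWE test unreliable for n < 5", stacklevel=2)
        exp = np.array(list(expected.values()))
        obs = np.array(
            [
                mat[i, j]
                for i in range(len(alleles))
                for j in range(i, len(alleles))
            ],
            dtype=float,
        )
        if (exp < 5).any():
            warnings.warn(
                "expected genotype count < 5; prefer the exact or Monte-Carlo test",
                stacklevel=2,
            )
        stat = float(((obs - exp) ** 2 / exp).sum())
        A = len(alleles)
        df = A * (A - 1) // 2
        from scipy import stats as sps

        return HweResult(observed=observed, expected=expected,
                         pvalue=float(sps.chi2.sf(stat, df)), method="chi-square",
                         statistic=stat, df=df)
    if method == "exact-enumeration":
        p = _exact_pvalue(mat, allele_counts)
        return HweResult(observed=observed, expected=expected, pvalue=p,
                         method="exact-enumeration")
    if method == "monte-carlo":
        p = _mc_pvalue(mat, allele_counts, replicates, seed)
        return HweResult(observed=observed, expected=expected, pvalue=p,
                         method="monte-carlo", replicates=replicates, seed=seed)
    raise ValueError(f"unknown HWE method: {method}")
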