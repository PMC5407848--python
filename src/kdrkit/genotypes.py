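"""Allele and genotype model at voltage-gated sodium channel codon 1014.

Knockdown resistance (*kdr*) in *Phlebotomus argentipes* is driven by
substitutions of the wild-type leucine at codon 1014 of the *Vgsc* gene
(house-fly numbering).  Four codon-level alleles are modelled:

======  =======  ==========================
codon   residue  class
======  =======  ==========================
TTA     Leu      wild type (susceptible)
TCA     Ser      L1014S
TTT     Phe      L1014F
TTC     Phe      L1014F (alternate codon)
======  =======  ==========================

The two phenylalanine codons are phenotypically equivalent and are pooled
at the residue level, giving 10 codon-level and 6 residue-level genotypes.
Genotypes are classified into four dominance groups — ``Leu/*`` (any
genotype carrying at least one wild-type allele, reflecting the largely
recessive action of the kdr alleles), ``Ser/Ser``, ``Ser/Phe`` and
``Phe/Phe``.

The module also implements the dual SNP-assay call model: assay 1
discriminates the 2nd codon position (TTA vs. TCA), assay 2 the 3rd
position (TTC vs. TTT), and the two calls are combined into the 1014
genotype.  Each fluorescent probe is assumed to detect exactly one codon
(exact-match probe model); alleles not matching any probe of an assay give
no signal on that assay.  Under this model every one of the 10 genotypes
yields a distinct readout pair and the combination is invertible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, Mapping, Tuple

__all__ = [
    "CODON_RESIDUES",
    "ALLELE_ORDER",
    "RESIDUE_ORDER",
    "KdrModelError",
    "UnknownAlleleError",
    "NovelAlleleError",
    "NoCallError",
    "InconsistentReadoutError",
    "KdrAllele",
    "KdrGenotype",
    "GenotypeGroup",
    "AssayReadout",
    "residue_of",
    "classify_group",
    "fine_label",
    "all_genotypes",
    "residue_genotype_labels",
    "expected_readout",
    "combine_assay_calls",
]

#: codon -> amino-acid class for the four modelled alleles.
CODON_RESIDUES: Mapping[str, str] = {
    "TTA": "Leu",
    "TCA": "Ser",
    "TTT": "Phe",
    "TTC": "Phe",
}

#: canonical display/sort order: wild type first, then Ser, then the Phe codons.
ALLELE_ORDER: Tuple[str, ...] = ("TTA", "TCA", "TTT", "TTC")
RESIDUE_ORDER: Tuple[str, ...] = ("Leu", "Ser", "Phe")

_DNA = frozenset("ACGT")


class KdrModelError(ValueError):
    """Base class for errors raised by the kdr allele/genotype model."""


class UnknownAlleleError(KdrModelError):
    """Codon is not one of the four alleles in the model ("allele not in model")."""


class NovelAlleleError(UnknownAlleleError):
    """A syntactically valid codon that encodes an allele outside the model.

    Raised for codons seen in sequence data that are real but unmodelled
    (e.g. the alternative leucine codon TTG, never observed in
    *P. argentipes*), so they are reported rather than silently classed.
    """


class NoCallError(KdrModelError):
    """Both SNP assays returned no signal; the specimen cannot be genotyped."""


class InconsistentReadoutError(KdrModelError):
    """The two assay calls jointly imply more than two alleles."""


def residue_of(codon: str) -> str:
    """Return the amino-acid class (Leu/Ser/Phe) of a modelled 1014 codon.

    Raises
    ------
    UnknownAlleleError
        If *codon* is not one of TTA, TCA, TTT, TTC.  The unobserved
        alternative leucine codon TTG raises the :class:`NovelAlleleError`
        subclass so callers can distinguish "plausible but unmodelled".
    """
    if not isinstance(codon, str) or len(codon) != 3 or not set(codon) <= _DNA:
        raise UnknownAlleleError(
            f"allele not in model: {codon!r} is not an uppercase 3-letter DNA codon"
        )
    try:
        return CODON_RESIDUES[codon]
    except KeyError:
        if codon == "TTG":
            raise NovelAlleleError(
                "allele not in model: TTG encodes leucine but was never observed "
                "at Vgsc-1014; refusing to class it silently as Leu"
            ) from None
        raise UnknownAlleleError(f"allele not in model: {codon}") from None


@dataclass(frozen=True, order=True)
class KdrAllele:
    """One codon-level allele at Vgsc-1014."""

    codon: str

    def __post_init__(self) -> None:
        residue_of(self.codon)  # validates

    @property
    def residue(self) -> str:
        return CODON_RESIDUES[self.codon]

    @property
    def rank(self) -> int:
        return ALLELE_ORDER.index(self.codon)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.codon


@dataclass(frozen=True)
class KdrGenotype:
    """Unordered pair of :class:`KdrAllele`, stored in canonical order.

    Canonical order is :data:`ALLELE_ORDER` (wild type first), matching the
    conventional Leu/Ser, Leu/Phe ... table headings.
    """

    alleles: Tuple[KdrAllele, KdrAllele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.rank > b.rank:
            object.__setattr__(self, "alleles", (b, a))

    @classmethod
    def from_codons(cls, first: str, second: str) -> "KdrGenotype":
        return cls((KdrAllele(first), KdrAllele(second)))

    @classmethod
    def from_label(cls, label: str) -> "KdrGenotype":
        """Parse a serialized genotype such as ``"TTA/TCA"``."""
        parts = label.strip().split("/")
        if len(parts) != 2:
            raise KdrModelError(f"malformed genotype label: {label!r}")
        return cls.from_codons(parts[0], parts[1])

    @property
    def codons(self) -> Tuple[str, str]:
        return (self.alleles[0].codon, self.alleles[1].codon)

    @property
    def residue_pair(self) -> Tuple[str, str]:
        pair = sorted(
            (self.alleles[0].residue, self.alleles[1].residue),
            key=RESIDUE_ORDER.index,
        )
        return (pair[0], pair[1])

    @property
    def label(self) -> str:
        return "/".join(self.codons)

    @property
    def residue_label(self) -> str:
        return "/".join(self.residue_pair)

    @property
    def is_homozygous(self) -> bool:
        return self.codons[0] == self.codons[1]

    @property
    def has_leu(self) -> bool:
        return "Leu" in self.residue_pair

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def all_genotypes() -> Tuple[KdrGenotype, ...]:
    """The 10 codon-level genotypes (4 alleles, unordered with replacement)."""
    return tuple(
        KdrGenotype.from_codons(a, b)
        for a, b in itertools.combinations_with_replacement(ALLELE_ORDER, 2)
    )


def residue_genotype_labels() -> Tuple[str, ...]:
    """The 6 residue-level genotypes after TTT/TTC pooling."""
    return tuple(
        f"{a}/{b}" for a, b in itertools.combinations_with_replacement(RESIDUE_ORDER, 2)
    )


class GenotypeGroup(Enum):
    """Dominance-based genotype grouping used throughout the analysis.

    ``LEU_STAR`` collects every genotype carrying at least one wild-type
    leucine allele (kdr acting recessively); the remaining kdr-only
    genotypes keep their residue identity.
    """

    LEU_STAR = "Leu/*"
    SER_SER = "Ser/Ser"
    SER_PHE = "Ser/Phe"
    PHE_PHE = "Phe/Phe"

    @property
    def label(self) -> str:
        return self.value


#: kdr-only groups, i.e. the default "positive test" set for diagnostics.
KDR_ONLY_GROUPS: Tuple[GenotypeGroup, ...] = (
    GenotypeGroup.SER_SER,
    GenotypeGroup.SER_PHE,
    GenotypeGroup.PHE_PHE,
)


def classify_group(genotype: KdrGenotype) -> GenotypeGroup:
    """Map a genotype to its unique dominance group."""
    if genotype.has_leu:
        return GenotypeGroup.LEU_STAR
    return GenotypeGroup(genotype.residue_label)


def fine_label(genotype: KdrGenotype) -> str:
    """Residue-level label splitting Leu/* into Leu/Leu, Leu/Ser, Leu/Phe."""
    if genotype.has_leu:
        return genotype.residue_label
    return classify_group(genotype).label


# ---------------------------------------------------------------------------
# Dual SNP-assay call model
# ---------------------------------------------------------------------------

#: declarative, overridable call -> detected-codon tables (exact-match probes).
ASSAY1_CALL_CODONS: Mapping[str, FrozenSet[str]] = {
    "homo_TTA": frozenset({"TTA"}),
    "homo_TCA": frozenset({"TCA"}),
    "het_TTA_TCA": frozenset({"TTA", "TCA"}),
    "null": frozenset(),
}
ASSAY2_CALL_CODONS: Mapping[str, FrozenSet[str]] = {
    "homo_TTC": frozenset({"TTC"}),
    "homo_TTT": frozenset({"TTT"}),
    "het_TTC_TTT": frozenset({"TTC", "TTT"}),
    "null": frozenset(),
}


@dataclass(frozen=True)
class AssayReadout:
    """Discrete call pair from the two allele-discrimination assays."""

    assay1: str
    assay2: str

    def __post_init__(self) -> None:
        if self.assay1 not in ASSAY1_CALL_CODONS:
            raise KdrModelError(f"unknown assay-1 call: {self.assay1!r}")
        if self.assay2 not in ASSAY2_CALL_CODONS:
            raise KdrModelError(f"unknown assay-2 call: {self.assay2!r}")

    @property
    def detected_codons(self) -> FrozenSet[str]:
        return ASSAY1_CALL_CODONS[self.assay1] | ASSAY2_CALL_CODONS[self.assay2]


def _call_for(detected: FrozenSet[str], call_table: Mapping[str, FrozenSet[str]]) -> str:
    for call, codons in call_table.items():
        if codons == detected:
            return call
    raise KdrModelError(f"no call represents detected codons {sorted(detected)}")


def expected_readout(genotype: KdrGenotype) -> AssayReadout:
    """Canonical readout of a genotype under the exact-match probe model."""
    present = set(genotype.codons)
    a1 = _call_for(frozenset(present & {"TTA", "TCA"}), ASSAY1_CALL_CODONS)
    a2 = _call_for(frozenset(present & {"TTC", "TTT"}), ASSAY2_CALL_CODONS)
    return AssayReadout(a1, a2)


def combine_assay_calls(
    readout: AssayReadout,
    assay1_calls: Mapping[str, FrozenSet[str]] = ASSAY1_CALL_CODONS,
    assay2_calls: Mapping[str, FrozenSet[str]] = ASSAY2_CALL_CODONS,
) -> KdrGenotype:
    """Combine the two assay calls into the 1014 genotype.

    The union of detected codons across the two assays determines the
    genotype: one distinct codon means a homozygote (every allele is
    detectable by exactly one probe, so there is no hemizygosity concept),
    two distinct codons mean a heterozygote.

    Raises
    ------
    NoCallError
        If both assays are null.
    InconsistentReadoutError
        If more than two distinct codons are detected (impossible for a
        diploid under the exact-match probe model).
    """
    detected = assay1_calls[readout.assay1] | assay2_calls[readout.assay2]
    if not detected:
        raise NoCallError("no-call: both assays returned no signal")
    if len(detected) > 2:
        raise InconsistentReadoutError(
            f"inconsistent readout: {sorted(detected)} implies >2 alleles"
        )
    codons = sorted(detected, key=ALLELE_ORDER.index)
    if len(codons) == 1:
        return KdrGenotype.from_codons(codons[0], codons[0])
    return KdrGenotype.from_codons(codons[0], codons[1])
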