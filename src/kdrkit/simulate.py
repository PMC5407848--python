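"""Synthetic specimen tables, assay readouts and amplicon sequences.

Generates field-collection-like data with the statistical structure the
analysis assumes: per-site allele frequencies at the tetra-allelic 1014
codon, Hardy-Weinberg (optionally inbreeding-perturbed) genotype
sampling, genotype-group-specific survival probabilities (penetrance),
genotype-independent control mortality, Sanger-style amplicons with
IUPAC heterozygote codes, and dual-assay readouts with a no-call rate.

``bioassay_fixture`` deterministically expands the published genotype x
outcome bioassay counts into pseudo-specimens, so every downstream table
and statistic of the original study is recomputable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import (
    ALLELE_ORDER,
    AssayReadout,
    KdrGenotype,
    all_genotypes,
    expected_readout,
    fine_label,
)
from .seqcall import ReferenceAnnotation, default_reference, iupac_superposition

__all__ = [
    "SitePopulation",
    "SyntheticConfig",
    "TABLE2_COUNTS",
    "EXPOSURE_MINUTES",
    "BIOASSAY_COHORT",
    "genotype_probabilities",
    "simulate_specimens",
    "simulate_group_outcomes",
    "simulate_amplicons",
    "simulate_assay_readouts",
    "fixture_penetrance",
    "bioassay_fixture",
]

SPECIMEN_COLUMNS = (
    "id", "district", "phc", "village", "insecticide", "exposure_minutes",
    "outcome", "role", "cohort", "genotype",
)

# ---------------------------------------------------------------------------
# Published bioassay genotype x outcome counts (the packaged fixture)
# ---------------------------------------------------------------------------

#: genotype-group counts per insecticide and outcome, with the Leu/* fine
#: split; N alive/dead: DDT 83/83, deltamethrin 47/62, alpha-cypermethrin
#: 23/137.
TABLE2_COUNTS: Mapping[str, Mapping[str, Mapping[str, int]]] = {
    "DDT": {
        "alive": {"Leu/Leu": 3, "Leu/Ser": 4, "Leu/Phe": 2,
                  "Ser/Ser": 28, "Ser/Phe": 33, "Phe/Phe": 13},
        "dead": {"Leu/Leu": 20, "Leu/Ser": 32, "Leu/Phe": 10,
                 "Ser/Ser": 15, "Ser/Phe": 6, "Phe/Phe": 0},
    },
    "deltamethrin": {
        "alive": {"Leu/Leu": 0, "Leu/Ser": 0, "Leu/Phe": 11,
                  "Ser/Ser": 11, "Ser/Phe": 18, "Phe/Phe": 7},
        "dead": {"Leu/Leu": 6, "Leu/Ser": 12, "Leu/Phe": 18,
                 "Ser/Ser": 8, "Ser/Phe": 16, "Phe/Phe": 2},
    },
    "alpha-cypermethrin": {
        "alive": {"Leu/Leu": 0, "Leu/Ser": 3, "Leu/Phe": 0,
                  "Ser/Ser": 13, "Ser/Phe": 5, "Phe/Phe": 2},
        "dead": {"Leu/Leu": 57, "Leu/Ser": 51, "Leu/Phe": 11,
                 "Ser/Ser": 15, "Ser/Phe": 2, "Phe/Phe": 1},
    },
}

#: WHO tube-assay exposure times: the 60-min mosquito standard for DDT,
#: deliberately shortened pyrethroid exposures to produce survivors.
EXPOSURE_MINUTES: Mapping[str, int] = {
    "DDT": 60,
    "deltamethrin": 20,
    "alpha-cypermethrin": 30,
}

#: DDT and alpha-cypermethrin assays used F1 progeny of wild-caught
#: females; deltamethrin assays used colony females.
BIOASSAY_COHORT: Mapping[str, str] = {
    "DDT": "F1",
    "deltamethrin": "colony",
    "alpha-cypermethrin": "F1",
}

#: residue -> fixture codon; the published genotype counts pool the two Phe
#: codons, so the fixture encodes every Phe allele as TTT (all derived
#: tables are invariant to this choice after pooling).
_FIXTURE_CODON = {"Leu": "TTA", "Ser": "TCA", "Phe": "TTT"}


def fixture_penetrance(fine: bool = True) -> Dict[str, Dict[str, float]]:
    """Default penetrance map: per-group survival ratios from the fixture.

    With ``fine`` the Leu/* group is split into its three genotypes; the
    kdr-only groups are always genotype-group level.  Every probability is
    the alive/(alive+dead) ratio of the corresponding fixture cells.
    """
    out: Dict[str, Dict[str, float]] = {}
    for ins, table in TABLE2_COUNTS.items():
        pmap: Dict[str, float] = {}
        labels = list(table["alive"])
        if not fine:
            leu = [l for l in labels if "Leu" in l]
            a = sum(table["alive"][l] for l in leu)
            d = sum(table["dead"][l] for l in leu)
            pmap["Leu/*"] = a / (a + d)
            labels = [l for l in labels if l not in leu]
        for label in labels:
            a, d = table["alive"][label], table["dead"][label]
            pmap[label] = a / (a + d)
        out[ins] = pmap
    return out


def bioassay_fixture() -> pd.DataFrame:
    """Deterministic specimen table expanding the published bioassay counts.

    One pseudo-specimen per counted sand fly, with genotype, outcome,
    insecticide, exposure time and cohort; site columns are empty (the
    published bioassay tables pool sites).
    """
    rows = []
    for ins, table in TABLE2_COUNTS.items():
        serial = 0
        for outcome in ("alive", "dead"):
            for label, count in table[outcome].items():
                res_a, res_b = label.split("/")
                genotype = KdrGenotype.from_codons(
                    _FIXTURE_CODON[res_a], _FIXTURE_CODON[res_b]
                )
                for _ in range(count):
                    serial += 1
                    rows.append(
                        {
                            "id": f"{ins}-{serial:04d}",
                            "district": None,
                            "phc": None,
                            "village": None,
                            "insecticide": ins,
                            "exposure_minutes": EXPOSURE_MINUTES[ins],
                            "outcome": outcome,
                            "role": "test",
                            "cohort": BIOASSAY_COHORT[ins],
                            "genotype": genotype.label,
                        }
                    )
    return pd.DataFrame(rows, columns=list(SPECIMEN_COLUMNS))


# ---------------------------------------------------------------------------
# Generative model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SitePopulation:
    """One collection site: allele frequencies and inbreeding coefficient."""

    name: str
    allele_freqs: Mapping[str, float]
    inbreeding: float = 0.0

    def __post_init__(self) -> None:
        for codon in self.allele_freqs:
            if codon not in ALLELE_ORDER:
                raise ValueError(f"unknown allele codon {codon!r}")
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1 (got {total})")
        if not -1.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [-1, 1]")


def _default_sites() -> Tuple[SitePopulation, ...]:
    # Two districts contrasting in kdr frequency: one nearly fixed for kdr
    # (~10% wild-type-carrying genotypes, Phe-dominated), one with roughly
    # threefold more wild type.
    return (
        SitePopulation(
            "Vaishali", {"TTA": 0.05, "TCA": 0.15, "TTT": 0.50, "TTC": 0.30}
        ),
        SitePopulation(
            "Patna", {"TTA": 0.25, "TCA": 0.35, "TTT": 0.25, "TTC": 0.15}
        ),
    )


@dataclass
class SyntheticConfig:
    """Configuration of the specimen generator.

    ``penetrance`` maps insecticide -> genotype label -> survival
    probability; labels may be fine (``Leu/Phe``) or group level
    (``Leu/*``, ``Ser/Ser``, ...), with fine labels taking precedence.
    Defaults emulate the study conditions: ~25 females per bioassay tube,
    genotype-independent control mortality of 2%, HWE within sites.
    ``seed`` is mandatory.
    """

    seed: int
    sites: Sequence[SitePopulation] = field(default_factory=_default_sites)
    penetrance: Mapping[str, Mapping[str, float]] = field(
        default_factory=fixture_penetrance
    )
    control_mortality: float = 0.02
    specimens_per_bioassay: int = 25
    n_bioassays_per_site: int = 4
    n_controls_per_site: int = 25
    no_call_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.control_mortality, self.no_call_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for ins, pmap in self.penetrance.items():
            for label, p in pmap.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"penetrance[{ins}][{label}] = {p} outside [0, 1]"
                    )
            for gt in all_genotypes():
                _resolve_penetrance(pmap, gt, ins)


def _resolve_penetrance(
    pmap: Mapping[str, float], genotype: KdrGenotype, insecticide: str
) -> float:
    fine = fine_label(genotype)
    if fine in pmap:
        return pmap[fine]
    if genotype.has_leu and "Leu/*" in pmap:
        return pmap["Leu/*"]
    raise KeyError(
        f"penetrance for insecticide {insecticide!r} covers neither "
        f"{fine!r} nor its group"
    )


def genotype_probabilities(
    allele_freqs: Mapping[str, float], inbreeding: float = 0.0
) -> Dict[KdrGenotype, float]:
    """HWE-with-F genotype law: p_i^2 + F p_i (1-p_i); 2 p_i p_j (1-F)."""
    F = inbreeding
    out: Dict[KdrGenotype, float] = {}
    for gt in all_genotypes():
        a, b = gt.codons
        pa = allele_freqs.get(a, 0.0)
        pb = allele_freqs.get(b, 0.0)
        if a == b:
            out[gt] = pa * pa + F * pa * (1 - pa)
        else:
            out[gt] = 2 * pa * pb * (1 - F)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("genotype probabilities do not sum to 1")
    return out


def simulate_specimens(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a specimen table under the configured generative model.

    Per specimen: genotype drawn from the site's HWE-with-F law; test
    outcome Bernoulli(penetrance of its genotype group); control outcome
    Bernoulli(control mortality) independent of genotype.  Fully
    reproducible from the seed (identical config + seed give
    byte-identical tables).
    """
    rng = np.random.default_rng(config.seed)
    genotypes = list(all_genotypes())
    rows = []
    n_test = config.specimens_per_bioassay * config.n_bioassays_per_site
    for site in config.sites:
        probs = np.array(
            [genotype_probabilities(site.allele_freqs, site.inbreeding)[g]
             for g in genotypes]
        )
        for ins in config.penetrance:
            pmap = config.penetrance[ins]
            draws = rng.choice(len(genotypes), size=n_test, p=probs)
            unif = rng.random(n_test)
            for i, (gi, u) in enumerate(zip(draws, unif), start=1):
                gt = genotypes[gi]
                alive = u < _resolve_penetrance(pmap, gt, ins)
                rows.append(
                    {
                        "id": f"{site.name}-{ins}-T{i:04d}",
                        "district": site.name,
                        "phc": None,
                        "village": None,
                        "insecticide": ins,
                        "exposure_minutes": EXPOSURE_MINUTES.get(ins, 60),
                        "outcome": "alive" if alive else "dead",
                        "role": "test",
                        "cohort": BIOASSAY_COHORT.get(ins, "F1"),
                        "genotype": gt.label,
                    }
                )
            cdraws = rng.choice(len(genotypes), size=config.n_controls_per_site, p=probs)
            cunif = rng.random(config.n_controls_per_site)
            for i, (gi, u) in enumerate(zip(cdraws, cunif), start=1):
                gt = genotypes[gi]
                rows.append(
                    {
                        "id": f"{site.name}-{ins}-C{i:04d}",
                        "district": site.name,
                        "phc": None,
                        "village": None,
                        "insecticide": ins,
                        "exposure_minutes": EXPOSURE_MINUTES.get(ins, 60),
                        "outcome": "dead" if u < config.control_mortality else "alive",
                        "role": "control",
                        "cohort": BIOASSAY_COHORT.get(ins, "F1"),
                        "genotype": gt.label,
                    }
                )
    return pd.DataFrame(rows, columns=list(SPECIMEN_COLUMNS))


def simulate_group_outcomes(
    penetrance: Mapping[str, float],
    n_per_group: int,
    seed: Optional[int] = None,
) -> Dict[str, Tuple[int, int]]:
    """Bioassay outcome layer alone: per group, alive count out of n.

    Convenience for calibration/coverage studies where the genotype
    composition is held fixed rather than drawn from allele frequencies.
    """
    rng = np.random.default_rng(seed)
    return {
        label: (int(rng.binomial(n_per_group, p)), n_per_group)
        for label, p in penetrance.items()
    }


# ---------------------------------------------------------------------------
# Amplicons and assay readouts
# ---------------------------------------------------------------------------


def simulate_amplicons(
    genotypes: Iterable[KdrGenotype],
    ref: Optional[ReferenceAnnotation] = None,
    seed: Optional[int] = None,
    ids: Optional[Sequence[str]] = None,
) -> List[SeqRecord]:
    """Sanger-style amplicon per genotype: reference fragment with the 1014
    codon substituted; heterozygotes carry the minimal position-wise IUPAC
    superposition of their two codons.  With a seed, each record is emitted
    on a random strand (the caller must be strand-invariant); without one,
    all records are plus-strand.
    """
    ref = ref or default_reference()
    rng = np.random.default_rng(seed) if seed is not None else None
    i = ref.coding_start + 3 * (ref.kdr_codon - ref.first_codon)
    records = []
    for idx, gt in enumerate(genotypes):
        a, b = gt.codons
        if a == b:
            codon = a
        else:
            codon = iupac_superposition(a, b)
            # with this allele set no position ever needs a >2-way code
            assert all(c in "ACGTRYSWKM" for c in codon), codon
        seq = ref.sequence[:i] + codon + ref.sequence[i + 3 :]
        if rng is not None and rng.random() < 0.5:
            seq = str(Seq(seq).reverse_complement())
        rec_id = ids[idx] if ids is not None else f"synthetic-{idx:04d}-{gt.label.replace('/', '_')}"
        records.append(SeqRecord(Seq(seq), id=rec_id, description="synthetic amplicon"))
    return records


def simulate_assay_readouts(
    genotypes: Iterable[KdrGenotype],
    no_call_rate: float = 0.0,
    seed: Optional[int] = None,
) -> List[AssayReadout]:
    """Canonical dual-assay readout per genotype, with independent per-assay
    null replacement at ``no_call_rate``."""
    if not 0.0 <= no_call_rate <= 1.0:
        raise ValueError("no_call_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for gt in genotypes:
        readout = expected_readout(gt)
        a1 = "null" if rng.random() < no_call_rate else readout.assay1
        a2 = "null" if rng.random() < no_call_rate else readout.assay2
        out.append(AssayReadout(a1, a2))
    return out
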