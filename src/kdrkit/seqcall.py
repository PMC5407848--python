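"""Codon-1014 calling from Vgsc domain-IIS6 amplicon sequences.

Sanger-style amplicons of the domain II segment 6 fragment (amplified with
the conserved primers Vssc8F/Vssc1bR) are anchored against a reference
fragment whose codons are numbered by the house-fly *para* channel
convention.  The 1014 codon is then read out, with heterozygotes encoded
as single sequences carrying IUPAC ambiguity codes, and the other three
resistance-associated codons in the fragment (1011, 1016, 1020) are
screened for departures from wild type (Ile, Val, Phe).

The default reference annotation shipped here is a synthetic, intron-free
stand-in fragment (the field amplicons live in public sequence archives
and are not required); it is user-replaceable, and the annotation format
supports one excluded (intron) interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import (
    CODON_RESIDUES,
    KdrGenotype,
    NovelAlleleError,
    classify_group,
    fine_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_CODES",
    "PrimerPair",
    "ReferenceAnnotation",
    "AmpliconLocation",
    "WatchedCodonReport",
    "SequenceCallError",
    "AmbiguousAmpliconError",
    "AnchorError",
    "UnresolvableHeterozygoteError",
    "default_primers",
    "default_reference",
    "locate_amplicon",
    "call_codon_1014",
    "screen_watched_codons",
    "call_table",
    "read_amplicons",
    "write_amplicons",
    "iupac_superposition",
]

# ---------------------------------------------------------------------------
# IUPAC machinery
# ---------------------------------------------------------------------------

IUPAC_CODES: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_CODE_OF = {v: k for k, v in IUPAC_CODES.items()}


def _bases(letter: str) -> frozenset:
    try:
        return IUPAC_CODES[letter]
    except KeyError:
        raise SequenceCallError(f"invalid nucleotide letter {letter!r}") from None


def _compatible(a: str, b: str) -> bool:
    return bool(_bases(a) & _bases(b))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def iupac_superposition(codon_a: str, codon_b: str) -> str:
    """Minimal IUPAC code covering two codons position-wise (Sanger semantics)."""
    if len(codon_a) != len(codon_b):
        raise SequenceCallError("codons must have equal length")
    return "".join(
        _CODE_OF[_bases(x) | _bases(y)] for x, y in zip(codon_a, codon_b)
    )


def expand_codon(codon: str) -> List[str]:
    """All concrete codons covered by an IUPAC-ambiguous codon."""
    pools = [sorted(_bases(c)) for c in codon]
    out = [""]
    for pool in pools:
        out = [pref + b for pref in out for b in pool]
    return out


class SequenceCallError(ValueError):
    """Base error for amplicon location / codon calling."""


class AmbiguousAmpliconError(SequenceCallError):
    """Multiple equally good primer sites."""


class AnchorError(SequenceCallError):
    """The codon anchor window could not be placed unambiguously."""


class UnresolvableHeterozygoteError(SequenceCallError):
    """Ambiguity pattern not uniquely invertible to <=2 modelled alleles."""


# ---------------------------------------------------------------------------
# Primers and reference annotation
# ---------------------------------------------------------------------------

VSSC8F = "AATGTGGGATTGCATGCTGG"
VSSC1BR = "CGTATCATTGTCTGCAGTTGGT"


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primer pair (IUPAC letters permitted)."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or not all(c in IUPAC_CODES for c in p):
                raise SequenceCallError(f"{name} primer must be non-empty uppercase DNA")


def default_primers() -> PrimerPair:
    """The conserved Vssc8F / Vssc1bR pair used to amplify the IIS6 fragment."""
    return PrimerPair(VSSC8F, VSSC1BR)


# Synthetic intron-free reference coding region, codons 1001-1030 (house-fly
# numbering); watched codons carry the wild-type residues 1011 Ile, 1014 Leu
# (TTA), 1016 Val, 1020 Phe.
_REF_CODONS = (
    "GGA GCT CTG GGT AAC CTC ACT TTC GTC CTT "  # 1001-1010
    "ATT TGT ATC TTA ATA GTT TTT AAT CTA TTC "  # 1011-1020
    "TTG GCA CTC CTG ATG TCT AGC TTT TCA GCC"   # 1021-1030
).replace(" ", "")


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Reference fragment with a codon-number anchor map.

    ``coding_start`` is the 0-based offset of the first full codon;
    ``first_codon`` its number under the house-fly convention.  ``intron``
    optionally names one half-open interval excluded from the coding frame.
    All coordinates are 0-based half-open.
    """

    sequence: str
    coding_start: int
    first_codon: int
    watched: Mapping[int, str] = field(
        default_factory=lambda: {1011: "Ile", 1016: "Val", 1020: "Phe"}
    )
    kdr_codon: int = 1014
    intron: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if str(Seq(self.codon(self.kdr_codon)).translate()) != "L":
            raise SequenceCallError(
                f"reference codon {self.kdr_codon} does not translate to Leu"
            )

    def spliced(self) -> str:
        if self.intron is None:
            return self.sequence
        i, j = self.intron
        return self.sequence[:i] + self.sequence[j:]

    def _spliced_index(self, codon_number: int) -> int:
        idx = self.coding_start + 3 * (codon_number - self.first_codon)
        if self.intron is not None and self.intron[0] <= self.coding_start:
            raise SequenceCallError("intron may not precede the coding start")
        return idx

    def codon(self, codon_number: int) -> str:
        i = self._spliced_index(codon_number)
        codon = self.spliced()[i : i + 3]
        if len(codon) != 3:
            raise SequenceCallError(f"codon {codon_number} outside reference fragment")
        return codon

    def anchor_window(self, codon_number: int, size: int = 30) -> Tuple[str, int]:
        """(window sequence, codon offset inside window) from the spliced frame."""
        spliced = self.spliced()
        i = self._spliced_index(codon_number)
        lead = min((size - 3) // 2, i)
        start = i - lead
        window = spliced[start : start + size]
        if len(window) < size:  # clamp at the right edge
            window = spliced[max(0, len(spliced) - size) :]
            lead = i - (len(spliced) - len(window))
        return window, lead


def default_reference() -> ReferenceAnnotation:
    """Synthetic intron-free IIS6 stand-in fragment with embedded primers."""
    seq = VSSC8F + _REF_CODONS + revcomp(VSSC1BR)
    return ReferenceAnnotation(sequence=seq, coding_start=len(VSSC8F), first_codon=1001)


# ---------------------------------------------------------------------------
# Amplicon location
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconLocation:
    """Insert interval between the primers on the plus-oriented sequence."""

    start: int
    end: int
    strand: str  # "+" if the input already reads forward, "-" if it was flipped
    mismatches: int
    oriented_sequence: str

    @property
    def insert(self) -> str:
        return self.oriented_sequence[self.start : self.end]


def _primer_hits(seq: str, primer: str, max_mismatch: int) -> List[Tuple[int, int]]:
    hits = []
    w = len(primer)
    for pos in range(len(seq) - w + 1):
        mm = sum(
            0 if _compatible(primer[k], seq[pos + k]) else 1 for k in range(w)
        )
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


def locate_amplicon(
    seq: str,
    primers: Optional[PrimerPair] = None,
    max_mismatch: int = 1,
) -> Optional[AmpliconLocation]:
    """Find the insert between the forward primer and the reverse primer site.

    Both orientations are scanned; if the reverse complement matches better
    the sequence is reported as minus-strand and returned reverse
    complemented.  Returns ``None`` when either primer site is missing.

    Raises
    ------
    AmbiguousAmpliconError
        If distinct, equally good primer-site placements exist.
    """
    if max_mismatch < 0:
        raise SequenceCallError("max_mismatch must be >= 0")
    primers = primers or default_primers()
    seq = seq.upper()
    rev_site = revcomp(primers.reverse)

    candidates: List[AmpliconLocation] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for fpos, fmm in _primer_hits(s, primers.forward, max_mismatch):
            for rpos, rmm in _primer_hits(s, rev_site, max_mismatch):
                if rpos >= fpos + len(primers.forward):
                    candidates.append(
                        AmpliconLocation(
                            start=fpos + len(primers.forward),
                            end=rpos,
                            strand=strand,
                            mismatches=fmm + rmm,
                            oriented_sequence=s,
                        )
                    )
    if not candidates:
        return None
    best = min(c.mismatches for c in candidates)
    top = [c for c in candidates if c.mismatches == best]
    coords = {(c.strand, c.start, c.end) for c in top}
    if len(coords) > 1:
        raise AmbiguousAmpliconError(
            f"ambiguous amplicon: {len(coords)} equally good primer placements"
        )
    return top[0]


# ---------------------------------------------------------------------------
# Codon anchoring and calling
# ---------------------------------------------------------------------------


def _anchor_codon(
    seq: str,
    ref: ReferenceAnnotation,
    codon_number: int,
    window_size: int = 30,
    min_identity: float = 0.8,
) -> Tuple[str, str]:
    """Locate a codon in *seq* by best ungapped match of a reference window.

    Returns (observed codon, strand).  A score tie between distinct
    placements is an error, never an arbitrary pick.
    """
    window, lead = ref.anchor_window(codon_number, window_size)
    w = len(window)
    best_score = -1
    best: List[Tuple[str, int]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for pos in range(len(s) - w + 1):
            score = sum(
                1 for k in range(w) if _compatible(window[k], s[pos + k])
            )
            if score > best_score:
                best_score = score
                best = [(strand, pos)]
            elif score == best_score:
                best.append((strand, pos))
    if best_score < min_identity * w or not best:
        raise AnchorError(
            f"codon {codon_number}: no anchor window match at >= "
            f"{min_identity:.0%} identity"
        )
    placements = {
        (strand, pos if strand == "+" else len(seq) - pos - w)
        for strand, pos in best
    }
    if len(placements) > 1:
        raise AnchorError(
            f"codon {codon_number}: tie between {len(placements)} anchor placements"
        )
    strand, pos = best[0]
    s = seq if strand == "+" else revcomp(seq)
    codon = s[pos + lead : pos + lead + 3]
    if len(codon) != 3:
        raise AnchorError(f"codon {codon_number}: anchor places codon outside sequence")
    return codon, strand


def _invert_superposition(observed: str) -> KdrGenotype:
    """Invert an observed (possibly IUPAC-ambiguous) 1014 codon to a genotype.

    A homozygote is an unambiguous modelled codon.  A heterozygote is
    recovered as the unique unordered pair of modelled alleles whose
    position-wise IUPAC superposition equals the observed pattern; with the
    four-allele model this inverse is unique for every heterozygote,
    including the two patterns ambiguous at both codon positions 2 and 3
    (TYW -> TCA/TTT, TYM -> TCA/TTC).
    """
    n_ambiguous = sum(1 for c in observed if len(_bases(c)) > 1)
    if any(len(_bases(c)) > 2 for c in observed):
        raise UnresolvableHeterozygoteError(
            f"unresolvable heterozygote: {observed} carries a >2-way ambiguity code"
        )
    if n_ambiguous == 0:
        if observed not in CODON_RESIDUES:
            raise NovelAlleleError(f"novel allele at 1014: codon {observed}")
        return KdrGenotype.from_codons(observed, observed)

    model = list(CODON_RESIDUES)
    pairs = [
        (a, b)
        for i, a in enumerate(model)
        for b in model[i + 1 :]
        if iupac_superposition(a, b) == observed
    ]
    if len(pairs) == 1:
        return KdrGenotype.from_codons(*pairs[0])
    expanded_in_model = [c for c in expand_codon(observed) if c in CODON_RESIDUES]
    if len(expanded_in_model) < 2:
        raise NovelAlleleError(
            f"novel allele at 1014: pattern {observed} expands to "
            f"{expand_codon(observed)}, fewer than two modelled codons"
        )
    raise UnresolvableHeterozygoteError(
        f"unresolvable heterozygote: pattern {observed} matches "
        f"{len(pairs)} modelled allele pairs"
    )


AmpliconLike = Union[str, SeqRecord, Tuple[str, str]]


def _as_id_seq(amplicon: AmpliconLike) -> Tuple[str, str]:
    if isinstance(amplicon, SeqRecord):
        return amplicon.id, str(amplicon.seq).upper()
    if isinstance(amplicon, tuple):
        return amplicon[0], amplicon[1].upper()
    return "amplicon", amplicon.upper()


def call_codon_1014(
    amplicon: AmpliconLike,
    ref: Optional[ReferenceAnnotation] = None,
) -> Tuple[KdrGenotype, Dict[str, object]]:
    """Call the 1014 genotype from one amplicon sequence.

    Returns the genotype plus an alignment report (strand, observed codon).
    Strand-invariant: the reverse complement of any input yields the same
    call.
    """
    ref = ref or default_reference()
    rec_id, seq = _as_id_seq(amplicon)
    observed, strand = _anchor_codon(seq, ref, ref.kdr_codon)
    genotype = _invert_superposition(observed)
    report: Dict[str, object] = {
        "id": rec_id,
        "codon": ref.kdr_codon,
        "observed_codon": observed,
        "strand": strand,
    }
    return genotype, report


@dataclass(frozen=True)
class WatchedCodonReport:
    codon_number: int
    observed_codon: str
    residues: Tuple[str, ...]
    wild_type: bool


_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}


def _translate(codon: str) -> str:
    return _THREE_LETTER[str(Seq(codon).translate())]


def screen_watched_codons(
    amplicon: AmpliconLike,
    ref: Optional[ReferenceAnnotation] = None,
) -> Dict[int, WatchedCodonReport]:
    """Report the residue genotype and wild-type flag at codons 1011/1016/1020.

    IUPAC ambiguity is expanded (a synonymous ambiguity still counts as wild
    type); a >2-way expansion is reported with ``wild_type=False`` and all
    residues listed.
    """
    ref = ref or default_reference()
    _, seq = _as_id_seq(amplicon)
    out: Dict[int, WatchedCodonReport] = {}
    for codon_number, wt_residue in sorted(ref.watched.items()):
        observed, _ = _anchor_codon(seq, ref, codon_number)
        residues = tuple(sorted({_translate(c) for c in expand_codon(observed)}))
        out[codon_number] = WatchedCodonReport(
            codon_number=codon_number,
            observed_codon=observed,
            residues=residues,
            wild_type=(residues == (wt_residue,)),
        )
    return out


def call_table(
    amplicons: Iterable[AmpliconLike],
    ref: Optional[ReferenceAnnotation] = None,
) -> pd.DataFrame:
    """Per-specimen call table for a batch of amplicons.

    Calling errors are captured per record in the ``qc`` column (pipeline
    semantics) rather than aborting the batch; novel alleles are reported,
    never silently dropped.
    """
    ref = ref or default_reference()
    rows = []
    for amp in amplicons:
        rec_id, seq = _as_id_seq(amp)
        row: Dict[str, object] = {
            "id": rec_id,
            "codon_1014": None,
            "genotype": None,
            "residue_genotype": None,
            "group": None,
            "fine_label": None,
            "strand": None,
            "qc": "ok",
        }
        try:
            genotype, report = call_codon_1014((rec_id, seq), ref)
            row.update(
                codon_1014=report["observed_codon"],
                genotype=genotype.label,
                residue_genotype=genotype.residue_label,
                group=classify_group(genotype).label,
                fine_label=fine_label(genotype),
                strand=report["strand"],
            )
        except NovelAlleleError as exc:
            row["qc"] = f"novel_allele: {exc}"
        except (UnresolvableHeterozygoteError, AnchorError, SequenceCallError) as exc:
            row["qc"] = f"{type(exc).__name__}: {exc}"
        else:
            try:
                watched = screen_watched_codons((rec_id, seq), ref)
                for num, rep in watched.items():
                    row[f"wt_{num}"] = rep.wild_type
            except SequenceCallError as exc:
                row["qc"] = f"watched-codon screen failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA I/O (multi-record, via biopython)
# ---------------------------------------------------------------------------


def read_amplicons(path) -> List[SeqRecord]:
    return list(SeqIO.parse(path, "fasta"))


def write_amplicons(records: Sequence[SeqRecord], path) -> None:
    SeqIO.write(records, path, "fasta")
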