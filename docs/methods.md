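# Methods

This note documents the statistical model, the defaults and the design
choices behind `kdrkit`, and what the synthetic-data generator does and
does not emulate.

## The locus model

Four alleles are modelled at *Vgsc* codon 1014: TTA (Leu, wild type),
TCA (Ser), TTT and TTC (both Phe). The residue map is total and closed:
any other codon is rejected, and the alternative leucine codon TTG —
plausible biologically but never observed at this locus — raises a
distinct "novel allele" error instead of being silently classed as Leu,
so that a genuinely new variant in field data surfaces in QC rather
than disappearing into the wild-type column. Ten codon-level genotypes
exist; pooling TTT/TTC gives six residue-level genotypes; the dominance
grouping (`Leu/*`, `Ser/Ser`, `Ser/Phe`, `Phe/Phe`) encodes the working
hypothesis that each kdr allele is recessive to wild type while two
different kdr alleles in heterozygosis act additively.

## Dual-assay calling

Assay 1 discriminates codon position 2 (TTA vs. TCA), assay 2 position
3 (TTC vs. TTT). We adopt an **exact-match probe model**: each
fluorescent probe detects exactly one codon, and an allele matching no
probe of an assay yields no signal there. Under this model the union of
detected codons across the two assays determines the genotype uniquely
(one codon → homozygote, two → heterozygote), all ten genotypes produce
distinct readout pairs, and the map is invertible. The call→codon
tables are declarative module data and can be overridden if a different
probe chemistry cross-reacts. A single detected codon is always called
homozygous — under exact matching every allele is detectable by exactly
one probe, so there is no hemizygosity concept. How a TTA/TTT or
TTA/TTC heterozygote presents on the position-3 assay is not
empirically settled; the exact-match model assumes a clean null there,
which is the only assumption under which all ten genotypes remain
unambiguously callable. Both assays null is a no-call; three or more
implied alleles is an inconsistent readout. Note that when a no-call
hits one assay of a cross-assay heterozygote (e.g. TTA/TTT reading as
`homo_TTA` + null), the combination is an undetectable miscall, not a
flagged failure — a limitation inherent to the assay design, not to the
software.

## Amplicon calling

The 1014 codon is located by **ungapped anchoring**: the best
IUPAC-aware match of a 30-nt reference window centred on the codon, at
a minimum identity of 80%, searched on both strands (calls are
strand-invariant). A score tie between distinct placements is an error,
never an arbitrary pick. Anchoring rather than absolute offset keeps
the caller robust to small length differences between field amplicons
and the reference. Heterozygotes are Sanger-style single sequences with
IUPAC ambiguity codes. The observed codon is inverted by searching the
four-allele model for the unique singleton or unordered pair whose
position-wise IUPAC superposition equals the observed pattern. Within
this model the inverse is unique for **all** heterozygotes, including
the two patterns ambiguous at both positions 2 and 3 (TYA→TTA/TCA,
TTW→TTA/TTT, TTM→TTA/TTC, TTY→TTT/TTC, TYW→TCA/TTT, TYM→TCA/TTC);
without the model constraint TYW and TYM would be 4-way ambiguous,
which is why generic IUPAC expansion alone cannot phase them. Patterns
with >2-way codes, or whose expansion leaves the model, raise
"unresolvable heterozygote" or "novel allele" respectively — never a
silent drop. Codons 1011, 1016 and 1020 are screened by expansion and
translation; a synonymous ambiguity still counts as wild type.

The shipped reference annotation is a **synthetic stand-in**: an
intron-free fragment carrying the published primer sites and wild-type
residues at the watched codons, with codon numbers anchored to the
house-fly convention. The true field amplicon's length and intron
structure are not modelled; the annotation format accepts a replacement
sequence and one excluded (intron) interval without code change.

## Association statistics

* **Abbott correction** uses the WHO gating convention: control
  mortality < 5% → no correction; 5–20% → `100·(T−C)/(100−C)`;
  > 20% → discard the assay. The thresholds are keyword parameters.
* **Contingency tables**: each genotyped test-role specimen contributes
  one count to the group table and two allele counts (Phe codons
  pooled) to the allele table; ungenotyped or control specimens are
  excluded with a logged count.
* **Chi-square** is Pearson's statistic without continuity correction,
  df = (R−1)(C−1), via `scipy.stats.chi2_contingency`; a zero margin is
  an error naming the degenerate level.
* **Fisher exact** (two-sided) sums hypergeometric outcomes with point
  probability ≤ that of the observed table (scipy's convention, checked
  against full enumeration). Other two-sided rules exist; p-values
  printed by other software may differ slightly, so cross-package
  comparisons of these p-values should be at order-of-magnitude
  precision.
* **Odds ratios** use the raw cross-product `ad/bc`, with
  Haldane–Anscombe +0.5 on all cells when any cell is zero (tagged in
  the result) and a Woolf logit interval. A conditional
  maximum-likelihood estimator would give slightly different values
  (e.g. 26.3 rather than 26.05 on the DDT Phe-vs-Leu table); the
  cross-product form is reported because it is the standard
  epidemiological estimator and is exactly reproducible from the
  printed counts.
* **Proportion CIs** are continuity-corrected Wilson score intervals
  (Newcombe). They respect [0, 1], collapse correctly at k = 0 and
  k = n, and are mildly conservative; the same interval backs survival
  proportions, sensitivity/specificity and predictive values.
* **Marascuilo–McSweeney**: for K groups, each pair is compared to the
  critical range `sqrt(χ²₁₋α,K₋₁)·sqrt(p̂ᵢ(1−p̂ᵢ)/nᵢ + p̂ⱼ(1−p̂ⱼ)/nⱼ)`.
  The classical procedure yields only significance flags, so a per-pair
  p-value is added McSweeney-style as the upper χ²(K−1) tail of the
  squared standardized difference. K defaults to the number of groups
  supplied and can be passed explicitly when a pair is drawn from a
  larger family. If both proportions sit on the {0, 1} boundary and
  differ, each zero variance is replaced by the variance of the shrunk
  proportion `(k+0.5)/(n+1)` and the comparison is flagged `boundary`.
* **Sequential Bonferroni** is Holm's step-down (compare sorted p(i) to
  α/(m−i+1), stop at the first failure); decisions match
  `statsmodels.stats.multitest` with `method="holm"`.

## Diagnostics

The positivity rule is **kdr-only genotype** (no Leu allele), matching
the TP/FP/TN/FN definitions used with these data; it is a parameter so
alternative cut-points (e.g. Phe-carrying only) can be evaluated.
Predictive values are computed at the sample's own prevalence — correct
for bioassay panels analysed as their own population; a Bayes-adjusted
variant for external prevalences is deliberately not the default.
One empirical caveat surfaced by the packaged fixture: serine
homozygotes do **not** have the uniformly lowest positive predictive
value among kdr-only groups — under deltamethrin the Ser/Phe group's
PPV (18/34 ≈ 0.53) is below the Ser/Ser value (11/19 ≈ 0.58) — so the
tests assert the published narrative ranges (47–65% for Ser/Ser, >80%
for Phe-carrying groups under DDT, 53–78% under pyrethroids) rather
than a strict ordering.

## Population genetics

Frequencies and HWE default to the three-allele residue level,
mirroring the phenotypic pooling; codon-level analysis is a flag away.
Site pooling (village/PHC/district) is explicit, defaulting to
district. The exact HWE test enumerates all genotype tables conditional
on allele counts with the conditional probability
`n!·2^het·∏mᵢ!/(∏nᵢⱼ!·(2n)!)` and sums probabilities ≤ the observed
table's. The Monte-Carlo test shuffles the 2n gametes, pairs them, and
reports `(hits+1)/(replicates+1)` — reproducible bit-for-bit from
(counts, replicates, seed). `auto` uses exact enumeration up to n = 50
and Monte-Carlo beyond. The asymptotic chi-square variant
(df = A(A−1)/2) is provided for comparison and warns when expected
counts drop below 5.

## Synthetic-data generator

The generator emulates the study design: per-site allele frequencies at
the tetra-allelic codon; genotypes drawn from the HWE-with-inbreeding
law `pᵢ² + F pᵢ(1−pᵢ)` / `2pᵢpⱼ(1−F)`; bioassay survival as a Bernoulli
draw from a genotype-group penetrance map (genotype-level penetrance is
the generative primitive because the scientific question is about
genotype groups and dominance; allele-level additive models can be
expressed through the map); control mortality independent of genotype;
roughly 25 flies per tube. Default penetrances are the observed survival
ratios of the packaged fixture (e.g. DDT: Leu/* 9/71, Ser/Ser 28/43,
Ser/Phe 33/39, Phe/Phe 13/13). Default site frequencies sketch two
districts contrasting threefold in wild-type frequency, one nearly
fixed for kdr. Control-arm defaults (2% control mortality, 25 controls
per site) are plausible stand-ins where no published value exists.

What it does **not** emulate: chromatogram noise and base-quality,
probe cross-reactivity, genotyping error other than symmetric per-assay
no-calls, overdispersion between bioassay tubes, temporal change, or
selection. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated model, not robustness to messy
field data.

The packaged fixture `bioassay_fixture()` deterministically expands the
published genotype × outcome counts into pseudo-specimens. The
published counts pool the two Phe codons, so the fixture encodes every
Phe allele as TTT; all derived tables are invariant to that choice
after pooling.

## Numerical conventions

Coordinates are 0-based half-open; codon numbers follow the house-fly
anchor map. Genotypes serialize with the wild-type-first allele order
(TTA, TCA, TTT, TTC → "TTA/TCA", "Leu/Ser"), matching conventional
table headings. Display rounding is 1 d.p. for chi-squares and
percentages and 2 d.p. for odds ratios; machine-readable outputs keep
full precision. Exact-test ties use a relative tolerance of 1e-9 when
comparing table probabilities.

## Study sizes used in tests and the acceptance script

Fixture analyses run on the published counts (166–320 alleles per
insecticide). Calibration studies use sizes chosen to give stable
estimates at interactive runtimes: 2,000 null tables (n = 100/group)
for the chi-square type-I error; 500 seeded replicates × 18
penetrance cells at n = 500/group for CI coverage (the
continuity-corrected Wilson interval is conservative, so coverage runs
a little above 95%); 10,000 Monte-Carlo replicates against exact
enumeration for HWE; 1,000 replicates at 1,000 alleles for odds-ratio
recovery — there, alleles arrive correlated in genotype pairs, a design
effect the Woolf variance ignores, so CI coverage of the induced odds
ratio sits near 91% rather than the nominal 95%.

## Known limitations

* The reference annotation is synthetic; real amplicons with large
  indels relative to it would defeat ungapped anchoring.
* Fisher p-values depend on the two-sided convention; only magnitudes
  are comparable across software.
* Cross-assay heterozygote no-calls silently degrade to homozygote
  calls (see above).
* The Marascuilo boundary-variance convention is a pragmatic choice;
  exact unconditional tests would be preferable at tiny n.
* Between-district comparisons assume independent samples within
  sites; no spatial or household clustering is modelled.
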