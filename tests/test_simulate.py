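"""Synthetic-data generator: determinism, calibration, fixture fidelity."""

import math

import numpy as np
import pytest

from kdrkit.genotypes import (
    KdrGenotype,
    all_genotypes,
    combine_assay_calls,
    expected_readout,
)
from kdrkit.simulate import (
    EXPOSURE_MINUTES,
    SitePopulation,
    SyntheticConfig,
    TABLE2_COUNTS,
    genotype_probabilities,
    bioassay_fixture,
    fixture_penetrance,
    simulate_amplicons,
    simulate_assay_readouts,
    simulate_specimens,
)
from kdrkit.stats import odds_ratio


def test_identical_config_and_seed_give_byte_identical_tables():
    a = simulate_specimens(SyntheticConfig(seed=5))
    b = simulate_specimens(SyntheticConfig(seed=5))
    c = simulate_specimens(SyntheticConfig(seed=6))
    assert a.to_csv(index=False) == b.to_csv(index=False)
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_genotype_probabilities_hwe_and_inbreeding():
    freqs = {"TTA": 0.2, "TCA": 0.3, "TTT": 0.4, "TTC": 0.1}
    probs = genotype_probabilities(freqs)
    assert sum(probs.values()) == pytest.approx(1.0)
    het = KdrGenotype.from_codons("TTA", "TCA")
    assert probs[het] == pytest.approx(2 * 0.2 * 0.3)
    inbred = genotype_probabilities(freqs, inbreeding=0.5)
    assert inbred[het] == pytest.approx(2 * 0.2 * 0.3 * 0.5)
    hom = KdrGenotype.from_codons("TTA", "TTA")
    assert inbred[hom] == pytest.approx(0.2**2 + 0.5 * 0.2 * 0.8)


def test_fixed_allele_means_all_homozygous():
    site = SitePopulation("mono", {"TCA": 1.0})
    config = SyntheticConfig(seed=1, sites=[site])
    df = simulate_specimens(config)
    assert set(df["genotype"]) == {"TCA/TCA"}


def test_full_penetrance_means_every_test_specimen_survives():
    pen = {"DDT": {"Leu/*": 1.0, "Ser/Ser": 1.0, "Ser/Phe": 1.0, "Phe/Phe": 1.0}}
    config = SyntheticConfig(seed=2, penetrance=pen, control_mortality=0.0)
    df = simulate_specimens(config)
    assert (df.loc[df.role == "test", "outcome"] == "alive").all()


def test_missing_penetrance_group_fails_before_sampling():
    with pytest.raises((KeyError, ValueError)):
        SyntheticConfig(seed=3, penetrance={"DDT": {"Ser/Ser": 0.5}})


def test_realized_allele_frequencies_track_truth():
    freqs = {"TTA": 0.1, "TCA": 0.4, "TTT": 0.3, "TTC": 0.2}
    site = SitePopulation("big", freqs)
    config = SyntheticConfig(
        seed=4,
        sites=[site],
        penetrance={"DDT": fixture_penetrance()["DDT"]},
        specimens_per_bioassay=125,
        n_bioassays_per_site=20,  # 2500 flies -> 5000 alleles
        n_controls_per_site=0,
    )
    df = simulate_specimens(config)
    counts = {c: 0 for c in freqs}
    for label in df["genotype"]:
        for codon in label.split("/"):
            counts[codon] += 1
    two_n = 2 * len(df)
    for codon, p in freqs.items():
        se = (p * (1 - p) / two_n) ** 0.5
        assert abs(counts[codon] / two_n - p) <= 3 * se + 1e-9


def test_control_mortality_independent_of_genotype():
    config = SyntheticConfig(seed=8, control_mortality=1.0)
    df = simulate_specimens(config)
    controls = df[df.role == "control"]
    assert len(controls) and (controls.outcome == "dead").all()


# ---------------------------------------------------------------------------
# amplicons and readouts
# ---------------------------------------------------------------------------


def test_amplicon_sequences_carry_expected_codons(reference):
    gts = [
        KdrGenotype.from_codons("TCA", "TCA"),
        KdrGenotype.from_codons("TTA", "TCA"),
        KdrGenotype.from_codons("TTT", "TTC"),
    ]
    seqs = [str(r.seq) for r in simulate_amplicons(gts, reference)]
    i = reference.coding_start + 3 * (1014 - reference.first_codon)
    assert seqs[0][i : i + 3] == "TCA"
    assert seqs[1][i : i + 3] == "TYA"
    assert seqs[2][i : i + 3] == "TTY"


def test_readout_round_trip_without_no_calls():
    gts = list(all_genotypes())
    readouts = simulate_assay_readouts(gts, no_call_rate=0.0, seed=1)
    assert [combine_assay_calls(r) for r in readouts] == gts


def test_all_no_calls_at_rate_one():
    readouts = simulate_assay_readouts(all_genotypes(), no_call_rate=1.0, seed=1)
    assert all(r.assay1 == "null" and r.assay2 == "null" for r in readouts)


def test_no_call_rate_is_calibrated():
    # only informative calls can be nulled out; genotypes invisible to one
    # assay produce a structural null there which must not be counted
    rng = np.random.default_rng(10)
    gts = [all_genotypes()[i] for i in rng.integers(0, 10, size=2000)]
    readouts = simulate_assay_readouts(gts, no_call_rate=0.1, seed=11)
    dropped = informative = 0
    for gt, readout in zip(gts, readouts):
        canonical = expected_readout(gt)
        for canon, got in (
            (canonical.assay1, readout.assay1),
            (canonical.assay2, readout.assay2),
        ):
            if canon != "null":
                informative += 1
                dropped += got == "null"
    frac = dropped / informative
    se = (0.1 * 0.9 / informative) ** 0.5
    assert abs(frac - 0.1) <= 3 * se


def test_amplicon_generation_is_seed_reproducible(reference):
    gts = list(all_genotypes())
    a = [str(r.seq) for r in simulate_amplicons(gts, reference, seed=3)]
    b = [str(r.seq) for r in simulate_amplicons(gts, reference, seed=3)]
    assert a == b


# ---------------------------------------------------------------------------
# the published-count fixture
# ---------------------------------------------------------------------------


def test_fixture_bioassay_sizes(fixture_df):
    ddt = fixture_df[fixture_df.insecticide == "DDT"]
    assert (ddt.outcome == "alive").sum() == 83
    assert (ddt.outcome == "dead").sum() == 83
    delta = fixture_df[fixture_df.insecticide == "deltamethrin"]
    assert len(delta) == 47 + 62
    assert set(fixture_df.role) == {"test"}


def test_fixture_exposure_times_and_cohorts(fixture_df):
    for ins, minutes in EXPOSURE_MINUTES.items():
        sub = fixture_df[fixture_df.insecticide == ins]
        assert set(sub.exposure_minutes) == {minutes}
    assert set(fixture_df[fixture_df.insecticide == "deltamethrin"].cohort) == {"colony"}


def test_fixture_is_deterministic():
    assert bioassay_fixture().to_csv(index=False) == bioassay_fixture().to_csv(index=False)


def test_fixture_penetrance_ratios_are_fixture_cell_ratios():
    pen = fixture_penetrance(fine=True)
    assert pen["DDT"]["Phe/Phe"] == 1.0
    assert pen["DDT"]["Ser/Ser"] == pytest.approx(28 / 43)
    assert pen["deltamethrin"]["Leu/Phe"] == pytest.approx(11 / 29)
    group = fixture_penetrance(fine=False)
    assert group["DDT"]["Leu/*"] == pytest.approx(9 / 71)
    for pmap in pen.values():
        assert all(0.0 <= p <= 1.0 for p in pmap.values())


def test_association_recovery_or_ci_covers_fixture_value():
    """Simulated bioassays under the fixture's genotype law and penetrance
    recover the Ser-vs-Leu odds ratio: the Woolf CI covers the fixture OR
    in >= 90% of replicates at 1,000 alleles (alleles arrive in genotype
    pairs, so coverage sits near, not above, the nominal CI level)."""
    table = TABLE2_COUNTS["DDT"]
    labels = list(table["alive"])
    totals = np.array([table["alive"][l] + table["dead"][l] for l in labels])
    pen = np.array([fixture_penetrance(fine=True)["DDT"][l] for l in labels])
    probs = totals / totals.sum()
    ser = np.array([l.split("/").count("Ser") for l in labels])
    leu = np.array([l.split("/").count("Leu") for l in labels])
    target_or = (93 * 82) / (68 * 12)  # fixture cross-product OR
    rng = np.random.default_rng(99)
    covered = 0
    reps = 1000
    for _ in range(reps):
        g = rng.choice(len(labels), size=500, p=probs)  # 1000 alleles
        alive = rng.random(500) < pen[g]
        tab = [
            [ser[g][alive].sum(), leu[g][alive].sum()],
            [ser[g][~alive].sum(), leu[g][~alive].sum()],
        ]
        res = odds_ratio(tab)
        if res.ci_low <= target_or <= res.ci_high:
            covered += 1
    # >= 90% within Monte-Carlo error of the 1,000-replicate estimate
    assert covered / reps >= 0.90 - 2 * math.sqrt(0.9 * 0.1 / reps)
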