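import numpy as np
import pandas as pd
import pytest

from asebead.mixture import MixtureDesign
from asebead.simulate import (SimConfig, allele_a_frequencies,
                              default_mode_counts, simulate_beads,
                              simulate_cohort, simulate_expression,
                              simulate_individual_genotypes,
                              simulate_mixture_series, simulate_trios)

# --------------------------------------------------------------- genotypes


def test_hardy_weinberg_het_fraction_at_half():
    rng = np.random.default_rng(0)
    geno = simulate_trios(5, 10_000, np.full(5, 0.5), rng)
    het = (geno["child"] == 1).mean(axis=1)
    np.testing.assert_allclose(het, 0.5, atol=0.02)


def test_monomorphic_limit_all_homozygous():
    rng = np.random.default_rng(1)
    geno = simulate_trios(3, 50, np.ones(3), rng)
    assert (geno["child"] == 2).all()
    assert (geno["mother"] == 2).all()


def test_child_dosage_equals_transmitted_alleles():
    rng = np.random.default_rng(2)
    geno = simulate_trios(20, 100, np.full(20, 0.3), rng)
    np.testing.assert_array_equal(
        geno["child"], geno["maternal_allele"] + geno["paternal_allele"])
    # a transmitted allele must exist in the parent
    assert (geno["mother"] >= geno["maternal_allele"]).all()
    assert (geno["father"] >= geno["paternal_allele"]).all()


def test_same_seed_reproduces_cohort_exactly():
    c1 = simulate_cohort(SimConfig(n_snps=12, n_trios=5, seed=9))
    c2 = simulate_cohort(SimConfig(n_snps=12, n_trios=5, seed=9))
    pd.testing.assert_frame_equal(c1.beads, c2.beads)
    pd.testing.assert_frame_equal(c1.snp_truth, c2.snp_truth)


# -------------------------------------------------------------- expression


def _expr(mode, maternal=1, paternal=0, **kw):
    cfg = SimConfig(n_snps=1, n_trios=1, **kw)
    rng = np.random.default_rng(0)
    child = np.array([[1]])
    frac = simulate_expression(child, np.array([[maternal]]),
                               np.array([[paternal]]), np.array([mode]),
                               cfg, rng, preferred_allele=np.array(["B"]))
    return float(frac[0, 0])


@pytest.mark.parametrize("mode, maternal, expected", [
    ("biallelic", 1, 0.5),
    ("imprinting_maternal", 1, 0.97),
    ("imprinting_maternal", 0, 0.03),
    ("imprinting_paternal", 1, 0.03),   # paternal allele is B here
    ("partial_imprinting", 0, 1 - 0.72),
    ("preferential", 1, 1 - 0.8),       # preferred allele forced to B
])
def test_expression_mode_rules(mode, maternal, expected):
    assert _expr(mode, maternal=maternal) == pytest.approx(expected)


def test_expression_homozygote_ignores_mode():
    cfg = SimConfig(n_snps=1, n_trios=1)
    rng = np.random.default_rng(0)
    frac = simulate_expression(np.array([[2]]), np.array([[1]]),
                               np.array([[1]]),
                               np.array(["imprinting_maternal"]), cfg, rng)
    assert frac[0, 0] == 1.0


def test_expression_unknown_mode_rejected():
    with pytest.raises(ValueError):
        _expr("nonsense")


def test_random_modes_pick_fair_coin_allele():
    cfg = SimConfig(n_snps=1, n_trios=4000)
    rng = np.random.default_rng(3)
    child = np.ones((1, 4000), dtype=int)
    frac = simulate_expression(child, child, 1 - child,
                               np.array(["random_monoallelic"]), cfg, rng)
    up = (frac > 0.5).mean()
    assert 0.45 < up < 0.55
    assert set(np.round(np.unique(frac), 6)) == {0.03, 0.97}


# ------------------------------------------------------------------- beads


def _noiseless(frac, background=0.15, dye=0.0, base=12.0):
    cfg = SimConfig(n_snps=1, n_trios=1, bead_noise_sd=1e-12,
                    beads_per_snp=4, dye_bias=dye, background=background)
    rng = np.random.default_rng(0)
    beads = simulate_beads(np.array([[frac]]), np.array([base]), cfg, rng,
                           np.array(["s"]), np.array(["s:r1"]),
                           np.array(["snp0"]))
    m = np.log2(beads["intensity_a"] / beads["intensity_b"])
    return m.to_numpy()


def test_beads_balanced_fraction_gives_zero_m():
    np.testing.assert_allclose(_noiseless(0.5), 0.0, atol=1e-9)


def test_beads_fraction_maps_through_log_ratio():
    # without cross-hybridisation background the dosage ratio is exact
    np.testing.assert_allclose(_noiseless(0.8, background=0.0), 2.0,
                               atol=1e-9)


def test_beads_dye_bias_shifts_m():
    np.testing.assert_allclose(_noiseless(0.5, dye=0.2), 0.2, atol=1e-9)


def test_bead_noise_scales_as_root_two():
    cfg = SimConfig(n_snps=1, n_trios=1, bead_noise_sd=0.3,
                    beads_per_snp=20_000, dye_bias=0.0)
    rng = np.random.default_rng(4)
    beads = simulate_beads(np.array([[0.5]]), np.array([12.0]), cfg, rng,
                           np.array(["s"]), np.array(["s:r1"]),
                           np.array(["snp0"]))
    m = np.log2(beads["intensity_a"] / beads["intensity_b"])
    assert np.std(m) == pytest.approx(np.sqrt(2) * 0.3, rel=0.03)


# ------------------------------------------------------------------ cohort


def test_cohort_shapes_and_truth_accompaniment(tmp_path):
    cfg = SimConfig(n_snps=10, n_trios=4, seed=5)
    cohort = simulate_cohort(cfg)
    n_arrays = 4 * (2 + 2 + 1 + 1)
    assert cohort.beads["array_id"].nunique() == n_arrays
    assert len(cohort.beads) == 10 * n_arrays * cfg.beads_per_snp
    assert set(cohort.snp_truth["mode"]).issubset(
        set(default_mode_counts(10)) | {"biallelic"})
    assert len(cohort.expression_truth) == 40
    cohort.write(tmp_path)
    for name in ("beads.tsv", "pedigree.tsv", "truth_snps.tsv",
                 "truth_genotypes.tsv", "truth_expression.tsv",
                 "sim_config.yaml"):
        assert (tmp_path / name).exists()


def test_cohort_missing_father_families():
    cfg = SimConfig(n_snps=6, n_trios=5, missing_father_families=2, seed=6)
    cohort = simulate_cohort(cfg)
    absent = [t for t in cohort.trios if t.father_gdna_sample is None]
    assert len(absent) == 2


def test_genotype_truth_consistent_with_bead_gdna_signal():
    """Placenta gDNA bead log-ratios reflect the recorded genotypes."""
    cohort = simulate_cohort(SimConfig(n_snps=8, n_trios=6, seed=7))
    beads = cohort.beads
    truth = cohort.genotype_truth.set_index(["snp_id", "sample_id"])["call"]
    gd = beads[beads["sample_id"].str.endswith(".Pg")]
    m = np.log2(gd["intensity_a"] / gd["intensity_b"])
    med = m.groupby([gd["snp_id"], gd["sample_id"]]).median()
    for (snp, samp), value in med.items():
        call = truth[(snp, samp)]
        if call == "AA":
            assert value > 1.5
        elif call == "BB":
            assert value < -1.5
        else:
            assert abs(value) < 1.5


# ----------------------------------------------------------------- mixture


def test_mixture_series_pure_and_balanced_fractions():
    rng = np.random.default_rng(8)
    design = MixtureDesign(proportions=((100, 0), (50, 50), (0, 100)),
                           replicates=2)
    cfg = SimConfig(n_snps=3, bead_noise_sd=1e-12, dye_bias=0.0,
                    background=0.0, beads_per_snp=4)
    beads, info, truth = simulate_mixture_series(
        ["AA", "AB", "AA"], ["BB", "AB", "AA"], design, cfg, rng)
    assert len(info) == 6
    m = np.log2(beads["intensity_a"] / beads["intensity_b"])
    by = m.groupby([beads["sample_id"], beads["snp_id"]]).mean()
    mid_100 = design.mixture_ids[0]
    mid_50 = design.mixture_ids[1]
    assert by[(mid_100, "snp0000")] > 10      # pure AA individual
    assert by[(mid_50, "snp0000")] == pytest.approx(0.0, abs=1e-6)
    # true negatives keep a constant fraction across mixtures
    tn = truth.set_index("snp_id")["label"]
    assert tn["snp0001"] == "true_negative"
    assert tn["snp0002"] == "true_negative"
    assert tn["snp0000"] == "true_positive"
    for mid in design.mixture_ids:
        assert by[(mid, "snp0001")] == pytest.approx(0.0, abs=1e-6)


def test_shared_frequencies_give_hardy_weinberg_pair_classes():
    rng = np.random.default_rng(9)
    p = allele_a_frequencies(4000, 0.3, rng)
    g1 = simulate_individual_genotypes(p, rng)
    g2 = simulate_individual_genotypes(p, rng)
    same = (g1 == g2).mean()
    # expected P(identical genotypes) = sum of squared HW class probs
    expected = (0.3 ** 2) ** 2 + (2 * 0.3 * 0.7) ** 2 + (0.7 ** 2) ** 2
    assert same == pytest.approx(expected, abs=0.03)
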