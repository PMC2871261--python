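import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asebead.ase import (bh_adjust, ebayes_moderate, estimate_variance_prior,
                         fit_snp_sample_model, platform_correlation,
                         sequenom_log_ratio, trigamma_inverse)
from asebead.config import PipelineConfig
from asebead.io import StatisticalPreconditionError

# ------------------------------------------------------------- linear fits


def test_fit_two_replicates_hand_values():
    coef, var, df = fit_snp_sample_model([1.0, 1.2])
    assert coef == pytest.approx(1.1)
    assert var == pytest.approx(0.02)
    assert df == 1


def test_fit_single_replicate_degenerate():
    coef, var, df = fit_snp_sample_model([0.7])
    assert coef == 0.7 and df == 0 and np.isnan(var)


def test_fit_null_replicates():
    coef, var, df = fit_snp_sample_model([0.0, 0.0, 0.0])
    assert coef == 0.0 and var == 0.0 and df == 2


def test_fit_empty_rejected():
    with pytest.raises(ValueError):
        fit_snp_sample_model([])


# -------------------------------------------------------- variance shrinkage


def _random_fits(seed, n=200, reps=3, d0=4.0, s02=0.05, delta=0.0):
    rng = np.random.default_rng(seed)
    sigma2 = d0 * s02 / rng.chisquare(d0, n)
    data = rng.normal(delta, np.sqrt(sigma2)[:, None], (n, reps))
    return (data.mean(axis=1), data.var(axis=1, ddof=1),
            np.full(n, reps - 1), 1.0 / np.sqrt(reps))


def test_trigamma_inverse_roundtrip():
    from scipy.special import polygamma
    for x in (0.01, 0.5, 2.0, 50.0):
        y = trigamma_inverse(x)
        assert polygamma(1, y) == pytest.approx(x, rel=1e-8)


def test_variance_prior_recovery_small():
    d0s, s0s = [], []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, 2000)
        s2 = sigma2 * rng.chisquare(1, 2000)
        d0, s0 = estimate_variance_prior(s2, 1)
        d0s.append(d0)
        s0s.append(s0)
    assert np.median(d0s) == pytest.approx(4.0, rel=0.25)
    assert np.median(s0s) == pytest.approx(0.05, rel=0.10)


def test_forced_zero_prior_df_recovers_ordinary_t():
    coef, s2, df, u = _random_fits(0)
    ms = ebayes_moderate(coef, s2, df, u, prior_df=0.0, prior_var=1.0)
    np.testing.assert_allclose(ms.mod_t, coef / (u * np.sqrt(s2)))
    np.testing.assert_array_equal(ms.df_total, df)


def test_infinite_prior_df_pins_variance_to_prior():
    coef, s2, df, u = _random_fits(1)
    ms = ebayes_moderate(coef, s2, df, u, prior_df=np.inf, prior_var=0.04)
    np.testing.assert_allclose(ms.mod_t, coef / (u * np.sqrt(0.04)))


def test_identical_variances_are_shrinkage_fixed_point():
    coef = np.linspace(-1, 1, 20)
    s2 = np.full(20, 0.3)
    ms = ebayes_moderate(coef, s2, np.full(20, 2), 0.5,
                         prior_df=5.0, prior_var=0.3)
    np.testing.assert_allclose(ms.mod_var, 0.3)


def test_moderated_variance_between_observed_and_prior():
    coef, s2, df, u = _random_fits(2)
    ms = ebayes_moderate(coef, s2, df, u)
    lo = np.minimum(s2, ms.prior_var)
    hi = np.maximum(s2, ms.prior_var)
    assert ((ms.mod_var >= lo - 1e-12) & (ms.mod_var <= hi + 1e-12)).all()
    assert (ms.p_adj >= ms.p_raw - 1e-15).all()


def test_single_replicate_fits_shrink_fully_to_prior():
    coef, s2, df, u = _random_fits(3)
    s2[:5] = np.nan
    df[:5] = 0
    ms = ebayes_moderate(coef, s2, df, u)
    np.testing.assert_allclose(ms.mod_var[:5], ms.prior_var)


def test_all_zero_variances_rejected():
    with pytest.raises(StatisticalPreconditionError):
        ebayes_moderate(np.ones(20), np.zeros(20), np.ones(20), 1.0)


def test_few_fits_falls_back_to_ordinary_t():
    coef, s2, df, u = _random_fits(4, n=5)
    with pytest.warns(UserWarning, match="ordinary t"):
        ms = ebayes_moderate(coef, s2, df, u)
    assert ms.prior_df == 0.0


def test_moderation_matches_independent_limma_reference(tmp_path):
    """Moderated t, raw p and log-odds agree with the R reference
    implementation of the same empirical-Bayes framework."""
    rng = np.random.default_rng(42)
    n, reps = 80, 3
    sigma2 = 4 * 0.05 / rng.chisquare(4, n)
    data = rng.normal(0.2, np.sqrt(sigma2)[:, None], (n, reps))
    infile = tmp_path / "fits.tsv"
    outfile = tmp_path / "limma.tsv"
    np.savetxt(infile, data, delimiter="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{infile}", header=FALSE))
        fit <- eBayes(lmFit(x, design=matrix(1, ncol(x), 1)),
                      proportion=0.01)
        write.table(cbind(fit$t, fit$p.value, fit$lods), "{outfile}",
                    sep="\\t", row.names=FALSE, col.names=FALSE)
    """)
    subprocess.run(["Rscript", "-e", script], check=True,
                   capture_output=True, text=True)
    ref = np.loadtxt(outfile)
    ms = ebayes_moderate(data.mean(1), data.var(1, ddof=1),
                         np.full(n, reps - 1), 1 / np.sqrt(reps))
    np.testing.assert_allclose(ms.mod_t, ref[:, 0], rtol=1e-10)
    np.testing.assert_allclose(ms.p_raw, ref[:, 1], rtol=1e-10)
    np.testing.assert_allclose(ms.log_odds, ref[:, 2], rtol=1e-8, atol=1e-8)


# ------------------------------------------------------------ BH adjustment


def bh_bruteforce(p):
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


@pytest.mark.parametrize("p, expected", [
    ([0.05], [0.05]),
    ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ([0.5, 0.01], [0.5, 0.02]),
])
def test_bh_adjust_hand_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected)


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(hvec := st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=200, deadline=None)
def test_bh_adjust_matches_bruteforce_and_bounds(p):
    p = np.asarray(p)
    q = bh_adjust(p)
    np.testing.assert_allclose(q, bh_bruteforce(p), rtol=1e-12, atol=1e-15)
    assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()


# ----------------------------------------------------------------- ASE call


def _stats_frame(coefs, p_adjs, fams):
    return pd.DataFrame({
        "snp_id": "s1", "sample_id": [f + ".Pc" for f in fams],
        "family_id": fams, "coef": coefs, "p_adj": p_adjs,
    })


def _summaries(a_value, fams):
    return pd.DataFrame({
        "snp_id": "s1", "sample_id": [f + ".Pc" for f in fams],
        "array_id": [f + ".Pc:r1" for f in fams], "a": a_value,
        "m": 0.0, "n_beads_used": 30, "n_beads_removed": 0,
    })


def _geno(calls, fams):
    return pd.DataFrame({"snp_id": "s1", "family_id": fams, "call": calls})


def _call(avg_a, het_coefs, het_ps, hom_coefs, hom_ps):
    from asebead.ase import call_ase
    n_het, n_hom = len(het_coefs), len(hom_coefs)
    fams = [f"F{i}" for i in range(n_het + n_hom)]
    stats = _stats_frame(list(het_coefs) + list(hom_coefs),
                         list(het_ps) + list(hom_ps), fams)
    calls = ["AB"] * n_het + ["AA"] * n_hom
    return call_ase(stats, _summaries(avg_a, fams), _geno(calls, fams))


def test_call_ase_low_intensity_blocks_flag():
    out = _call(10.0, [3.5] * 12, [1e-9] * 12, [3.8] * 10, [1e-9] * 10)
    assert not out.loc[0, "ase_flag"]
    assert out.loc[0, "crit_hets"] and out.loc[0, "crit_homs"]


def test_call_ase_strong_imprinting_pattern_flags():
    out = _call(14.0, [3.5] * 12, [1e-9] * 12, [3.8] * 10, [1e-9] * 10)
    assert bool(out.loc[0, "ase_flag"])
    assert out.loc[0, "n_hets_sig"] == 12


def test_call_ase_single_significant_het_insufficient():
    out = _call(13.0, [3.5] + [0.1] * 11, [1e-9] + [0.9] * 11,
                [3.8] * 10, [1e-9] * 10)
    assert not out.loc[0, "ase_flag"]


def test_call_ase_homozygote_fraction_criterion():
    # 7 of 10 homozygotes passing (70%) is below the 80% requirement
    out = _call(14.0, [3.5] * 12, [1e-9] * 12,
                [3.8] * 7 + [0.1] * 3, [1e-9] * 7 + [0.9] * 3)
    assert not out.loc[0, "ase_flag"]
    assert out.loc[0, "hom_pass_fraction"] == pytest.approx(0.7)


def test_call_ase_zero_homozygotes_not_evaluable():
    from asebead.ase import call_ase
    fams = [f"F{i}" for i in range(12)]
    stats = _stats_frame([3.5] * 12, [1e-9] * 12, fams)
    out = call_ase(stats, _summaries(14.0, fams), _geno(["AB"] * 12, fams))
    assert not out.loc[0, "evaluable"]
    assert not out.loc[0, "ase_flag"]


def test_call_ase_nn_genotypes_excluded_from_counts():
    from asebead.ase import call_ase
    fams = [f"F{i}" for i in range(6)]
    stats = _stats_frame([3.5] * 6, [1e-9] * 6, fams)
    out = call_ase(stats, _summaries(14.0, fams),
                   _geno(["AB", "AB", "NN", "NN", "AA", "AA"], fams))
    assert out.loc[0, "n_hets"] == 2 and out.loc[0, "n_homs"] == 2


def test_call_ase_monotone_in_intensity_threshold():
    cfg_low = PipelineConfig(intensity_threshold=11.25)
    cfg_high = PipelineConfig(intensity_threshold=13.0)
    from asebead.ase import call_ase
    fams = [f"F{i}" for i in range(6)]
    stats = _stats_frame([3.5] * 6, [1e-9] * 6, fams)
    summ = _summaries(12.0, fams)
    geno = _geno(["AB"] * 4 + ["AA"] * 2, fams)
    low = call_ase(stats, summ, geno, cfg_low)
    high = call_ase(stats, summ, geno, cfg_high)
    assert bool(low.loc[0, "ase_flag"]) >= bool(high.loc[0, "ase_flag"])
    assert not high.loc[0, "ase_flag"]


# --------------------------------------------------- platform correlation


def test_platform_correlation_perfect_and_inverse():
    x = np.array([0.1, 0.5, -0.3, 1.2, 0.0])
    assert platform_correlation(x, x) == pytest.approx(1.0)
    assert platform_correlation(x, -x) == pytest.approx(-1.0)


def test_platform_correlation_zero_variance_rejected():
    with pytest.raises(StatisticalPreconditionError):
        platform_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


def test_sequenom_log_ratio_pseudocount():
    assert sequenom_log_ratio(1.0, 0.0) == pytest.approx(1.0)
    np.testing.assert_allclose(sequenom_log_ratio([3], [1]), [1.0])


def test_platform_correlation_null_is_small():
    """Independent 1000-pair vectors give |r| < 0.1 in nearly all seeds."""
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        r = platform_correlation(rng.normal(size=1000),
                                 rng.normal(size=1000))
        hits += abs(r) < 0.1
    assert hits / n_seeds >= 0.95
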