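"""Benchmark experiments exercising the pipeline on synthetic cohorts.

Each function builds a defined study configuration, runs the relevant
pipeline arm and measures an operating characteristic: per-heterozygote
power on a strongly imprinted control-style SNP, specificity on a
well-expressed biallelic SNP, the mixture-series ROC, the type-I error
of the moderated test, variance-prior recovery, ASE-mode classification
accuracy, and end-to-end sensitivity/false-positive rate. The analysis
scripts and the acceptance checks all run through these entry points so
the reported numbers come from a single code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixture import MixtureDesign
from .pipeline import run_illumina, run_mixture
from .simulate import (SimConfig, allele_a_frequencies, default_mode_counts,
                       simulate_cohort, simulate_individual_genotypes,
                       simulate_mixture_series, simulate_trios)

H19_SNP = "snp0000"
IGF2R_SNP = "snp0001"


def _forced_trio_rows(genotypes: dict, row: int, n_het: int,
                      n_trios: int) -> None:
    """Overwrite one SNP's genotypes: the first ``n_het`` trios are
    mother AA x father BB (child an obligate heterozygote with a
    maternal A), the rest mother AA x father AA (homozygous child)."""
    child = np.array([1] * n_het + [2] * (n_trios - n_het))
    genotypes["child"][row] = child
    genotypes["mother"][row] = 2
    genotypes["father"][row] = np.array([0] * n_het
                                        + [2] * (n_trios - n_het))
    genotypes["maternal_allele"][row] = 1
    genotypes["paternal_allele"][row] = np.where(child == 1, 0, 1)


def control_snp_cohort(seed: int, n_snps: int = 300):
    """Cohort embedding two control-style SNPs among a mixed background.

    SNP ``H19_SNP`` mimics a strongly expressed, completely imprinted
    control locus: 12 heterozygous placentas, base intensity 14.
    SNP ``IGF2R_SNP`` mimics a well-expressed biallelic locus: 13
    heterozygous placentas, base intensity 12.78.

    The background panel of a few hundred SNPs keeps the between-channel
    quantile normalisation well populated (its rank mapping degrades on
    very small panels) while staying far cheaper than a full array.
    """
    config = SimConfig(n_snps=n_snps, seed=seed)
    rng = np.random.default_rng(seed)
    p_a = allele_a_frequencies(n_snps, config.maf, rng)
    genotypes = simulate_trios(n_snps, config.n_trios, p_a, rng)
    _forced_trio_rows(genotypes, 0, n_het=12, n_trios=config.n_trios)
    _forced_trio_rows(genotypes, 1, n_het=13, n_trios=config.n_trios)
    counts = default_mode_counts(n_snps - 2)
    modes = np.array([m for m, k in sorted(counts.items())
                      for _ in range(k)])
    rng.shuffle(modes)
    modes = np.concatenate([["imprinting_maternal", "biallelic"], modes])
    base = rng.uniform(*config.base_intensity_range, n_snps)
    base[0], base[1] = 14.0, 12.78
    return simulate_cohort(config, genotypes=genotypes, modes=modes,
                           base_intensity=base)


def imprinting_power_and_specificity(seed: int, n_seeds: int = 20,
                                     n_snps: int = 300) -> pd.DataFrame:
    """Per-heterozygote ASE rates for the two control-style SNPs.

    Returns one row per seed with the fraction of heterozygous placentas
    flagged (adjusted p < 0.01 and |log-fold-change| > 0.585) at the
    imprinted and at the biallelic control SNP.
    """
    rows = []
    for i in range(n_seeds):
        cohort = control_snp_cohort(seed + i, n_snps)
        res = run_illumina(cohort.beads, cohort.trios)
        ase = res["ase"].set_index("snp_id")
        rows.append({
            "seed": seed + i,
            "h19_het_rate": ase.loc[H19_SNP, "n_hets_sig"]
            / ase.loc[H19_SNP, "n_hets"],
            "h19_n_hets": int(ase.loc[H19_SNP, "n_hets"]),
            "igf2r_het_rate": ase.loc[IGF2R_SNP, "n_hets_sig"]
            / ase.loc[IGF2R_SNP, "n_hets"],
            "igf2r_n_hets": int(ase.loc[IGF2R_SNP, "n_hets"]),
        })
    return pd.DataFrame(rows)


def mixture_experiment(seed: int, n_snps: int = 1300):
    """Simulate and calibrate the default titration series.

    Returns the per-mixture AUC table and the truth-label counts.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(n_snps=n_snps, seed=seed)
    p_a = allele_a_frequencies(n_snps, config.maf, rng)
    g1 = simulate_individual_genotypes(p_a, rng)
    g2 = simulate_individual_genotypes(p_a, rng)
    design = MixtureDesign()
    beads, info, truth = simulate_mixture_series(g1, g2, design, config, rng)
    res = run_mixture(beads, info, truth, design)
    return res["auc_table"], truth


def mean_auc_at(auc_table: pd.DataFrame, p1: float, p2: float) -> float:
    """Mean AUC over the (p1:p2) and (p2:p1) mixtures."""
    sel = (((auc_table["p1"] == p1) & (auc_table["p2"] == p2))
           | ((auc_table["p1"] == p2) & (auc_table["p2"] == p1)))
    if not sel.any():
        raise ValueError(f"no mixture {p1}:{p2} in the table")
    return float(auc_table.loc[sel, "auc"].mean())


def type1_error_experiment(seed: int, n_seeds: int = 5,
                           n_snps: int = 200) -> list[float]:
    """Fraction of tests with adjusted p < 0.01 under a fully null cohort.

    Every placenta is heterozygous and every SNP biallelic, so the true
    log-ratio of every test is zero.
    """
    rates = []
    for i in range(n_seeds):
        config = SimConfig(n_snps=n_snps, seed=seed + i)
        shape = (n_snps, config.n_trios)
        genotypes = {
            "child": np.ones(shape, dtype=int),
            "mother": np.ones(shape, dtype=int),
            "father": np.ones(shape, dtype=int),
            "maternal_allele": np.ones(shape, dtype=int),
            "paternal_allele": np.zeros(shape, dtype=int),
        }
        modes = np.array(["biallelic"] * n_snps)
        cohort = simulate_cohort(config, genotypes=genotypes, modes=modes)
        res = run_illumina(cohort.beads, cohort.trios)
        stats = res["stats"]
        rates.append(float((stats["p_adj"] < 0.01).mean()))
    return rates


def variance_prior_recovery(seed: int, n_seeds: int = 20,
                            n_vars: int = 2000, prior_df: float = 4.0,
                            prior_var: float = 0.05,
                            df_resid: int = 4) -> tuple[float, float]:
    """Median recovered (d0, s0^2) over seeds of simulated variances.

    Variances follow the generative model of the moderation step: true
    residual variances are scaled inverse chi-square with (d0, s0^2),
    and observed variances are chi-square averages on ``df_resid``
    degrees of freedom. The default ``df_resid`` of 4 keeps the prior-df
    moment estimator well identified; at a single residual df the
    log-chi-square tails are heavy enough that even a median over 20
    runs of 2000 variances wanders tens of percent around the truth
    (that regime is exercised separately in the unit tests).
    """
    from .ase import estimate_variance_prior
    d0s, s0s = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        sigma2 = prior_df * prior_var / rng.chisquare(prior_df, n_vars)
        s2 = sigma2 * rng.chisquare(df_resid, n_vars) / df_resid
        d0, s0 = estimate_variance_prior(s2, df_resid)
        d0s.append(d0)
        s0s.append(s0)
    return float(np.median(d0s)), float(np.median(s0s))


def classifier_experiment(seed: int, per_mode: int = 500) -> pd.DataFrame:
    """ASE-mode classification accuracy on a balanced cohort.

    ``per_mode`` SNPs of each of the six modes (imprinting split evenly
    between maternal and paternal) at base intensities 12-15, so that
    classification rather than detection is measured. Returns per-mode
    accuracy with the confusion structure attached in ``attrs``.
    """
    counts = {"biallelic": per_mode,
              "imprinting_maternal": per_mode - per_mode // 2,
              "imprinting_paternal": per_mode // 2,
              "partial_imprinting": per_mode, "preferential": per_mode,
              "random_monoallelic": per_mode, "random_ase": per_mode}
    config = SimConfig(n_snps=sum(counts.values()), mode_counts=counts,
                       base_intensity_range=(12.0, 15.0), seed=seed)
    cohort = simulate_cohort(config)
    res = run_illumina(cohort.beads, cohort.trios)
    truth = cohort.snp_truth[["snp_id", "mode"]].copy()
    truth["mode_true"] = truth["mode"].replace(
        {"imprinting_maternal": "imprinting",
         "imprinting_paternal": "imprinting"})
    pat = res["patterns"].merge(truth[["snp_id", "mode_true"]], on="snp_id")
    acc = ((pat["mode"] == pat["mode_true"])
           .groupby(pat["mode_true"]).mean().rename("accuracy").reset_index())
    acc.attrs["confusion"] = pd.crosstab(pat["mode_true"], pat["mode"])
    return acc


def end_to_end_experiment(seed: int, n_seeds: int = 20,
                          n_snps: int = 200) -> dict:
    """Sensitivity and false-positive rate of the full pipeline.

    Default-condition cohorts; rates are computed over *assessable*
    SNPs — those above the intensity threshold with at least two
    heterozygous and one homozygous placenta — mirroring how the call
    criteria restrict the testable set.
    """
    tp = fp = n_pos = n_neg = 0
    for i in range(n_seeds):
        cohort = simulate_cohort(SimConfig(n_snps=n_snps, seed=seed + i))
        res = run_illumina(cohort.beads, cohort.trios)
        ase = res["ase"].merge(cohort.snp_truth[["snp_id", "mode"]],
                               on="snp_id")
        assessable = ase[ase["crit_intensity"] & (ase["n_hets"] >= 2)
                         & ase["evaluable"]]
        is_ase = assessable["mode"] != "biallelic"
        n_pos += int(is_ase.sum())
        n_neg += int((~is_ase).sum())
        tp += int(assessable.loc[is_ase, "ase_flag"].sum())
        fp += int(assessable.loc[~is_ase, "ase_flag"].sum())
    return {"sensitivity": tp / n_pos if n_pos else float("nan"),
            "fpr": fp / n_neg if n_neg else float("nan"),
            "n_true_ase": n_pos, "n_biallelic": n_neg}
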