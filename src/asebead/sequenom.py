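"""Medium-throughput allelic-ratio screen (mass-spectrometry arm).

Starts from per-sample allele quantifications (the fraction of allele-A
signal) with a call-quality rating. SNPs are filtered by genotyping
success rate — the fraction of attempts rated "conservative" — requiring
the cDNA/gDNA success-rate ratio to reach 75% (a proxy for sufficient
expression). On heterozygous-placenta trios a one-tailed paired t-test
asks whether the allelic skew |frac - 0.5| is larger in cDNA than in the
matching gDNA; testing the skew rather than the raw fraction keeps
imprinted genes detectable, since the over-expressed allele differs
between trios and raw fractions would cancel. P-values are BH-adjusted
across SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ase import bh_adjust

QUANT_COLUMNS = ["snp_id", "sample_id", "sample_type", "frac_a", "rating"]


def success_rate(ratings) -> float:
    """Fraction of genotyping attempts with a "conservative" rating."""
    r = list(ratings)
    if len(r) == 0:
        raise ValueError("no genotyping attempts")
    return sum(x == "conservative" for x in r) / len(r)


def sr_filter(sr_cdna: float, sr_gdna: float, min_ratio: float = 0.75) -> bool:
    """Expression filter: cDNA/gDNA success-rate ratio >= min_ratio."""
    if sr_gdna <= 0:
        raise ValueError("gDNA success rate is zero; SNP not assayable")
    return sr_cdna / sr_gdna >= min_ratio


def call_from_frac(frac_a: float, het_margin: float = 0.2) -> str:
    """Coarse genotype from a gDNA allele fraction."""
    if not np.isfinite(frac_a):
        return "NN"
    if abs(frac_a - 0.5) < het_margin:
        return "AB"
    return "AA" if frac_a > 0.5 else "BB"


def paired_allele_ttest(frac_a_cdna, frac_a_gdna) -> tuple[float, float]:
    """One-tailed paired t-test of allelic skew, cDNA vs gDNA.

    The paired difference is d_i = |c_i - 0.5| - |g_i - 0.5|; the upper
    tail of t_{n-1} tests for increased skew in cDNA. Returns (t, p);
    n < 2 raises. Identical skews give t = 0, p = 0.5.
    """
    c = np.asarray(frac_a_cdna, dtype=float)
    g = np.asarray(frac_a_gdna, dtype=float)
    if c.shape != g.shape or c.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if c.size < 2:
        raise ValueError("need at least two heterozygous trios")
    d = np.abs(c - 0.5) - np.abs(g - 0.5)
    if np.std(d, ddof=1) == 0:
        mean = float(np.mean(d))
        if mean == 0:
            return 0.0, 0.5
        return (float("inf"), 0.0) if mean > 0 else (float("-inf"), 1.0)
    res = stats.ttest_1samp(d, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def skew_difference(frac_a_cdna) -> float:
    """Mean allelic difference in cDNA, percentage points.

    mean over heterozygotes of |frac_a - frac_b| * 100
    = mean(|2*frac_a - 1|) * 100.
    """
    c = np.asarray(frac_a_cdna, dtype=float)
    if c.size == 0:
        raise ValueError("no heterozygous cDNA quantifications")
    return float(np.mean(np.abs(2.0 * c - 1.0)) * 100.0)


def analyze_sequenom(quants: pd.DataFrame, trios,
                     min_sr_ratio: float = 0.75,
                     het_margin: float = 0.2) -> pd.DataFrame:
    """Full screen: success-rate filter then paired skew test per SNP.

    ``quants`` is a long table with columns snp_id, sample_id,
    sample_type (gDNA|cDNA), frac_a, rating; sample ids follow the trio
    records (placental gDNA / cDNA per family). Heterozygous placentas
    are identified from the gDNA allele fraction. Returns one row per
    SNP with success rates, the skew test and its BH adjustment (NaN p
    for SNPs failing the filter or with fewer than two informative
    trios).
    """
    bad = ~quants["frac_a"].between(0, 1) & quants["frac_a"].notna()
    if bad.any():
        raise ValueError("frac_a outside [0, 1]")
    gdna_map = {t.placenta_gdna_sample: t.family_id for t in trios}
    cdna_map = {t.placenta_cdna_sample: t.family_id for t in trios}
    rows = []
    for snp_id, grp in quants.groupby("snp_id", sort=True):
        gd = grp[grp["sample_type"] == "gDNA"]
        cd = grp[grp["sample_type"] == "cDNA"]
        if gd.empty or cd.empty:
            continue
        sr_g = success_rate(gd["rating"])
        sr_c = success_rate(cd["rating"])
        row = {"snp_id": snp_id, "sr_gdna": sr_g, "sr_cdna": sr_c,
               "sr_ratio": sr_c / sr_g if sr_g > 0 else float("nan"),
               "n_hets": 0, "t_stat": float("nan"), "p_raw": float("nan"),
               "difference": float("nan"), "tested": False,
               "reason": ""}
        if sr_g == 0:
            row["reason"] = "gDNA success rate zero"
            rows.append(row)
            continue
        if not sr_filter(sr_c, sr_g, min_sr_ratio):
            row["reason"] = "SR ratio below threshold"
            rows.append(row)
            continue
        ok_g = gd[gd["rating"] == "conservative"]
        ok_c = cd[cd["rating"] == "conservative"]
        g_by_fam = {gdna_map[s]: f for s, f in
                    zip(ok_g["sample_id"], ok_g["frac_a"]) if s in gdna_map}
        c_by_fam = {cdna_map[s]: f for s, f in
                    zip(ok_c["sample_id"], ok_c["frac_a"]) if s in cdna_map}
        fams = [f for f in g_by_fam
                if f in c_by_fam and call_from_frac(g_by_fam[f],
                                                    het_margin) == "AB"]
        row["n_hets"] = len(fams)
        if len(fams) < 2:
            row["reason"] = "fewer than two heterozygous trios"
            rows.append(row)
            continue
        c_vec = np.array([c_by_fam[f] for f in fams])
        g_vec = np.array([g_by_fam[f] for f in fams])
        t_stat, p = paired_allele_ttest(c_vec, g_vec)
        row.update({"t_stat": t_stat, "p_raw": p, "tested": True,
                    "difference": skew_difference(c_vec)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = float("nan")
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"])
    return out
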