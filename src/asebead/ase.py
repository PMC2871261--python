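"""The ASE statistical test.

Per SNP x sample, replicate cDNA log-ratios are summarised by an
intercept-only linear model (mean and residual variance). Residual
variances are then shrunk towards a common prior by empirical Bayes:
the observed variances s_g^2 are modelled as scaled F draws around a
prior (d0, s0^2) estimated by method of moments on log s_g^2, the
posterior variance is

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g),

and moderated t-statistics t~_g = coef_g / (u_g * s~_g) are referred to
a t distribution on d0 + d_g degrees of freedom (u_g is the unscaled
standard error, 1/sqrt(n) for an n-replicate mean). Two-sided p-values
are adjusted globally by Benjamini-Hochberg. A posterior log-odds of
differential allelic expression (B-statistic) is computed for ranking
only.

The final ASE call for a SNP requires (1) average log2 intensity across
all cDNA samples above the intensity threshold, (2) at least
``min_sig_hets`` heterozygotes with adjusted p below ``alpha_adj`` and
|coef| above ``lfc_threshold``, and (3) at least
``homozygote_pass_fraction`` of homozygotes passing the same test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import StatisticalPreconditionError

MIN_FITS_FOR_SHRINKAGE = 10


def fit_snp_sample_model(replicate_m) -> tuple[float, float, int]:
    """Intercept-only fit to one SNP x sample's replicate log-ratios.

    Returns (coef, resid_var, df_resid). A single replicate yields
    df_resid = 0 and a missing (nan) variance, which the moderation step
    shrinks fully to the prior.
    """
    v = np.asarray(replicate_m, dtype=float)
    if v.size == 0:
        raise ValueError("no replicate observations")
    coef = float(np.mean(v))
    if v.size == 1:
        return coef, float("nan"), 0
    return coef, float(np.var(v, ddof=1)), v.size - 1


def trigamma_inverse(x):
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y if y.size > 1 else float(y[0])


def estimate_variance_prior(resid_var, df_resid) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0^2).

    Matches mean and variance of log s_g^2 against the theoretical
    moments of log of a scaled F / chi-square variate: for s^2 ~
    s0^2 * chi2_d/d * (d0/chi2_d0-style prior), E[log s^2] and
    Var[log s^2] involve digamma/trigamma terms; the excess variance of
    log s^2 beyond trigamma(d/2) identifies d0 via the trigamma inverse.
    Returns d0 = inf when the observed spread is at or below the
    sampling floor (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(resid_var, dtype=float)
    df = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise StatisticalPreconditionError(
            "need at least two positive residual variances to fit the prior")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)
                 - polygamma(1, d / 2.0).mean())
    if evar > 0:
        prior_df = float(2.0 * trigamma_inverse(evar))
        prior_var = float(np.exp(emean + digamma(prior_df / 2.0)
                                 - np.log(prior_df / 2.0)))
    else:
        prior_df = float("inf")
        prior_var = float(np.exp(emean))
    return prior_df, prior_var


def _tmixture_vector(tstat, unscaled_sd, df, proportion, v0_lim=None):
    """Estimate the prior variance of non-null coefficients.

    The top ``proportion/2`` of |t| values are treated as draws from the
    alternative; each contributes an estimate of the extra coefficient
    variance, and the mean is returned (clipped to ``v0_lim``).
    """
    t = np.abs(np.asarray(tstat, dtype=float))
    u2 = np.asarray(unscaled_sd, dtype=float) ** 2
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape).copy()
    n = t.size
    ntarget = int(np.ceil(proportion / 2.0 * n))
    if ntarget < 1:
        return float("nan")
    p = max(ntarget / n, proportion)
    max_df = df.max()
    low = df < max_df
    if low.any():
        log_tail = stats.t.logsf(t[low], df[low])
        t[low] = -stats.t.ppf(np.exp(np.clip(log_tail, -700, 0)), max_df)
        df[low] = max_df
    order = np.argsort(-t)[:ntarget]
    tt = t[order]
    v1 = u2[order]
    r = np.arange(1, ntarget + 1) - 0.5
    p0 = 2.0 * stats.t.sf(tt, max_df)
    ptarget = ((r / n) - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(0.5 * ptarget[pos], max_df)
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    if v0_lim is not None:
        v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(np.maximum(v0, 0).mean())


@dataclass
class ModeratedStats:
    """Arrays of per-fit moderated statistics plus the shared prior."""

    coef: np.ndarray
    resid_var: np.ndarray
    df_resid: np.ndarray
    unscaled_sd: np.ndarray
    prior_df: float
    prior_var: float
    mod_var: np.ndarray
    mod_t: np.ndarray
    df_total: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    log_odds: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "resid_var": self.resid_var,
            "df_resid": self.df_resid, "mod_var": self.mod_var,
            "mod_t": self.mod_t, "df_total": self.df_total,
            "p_raw": self.p_raw, "p_adj": self.p_adj,
            "log_odds": self.log_odds,
        })


def ebayes_moderate(coef, resid_var, df_resid, unscaled_sd,
                    prior_proportion: float = 0.01,
                    prior_df: float | None = None,
                    prior_var: float | None = None) -> ModeratedStats:
    """Empirical-Bayes moderated t-statistics for a set of fits.

    ``unscaled_sd`` is the standard-error multiplier of each coefficient
    (1/sqrt(n) for an n-replicate mean; contrast geometry otherwise).
    ``prior_df``/``prior_var`` override the method-of-moments estimates
    (used by tests probing the shrinkage limits).

    With fewer than 10 fits carrying a residual df the moderation is
    unreliable; the function falls back to ordinary t-statistics with a
    warning.
    """
    coef = np.asarray(coef, dtype=float)
    s2 = np.asarray(resid_var, dtype=float)
    df = np.asarray(df_resid, dtype=float)
    u = np.broadcast_to(np.asarray(unscaled_sd, dtype=float), coef.shape)
    with_df = np.isfinite(s2) & (df > 0)
    if not with_df.any() or np.nanmax(np.where(with_df, s2, 0)) == 0:
        raise StatisticalPreconditionError(
            "all residual variances are zero; add replicates or jitter")
    if prior_df is None or prior_var is None:
        if with_df.sum() < MIN_FITS_FOR_SHRINKAGE:
            warnings.warn(
                "fewer than 10 fits with residual df; falling back to "
                "ordinary t-statistics", stacklevel=2)
            prior_df, prior_var = 0.0, float(np.nanmedian(s2[with_df]))
        else:
            est_df, est_var = estimate_variance_prior(s2[with_df], df[with_df])
            prior_df = est_df if prior_df is None else prior_df
            prior_var = est_var if prior_var is None else prior_var

    d0, s02 = float(prior_df), float(prior_var)
    s2_filled = np.where(with_df, s2, 0.0)
    df_filled = np.where(with_df, df, 0.0)
    if np.isinf(d0):
        mod_var = np.full_like(coef, s02)
        df_total = np.full_like(coef, np.inf)
    elif d0 == 0:
        mod_var = np.where(with_df, s2_filled, s02)
        df_total = df_filled
    else:
        mod_var = (d0 * s02 + df_filled * s2_filled) / (d0 + df_filled)
        df_total = d0 + df_filled
    with np.errstate(divide="ignore", invalid="ignore"):
        mod_t = coef / (u * np.sqrt(mod_var))
    finite_df = np.where(np.isinf(df_total), 1e9, df_total)
    bad = ~np.isfinite(mod_t) | (finite_df <= 0)
    p_raw = np.ones_like(coef)
    p_raw[~bad] = 2.0 * stats.t.sf(np.abs(mod_t[~bad]), finite_df[~bad])
    mod_t = np.where(bad, 0.0, mod_t)
    p_adj = bh_adjust(p_raw)
    log_odds = _posterior_log_odds(mod_t, u, finite_df, prior_proportion,
                                   s02)
    return ModeratedStats(coef=coef, resid_var=s2, df_resid=df,
                          unscaled_sd=np.asarray(u, dtype=float),
                          prior_df=d0, prior_var=s02, mod_var=mod_var,
                          mod_t=mod_t, df_total=df_total, p_raw=p_raw,
                          p_adj=p_adj, log_odds=log_odds)


def _posterior_log_odds(mod_t, unscaled_sd, df_total, proportion,
                        prior_var=1.0):
    """B-statistic: posterior log-odds that a fit is non-null.

    Uses the standard normal-on-coefficients mixture: the non-null prior
    coefficient variance v0 is estimated from the extreme t-statistics,
    and the log-odds follow from the ratio of the two scaled-t
    likelihoods. Monotone in |t| when the design is balanced, so it is
    a pure ranking statistic.
    """
    t = np.asarray(mod_t, dtype=float)
    u = np.asarray(unscaled_sd, dtype=float)
    df = np.asarray(df_total, dtype=float)
    u2 = u ** 2
    # clip the non-null coefficient sd into [0.1, 4] absolute units;
    # v0 is relative to the residual variance, hence the prior_var scaling
    v0 = _tmixture_vector(t, u, df, proportion,
                          v0_lim=(0.01 / prior_var, 16.0 / prior_var))
    if not np.isfinite(v0) or v0 <= 0:
        v0 = np.median(u2)
    r = (u2 + v0) / u2
    t2 = t ** 2
    big = df > 1e6
    kernel = np.where(
        big,
        t2 * (1.0 - 1.0 / r) / 2.0,
        (1.0 + df) / 2.0 * np.log((t2 + df) / (t2 / r + df)))
    return np.log(proportion / (1.0 - proportion)) - 0.5 * np.log(r) + kernel


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderate_cdna_fits(summaries: pd.DataFrame, trios,
                       prior_proportion: float = 0.01) -> pd.DataFrame:
    """Fit and moderate all SNP x placenta-cDNA models of a run.

    ``summaries`` is the preprocessed long table; only rows whose
    sample_id is a trio's placental cDNA sample are used. Returns a long
    frame keyed by (snp_id, sample_id) with the moderated statistics;
    BH adjustment is global across every fit in the frame.
    """
    cdna_samples = {t.placenta_cdna_sample: t.family_id for t in trios}
    sub = summaries[summaries["sample_id"].isin(cdna_samples)]
    if sub.empty:
        raise StatisticalPreconditionError("no placental cDNA summaries found")
    grouped = sub.groupby(["snp_id", "sample_id"], sort=True, observed=True)
    agg = grouped["m"].agg(coef="mean", resid_var="var", n="count")
    agg = agg.reset_index()
    agg["df_resid"] = agg["n"] - 1
    ms = ebayes_moderate(agg["coef"].to_numpy(),
                         agg["resid_var"].to_numpy(),
                         agg["df_resid"].to_numpy(),
                         1.0 / np.sqrt(agg["n"].to_numpy()),
                         prior_proportion=prior_proportion)
    out = pd.concat([agg[["snp_id", "sample_id", "n"]], ms.frame()], axis=1)
    out.attrs["prior_df"] = ms.prior_df
    out.attrs["prior_var"] = ms.prior_var
    out["family_id"] = out["sample_id"].map(cdna_samples)
    return out


def call_ase(stats_frame: pd.DataFrame, summaries: pd.DataFrame,
             placenta_genotypes: pd.DataFrame,
             config: PipelineConfig | None = None) -> pd.DataFrame:
    """Apply the three-criterion ASE call rule per SNP.

    Parameters
    ----------
    stats_frame : long moderated-statistics table from
        :func:`moderate_cdna_fits` (one row per SNP x cDNA sample).
    summaries : preprocessed long table (for average intensity, computed
        over the same cDNA sample rows used for testing).
    placenta_genotypes : columns snp_id, family_id, call — placental
        gDNA genotype per family (NN rows are excluded from both the
        heterozygote and homozygote counts).

    Returns one row per SNP with the three sub-criteria, counts and the
    final ``ase_flag``. SNPs with zero genotyped homozygotes cannot
    evaluate criterion 3: they are reported with ``evaluable`` False and
    ``ase_flag`` False.
    """
    config = config or PipelineConfig()
    geno = placenta_genotypes.set_index(["snp_id", "family_id"])["call"]
    df = stats_frame.copy()
    df["call"] = geno.reindex(
        pd.MultiIndex.from_frame(df[["snp_id", "family_id"]])).to_numpy()
    df["call"] = df["call"].fillna("NN")
    df["sig"] = ((df["p_adj"] < config.alpha_adj)
                 & (df["coef"].abs() > config.lfc_threshold))

    cdna_samples = set(stats_frame["sample_id"].unique())
    avg_a = (summaries[summaries["sample_id"].isin(cdna_samples)]
             .groupby("snp_id", observed=True)["a"].mean())

    rows = []
    for snp_id, grp in df.groupby("snp_id", sort=True, observed=True):
        hets = grp[grp["call"] == "AB"]
        homs = grp[grp["call"].isin(("AA", "BB"))]
        n_hets_sig = int(hets["sig"].sum())
        n_homs_sig = int(homs["sig"].sum())
        hom_frac = n_homs_sig / len(homs) if len(homs) else float("nan")
        avg_intensity = float(avg_a.get(snp_id, float("nan")))
        crit_intensity = avg_intensity > config.intensity_threshold
        crit_hets = n_hets_sig >= config.min_sig_hets
        evaluable = len(homs) > 0
        crit_homs = evaluable and hom_frac >= config.homozygote_pass_fraction
        rows.append({
            "snp_id": snp_id, "avg_intensity": avg_intensity,
            "n_hets": len(hets), "n_hets_sig": n_hets_sig,
            "n_homs": len(homs), "n_homs_sig": n_homs_sig,
            "hom_pass_fraction": hom_frac,
            "crit_intensity": crit_intensity, "crit_hets": crit_hets,
            "crit_homs": bool(crit_homs), "evaluable": evaluable,
            "ase_flag": bool(crit_intensity and crit_hets and crit_homs),
        })
    return pd.DataFrame(rows)


def sequenom_log_ratio(x, y):
    """Cross-platform log-ratio with pseudo-counts: log2((x+1)/(y+1))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.log2((x + 1.0) / (y + 1.0))


def platform_correlation(log_ratios_x, log_ratios_y) -> float:
    """Pearson correlation of paired log-ratios from two platforms."""
    x = np.asarray(log_ratios_x, dtype=float)
    y = np.asarray(log_ratios_y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticalPreconditionError(
            "correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y)[0])
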