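"""Sensitivity/specificity calibration from a two-individual gDNA
titration series.

Genomic DNA of two individuals is mixed in known proportions and
hybridised in duplicate. For each SNP a linear model across the mixture
arrays yields contrasts of every mixture against the 50:50 reference
(cancelling dye bias and systematic shifts), with empirical-Bayes
moderated statistics. Genotype pairs define ground truth: SNPs where
the two individuals differ (AA:BB, AA:AB, ...) must shift with mixing
(true positives); identical genotypes must not (true negatives). Ranking
SNPs by their posterior log-odds per contrast gives ROC curves and AUCs
per mixing ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .ase import ebayes_moderate
from .io import StatisticalPreconditionError

# The titration series: percentage of individual 1 vs individual 2.
# The 5:95 point appears twice in the assayed series; duplicate design
# entries are kept as separate conditions.
DEFAULT_PROPORTIONS: tuple[tuple[int, int], ...] = (
    (0, 100), (5, 95), (91, 9), (83, 17), (67, 33), (64, 36), (60, 40),
    (56, 44), (50, 50), (44, 56), (40, 60), (36, 64), (33, 67), (17, 83),
    (9, 91), (5, 95), (100, 0),
)


@dataclass
class MixtureDesign:
    """Ordered list of mixing proportions, each hybridised in replicate."""

    proportions: tuple[tuple[float, float], ...] = DEFAULT_PROPORTIONS
    replicates: int = 2

    def __post_init__(self) -> None:
        for p1, p2 in self.proportions:
            if abs(p1 + p2 - 100.0) > 1e-9:
                raise ValueError(f"proportions must sum to 100: {(p1, p2)}")
        if (50.0, 50.0) not in [(float(a), float(b))
                                for a, b in self.proportions]:
            raise ValueError("design must include the 50:50 reference")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per mixture")

    @property
    def mixture_ids(self) -> list[str]:
        return [f"mix{i:02d}_{int(p1)}-{int(p2)}"
                for i, (p1, p2) in enumerate(self.proportions)]

    @property
    def reference_id(self) -> str:
        for mid, (p1, p2) in zip(self.mixture_ids, self.proportions):
            if float(p1) == 50.0 and float(p2) == 50.0:
                return mid
        raise AssertionError("validated design lost its 50:50 entry")


_DOSAGE = {"AA": 2, "AB": 1, "BB": 0}

TRUE_POSITIVE_PAIRS = {("AA", "BB"), ("BB", "AA"), ("AA", "AB"), ("BB", "AB"),
                       ("AB", "AA"), ("AB", "BB")}
TRUE_NEGATIVE_PAIRS = {("AA", "AA"), ("BB", "BB"), ("AB", "AB")}


def build_truth_sets(genotypes_1: dict, genotypes_2: dict) -> pd.DataFrame:
    """Label SNPs TP/TN/excluded from the two individuals' genotypes.

    A pair of differing genotypes implies the allelic ratio moves with
    the mixing proportion (true positive); identical genotypes imply no
    movement (true negative); NN on either side is excluded.
    """
    rows = []
    for snp_id in sorted(set(genotypes_1) | set(genotypes_2)):
        g1 = genotypes_1.get(snp_id, "NN")
        g2 = genotypes_2.get(snp_id, "NN")
        if g1 == "NN" or g2 == "NN":
            label, reason = "excluded", "missing genotype"
        elif (g1, g2) in TRUE_POSITIVE_PAIRS:
            label, reason = "true_positive", f"{g1}:{g2}"
        elif (g1, g2) in TRUE_NEGATIVE_PAIRS:
            label, reason = "true_negative", f"{g1}:{g2}"
        else:  # unreachable with the four-symbol alphabet
            label, reason = "excluded", f"unrecognised pair {g1}:{g2}"
        rows.append({"snp_id": snp_id, "label": label, "reason": reason})
    return pd.DataFrame(rows)


def blend_fraction(call_1: str, call_2: str, p1: float, p2: float) -> float:
    """Allele-A fraction of a gDNA blend from the two genotype dosages."""
    d1, d2 = _DOSAGE[call_1], _DOSAGE[call_2]
    return (p1 * d1 + p2 * d2) / (2.0 * (p1 + p2))


def mixture_contrasts(summaries: pd.DataFrame, design: MixtureDesign,
                      prior_proportion: float = 0.01) -> pd.DataFrame:
    """Per-SNP contrasts of each mixture against the 50:50 reference.

    ``summaries`` is the preprocessed long table whose ``array_id``
    carries a ``mixture_id`` column (one row per SNP x array). Per SNP a
    mixture-indexed linear model is fitted (group means; residual
    variance pooled across mixtures). Each contrast mean_M(mix) -
    mean_M(50:50) is moderated with the empirical-Bayes machinery shared
    with the ASE test, giving a moderated t and log-odds per SNP per
    mixture.
    """
    ref = design.reference_id
    if ref not in set(summaries["mixture_id"]):
        raise StatisticalPreconditionError("no arrays for the 50:50 reference")
    n_ref_arrays = summaries.loc[summaries["mixture_id"] == ref,
                                 "array_id"].nunique()
    if n_ref_arrays < 2:
        raise StatisticalPreconditionError(
            "need at least two replicates of the 50:50 mixture")

    cell = (summaries.groupby(["snp_id", "mixture_id"], observed=True)["m"]
            .agg(["mean", "count", "var"]).reset_index())
    # pooled residual variance per SNP: sum (n_i - 1) s_i^2 / sum (n_i - 1)
    cell["ss"] = cell["var"].fillna(0.0) * (cell["count"] - 1)
    per_snp = cell.groupby("snp_id", observed=True).agg(
        ss=("ss", "sum"), df=("count", lambda c: int((c - 1).sum())))
    per_snp["resid_var"] = per_snp["ss"] / per_snp["df"].where(per_snp["df"] > 0)

    wide_mean = cell.pivot(index="snp_id", columns="mixture_id", values="mean")
    wide_n = cell.pivot(index="snp_id", columns="mixture_id", values="count")
    snp_ids = wide_mean.index.to_numpy()
    others = [m for m in design.mixture_ids if m != ref and m in wide_mean]

    frames = []
    for mid in others:
        contrast = (wide_mean[mid] - wide_mean[ref]).to_numpy()
        u = np.sqrt(1.0 / wide_n[mid].to_numpy() + 1.0 / wide_n[ref].to_numpy())
        frames.append(pd.DataFrame({
            "snp_id": snp_ids, "mixture_id": mid, "contrast": contrast,
            "unscaled_sd": u,
            "resid_var": per_snp["resid_var"].reindex(snp_ids).to_numpy(),
            "df_resid": per_snp["df"].reindex(snp_ids).to_numpy(),
        }))
    long = pd.concat(frames, ignore_index=True).dropna(subset=["contrast"])

    out_parts = []
    for mid, grp in long.groupby("mixture_id", sort=False):
        ms = ebayes_moderate(grp["contrast"].to_numpy(),
                             grp["resid_var"].to_numpy(),
                             grp["df_resid"].to_numpy(),
                             grp["unscaled_sd"].to_numpy(),
                             prior_proportion=prior_proportion)
        part = grp[["snp_id", "mixture_id", "contrast"]].reset_index(drop=True)
        part = pd.concat([part, ms.frame()[["mod_t", "p_raw", "p_adj",
                                            "log_odds"]]], axis=1)
        out_parts.append(part)
    return pd.concat(out_parts, ignore_index=True)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC and the full sensitivity/specificity curve for one contrast.

    ``labels`` are "true_positive"/"true_negative" (others must be
    filtered upstream). The AUC equals the Mann-Whitney U statistic
    normalised by n_TP * n_TN, ties counting one half.
    """
    y = np.asarray([1 if l == "true_positive" else 0 for l in labels])
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise StatisticalPreconditionError(
            "ROC needs at least one true positive and one true negative")
    if np.unique(s).size == 1:
        # degenerate scores: every threshold is equivalent, AUC is 1/2
        curve = pd.DataFrame({"threshold": [s[0]],
                              "sensitivity": [1.0], "specificity": [0.0]})
        return 0.5, curve
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": tpr,
                          "specificity": 1.0 - fpr})
    return auc, curve


def mixture_auc_table(contrasts: pd.DataFrame, truth: pd.DataFrame,
                      design: MixtureDesign,
                      score: str = "log_odds") -> tuple[pd.DataFrame, dict]:
    """AUC per non-reference mixture, ranking SNPs by ``score``."""
    labels = truth.set_index("snp_id")["label"]
    rows, curves = [], {}
    mix_props = dict(zip(design.mixture_ids, design.proportions))
    for mid, grp in contrasts.groupby("mixture_id", sort=False):
        lab = labels.reindex(grp["snp_id"]).to_numpy()
        keep = np.isin(lab, ("true_positive", "true_negative"))
        auc, curve = roc_auc(grp.loc[keep, score].to_numpy(), lab[keep])
        p1, p2 = mix_props[mid]
        rows.append({"mixture_id": mid, "p1": p1, "p2": p2, "auc": auc,
                     "n_tp": int((lab[keep] == "true_positive").sum()),
                     "n_tn": int((lab[keep] == "true_negative").sum())})
        curves[mid] = curve
    return pd.DataFrame(rows), curves
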