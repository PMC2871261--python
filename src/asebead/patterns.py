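"""Parent-of-origin inference and ASE-mode classification.

For a heterozygous placenta the sign of the cDNA log-ratio names the
over-expressed allele; if at least one parent is homozygous the
transmitting parent of that allele can be deduced (a homozygous mother
identifies the maternal allele even when the father is absent). SNPs
flagged by the ASE test are then sorted into six modes:

1. imprinting — significant heterozygotes consistently over-express the
   allele from one parent, with near-complete silencing of the other;
2. partial_imprinting — the parental bias is consistent but silencing is
   incomplete;
3. preferential — one allele *identity* is over-expressed regardless of
   parental origin;
4. random_monoallelic — near-complete silencing of a randomly chosen
   allele, no parental or allelic consistency;
5. random_ase — significant but inconsistent imbalance;
plus biallelic for SNPs that fail the ASE test and unclassified when
too few informative trios exist to judge.

"Complete" silencing is judged against the SNP's homozygous-gDNA
log-ratio magnitude, the array's effective dynamic range: the cDNA
log-ratio of a truly monoallelic transcript approaches (but, with any
residual expression, stays below) the homozygote value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassifyConfig

MODES = ("imprinting", "partial_imprinting", "preferential",
         "random_monoallelic", "random_ase", "biallelic", "unclassified")


@dataclass(frozen=True)
class OriginCall:
    """Expressed allele and its parental origin for one trio at one SNP."""

    family_id: str
    snp_id: str
    expressed_allele: str          # "A" or "B" (sign of the cDNA log-ratio)
    origin: str                    # maternal | paternal | uninformative
    completeness: str | None       # complete | partial | None (no reference)
    mendelian_error: bool = False


@dataclass(frozen=True)
class PatternCall:
    snp_id: str
    mode: str
    oriented_parent: str           # maternal | paternal | none
    preferred_allele: str          # A | B | none
    fold_difference: float
    n_informative: int
    n_significant: int


def infer_origin(child: str, mother: str, father: str | None, cdna_m: float,
                 family_id: str = "", snp_id: str = "",
                 reference_m: float | None = None,
                 completeness_factor: float = 0.8) -> OriginCall:
    """Deduce the parental origin of the over-expressed allele.

    Requires a heterozygous placenta (child "AB") and a nonzero cDNA
    log-ratio. With a homozygous parent the origin follows from
    transmission: the parent homozygous for the expressed allele must
    have transmitted it; a parent homozygous for the *other* allele
    implies the expressed allele came from the other side. Both parents
    heterozygous (or the needed parent missing) is uninformative. Both
    parents homozygous for the same allele cannot produce a heterozygous
    child and is flagged as a Mendelian error.
    """
    if child != "AB":
        raise ValueError("parent-of-origin inference requires an AB placenta")
    expressed = "A" if cdna_m > 0 else "B"
    other = "B" if expressed == "A" else "A"
    mother = mother or "NN"
    father = father or "NN"

    if mother in ("AA", "BB") and father in ("AA", "BB") and mother == father:
        return OriginCall(family_id, snp_id, expressed, "uninformative",
                          _completeness(cdna_m, reference_m,
                                        completeness_factor),
                          mendelian_error=True)
    origin = "uninformative"
    if mother == 2 * expressed or father == 2 * other:
        origin = "maternal"
    elif father == 2 * expressed or mother == 2 * other:
        origin = "paternal"
    return OriginCall(family_id, snp_id, expressed, origin,
                      _completeness(cdna_m, reference_m, completeness_factor))


def _completeness(cdna_m: float, reference_m: float | None,
                  factor: float) -> str | None:
    if reference_m is None or not np.isfinite(reference_m) or reference_m <= 0:
        return None
    return "complete" if abs(cdna_m) >= factor * reference_m else "partial"


def homozygote_reference_m(summaries: pd.DataFrame,
                           genotypes: pd.DataFrame) -> pd.Series:
    """Median |M| of homozygous gDNA measurements per SNP.

    ``summaries`` holds gDNA rows (long table with snp_id, sample_id, m);
    ``genotypes`` maps (snp_id, sample_id) to a call. Only AA/BB samples
    contribute. SNPs without any homozygote get NaN.
    """
    geno = genotypes.set_index(["snp_id", "sample_id"])["call"]
    key = pd.MultiIndex.from_frame(summaries[["snp_id", "sample_id"]])
    calls = geno.reindex(key).to_numpy()
    hom = summaries[np.isin(calls, ("AA", "BB"))]
    return hom.groupby("snp_id", observed=True)["m"].agg(
        lambda v: float(np.median(np.abs(v))))


def classify_pattern(snp_id: str, origin_calls: list[OriginCall],
                     significant: list[bool], ase_flag: bool,
                     fold_diff: float = float("nan"),
                     config: ClassifyConfig | None = None) -> PatternCall:
    """Assign one SNP to an ASE mode by a first-match decision ladder.

    ``origin_calls`` covers the informative heterozygous trios of the
    SNP, ``significant`` marks which of them passed the per-sample ASE
    test. Consistency fractions are computed over the significant calls
    (parental shares over the origin-informative subset).
    """
    config = config or ClassifyConfig()
    if not ase_flag:
        return PatternCall(snp_id, "biallelic", "none", "none", fold_diff,
                           len(origin_calls), int(np.sum(significant)))
    sig_calls = [c for c, s in zip(origin_calls, significant) if s]
    n_sig = len(sig_calls)
    informative = [c for c in sig_calls if c.origin in ("maternal", "paternal")]

    complete_frac = (np.mean([c.completeness == "complete" for c in sig_calls])
                     if n_sig else 0.0)
    allele_counts = pd.Series([c.expressed_allele for c in sig_calls])
    allele_share = allele_counts.value_counts(normalize=True).max() if n_sig else 0.0
    top_allele = allele_counts.value_counts().idxmax() if n_sig else "none"

    if len(informative) >= config.min_origin_informative:
        origins = pd.Series([c.origin for c in informative])
        parent_share = origins.value_counts(normalize=True).max()
        top_parent = origins.value_counts().idxmax()
        if parent_share >= config.parent_share:
            if complete_frac >= config.complete_fraction:
                return PatternCall(snp_id, "imprinting", top_parent, "none",
                                   fold_diff, len(origin_calls), n_sig)
            return PatternCall(snp_id, "partial_imprinting", top_parent,
                               "none", fold_diff, len(origin_calls), n_sig)
    if n_sig and allele_share >= config.allele_share:
        return PatternCall(snp_id, "preferential", "none", top_allele,
                           fold_diff, len(origin_calls), n_sig)
    if n_sig and complete_frac >= config.complete_fraction:
        return PatternCall(snp_id, "random_monoallelic", "none", "none",
                           fold_diff, len(origin_calls), n_sig)
    if len(informative) >= config.min_origin_informative:
        # origins were observable and inconsistent: genuinely random ASE
        return PatternCall(snp_id, "random_ase", "none", "none",
                           fold_diff, len(origin_calls), n_sig)
    return PatternCall(snp_id, "unclassified", "none", "none", fold_diff,
                       len(origin_calls), n_sig)


def allele_intensities_from_ma(m, a):
    """Reconstruct per-allele raw intensities from (M, A).

    allele_a = 2**(A + M/2), allele_b = 2**(A - M/2); their ratio is
    2**M and their geometric mean 2**A.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    return 2.0 ** (a + m / 2.0), 2.0 ** (a - m / 2.0)


def fold_difference(raw_expressed, raw_silenced) -> float:
    """Mean expressed-allele intensity over mean silenced-allele intensity."""
    e = np.asarray(raw_expressed, dtype=float)
    s = np.asarray(raw_silenced, dtype=float)
    if e.size == 0 or s.size == 0:
        raise ValueError("need at least one informative sample")
    if np.any(e <= 0) or np.any(s <= 0):
        raise ValueError("allele intensities must be positive")
    return float(np.mean(e) / np.mean(s))


def snp_fold_difference(m_values, a_values) -> float:
    """Fold difference of expressed vs silenced allele for one SNP.

    For each informative cDNA sample the expressed allele is the one
    with the larger reconstructed intensity; means are taken across
    samples on the raw scale.
    """
    ia, ib = allele_intensities_from_ma(m_values, a_values)
    expressed = np.maximum(ia, ib)
    silenced = np.minimum(ia, ib)
    return fold_difference(expressed, silenced)
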