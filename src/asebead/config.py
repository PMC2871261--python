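"""Run configuration for the ASE bead-array pipeline.

Defaults correspond to the GoldenGate allele-specific-expression screen
this package models: average log2 intensity above 11.25 arbitrary
fluorescence units, an absolute log-fold-change above log2(60/40) = 0.585
(the mixture-calibrated detection limit), adjusted p below 0.01, at least
two significant heterozygotes and at least 80% of homozygotes passing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


def lfc_threshold_from_ratio(major: float, minor: float) -> float:
    """Absolute log2 fold-change implied by a mixing ratio, e.g. 60:40.

    A 60:40 allelic imbalance corresponds to |log2(60/40)| = 0.585, the
    smallest imbalance the titration experiment resolves reliably.
    """
    if major <= 0 or minor <= 0:
        raise ValueError("mixing proportions must be positive")
    return abs(math.log2(major / minor))


@dataclass
class PipelineConfig:
    """Thresholds and tuning knobs for the ASE analysis.

    Attributes
    ----------
    intensity_threshold : float
        Minimum average log2 intensity (A) across cDNA samples for a SNP
        to be considered reliably quantified (criterion 1).
    lfc_threshold : float
        Minimum absolute fitted log-ratio for a sample to count as
        allelically imbalanced (criterion 2/3), log2 units.
    alpha_adj : float
        BH-adjusted p-value cutoff.
    min_sig_hets : int
        Minimum number of significant heterozygotes (criterion 2).
    homozygote_pass_fraction : float
        Minimum fraction of homozygotes that must show the imbalance
        expected from their genotype (criterion 3).
    mad_k : float
        Bead-outlier cutoff in (unscaled) median-absolute-deviations.
    genotype_call_margin : float
        Symmetric gDNA log-ratio margin of the threshold genotype caller.
    """

    intensity_threshold: float = 11.25
    lfc_threshold: float = 0.585
    alpha_adj: float = 0.01
    min_sig_hets: int = 2
    homozygote_pass_fraction: float = 0.80
    mad_k: float = 3.0
    genotype_call_margin: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intensity_threshold", "lfc_threshold", "alpha_adj",
                     "mad_k", "genotype_call_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_sig_hets < 1:
            raise ValueError("min_sig_hets must be >= 1")
        if not 0.0 < self.homozygote_pass_fraction <= 1.0:
            raise ValueError("homozygote_pass_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassifyConfig:
    """Thresholds codifying the visual ASE-mode categorisation.

    ``completeness_factor``: a heterozygote's cDNA log-ratio counts as
    *complete* silencing when |M| reaches this fraction of the SNP's
    homozygous-gDNA reference |M| (the array's dynamic-range proxy).
    ``parent_share`` / ``allele_share``: minimum fraction of informative
    significant heterozygotes sharing one parental origin (imprinting) or
    one over-expressed allele identity (preferential ASE).
    """

    completeness_factor: float = 0.8
    parent_share: float = 0.8
    allele_share: float = 0.9
    complete_fraction: float = 0.8
    min_origin_informative: int = 2

    def __post_init__(self) -> None:
        for name in ("completeness_factor", "parent_share", "allele_share",
                     "complete_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
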