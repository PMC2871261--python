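#!/usr/bin/env python
"""Generate the synthetic 23-trio cohort used by the downstream analyses.

Writes the pedigree and full ground truth (per-SNP mode, genotypes,
true allelic fractions) under results/cohort/, plus a small bead-level
excerpt illustrating the raw input format. The full bead table
(~800k rows) is regenerated from the seed by the later scripts rather
than stored.
"""

from pathlib import Path

from asebead.io import write_bead_table, write_pedigree
from asebead.simulate import SimConfig, simulate_cohort

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    config = SimConfig(n_snps=200, seed=SEED)
    cohort = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_pedigree(cohort.trios, OUT / "pedigree.tsv")
    cohort.snp_truth.to_csv(OUT / "truth_snps.tsv", sep="\t", index=False)
    cohort.genotype_truth.to_csv(OUT / "truth_genotypes.tsv", sep="\t",
                                 index=False)
    cohort.expression_truth.to_csv(OUT / "truth_expression.tsv", sep="\t",
                                   index=False)
    excerpt = cohort.beads[cohort.beads["snp_id"].isin(["snp0000",
                                                        "snp0001"])]
    write_bead_table(excerpt, OUT / "beads_excerpt.tsv")

    modes = cohort.snp_truth["mode"].value_counts()
    print(f"cohort: {config.n_snps} SNPs x {config.n_trios} trios, "
          f"{cohort.beads['array_id'].nunique()} arrays, "
          f"{len(cohort.beads):,} beads (seed {SEED})")
    print("per-SNP expression modes:")
    print(modes.to_string())
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
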