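"""Synthetic trio-cohort and titration-series generator.

Emulates the study design the pipeline assumes: 23 family trios, each
contributing placental gDNA and cDNA hybridised in duplicate plus one
array per parent, ~30 beads per SNP, two-channel log-normal bead noise
and an additive per-array dye bias. Parental genotypes are drawn from
Hardy-Weinberg equilibrium at each SNP's minor-allele frequency, and
children receive one uniformly chosen allele from each parent, with the
transmitted alleles retained as ground truth.

Expression model for a heterozygous placenta (true allele-A fraction of
the cDNA): biallelic 0.5; imprinting expresses the maternal (or
paternal) allele at the ``silencing`` fraction (default 0.97 — complete
imprinting still leaves a few percent of residual expression); partial
imprinting uses a milder maternal bias; preferential ASE favours a fixed
allele identity; random monoallelic / random ASE favour a fair-coin
allele per sample. Homozygotes carry only one allele (fraction 0 or 1).

Bead intensities: channel A of one bead is
``2**(base + log2(2*frac_a + background) + dye_bias/2 + N(0, sd))`` and
channel B the mirror image. ``background`` models cross-hybridisation of
the absent allele and bounds the array's dynamic range: with the default
0.15 a homozygote reads |M| ~ 3.8 and a 97%-silenced transcript ~ 3.3,
so complete imprinting approaches but does not exceed the homozygous
reference, as on real arrays.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import TrioRecord
from .mixture import MixtureDesign, blend_fraction, build_truth_sets

MODE_NAMES = ("biallelic", "imprinting_maternal", "imprinting_paternal",
              "partial_imprinting", "preferential", "random_monoallelic",
              "random_ase")


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_trios: int = 23
    n_snps: int = 200
    maf: float = 0.3
    mode_counts: dict | None = None        # mode -> number of SNPs
    base_intensity_range: tuple[float, float] = (9.0, 15.0)
    bead_noise_sd: float = 0.3
    beads_per_snp: int = 30
    replicates: int = 2
    dye_bias: float = 0.1
    silencing: float = 0.97
    partial_bias: float = 0.72
    preferential_bias: float = 0.8
    random_ase_bias: float = 0.75
    background: float = 0.15
    missing_father_families: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        for name in ("silencing", "partial_bias", "preferential_bias",
                     "random_ase_bias"):
            if not 0.5 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0.5, 1]")
        if self.mode_counts is not None:
            for mode in self.mode_counts:
                if mode not in MODE_NAMES:
                    raise ValueError(f"unknown ASE mode {mode!r}")
            if sum(self.mode_counts.values()) != self.n_snps:
                raise ValueError("mode_counts must sum to n_snps")


def default_mode_counts(n_snps: int) -> dict:
    """Roughly one fifth of SNPs carry ASE, split across the five modes
    (mirroring the observed proportion of significant SNPs among those
    passing quality control)."""
    per_mode = max(1, round(0.04 * n_snps))
    counts = {m: per_mode for m in MODE_NAMES if m != "biallelic"}
    counts["biallelic"] = n_snps - sum(counts.values())
    if counts["biallelic"] < 0:
        raise ValueError("n_snps too small for the default mode mix")
    return counts


@dataclass
class Cohort:
    """A simulated trio cohort plus full ground truth."""

    config: SimConfig
    trios: list
    samples: pd.DataFrame          # sample_id, family_id, role, template
    snp_truth: pd.DataFrame        # snp_id, mode, p_allele_a, base_intensity,
                                   # preferred_allele
    genotype_truth: pd.DataFrame   # snp_id, sample_id, call (all gDNA people)
    expression_truth: pd.DataFrame  # snp_id, family_id, child_call,
                                    # maternal_allele, paternal_allele, frac_a
    beads: pd.DataFrame            # bead-level two-channel intensities

    def write(self, outdir) -> None:
        from pathlib import Path
        from . import io as _io
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_bead_table(self.beads, out / "beads.tsv")
        _io.write_pedigree(self.trios, out / "pedigree.tsv")
        self.snp_truth.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        self.genotype_truth.to_csv(out / "truth_genotypes.tsv", sep="\t",
                                   index=False)
        self.expression_truth.to_csv(out / "truth_expression.tsv", sep="\t",
                                     index=False)
        import yaml
        cfg = asdict(self.config)
        cfg["base_intensity_range"] = list(cfg["base_intensity_range"])
        (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg))


def simulate_trios(n_snps: int, n_trios: int, p_allele_a, rng):
    """Hardy-Weinberg parents and Mendelian transmission.

    Returns a dict of (n_snps, n_trios) integer arrays: child/mother/
    father allele-A dosages and the transmitted maternal/paternal
    alleles (1 = A, 0 = B).
    """
    p = np.broadcast_to(np.asarray(p_allele_a, float)[:, None],
                        (n_snps, n_trios))
    m1, m2, f1, f2 = (rng.random((n_snps, n_trios)) < p for _ in range(4))
    pick_m = rng.integers(0, 2, (n_snps, n_trios)).astype(bool)
    pick_f = rng.integers(0, 2, (n_snps, n_trios)).astype(bool)
    mt = np.where(pick_m, m1, m2).astype(int)
    ft = np.where(pick_f, f1, f2).astype(int)
    return {
        "mother": m1.astype(int) + m2.astype(int),
        "father": f1.astype(int) + f2.astype(int),
        "child": mt + ft,
        "maternal_allele": mt,
        "paternal_allele": ft,
    }


def simulate_expression(child, maternal_allele, paternal_allele, modes,
                        config: SimConfig, rng,
                        preferred_allele=None) -> np.ndarray:
    """True cDNA allele-A fraction per SNP x trio.

    Homozygotes express their only allele (fraction 1 or 0); modes act on
    heterozygotes as documented in the module docstring.
    """
    n_snps, n_trios = child.shape
    modes = np.asarray(modes)
    frac = child / 2.0                      # homozygote default
    het = child == 1
    s, b_part = config.silencing, config.partial_bias
    b_pref, b_rand = config.preferential_bias, config.random_ase_bias
    coin = rng.integers(0, 2, (n_snps, n_trios)).astype(bool)
    for i, mode in enumerate(modes):
        row = het[i]
        if mode == "biallelic":
            frac[i, row] = 0.5
        elif mode == "imprinting_maternal":
            frac[i, row] = np.where(maternal_allele[i, row] == 1, s, 1 - s)
        elif mode == "imprinting_paternal":
            frac[i, row] = np.where(paternal_allele[i, row] == 1, s, 1 - s)
        elif mode == "partial_imprinting":
            frac[i, row] = np.where(maternal_allele[i, row] == 1,
                                    b_part, 1 - b_part)
        elif mode == "preferential":
            pref = preferred_allele[i] if preferred_allele is not None else "A"
            frac[i, row] = b_pref if pref == "A" else 1 - b_pref
        elif mode == "random_monoallelic":
            frac[i, row] = np.where(coin[i, row], s, 1 - s)
        elif mode == "random_ase":
            frac[i, row] = np.where(coin[i, row], b_rand, 1 - b_rand)
        else:
            raise ValueError(f"unknown ASE mode {mode!r}")
    return frac


def simulate_beads(frac_a, base_intensity, config: SimConfig, rng,
                   sample_ids, array_ids, snp_ids) -> pd.DataFrame:
    """Bead-level intensities for a stack of arrays.

    ``frac_a`` has shape (n_arrays, n_snps); ``base_intensity`` is per
    SNP. Returns the long bead table for all arrays.
    """
    frac = np.asarray(frac_a, dtype=float)
    n_arrays, n_snps = frac.shape
    nb = config.beads_per_snp
    base = np.broadcast_to(np.asarray(base_intensity, float),
                           (n_arrays, n_snps))[:, :, None]
    eps = config.background
    la = base + np.log2(2.0 * frac + eps)[:, :, None] + config.dye_bias / 2.0
    lb = base + np.log2(2.0 * (1.0 - frac) + eps)[:, :, None] \
        - config.dye_bias / 2.0
    shape = (n_arrays, n_snps, nb)
    ia = 2.0 ** (la + rng.normal(0.0, config.bead_noise_sd, shape))
    ib = 2.0 ** (lb + rng.normal(0.0, config.bead_noise_sd, shape))
    return pd.DataFrame({
        "snp_id": np.tile(np.repeat(snp_ids, nb), n_arrays),
        "sample_id": np.repeat(sample_ids, n_snps * nb),
        "array_id": np.repeat(array_ids, n_snps * nb),
        "intensity_a": ia.ravel(),
        "intensity_b": ib.ravel(),
    })


def _sample_table(n_trios: int, missing_father: int) -> pd.DataFrame:
    rows = []
    for i in range(n_trios):
        fam = f"F{i + 1:02d}"
        rows.append((f"{fam}.Pg", fam, "placenta_gdna", "gdna"))
        rows.append((f"{fam}.Pc", fam, "placenta_cdna", "cdna"))
        rows.append((f"{fam}.M", fam, "mother_gdna", "gdna"))
        if i >= n_trios - missing_father:
            continue
        rows.append((f"{fam}.F", fam, "father_gdna", "gdna"))
    return pd.DataFrame(rows, columns=["sample_id", "family_id", "role",
                                       "template"])


_CALL = np.array(["BB", "AB", "AA"])


def simulate_cohort(config: SimConfig,
                    genotypes: dict | None = None,
                    modes=None,
                    base_intensity=None) -> Cohort:
    """Generate a full trio cohort: genotypes, expression, beads, truth.

    ``genotypes`` (as returned by :func:`simulate_trios`), ``modes``
    (per-SNP array) and ``base_intensity`` (per-SNP array) may be
    supplied to pin the design — e.g. to force an exact number of
    heterozygous placentas — otherwise they are drawn from the
    configuration.
    """
    rng = np.random.default_rng(config.seed)
    n_snps, n_trios = config.n_snps, config.n_trios
    snp_ids = np.array([f"snp{i:04d}" for i in range(n_snps)])

    # minor allele is A or B with equal probability, so per-array
    # log-ratio distributions stay roughly symmetric (as on real arrays)
    p_a = allele_a_frequencies(n_snps, config.maf, rng)
    if genotypes is None:
        genotypes = simulate_trios(n_snps, n_trios, p_a, rng)
    if modes is None:
        counts = config.mode_counts or default_mode_counts(n_snps)
        modes = np.array([m for m, k in sorted(counts.items())
                          for _ in range(k)])
        rng.shuffle(modes)
    modes = np.asarray(modes)
    preferred = np.where(rng.random(n_snps) < 0.5, "A", "B")
    base = (rng.uniform(*config.base_intensity_range, n_snps)
            if base_intensity is None
            else np.broadcast_to(np.asarray(base_intensity, float), (n_snps,)))

    frac_cdna = simulate_expression(genotypes["child"],
                                    genotypes["maternal_allele"],
                                    genotypes["paternal_allele"],
                                    modes, config, rng, preferred)

    samples = _sample_table(n_trios, config.missing_father_families)
    trios = []
    fams = [f"F{i + 1:02d}" for i in range(n_trios)]
    with_father = set(samples.loc[samples["role"] == "father_gdna",
                                  "family_id"])
    for fam in fams:
        trios.append(TrioRecord(fam, f"{fam}.Pg", f"{fam}.Pc", f"{fam}.M",
                                f"{fam}.F" if fam in with_father else None))

    role_frac = {
        "placenta_gdna": genotypes["child"] / 2.0,
        "placenta_cdna": frac_cdna,
        "mother_gdna": genotypes["mother"] / 2.0,
        "father_gdna": genotypes["father"] / 2.0,
    }
    frac_rows, sample_ids, array_ids = [], [], []
    for row in samples.itertuples(index=False):
        fam_idx = fams.index(row.family_id)
        reps = config.replicates if row.role.startswith("placenta") else 1
        for rep in range(1, reps + 1):
            frac_rows.append(role_frac[row.role][:, fam_idx])
            sample_ids.append(row.sample_id)
            array_ids.append(f"{row.sample_id}:r{rep}")
    beads = simulate_beads(np.stack(frac_rows), base, config, rng,
                           np.array(sample_ids), np.array(array_ids), snp_ids)

    snp_truth = pd.DataFrame({
        "snp_id": snp_ids, "mode": modes, "p_allele_a": p_a,
        "base_intensity": base,
        "preferred_allele": np.where(modes == "preferential", preferred, "-"),
    })
    geno_rows = []
    for row in samples.itertuples(index=False):
        if row.template != "gdna":
            continue
        person = {"placenta_gdna": "child", "mother_gdna": "mother",
                  "father_gdna": "father"}[row.role]
        fam_idx = fams.index(row.family_id)
        geno_rows.append(pd.DataFrame({
            "snp_id": snp_ids, "sample_id": row.sample_id,
            "call": _CALL[genotypes[person][:, fam_idx]]}))
    genotype_truth = pd.concat(geno_rows, ignore_index=True)
    expression_truth = pd.DataFrame({
        "snp_id": np.repeat(snp_ids, n_trios),
        "family_id": np.tile(fams, n_snps),
        "child_call": _CALL[genotypes["child"]].ravel(),
        "maternal_allele": np.where(genotypes["maternal_allele"] == 1,
                                    "A", "B").ravel(),
        "paternal_allele": np.where(genotypes["paternal_allele"] == 1,
                                    "A", "B").ravel(),
        "frac_a": frac_cdna.ravel(),
    })
    return Cohort(config=config, trios=trios, samples=samples,
                  snp_truth=snp_truth, genotype_truth=genotype_truth,
                  expression_truth=expression_truth, beads=beads)


def allele_a_frequencies(n_snps: int, maf: float, rng) -> np.ndarray:
    """Per-SNP allele-A frequency: the minor allele is A or B at random."""
    return np.where(rng.random(n_snps) < 0.5, maf, 1.0 - maf)


def simulate_individual_genotypes(p_allele_a, rng):
    """Genotype calls for one individual under Hardy-Weinberg.

    ``p_allele_a`` is the shared per-SNP allele-A frequency; individuals
    drawn from the same population must use the same vector.
    """
    p = np.asarray(p_allele_a, dtype=float)
    dosage = ((rng.random(p.size) < p).astype(int)
              + (rng.random(p.size) < p).astype(int))
    return _CALL[dosage]


def simulate_mixture_series(calls_1, calls_2, design: MixtureDesign,
                            config: SimConfig, rng=None):
    """Bead tables for a two-individual gDNA titration series.

    Returns ``(beads, array_info, truth)``: the bead table covering
    every mixture x replicate array, a per-array frame with its
    mixture_id and proportions, and the genotype-derived truth labels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    calls_1 = np.asarray(calls_1)
    calls_2 = np.asarray(calls_2)
    n_snps = calls_1.size
    snp_ids = np.array([f"snp{i:04d}" for i in range(n_snps)])
    base = rng.uniform(*config.base_intensity_range, n_snps)

    frac = np.empty((len(design.proportions), n_snps))
    for j, (p1, p2) in enumerate(design.proportions):
        frac[j] = [blend_fraction(c1, c2, p1, p2)
                   for c1, c2 in zip(calls_1, calls_2)]
    frac_rows, sample_ids, array_ids, info = [], [], [], []
    for mid, (p1, p2), f in zip(design.mixture_ids, design.proportions, frac):
        for rep in range(1, design.replicates + 1):
            aid = f"{mid}:r{rep}"
            frac_rows.append(f)
            sample_ids.append(mid)
            array_ids.append(aid)
            info.append({"array_id": aid, "mixture_id": mid,
                         "p1": p1, "p2": p2})
    beads = simulate_beads(np.stack(frac_rows), base, config, rng,
                           np.array(sample_ids), np.array(array_ids), snp_ids)
    truth = build_truth_sets(dict(zip(snp_ids, calls_1)),
                             dict(zip(snp_ids, calls_2)))
    return beads, pd.DataFrame(info), truth


def simulate_allele_quants(config: SimConfig, rng=None,
                           gdna_noise_sd: float = 0.03,
                           cdna_noise_sd: float = 0.03,
                           conservative_rate: float = 0.95):
    """Mass-spec-style allele quantifications for a trio cohort.

    A light-weight companion to :func:`simulate_cohort` for the paired
    allelic-ratio screen: per SNP x placenta, a gDNA and a cDNA
    allele-A fraction with Gaussian measurement noise, each attempt
    rated "conservative" with the given probability (others "failed").
    The same measurement noise applies to both template types, as both
    come from the same assay chemistry. Returns
    ``(quants, trios, snp_truth)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_snps, n_trios = config.n_snps, config.n_trios
    snp_ids = np.array([f"snp{i:04d}" for i in range(n_snps)])
    p_a = np.where(rng.random(n_snps) < 0.5, config.maf, 1.0 - config.maf)
    geno = simulate_trios(n_snps, n_trios, p_a, rng)
    counts = config.mode_counts or default_mode_counts(n_snps)
    modes = np.array([m for m, k in sorted(counts.items())
                      for _ in range(k)])
    rng.shuffle(modes)
    preferred = np.where(rng.random(n_snps) < 0.5, "A", "B")
    frac_cdna = simulate_expression(geno["child"], geno["maternal_allele"],
                                    geno["paternal_allele"], modes, config,
                                    rng, preferred)
    frac_gdna = geno["child"] / 2.0
    fams = [f"F{i + 1:02d}" for i in range(n_trios)]
    trios = [TrioRecord(f, f"{f}.Pg", f"{f}.Pc", f"{f}.M", f"{f}.F")
             for f in fams]
    frames = []
    for kind, frac, sd in (("gDNA", frac_gdna, gdna_noise_sd),
                           ("cDNA", frac_cdna, cdna_noise_sd)):
        obs = np.clip(frac + rng.normal(0, sd, frac.shape), 0.0, 1.0)
        rating = np.where(rng.random(frac.shape) < conservative_rate,
                          "conservative", "failed")
        suffix = ".Pg" if kind == "gDNA" else ".Pc"
        frames.append(pd.DataFrame({
            "snp_id": np.repeat(snp_ids, n_trios),
            "sample_id": np.tile([f + suffix for f in fams], n_snps),
            "sample_type": kind,
            "frac_a": obs.ravel(),
            "rating": rating.ravel(),
        }))
    quants = pd.concat(frames, ignore_index=True)
    snp_truth = pd.DataFrame({"snp_id": snp_ids, "mode": modes,
                              "preferred_allele": preferred})
    return quants, trios, snp_truth
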