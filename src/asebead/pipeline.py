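"""End-to-end orchestration: bead table + pedigree in, ASE calls,
pattern classifications and calibration tables out.

The Illumina-style arm runs preprocess -> threshold genotype calling ->
moderated ASE test -> parent-of-origin pattern classification and logs a
five-row filter-chain ledger (tested / above intensity threshold /
>= 2 heterozygotes / homozygote-evaluable / ASE-significant). The
mixture arm runs preprocess -> per-mixture contrasts -> ROC/AUC per
mixing ratio.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase import call_ase, moderate_cdna_fits
from .config import ClassifyConfig, PipelineConfig
from .io import (StatisticalPreconditionError, TrioRecord, call_genotypes,
                 check_mendelian)
from .mixture import MixtureDesign, mixture_auc_table, mixture_contrasts
from .patterns import (classify_pattern, homozygote_reference_m, infer_origin,
                       snp_fold_difference)
from .preprocess import preprocess_cohort

log = logging.getLogger(__name__)


def genotype_gdna_samples(summaries: pd.DataFrame, samples_or_trios,
                          margin: float = 1.5) -> pd.DataFrame:
    """Threshold genotype calls for every gDNA sample.

    Replicate arrays of a sample are averaged on the M scale before
    calling. ``samples_or_trios`` is either a sample table with a
    ``template`` column or a list of :class:`TrioRecord` (whose gDNA
    sample ids are used).
    """
    if isinstance(samples_or_trios, pd.DataFrame):
        gdna_ids = set(samples_or_trios.loc[
            samples_or_trios["template"] == "gdna", "sample_id"])
    else:
        gdna_ids = set()
        for t in samples_or_trios:
            gdna_ids.update(filter(None, (t.placenta_gdna_sample,
                                          t.mother_gdna_sample,
                                          t.father_gdna_sample)))
    sub = summaries[summaries["sample_id"].isin(gdna_ids)]
    mean_m = (sub.groupby(["snp_id", "sample_id"], observed=True)["m"]
              .mean().reset_index())
    mean_m["call"] = call_genotypes(mean_m["m"].to_numpy(), margin)
    return mean_m[["snp_id", "sample_id", "call"]]


def mendelian_report(genotypes: pd.DataFrame,
                     trios: list[TrioRecord]) -> pd.DataFrame:
    """Per SNP x trio Mendelian-consistency classification."""
    calls = genotypes.set_index(["snp_id", "sample_id"])["call"]
    rows = []
    for snp_id in genotypes["snp_id"].unique():
        snp_calls = calls.loc[snp_id] if snp_id in calls.index else {}
        for t in trios:
            child = snp_calls.get(t.placenta_gdna_sample, "NN")
            mother = snp_calls.get(t.mother_gdna_sample, "NN")
            father = (snp_calls.get(t.father_gdna_sample, "NN")
                      if t.father_gdna_sample else None)
            rows.append({"snp_id": snp_id, "family_id": t.family_id,
                         "status": check_mendelian(child, mother, father)})
    return pd.DataFrame(rows)


def _placenta_genotypes(genotypes: pd.DataFrame,
                        trios: list[TrioRecord]) -> pd.DataFrame:
    fam_of = {t.placenta_gdna_sample: t.family_id for t in trios}
    sub = genotypes[genotypes["sample_id"].isin(fam_of)].copy()
    sub["family_id"] = sub["sample_id"].map(fam_of)
    return sub[["snp_id", "family_id", "call"]]


def run_illumina(beads: pd.DataFrame, trios: list[TrioRecord],
                 config: PipelineConfig | None = None,
                 classify_config: ClassifyConfig | None = None,
                 genotypes: pd.DataFrame | None = None) -> dict:
    """Full ASE analysis of a bead-level trio cohort.

    Returns a dict of result frames: summaries, genotypes, mendelian,
    stats (per SNP x cDNA sample), ase (per SNP), origin_calls,
    patterns, filter_chain.
    """
    config = config or PipelineConfig()
    classify_config = classify_config or ClassifyConfig()
    if not trios:
        raise ValueError("empty pedigree")
    log.info("preprocessing %d beads on %d arrays",
             len(beads), beads["array_id"].nunique())
    summaries = preprocess_cohort(beads, config)
    if genotypes is None:
        genotypes = genotype_gdna_samples(summaries, trios,
                                          config.genotype_call_margin)
    mendelian = mendelian_report(genotypes, trios)
    n_inconsistent = int((mendelian["status"] == "inconsistent").sum())
    if n_inconsistent:
        log.warning("%d Mendelian-inconsistent SNP x trio combinations",
                    n_inconsistent)

    stats_frame = moderate_cdna_fits(summaries, trios)
    placenta_geno = _placenta_genotypes(genotypes, trios)
    ase = call_ase(stats_frame, summaries, placenta_geno, config)

    chain = filter_chain(ase, config)
    for row in chain.itertuples(index=False):
        log.info("filter chain %s: %s -> %d SNPs", row.step, row.description,
                 row.n_snps)

    origin_calls, patterns = classify_all(
        stats_frame, summaries, genotypes, placenta_geno, ase, trios,
        config, classify_config)
    return {"summaries": summaries, "genotypes": genotypes,
            "mendelian": mendelian, "stats": stats_frame, "ase": ase,
            "origin_calls": origin_calls, "patterns": patterns,
            "filter_chain": chain}


def filter_chain(ase: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Five-row ledger of the SNP attrition through the call criteria."""
    a = len(ase)
    b = ase["crit_intensity"]
    c = b & (ase["n_hets"] >= config.min_sig_hets)
    d = c & ase["evaluable"]
    e = d & ase["ase_flag"]
    rows = [
        ("A", "tested on the array", a),
        ("B", f"average intensity above {config.intensity_threshold}",
         int(b.sum())),
        ("C", "as B with at least two heterozygous samples", int(c.sum())),
        ("D", "as C with homozygote quality evaluable", int(d.sum())),
        ("E", "as D significant for ASE", int(e.sum())),
    ]
    return pd.DataFrame(rows, columns=["step", "description", "n_snps"])


def classify_all(stats_frame, summaries, genotypes, placenta_geno, ase,
                 trios, config: PipelineConfig,
                 classify_config: ClassifyConfig):
    """Parent-of-origin calls and mode classification for every SNP."""
    gdna_samples = {t.placenta_gdna_sample for t in trios}
    gdna_sum = summaries[summaries["sample_id"].isin(gdna_samples)]
    ref_m = homozygote_reference_m(gdna_sum, genotypes)

    calls = genotypes.set_index(["snp_id", "sample_id"])["call"]
    pg = placenta_geno.set_index(["snp_id", "family_id"])["call"]
    stats_idx = stats_frame.set_index(["snp_id", "family_id"])
    cdna_a = (summaries.groupby(["snp_id", "sample_id"], observed=True)["a"]
              .mean())

    origin_rows, pattern_rows = [], []
    for ase_row in ase.itertuples(index=False):
        snp_id = ase_row.snp_id
        ref = ref_m.get(snp_id, float("nan"))
        ref = ref if np.isfinite(ref) else None
        calls_here, sig_here, m_list, a_list = [], [], [], []
        for t in trios:
            child = pg.get((snp_id, t.family_id), "NN")
            if child != "AB":
                continue
            try:
                st = stats_idx.loc[(snp_id, t.family_id)]
            except KeyError:
                continue
            mother = calls.get((snp_id, t.mother_gdna_sample), "NN")
            father = (calls.get((snp_id, t.father_gdna_sample), "NN")
                      if t.father_gdna_sample else None)
            oc = infer_origin(child, mother, father, float(st["coef"]),
                              family_id=t.family_id, snp_id=snp_id,
                              reference_m=ref,
                              completeness_factor=(
                                  classify_config.completeness_factor))
            sig = bool((st["p_adj"] < config.alpha_adj)
                       and abs(st["coef"]) > config.lfc_threshold)
            calls_here.append(oc)
            sig_here.append(sig)
            origin_rows.append({
                "snp_id": snp_id, "family_id": t.family_id,
                "expressed_allele": oc.expressed_allele, "origin": oc.origin,
                "completeness": oc.completeness,
                "mendelian_error": oc.mendelian_error,
                "coef": float(st["coef"]), "significant": sig})
            if sig:
                m_list.append(float(st["coef"]))
                a_list.append(float(cdna_a.get(
                    (snp_id, t.placenta_cdna_sample), float("nan"))))
        fold = float("nan")
        if m_list and np.all(np.isfinite(a_list)):
            fold = snp_fold_difference(np.array(m_list), np.array(a_list))
        pc = classify_pattern(snp_id, calls_here, sig_here,
                              bool(ase_row.ase_flag), fold, classify_config)
        pattern_rows.append({
            "snp_id": snp_id, "mode": pc.mode,
            "oriented_parent": pc.oriented_parent,
            "preferred_allele": pc.preferred_allele,
            "fold_difference": pc.fold_difference,
            "n_informative": pc.n_informative,
            "n_significant": pc.n_significant})
    origin_cols = ["snp_id", "family_id", "expressed_allele", "origin",
                   "completeness", "mendelian_error", "coef", "significant"]
    return (pd.DataFrame(origin_rows, columns=origin_cols),
            pd.DataFrame(pattern_rows))


def run_mixture(beads: pd.DataFrame, array_info: pd.DataFrame,
                truth: pd.DataFrame, design: MixtureDesign | None = None,
                config: PipelineConfig | None = None) -> dict:
    """Mixture-series calibration: contrasts, AUC table, ROC curves."""
    design = design or MixtureDesign()
    config = config or PipelineConfig()
    summaries = preprocess_cohort(beads, config)
    summaries = summaries.merge(array_info[["array_id", "mixture_id"]],
                                on="array_id", how="left")
    if summaries["mixture_id"].isna().any():
        raise ValueError("arrays missing from the design file")
    contrasts = mixture_contrasts(summaries, design)
    auc_table, curves = mixture_auc_table(contrasts, truth, design)
    for row in auc_table.itertuples(index=False):
        log.info("mixture %s (%g:%g): AUC %.3f (%d TP / %d TN)",
                 row.mixture_id, row.p1, row.p2, row.auc, row.n_tp, row.n_tn)
    return {"summaries": summaries, "contrasts": contrasts,
            "auc_table": auc_table, "roc_curves": curves}


def write_manifest(outdir, config, seed=None, inputs: dict | None = None):
    """Write a run manifest (config snapshot, input digests, version)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}
    for name, path in (inputs or {}).items():
        p = Path(path)
        if p.exists():
            digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict() if hasattr(config, "to_dict") else config,
        "input_digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_illumina_outputs(results: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("summaries", "genotypes", "mendelian", "stats", "ase",
                 "origin_calls", "patterns", "filter_chain"):
        results[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
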