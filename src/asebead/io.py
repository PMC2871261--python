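"""Domain types, TSV/pedigree I/O, threshold genotype calling and
Mendelian consistency checks.

Bulk bead and summary data travel as pandas DataFrames; the dataclasses
here document the row schemas and carry small per-family records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INTENSITY_FLOOR = 1.0

BEAD_COLUMNS = ["snp_id", "sample_id", "array_id", "intensity_a", "intensity_b"]
SUMMARY_COLUMNS = ["snp_id", "sample_id", "array_id", "m", "a",
                   "n_beads_used", "n_beads_removed"]

GENOTYPES = ("AA", "AB", "BB", "NN")


class FormatError(ValueError):
    """A tabular input does not match the declared schema."""


class EmptyInputError(ValueError):
    """An input table contains no data rows."""


class StatisticalPreconditionError(RuntimeError):
    """A statistical operation's preconditions are not met by the data."""


@dataclass(frozen=True)
class BeadMeasurement:
    """One bead's raw two-channel fluorescence for one SNP on one array.

    ``intensity_a`` is the channel measuring allele A (the Cy5 role),
    ``intensity_b`` allele B (Cy3).
    """

    snp_id: str
    sample_id: str
    array_id: str
    intensity_a: float
    intensity_b: float


@dataclass(frozen=True)
class TrioRecord:
    """Pedigree unit: placental gDNA/cDNA plus parental gDNA sample ids.

    ``father_gdna_sample`` may be None (absent father).
    """

    family_id: str
    placenta_gdna_sample: str
    placenta_cdna_sample: str
    mother_gdna_sample: str
    father_gdna_sample: str | None = None


def read_bead_table(path) -> pd.DataFrame:
    """Read a bead-level intensity TSV.

    Non-positive intensities are clipped up to ``INTENSITY_FLOOR`` so that
    log-ratios stay finite; the number of clipped values is recorded in
    ``df.attrs["n_clipped"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample_id": str,
                                            "array_id": str})
    for col in BEAD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"bead table missing required column {col!r}")
    if len(df) == 0:
        raise EmptyInputError("bead table contains no data rows")
    df = df.loc[:, BEAD_COLUMNS].copy()
    n_clipped = 0
    for col in ("intensity_a", "intensity_b"):
        bad = df[col] < INTENSITY_FLOOR
        n_clipped += int(bad.sum())
        df.loc[bad, col] = INTENSITY_FLOOR
    df.attrs["n_clipped"] = n_clipped
    return df


def write_bead_table(df: pd.DataFrame, path) -> None:
    df.loc[:, BEAD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> list[TrioRecord]:
    """Read a PED-like trio table; "-" marks an absent father."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["family_id", "placenta_gdna", "placenta_cdna", "mother_gdna",
                "father_gdna"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"pedigree missing required column {col!r}")
    if df["family_id"].duplicated().any():
        dupes = df.loc[df["family_id"].duplicated(), "family_id"].tolist()
        raise FormatError(f"duplicate family_id in pedigree: {dupes}")
    trios = []
    for row in df.itertuples(index=False):
        father = None if row.father_gdna in ("-", "", None) else row.father_gdna
        trios.append(TrioRecord(row.family_id, row.placenta_gdna,
                                row.placenta_cdna, row.mother_gdna, father))
    return trios


def write_pedigree(trios: Sequence[TrioRecord], path) -> None:
    rows = [{"family_id": t.family_id, "placenta_gdna": t.placenta_gdna_sample,
             "placenta_cdna": t.placenta_cdna_sample,
             "mother_gdna": t.mother_gdna_sample,
             "father_gdna": t.father_gdna_sample or "-"} for t in trios]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("snp_id", "sample_id", "call"):
        if col not in df.columns:
            raise FormatError(f"genotype table missing required column {col!r}")
    bad = ~df["call"].isin(GENOTYPES)
    if bad.any():
        raise FormatError(
            f"invalid genotype calls: {sorted(df.loc[bad, 'call'].unique())}")
    return df


def call_genotype(m_gdna: float, margin: float = 1.5) -> str:
    """Threshold genotype call from a gDNA log-ratio.

    M at or beyond +margin is AA, at or beyond -margin is BB, in between
    AB; a non-finite M is uncallable (NN). Boundary values go to the
    homozygote side.
    """
    if not np.isfinite(m_gdna):
        return "NN"
    if m_gdna >= margin:
        return "AA"
    if m_gdna <= -margin:
        return "BB"
    return "AB"


def call_genotypes(m_values: np.ndarray, margin: float = 1.5) -> np.ndarray:
    """Vectorised :func:`call_genotype`."""
    m = np.asarray(m_values, dtype=float)
    out = np.full(m.shape, "AB", dtype=object)
    out[m >= margin] = "AA"
    out[m <= -margin] = "BB"
    out[~np.isfinite(m)] = "NN"
    return out


_ALLELES = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}


def check_mendelian(child: str, mother: str, father: str | None) -> str:
    """Classify a trio genotype combination.

    Returns "consistent", "inconsistent" or "indeterminate". Any missing
    (NN or absent) call makes the trio indeterminate rather than
    inconsistent.
    """
    calls = (child, mother, father)
    for c in calls:
        if c is not None and c not in GENOTYPES:
            raise ValueError(f"invalid genotype call {c!r}")
    if any(c is None or c == "NN" for c in calls):
        return "indeterminate"
    child_alleles = sorted(_ALLELES[child])
    for ma in _ALLELES[mother]:
        for fa in _ALLELES[father]:
            if sorted((ma, fa)) == child_alleles:
                return "consistent"
    return "inconsistent"


def informative_hets(snp_id: str, trios: Sequence[TrioRecord],
                     genotypes: Mapping[str, str]) -> pd.DataFrame:
    """Select trios informative for allelic readout at one SNP.

    A trio is informative when its placental gDNA is heterozygous, and
    additionally *origin-informative* when at least one parent is
    homozygous (with an absent father, a homozygous mother suffices: the
    untransmitted maternal allele implies the paternal one).

    Parameters
    ----------
    genotypes : mapping sample_id -> call for this SNP.
    """
    rows = []
    for trio in trios:
        child = genotypes.get(trio.placenta_gdna_sample, "NN")
        if child != "AB":
            continue
        mother = genotypes.get(trio.mother_gdna_sample, "NN")
        father = ("NN" if trio.father_gdna_sample is None
                  else genotypes.get(trio.father_gdna_sample, "NN"))
        origin_informative = mother in ("AA", "BB") or father in ("AA", "BB")
        rows.append({"snp_id": snp_id, "family_id": trio.family_id,
                     "mother_call": mother, "father_call": father,
                     "origin_informative": origin_informative})
    return pd.DataFrame(rows, columns=["snp_id", "family_id", "mother_call",
                                       "father_call", "origin_informative"])
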