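"""Bead-level two-channel preprocessing.

Fixed pipeline per array: quantile-normalise the two channels across all
beads of the array, compute per-bead M = log2(a/b) and
A = 0.5*log2(a*b), summarise each bead type (SNP) by the mean of values
within ``mad_k`` unscaled median-absolute-deviations of the median, then
median-centre the summarised log-ratios so each array has median M = 0.
A is summarised with the same outlier rule (applied independently of M's
filter) but is not centred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import PipelineConfig
from .io import SUMMARY_COLUMNS


def quantile_normalize_channels(a_values, b_values):
    """Quantile-normalise two equal-length channel vectors jointly.

    After normalisation both channels share the same empirical
    distribution: the mean of the two sorted vectors. Rank order within
    each channel is preserved; ties receive the mean of their target
    quantiles (fractional average ranks are linearly interpolated).
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("channel vectors must be 1-D and of equal length")
    target = (np.sort(a) + np.sort(b)) / 2.0
    positions = np.arange(1.0, a.size + 1.0)
    a_norm = np.interp(rankdata(a, method="average"), positions, target)
    b_norm = np.interp(rankdata(b, method="average"), positions, target)
    return a_norm, b_norm


def bead_m_a(intensity_a, intensity_b):
    """Per-bead log-ratio M and average log-intensity A.

    M = log2(a/b), A = 0.5*log2(a*b); inputs must be positive (clip
    upstream).
    """
    ia = np.asarray(intensity_a, dtype=float)
    ib = np.asarray(intensity_b, dtype=float)
    if np.any(ia <= 0) or np.any(ib <= 0):
        raise ValueError("intensities must be positive; floor-clip first")
    la, lb = np.log2(ia), np.log2(ib)
    return la - lb, 0.5 * (la + lb)


def summarize_bead_type(values, mad_k: float = 3.0):
    """Outlier-trimmed mean of one bead type's per-bead values.

    Values farther than ``mad_k`` * MAD from the median are removed,
    where MAD is the unscaled median absolute deviation about the
    median. A zero MAD (constant beads) removes nothing. Returns
    ``(mean_of_retained, n_removed)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty bead type")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return float(np.mean(v)), 0
    keep = np.abs(v - med) <= mad_k * mad
    return float(np.mean(v[keep])), int(v.size - keep.sum())


def median_center(m_values):
    """Centre a vector of summarised log-ratios to median zero."""
    m = np.asarray(m_values, dtype=float)
    if m.size == 0:
        raise ValueError("cannot centre an empty vector")
    return m - np.median(m)


def _summarize_groups(codes: np.ndarray, values: np.ndarray, n_groups: int,
                      mad_k: float):
    """Trimmed means for all bead types of one array at once.

    ``codes`` assigns each bead to a SNP. When every SNP has the same
    bead count the computation is a reshape plus axis-wise medians;
    otherwise it falls back to a per-group loop.
    """
    order = np.argsort(codes, kind="stable")
    codes_s, values_s = codes[order], values[order]
    counts = np.bincount(codes_s, minlength=n_groups)
    if counts.min() == 0:
        raise ValueError("every SNP on an array needs at least one bead")
    if counts.min() == counts.max():
        mat = values_s.reshape(n_groups, counts[0])
        med = np.median(mat, axis=1, keepdims=True)
        dev = np.abs(mat - med)
        mad = np.median(dev, axis=1, keepdims=True)
        keep = (dev <= mad_k * mad) | (mad == 0)
        n_used = keep.sum(axis=1)
        means = np.where(keep, mat, 0.0).sum(axis=1) / n_used
        return means, counts - n_used
    means = np.empty(n_groups)
    removed = np.empty(n_groups, dtype=int)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    for g in range(n_groups):
        means[g], removed[g] = summarize_bead_type(
            values_s[bounds[g]:bounds[g + 1]], mad_k)
    return means, removed


def preprocess_array(beads: pd.DataFrame,
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full per-array pipeline on one array's beads.

    Returns one row per SNP with columns snp_id, sample_id, array_id, m,
    a, n_beads_used, n_beads_removed (the removal count refers to the
    M summarisation; A is filtered independently).
    """
    config = config or PipelineConfig()
    if beads["array_id"].nunique() != 1:
        raise ValueError("preprocess_array expects beads of a single array")
    a_norm, b_norm = quantile_normalize_channels(
        beads["intensity_a"].to_numpy(), beads["intensity_b"].to_numpy())
    m, a = bead_m_a(a_norm, b_norm)
    snp_ids, codes = np.unique(beads["snp_id"].to_numpy(), return_inverse=True)
    m_sum, m_removed = _summarize_groups(codes, m, snp_ids.size, config.mad_k)
    a_sum, _ = _summarize_groups(codes, a, snp_ids.size, config.mad_k)
    counts = np.bincount(codes, minlength=snp_ids.size)
    out = pd.DataFrame({
        "snp_id": snp_ids,
        "sample_id": beads["sample_id"].iloc[0],
        "array_id": beads["array_id"].iloc[0],
        "m": median_center(m_sum),
        "a": a_sum,
        "n_beads_used": counts - m_removed,
        "n_beads_removed": m_removed,
    })
    return out.loc[:, SUMMARY_COLUMNS]


def preprocess_cohort(beads: pd.DataFrame,
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Apply :func:`preprocess_array` to every array in a bead table."""
    parts = [preprocess_array(group, config)
             for _, group in beads.groupby("array_id", sort=False)]
    if not parts:
        raise ValueError("bead table contains no arrays")
    return pd.concat(parts, ignore_index=True)
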