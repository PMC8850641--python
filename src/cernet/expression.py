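"""Normalization, differential-expression calling, and qRT-PCR arithmetic.

The differential test is a transparent stand-in for the dedicated count
packages used in production pipelines: median-of-ratios size-factor
normalization, Welch's t on log2(normalized + 1), and Benjamini-Hochberg
adjustment.  Calibration of the stand-in is asserted by simulation in the
test suite rather than assumed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _st

from .models import CountMatrix, DERecord
from .stats import bh_adjust

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


def _column_totals(cm: CountMatrix) -> pd.Series:
    totals = cm.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-depth samples: {list(zero.index)}")
    return totals.astype(float)


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * total[s]) with total[s]
    the column sum.
    """
    if cm.lengths is None:
        raise ValueError("FPKM requires feature lengths")
    zero_len = cm.lengths[cm.lengths <= 0]
    if len(zero_len):
        raise ValueError(f"zero-length features: {list(zero_len.index)}")
    totals = _column_totals(cm)
    return cm.counts * 1e9 / np.outer(cm.lengths.to_numpy(float), totals.to_numpy())


def tpm_mirna(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million for small-RNA tags: count fraction x 1e6."""
    totals = _column_totals(cm)
    return cm.counts * 1e6 / totals


def normalize_total_count(cm: CountMatrix) -> pd.DataFrame:
    """Scale each sample's counts to the mean library depth."""
    totals = _column_totals(cm)
    return cm.counts * (totals.mean() / totals)


def size_factors_median_ratio(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Computed over features with nonzero counts in every sample; robust to
    a sizeable unbalanced fraction of truly changing features, where plain
    total-count scaling absorbs part of the fold change.  Falls back to
    total-count factors when no feature is everywhere nonzero.
    """
    arr = cm.counts.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        totals = _column_totals(cm)
        return totals / totals.mean()
    logs = np.log(arr[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=cm.counts.columns)


def normalize_median_ratio(cm: CountMatrix) -> pd.DataFrame:
    """Counts divided by median-of-ratios size factors."""
    return cm.counts / size_factors_median_ratio(cm)


def differential_test(
    cm: CountMatrix,
    pseudocount: float = 1.0,
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Per-feature log2 fold change (BH over BN) and Welch-t p-value.

    Returns a DataFrame indexed by feature id with columns ``log2fc`` and
    ``p_value``.  A feature with zero variance in both groups gets p = 1
    when the group means are equal and p = 0 otherwise.  ``normalization``
    is ``median_ratio`` (default, robust to unbalanced DE) or ``total``.
    """
    bh = cm.samples_of("BH")
    bn = cm.samples_of("BN")
    if len(bh) < 2 or len(bn) < 2:
        raise ValueError(
            f"need >= 2 samples per condition, got BH={len(bh)}, BN={len(bn)}"
        )
    if normalization == "median_ratio":
        norm = normalize_median_ratio(cm)
    elif normalization == "total":
        norm = normalize_total_count(cm)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    log_bh = np.log2(norm[bh].to_numpy() + 1.0)
    log_bn = np.log2(norm[bn].to_numpy() + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss", category=RuntimeWarning)
        res = _st.ttest_ind(log_bh, log_bn, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(log_bh.mean(axis=1), log_bn.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0

    mean_bh = norm[bh].mean(axis=1).to_numpy()
    mean_bn = norm[bn].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_bh + pseudocount) / (mean_bn + pseudocount))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p}, index=cm.counts.index.copy()
    )


def call_de(
    stats: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> list[DERecord]:
    """Apply the printed thresholds, strictly: fdr < t and |log2fc| > t.

    ``stats`` needs columns ``log2fc`` and ``p_value``; an ``fdr`` column is
    computed with Benjamini-Hochberg if absent.
    """
    if not {"log2fc", "p_value"}.issubset(stats.columns):
        raise ValueError("stats must have 'log2fc' and 'p_value' columns")
    fdr = (
        stats["fdr"].to_numpy(float)
        if "fdr" in stats.columns
        else bh_adjust(stats["p_value"].to_numpy(float))
    )
    records = []
    for fid, lfc, p, q in zip(
        stats.index, stats["log2fc"].to_numpy(float), stats["p_value"].to_numpy(float), fdr
    ):
        if q < fdr_threshold and lfc > lfc_threshold:
            call = "up"
        elif q < fdr_threshold and lfc < -lfc_threshold:
            call = "down"
        else:
            call = "null"
        records.append(DERecord(str(fid), float(lfc), float(p), float(q), call))
    return records


def de_analysis(
    cm: CountMatrix,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full DE table: test, adjust, call; indexed by feature id."""
    stats = differential_test(cm, pseudocount=pseudocount)
    stats["fdr"] = bh_adjust(stats["p_value"].to_numpy(float))
    recs = call_de(stats, fdr_threshold, lfc_threshold)
    stats["call"] = [r.call for r in recs]
    return stats


def delta_delta_ct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by 2^-ddCt against a reference gene + calibrator."""
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
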