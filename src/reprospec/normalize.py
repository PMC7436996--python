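"""Within- and between-sample normalization and expression summaries.

CPM divides counts by the (optionally TMM-rescaled) library size; TPM
additionally divides by gene length so that abundances are comparable
across genes and every non-empty sample sums to one million. TMM scaling
factors follow the trimmed-mean-of-M-values construction of Robinson &
Oshlack: log ratios to a reference sample are doubly trimmed (by M and by
average abundance A) and averaged with inverse-asymptotic-variance weights,
then the factors are rescaled to geometric mean one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import CountDataset

DEFAULT_PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    pass


def compute_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    log: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Counts per million per sample, optionally log2 with a pseudocount.

    ``factors`` are multiplicative library-size corrections (e.g. TMM);
    the effective library size of a sample is column-sum times factor.
    """
    colsum = counts.sum(axis=0).astype(float)
    if factors is not None:
        eff = colsum * factors.reindex(counts.columns)
    else:
        eff = colsum
    zero = eff[eff <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero/negative effective library size for sample(s): {list(zero.index)}"
        )
    cpm = counts.div(eff, axis=1) * 1e6
    if log:
        return np.log2(cpm + pseudocount)
    return cpm


def compute_tpm(
    counts: pd.DataFrame, lengths: pd.Series
) -> pd.DataFrame:
    """Transcripts per million: length-normalized within-sample abundance."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise NormalizationError(f"gene lengths missing for: {list(missing[:10])}")
    kb = lengths.reindex(counts.index).astype(float) / 1e3
    rate = counts.div(kb, axis=0)
    total = rate.sum(axis=0)
    # all-zero samples stay all-zero rather than dividing by zero
    safe = total.replace(0.0, np.nan)
    return (rate.div(safe, axis=1) * 1e6).fillna(0.0)


def dataset_tpm(dataset: CountDataset) -> pd.DataFrame:
    if dataset.lengths is None:
        raise NormalizationError("dataset has no gene lengths; TPM unavailable")
    return compute_tpm(dataset.counts, dataset.lengths)


# ---------------------------------------------------------------------- #
# TMM
# ---------------------------------------------------------------------- #

def _choose_reference(cpm: pd.DataFrame) -> str:
    uq = cpm.quantile(0.75)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean one.

    The reference defaults to the sample whose upper-quartile CPM is closest
    to the mean upper-quartile. Samples sharing no co-expressed genes with
    the reference get factor 1 with a warning.
    """
    if counts.shape[1] < 2:
        raise NormalizationError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise NormalizationError(
            f"zero-total sample(s): {list(lib.index[lib <= 0])}"
        )
    if ref_sample is None:
        ref_sample = _choose_reference(counts.div(lib, axis=1) * 1e6)

    yr = counts[ref_sample].to_numpy(dtype=float)
    nr = lib[ref_sample]
    logf = {}
    for s in counts.columns:
        if s == ref_sample:
            logf[s] = 0.0
            continue
        ys = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            warnings.warn(f"sample {s} shares no expressed genes with reference")
            logf[s] = 0.0
            continue
        ps, pr = ys[keep] / ns, yr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        # double trim: drop extreme M and extreme A quantiles (rank-based,
        # average ranks for ties)
        n = len(m)
        m_rank = rankdata(m)
        a_rank = rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        sel = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
        if not sel.any():
            logf[s] = 0.0
            continue
        logf[s] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()}).reindex(counts.columns)
    return f / np.exp(np.mean(np.log(f)))


# ---------------------------------------------------------------------- #
# per-group summaries
# ---------------------------------------------------------------------- #

def summarize_by_group(
    tpm: pd.DataFrame, log_cpm: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Mean/SD TPM and mean log2 CPM per (gene, group).

    SD uses the n-1 denominator; singleton groups get SD 0 by convention
    and are flagged in the ``singleton`` column. Returns a tidy frame with
    columns gene, group, mean_tpm, sd_tpm, mean_log2cpm, singleton.
    """
    groups = groups.reindex(tpm.columns)
    if groups.isna().any():
        raise NormalizationError(
            f"samples without a group: {list(groups.index[groups.isna()])}"
        )
    frames = []
    for g in pd.unique(groups):
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise NormalizationError(f"group '{g}' is empty")
        sub = tpm[cols]
        sd = sub.std(axis=1, ddof=1).fillna(0.0) if len(cols) > 1 else pd.Series(
            0.0, index=sub.index
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": tpm.index,
                    "group": g,
                    "mean_tpm": sub.mean(axis=1).to_numpy(),
                    "sd_tpm": sd.to_numpy(),
                    "mean_log2cpm": log_cpm[cols].mean(axis=1).to_numpy(),
                    "singleton": len(cols) == 1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summary_lookup(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy summary to a gene x group mean-TPM matrix."""
    return summary.pivot(index="gene", columns="group", values="mean_tpm")


# ---------------------------------------------------------------------- #
# PCA (QC projection)
# ---------------------------------------------------------------------- #

def pca_qc(log_cpm: pd.DataFrame, n_components: int | None = None):
    """Gene-centered SVD of log2 CPM; sample scores and variance fractions.

    The sign of each component is fixed by making the largest-magnitude gene
    loading positive. A constant matrix yields zero scores and a
    ``degenerate`` flag instead of variance fractions.
    """
    if log_cpm.shape[1] < 2:
        raise NormalizationError("PCA needs at least two samples")
    x = log_cpm.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        scores = pd.DataFrame(
            0.0,
            index=log_cpm.columns,
            columns=[f"PC{i+1}" for i in range(min(x.shape) if n_components is None else n_components)],
        )
        return scores, None, True
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    sign = np.sign(u[np.argmax(np.abs(u[:, :k]), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]) * sign,
        index=log_cpm.columns,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    frac = s**2 / np.sum(s**2)
    return scores, pd.Series(frac[:k], index=scores.columns, name="variance_fraction"), False
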