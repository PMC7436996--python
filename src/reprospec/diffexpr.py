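"""Two-group negative-binomial differential expression.

The test is the classic conditional exact test for overdispersed counts:
library sizes are first equalized by rescaling each sample's counts to the
geometric-mean effective library ("pseudo-counts"), group sums are formed,
and the p-value is the probability, conditional on the total, of all splits
no more likely than the observed one. For independent NB group sums with a
shared mean-per-sample and dispersion ``phi``, the conditional distribution
of one group's sum given the total ``T`` is exactly beta-binomial with
parameters ``(T, n_A/phi, n_B/phi)``; as ``phi -> 0`` this collapses to the
conditional binomial of the Poisson case.

Dispersions are estimated by conditional maximum likelihood on the
equalized counts (common dispersion), with per-gene values shrunk toward
the common one by weighted-likelihood empirical Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datasets import CountDataset
from .normalize import DEFAULT_PSEUDOCOUNT, compute_cpm, tmm_factors
from .ruv import UnwantedFactors, correct_expression

#: log-space tolerance for declaring two outcome probabilities tied; must
#: exceed the O(phi) perturbation of exact ties in the small-phi regime
_TIE_LOG_TOL = 1e-6

DEFAULT_PRIOR_COUNT = 0.125
DEFAULT_TAGWISE_WEIGHT = 10.0


class DEError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# Benjamini-Hochberg
# ---------------------------------------------------------------------- #

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DEError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------- #
# exact test
# ---------------------------------------------------------------------- #

def _conditional_logpmf(total: int, r_a: float, r_b: float) -> np.ndarray:
    """log pmf of the beta-binomial split of ``total`` between two NB sums.

    Computed with cumulative log products, which stays accurate for the
    enormous shape parameters of the small-dispersion limit (a direct
    ``betaln`` difference cancels catastrophically there).
    """
    a = np.arange(total + 1)
    j = np.arange(total, dtype=float)
    c_a = np.concatenate(([0.0], np.cumsum(np.log(r_a + j))))
    c_b = np.concatenate(([0.0], np.cumsum(np.log(r_b + j))))
    c_ab = np.concatenate(([0.0], np.cumsum(np.log(r_a + r_b + j))))
    return (
        gammaln(total + 1.0)
        - gammaln(a + 1.0)
        - gammaln(total - a + 1.0)
        + c_a[a]
        + c_b[total - a]
        - c_ab[total]
    )


def _binomial_logpmf(total: int, p: float) -> np.ndarray:
    a = np.arange(total + 1)
    return (
        gammaln(total + 1.0)
        - gammaln(a + 1.0)
        - gammaln(total - a + 1.0)
        + a * np.log(p)
        + (total - a) * np.log1p(-p)
    )


def _exact_p(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    if phi < 0:
        raise DEError("dispersion must be non-negative")
    if phi == 0.0:
        lp = _binomial_logpmf(total, n_a / (n_a + n_b))
    else:
        lp = _conditional_logpmf(total, n_a / phi, n_b / phi)
    # normalize by the total enumerated mass so the all-inclusive case is
    # exactly 1 despite floating-point leakage
    mass = np.exp(lp)
    p = float(mass[lp <= lp[sum_a] + _TIE_LOG_TOL].sum() / mass.sum())
    return min(p, 1.0)


def nb_exact_test(
    counts_a,
    counts_b,
    lib_a,
    lib_b,
    phi: float,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> tuple[float, float]:
    """Exact two-sided NB test of one gene between two sample groups.

    Counts are rescaled to the geometric-mean library size before summing;
    the two-sided p-value sums conditional probabilities of all splits no
    more likely than the observed one. The log2 fold change is computed
    from the per-sample group means with a prior count to avoid infinities,
    signed so that positive means higher in group A.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise DEError("both groups must be non-empty")
    if phi < 0:
        raise DEError("dispersion must be non-negative")
    libs = np.concatenate([np.atleast_1d(lib_a), np.atleast_1d(lib_b)]).astype(float)
    if (libs <= 0).any():
        raise DEError("library sizes must be positive")
    common = np.exp(np.mean(np.log(libs)))
    pseudo_a = counts_a * common / np.asarray(lib_a, dtype=float)
    pseudo_b = counts_b * common / np.asarray(lib_b, dtype=float)
    n_a, n_b = len(counts_a), len(counts_b)

    sum_a = int(round(pseudo_a.sum()))
    sum_b = int(round(pseudo_b.sum()))
    mean_a = pseudo_a.sum() / n_a
    mean_b = pseudo_b.sum() / n_b
    log2fc = float(np.log2((mean_a + prior_count) / (mean_b + prior_count)))
    if sum_a + sum_b == 0:
        return 1.0, 0.0
    return _exact_p(sum_a, sum_b, n_a, n_b, phi), log2fc


# ---------------------------------------------------------------------- #
# dispersion estimation
# ---------------------------------------------------------------------- #

@dataclass
class DispersionEstimates:
    common: float
    tagwise: pd.Series  # per gene
    prior_weight: float
    all_zero: pd.Series  # flag: gene had no counts, tagwise set to common


def _phi_grid() -> np.ndarray:
    # leading point is numerically zero; spacing ~8% in phi
    return np.concatenate(([1e-10], np.exp(np.linspace(np.log(1e-4), np.log(30.0), 160))))


def _conditional_loglik(pseudo: np.ndarray, group_sizes, group_slices, grid) -> np.ndarray:
    """Genes x grid matrix of NB conditional log-likelihood.

    For a group of n samples with equalized libraries and counts y, the
    likelihood conditional on the group sum z is
    ``sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r)``
    with r = 1/phi; summed over groups.
    """
    n_genes = pseudo.shape[0]
    ll = np.zeros((n_genes, len(grid)))
    for (sl, n) in zip(group_slices, group_sizes):
        y = pseudo[:, sl]
        z = y.sum(axis=1)
        for j, phi in enumerate(grid):
            r = 1.0 / phi
            ll[:, j] += (
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
    return ll


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    lib_sizes: pd.Series | None = None,
    prior_weight: float = DEFAULT_TAGWISE_WEIGHT,
) -> DispersionEstimates:
    """Common and tagwise NB dispersions by conditional maximum likelihood.

    Tagwise values maximize the gene's own conditional likelihood plus
    ``prior_weight`` times the average likelihood across genes, shrinking
    noisy per-gene estimates toward the common value. Genes with no counts
    get the common dispersion and are flagged.
    """
    if counts.shape[1] < 2:
        raise DEError("dispersion estimation needs at least two samples")
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise DEError("every sample needs a group for dispersion estimation")
    lib = (
        counts.sum(axis=0).astype(float)
        if lib_sizes is None
        else lib_sizes.reindex(counts.columns).astype(float)
    )
    common_lib = np.exp(np.mean(np.log(lib)))
    pseudo = (counts.to_numpy(dtype=float) * (common_lib / lib.to_numpy()))

    # pack group columns contiguously
    order = []
    group_sizes, group_slices = [], []
    pos = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero((groups == g).to_numpy())
        order.extend(idx)
        group_sizes.append(len(idx))
        group_slices.append(slice(pos, pos + len(idx)))
        pos += len(idx)
    pseudo = pseudo[:, order]

    grid = _phi_grid()
    ll = _conditional_loglik(pseudo, group_sizes, group_slices, grid)

    zero = pd.Series(counts.sum(axis=1).to_numpy() == 0, index=counts.index)
    informative = ~zero.to_numpy()
    if informative.any():
        common_idx = int(np.argmax(ll[informative].sum(axis=0)))
    else:
        common_idx = 0
    common = float(grid[common_idx])
    if common_idx == 0:
        common = 0.0

    lbar = ll[informative].mean(axis=0) if informative.any() else np.zeros(len(grid))
    tag_idx = np.argmax(ll + prior_weight * lbar, axis=1)
    tagwise = grid[tag_idx]
    tagwise[tag_idx == 0] = 0.0
    tagwise[zero.to_numpy()] = common
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tagwise, index=counts.index, name="phi"),
        prior_weight=prior_weight,
        all_zero=zero,
    )


# ---------------------------------------------------------------------- #
# pairwise comparison driver
# ---------------------------------------------------------------------- #

def run_pairwise_de(
    dataset: CountDataset,
    repro_tissue: str,
    nonrepro_tissue: str,
    factors: UnwantedFactors | None = None,
    tmm: pd.Series | None = None,
    mode: str = "covariate",
    prior_weight: float = DEFAULT_TAGWISE_WEIGHT,
    prior_count: float = DEFAULT_PRIOR_COUNT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    corrected_cpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exact-test DE of one reproductive tissue against one somatic tissue.

    With unwanted-variation factors supplied, counts are first adjusted by
    the fitted nuisance term in log space and re-formed on the count scale
    (an approximation that keeps the exact test applicable); this is the
    ``covariate`` mode. ``corrected_counts`` mode reuses a precomputed
    batch-corrected CPM matrix instead. BH adjustment is applied within
    this comparison. Returns a frame with columns gene, repro_tissue,
    nonrepro_tissue, log2fc (positive = higher in the reproductive group),
    pvalue, fdr.
    """
    for label in (repro_tissue, nonrepro_tissue):
        if label not in set(dataset.samples["tissue"]):
            raise DEError(f"tissue '{label}' absent from metadata")
    cols_a = dataset.samples_of_tissue(repro_tissue)
    cols_b = dataset.samples_of_tissue(nonrepro_tissue)
    cols = cols_a + cols_b

    counts = dataset.counts
    if tmm is None:
        tmm = tmm_factors(counts[cols])
    eff_lib = counts[cols].sum(axis=0).astype(float) * tmm.reindex(cols)

    if factors is not None and factors.k > 0:
        if mode == "corrected_counts":
            if corrected_cpm is None:
                raise DEError("corrected_counts mode needs the corrected CPM matrix")
            lin = corrected_cpm
        elif mode == "covariate":
            log_cpm = compute_cpm(counts, log=True, pseudocount=pseudocount)
            _, lin = correct_expression(log_cpm, factors, pseudocount=pseudocount)
        else:
            raise DEError(f"unknown DE mode '{mode}'")
        work = lin[cols] * (eff_lib / 1e6)
    else:
        work = counts[cols].astype(float)

    groups = pd.Series(
        ["A"] * len(cols_a) + ["B"] * len(cols_b), index=cols, name="group"
    )
    disp = estimate_dispersions(
        work, groups, lib_sizes=eff_lib, prior_weight=prior_weight
    )

    lib_a = eff_lib[cols_a].to_numpy()
    lib_b = eff_lib[cols_b].to_numpy()
    mat_a = work[cols_a].to_numpy()
    mat_b = work[cols_b].to_numpy()
    phis = disp.tagwise.to_numpy()

    pvals = np.empty(len(work.index))
    fcs = np.empty(len(work.index))
    for i in range(len(work.index)):
        pvals[i], fcs[i] = nb_exact_test(
            mat_a[i], mat_b[i], lib_a, lib_b, phis[i], prior_count=prior_count
        )
    return pd.DataFrame(
        {
            "gene": work.index,
            "repro_tissue": repro_tissue,
            "nonrepro_tissue": nonrepro_tissue,
            "log2fc": fcs,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )


def run_all_pairwise(
    dataset: CountDataset,
    factors: UnwantedFactors | None = None,
    tmm: pd.Series | None = None,
    global_bh: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """DE of every reproductive tissue against every non-reproductive tissue.

    BH adjustment is per comparison by default; ``global_bh=True`` pools all
    comparisons into one adjustment instead.
    """
    from .datasets import NON_REPRODUCTIVE, REPRODUCTIVE

    repro = dataset.tissues(REPRODUCTIVE)
    nonrepro = dataset.tissues(NON_REPRODUCTIVE)
    if not repro or not nonrepro:
        raise DEError("need at least one tissue of each class")
    frames = [
        run_pairwise_de(dataset, r, n, factors=factors, tmm=tmm, **kwargs)
        for r in repro
        for n in nonrepro
    ]
    out = pd.concat(frames, ignore_index=True)
    if global_bh:
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out
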