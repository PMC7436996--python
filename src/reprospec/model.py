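"""Model/Results interface over the screening pipeline.

:class:`TissueSpecificityScreen` is constructed from a
:class:`~reprospec.datasets.CountDataset` (or raw DataFrames) plus the
screening options; :meth:`~TissueSpecificityScreen.fit` runs TMM
normalization, RUVr batch correction, pairwise NB exact-test differential
expression and the three-filter specificity cascade, returning a
:class:`ScreenResults` that carries every intermediate table, the candidate
matrix, QC PCA and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import NON_REPRODUCTIVE, REPRODUCTIVE, CountDataset
from .diffexpr import (
    DEFAULT_PRIOR_COUNT,
    DEFAULT_TAGWISE_WEIGHT,
    run_all_pairwise,
)
from .normalize import (
    DEFAULT_PSEUDOCOUNT,
    compute_cpm,
    compute_tpm,
    pca_qc,
    summarize_by_group,
    tmm_factors,
)
from .ruv import fit_ruv
from .screen import CandidateTable, ThresholdConfig, build_candidate_table


class TissueSpecificityScreen:
    """Reproductive tract-specific gene screen on a multi-tissue count matrix.

    Parameters
    ----------
    dataset
        Counts, sample metadata and gene lengths.
    species
        ``human`` or ``mouse``; fixes the default FDR/TPM thresholds
        (human: FDR 0.05, non-reproductive TPM <= 1.0, reproductive
        TPM >= 10.0; mouse: 0.05 / 2.0 / 8.0).
    thresholds
        Explicit :class:`ThresholdConfig`, overriding the species preset.
    ruv_k
        Number of unwanted-variation factors (0 disables correction).
    de_mode
        ``covariate`` adjusts counts by the fitted nuisance term before the
        exact test; ``corrected_counts`` tests the batch-corrected CPM
        directly.
    tpm_source
        ``corrected`` computes the TPM summaries from batch-corrected
        expression; ``raw`` from the raw counts.
    """

    def __init__(
        self,
        dataset: CountDataset,
        species: str = "human",
        thresholds: ThresholdConfig | None = None,
        ruv_k: int = 1,
        de_mode: str = "covariate",
        tpm_source: str = "corrected",
        tagwise_weight: float = DEFAULT_TAGWISE_WEIGHT,
        prior_count: float = DEFAULT_PRIOR_COUNT,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        global_bh: bool = False,
    ) -> None:
        self.dataset = dataset
        self.species = species
        self.thresholds = thresholds or ThresholdConfig.preset(species)
        self.ruv_k = ruv_k
        self.de_mode = de_mode
        if tpm_source not in {"corrected", "raw"}:
            raise ValueError("tpm_source must be 'corrected' or 'raw'")
        self.tpm_source = tpm_source
        self.tagwise_weight = tagwise_weight
        self.prior_count = prior_count
        self.pseudocount = pseudocount
        self.global_bh = global_bh

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        lengths: pd.Series | None = None,
        **kwargs,
    ) -> "TissueSpecificityScreen":
        return cls(CountDataset(counts=counts, samples=samples, lengths=lengths), **kwargs)

    # ------------------------------------------------------------------ #
    def fit(self) -> "ScreenResults":
        ds = self.dataset
        tmm = tmm_factors(ds.counts)
        factors, corrected_log, corrected_lin = fit_ruv(
            ds, k=self.ruv_k, tmm=tmm, pseudocount=self.pseudocount
        )

        eff_lib = ds.counts.sum(axis=0).astype(float) * tmm
        if self.tpm_source == "corrected" and self.ruv_k > 0:
            pseudo_counts = corrected_lin * (eff_lib / 1e6)
            tpm = compute_tpm(pseudo_counts, ds.lengths)
        else:
            tpm = compute_tpm(ds.counts, ds.lengths)

        summary = summarize_by_group(tpm, corrected_log, ds.samples["tissue"])
        de = run_all_pairwise(
            ds,
            factors=factors,
            tmm=tmm,
            mode=self.de_mode,
            prior_weight=self.tagwise_weight,
            prior_count=self.prior_count,
            pseudocount=self.pseudocount,
            global_bh=self.global_bh,
            corrected_cpm=corrected_lin if self.de_mode == "corrected_counts" else None,
        )
        candidates = build_candidate_table(de, summary, self.thresholds)
        pca_scores, pca_var, degenerate = pca_qc(corrected_log, n_components=10)
        return ScreenResults(
            model=self,
            tmm=tmm,
            factors=factors,
            log_cpm=corrected_log,
            tpm=tpm,
            expression_summary=summary,
            de_results=de,
            candidate_table=candidates,
            pca_scores=pca_scores,
            pca_variance=pca_var,
            pca_degenerate=degenerate,
        )


@dataclass
class ScreenResults:
    """Fitted screen: all intermediate tables plus the candidate matrix."""

    model: TissueSpecificityScreen
    tmm: pd.Series
    factors: object
    log_cpm: pd.DataFrame
    tpm: pd.DataFrame
    expression_summary: pd.DataFrame
    de_results: pd.DataFrame
    candidate_table: CandidateTable
    pca_scores: pd.DataFrame
    pca_variance: pd.Series | None
    pca_degenerate: bool = False

    @property
    def candidates(self) -> pd.Index:
        return self.candidate_table.candidates

    def candidate_sets(self) -> dict[str, set[str]]:
        """Per reproductive tissue: genes passing the cascade there."""
        return {
            rt: self.candidate_table.candidate_set(rt)
            for rt in self.candidate_table.log2fc.columns
        }

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        ds = self.model.dataset
        th = self.model.thresholds
        lines = [
            "Reproductive tract specificity screen",
            "=" * 53,
            f"genes: {len(ds.gene_ids)}   samples: {len(ds.sample_ids)}",
            f"reproductive tissues:     {', '.join(ds.tissues(REPRODUCTIVE))}",
            f"non-reproductive tissues: {', '.join(ds.tissues(NON_REPRODUCTIVE))}",
            f"species preset: {self.model.species}   RUV k: {self.model.ruv_k}",
            (
                f"thresholds: FDR <= {th.fdr_alpha}, "
                f"non-repro TPM <= {th.max_nonrepro_tpm}, "
                f"repro TPM >= {th.min_repro_tpm}"
            ),
            "-" * 53,
            "candidates per reproductive tissue:",
        ]
        for rt in self.candidate_table.log2fc.columns:
            n = int((self.candidate_table.log2fc[rt] != 0).sum())
            lines.append(f"  {rt:<24s} {n:6d}")
        lines.append(f"total candidate genes: {len(self.candidates)}")
        if self.pca_variance is not None:
            pcs = ", ".join(
                f"{c}: {v:.1%}" for c, v in self.pca_variance.head(3).items()
            )
            lines.append(f"PCA variance explained ({pcs})")
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def benchmark(self, truth) -> pd.DataFrame:
        """Planted-truth recovery metrics (synthetic data only).

        Sensitivity counts strictly-specific planted genes recovered as
        candidates; the false-discovery proportion counts candidates that
        were not planted as specific; per-class admission rates cover every
        planted class.
        """
        found = set(self.candidates)
        truth_genes = set(truth.genes.index)
        if truth_genes != set(self.model.dataset.gene_ids):
            raise ValueError("truth gene universe does not match the dataset")
        specific = set(truth.specific_genes)
        rows = []
        sens = len(found & specific) / len(specific) if specific else float("nan")
        fdp = len(found - specific) / len(found) if found else 0.0
        rows.append({"metric": "sensitivity_specific", "value": sens})
        rows.append({"metric": "false_discovery_proportion", "value": fdp})
        for cls, genes in truth.genes.groupby("planted_class").groups.items():
            admitted = len(found & set(genes)) / len(genes)
            rows.append({"metric": f"admission[{cls}]", "value": admitted})
        reject = set(truth.reject_genes)
        rows.append(
            {
                "metric": "false_admission_rate",
                "value": len(found & reject) / len(reject) if reject else 0.0,
            }
        )
        return pd.DataFrame(rows)
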