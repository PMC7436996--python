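"""The three-filter specificity cascade.

For each gene and each reproductive tissue, the non-reproductive tissue
with the maximum expression is located as the comparison with the minimal
log2 fold change (reproductive over non-reproductive). The gene passes for
that reproductive tissue iff, against that maximal tissue:

1. the BH-adjusted p-value (FDR) is at most ``fdr_alpha``;
2. the maximal non-reproductive tissue's mean TPM is at most
   ``max_nonrepro_tpm`` (1.0 for the human preset, 2.0 for mouse);
3. the reproductive tissue's mean TPM is at least ``min_repro_tpm``
   (10.0 for human, 8.0 for mouse).

All three comparisons are inclusive. The candidate table is a gene x
reproductive-tissue matrix of log2 fold changes in which 0 encodes "failed
the filters for this tissue"; a gene is a candidate iff at least one entry
is non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdConfig:
    """FDR and dual-TPM thresholds of the specificity cascade."""

    fdr_alpha: float = 0.05
    max_nonrepro_tpm: float = 1.0
    min_repro_tpm: float = 10.0

    def __post_init__(self) -> None:
        if min(self.fdr_alpha, self.max_nonrepro_tpm, self.min_repro_tpm) < 0:
            raise ScreenError("thresholds must be non-negative")

    @classmethod
    def preset(cls, species: str) -> "ThresholdConfig":
        if species == "human":
            return cls(fdr_alpha=0.05, max_nonrepro_tpm=1.0, min_repro_tpm=10.0)
        if species == "mouse":
            return cls(fdr_alpha=0.05, max_nonrepro_tpm=2.0, min_repro_tpm=8.0)
        raise ScreenError(f"no threshold preset for species '{species}'")


@dataclass
class MaxTissueAssignment:
    """Per (gene, reproductive tissue): the maximal non-reproductive tissue."""

    gene: str
    repro_tissue: str
    max_tissue: str
    log2fc: float
    fdr: float
    max_tissue_tpm: float
    repro_tpm: float


def max_nonrepro_tissue(
    de_rows: pd.DataFrame, mean_tpm: pd.DataFrame
) -> MaxTissueAssignment:
    """Pick the non-reproductive tissue with maximal expression for one gene.

    ``de_rows`` holds this gene's DE results against every non-reproductive
    tissue for one reproductive tissue; the maximal tissue is the one
    minimizing log2FC (ties broken lexicographically by tissue label).
    ``mean_tpm`` is the gene x group mean-TPM matrix.
    """
    if de_rows.empty:
        raise ScreenError("no DE rows supplied")
    gene = de_rows["gene"].iloc[0]
    repro = de_rows["repro_tissue"].iloc[0]
    if de_rows["gene"].nunique() != 1 or de_rows["repro_tissue"].nunique() != 1:
        raise ScreenError("rows must belong to a single (gene, reproductive tissue)")
    ordered = de_rows.sort_values(
        ["log2fc", "nonrepro_tissue"], kind="stable"
    ).iloc[0]
    max_tissue = ordered["nonrepro_tissue"]
    return MaxTissueAssignment(
        gene=gene,
        repro_tissue=repro,
        max_tissue=max_tissue,
        log2fc=float(ordered["log2fc"]),
        fdr=float(ordered["fdr"]),
        max_tissue_tpm=float(mean_tpm.at[gene, max_tissue]),
        repro_tpm=float(mean_tpm.at[gene, repro]),
    )


def apply_specificity_filters(
    assignment: MaxTissueAssignment, thresholds: ThresholdConfig
) -> tuple[float, list[str]]:
    """Return (log2FC or 0, list of failed filter names); inclusive bounds."""
    if assignment.max_tissue_tpm < 0 or assignment.repro_tpm < 0:
        raise ScreenError("negative TPM values")
    failed = []
    if not assignment.fdr <= thresholds.fdr_alpha:
        failed.append("fdr")
    if not assignment.max_tissue_tpm <= thresholds.max_nonrepro_tpm:
        failed.append("max_nonrepro_tpm")
    if not assignment.repro_tpm >= thresholds.min_repro_tpm:
        failed.append("min_repro_tpm")
    return (assignment.log2fc if not failed else 0.0), failed


@dataclass
class CandidateTable:
    """Gene x reproductive-tissue log2FC matrix; 0 = failed the cascade.

    ``provenance`` records, per (gene, reproductive tissue), the selected
    maximal tissue, its FDR and both TPM values, and which filters failed.
    """

    log2fc: pd.DataFrame
    provenance: pd.DataFrame
    thresholds: ThresholdConfig

    @property
    def candidates(self) -> pd.Index:
        return self.log2fc.index[(self.log2fc != 0).any(axis=1)]

    def candidate_set(self, repro_tissue: str | None = None) -> set[str]:
        if repro_tissue is None:
            return set(self.candidates)
        col = self.log2fc[repro_tissue]
        return set(col.index[col != 0])


def build_candidate_table(
    de_results: pd.DataFrame,
    summary: pd.DataFrame,
    thresholds: ThresholdConfig,
) -> CandidateTable:
    """Run the cascade over every (gene, reproductive tissue).

    ``de_results`` is the pooled pairwise DE frame (gene, repro_tissue,
    nonrepro_tissue, log2fc, pvalue, fdr); ``summary`` the tidy per-group
    expression summary. Genes missing a comparison are an error; genes
    missing from the summary are an error.
    """
    genes = pd.Index(pd.unique(de_results["gene"]))
    mean_tpm = summary.pivot(index="gene", columns="group", values="mean_tpm")
    missing = genes.difference(mean_tpm.index)
    if len(missing):
        raise ScreenError(
            f"genes in DE results but not in summaries: {list(missing[:10])}"
        )
    repro_tissues = list(pd.unique(de_results["repro_tissue"]))
    nonrepro = set(pd.unique(de_results["nonrepro_tissue"]))

    fc = pd.DataFrame(0.0, index=genes, columns=repro_tissues)
    prov_rows = []
    for rt, block in de_results.groupby("repro_tissue", sort=False):
        counts = block.groupby("gene")["nonrepro_tissue"].nunique()
        incomplete = counts[counts != len(nonrepro)]
        if len(incomplete):
            raise ScreenError(
                f"missing comparisons for genes {list(incomplete.index[:5])} "
                f"in reproductive tissue '{rt}'"
            )
        # vectorized argmin of log2fc with lexicographic tie-break
        ordered = block.sort_values(
            ["gene", "log2fc", "nonrepro_tissue"], kind="stable"
        ).drop_duplicates("gene", keep="first").set_index("gene")
        max_tissue = ordered["nonrepro_tissue"]
        fdr = ordered["fdr"]
        l2fc = ordered["log2fc"]
        mt_tpm = pd.Series(
            mean_tpm.to_numpy()[
                mean_tpm.index.get_indexer(ordered.index),
                mean_tpm.columns.get_indexer(max_tissue),
            ],
            index=ordered.index,
        )
        rt_tpm = mean_tpm.loc[ordered.index, rt]
        if (mt_tpm < 0).any() or (rt_tpm < 0).any():
            raise ScreenError("negative TPM values in summaries")
        passed = (
            (fdr <= thresholds.fdr_alpha)
            & (mt_tpm <= thresholds.max_nonrepro_tpm)
            & (rt_tpm >= thresholds.min_repro_tpm)
        )
        fc.loc[ordered.index, rt] = np.where(passed, l2fc, 0.0)
        prov = pd.DataFrame(
            {
                "gene": ordered.index,
                "repro_tissue": rt,
                "max_tissue": max_tissue.to_numpy(),
                "log2fc": l2fc.to_numpy(),
                "fdr": fdr.to_numpy(),
                "max_tissue_tpm": mt_tpm.to_numpy(),
                "repro_tpm": rt_tpm.to_numpy(),
                "passed": passed.to_numpy(),
            }
        )
        fails = []
        for _, row in prov.iterrows():
            f = []
            if not row["fdr"] <= thresholds.fdr_alpha:
                f.append("fdr")
            if not row["max_tissue_tpm"] <= thresholds.max_nonrepro_tpm:
                f.append("max_nonrepro_tpm")
            if not row["repro_tpm"] >= thresholds.min_repro_tpm:
                f.append("min_repro_tpm")
            fails.append(";".join(f))
        prov["failed_filters"] = fails
        prov_rows.append(prov)

    provenance = pd.concat(prov_rows, ignore_index=True)
    return CandidateTable(log2fc=fc, provenance=provenance, thresholds=thresholds)


def candidate_table_frame(table: CandidateTable) -> pd.DataFrame:
    """Flat export: gene, one log2FC column per reproductive tissue."""
    return table.log2fc.rename_axis("gene").reset_index()
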