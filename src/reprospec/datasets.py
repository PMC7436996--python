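"""Core data container and TSV input/output.

A :class:`CountDataset` bundles a gene x sample matrix of raw read counts
with per-sample metadata (tissue, reproductive class, batch, species) and
optional gene lengths. All pipeline stages consume and return plain pandas
objects; this module is the only place that touches files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REPRODUCTIVE = "reproductive_target"
NON_REPRODUCTIVE = "non_reproductive"

#: required columns of the sample-metadata table
METADATA_COLUMNS = ("sample_id", "tissue", "class", "batch", "species")


class DatasetError(ValueError):
    """Raised when counts, metadata and lengths are mutually inconsistent."""


@dataclass
class CountDataset:
    """Gene x sample raw counts with sample metadata and gene lengths.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene ids),
        samples as columns (column names = sample ids).
    samples
        DataFrame indexed by sample id with columns ``tissue``, ``class``
        (``reproductive_target`` or ``non_reproductive``), ``batch`` and
        ``species``.
    lengths
        Optional Series mapping gene id -> length in bp (>= 1). Required for
        TPM computation.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.counts.shape[1] != len(self.samples):
            raise DatasetError(
                f"counts have {self.counts.shape[1]} sample columns but "
                f"metadata describes {len(self.samples)} samples"
            )
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise DatasetError(f"samples missing from metadata: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise DatasetError("negative counts are not allowed")
        for col in ("tissue", "class", "batch"):
            if col not in self.samples.columns:
                raise DatasetError(f"metadata lacks required column '{col}'")
        bad_class = set(self.samples["class"]) - {REPRODUCTIVE, NON_REPRODUCTIVE}
        if bad_class:
            raise DatasetError(f"unknown sample class labels: {sorted(bad_class)}")
        if self.lengths is not None:
            absent = self.counts.index.difference(self.lengths.index)
            if len(absent):
                raise DatasetError(
                    f"gene lengths missing for: {list(absent[:10])}"
                )
            if (self.lengths.reindex(self.counts.index) < 1).any():
                raise DatasetError("gene lengths must be >= 1 bp")
        # align metadata row order to count columns; canonical axis names
        self.samples = self.samples.loc[list(self.counts.columns)]
        self.counts.index.name = None
        self.counts.columns.name = None

    # ------------------------------------------------------------------ #
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def tissues(self, cls: str | None = None) -> list[str]:
        """Distinct tissue labels, optionally restricted to one class."""
        meta = self.samples
        if cls is not None:
            meta = meta[meta["class"] == cls]
        seen: dict[str, None] = {}
        for t in meta["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])

    def subset_samples(self, sample_ids: list[str]) -> "CountDataset":
        return CountDataset(
            counts=self.counts[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            lengths=self.lengths,
        )

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------- #
# TSV round-trip (synthetic_data dialect: tab-separated, '.' decimal, UTF-8)
# ---------------------------------------------------------------------- #

def read_count_matrix(
    counts_path: str | Path,
    metadata_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountDataset:
    """Read a counts TSV plus metadata (and optional lengths) into a dataset.

    The counts file has gene ids in the first column and one column per
    sample; every sample column must appear in the metadata table. Negative
    or non-numeric counts are rejected with a descriptive error.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise DatasetError(f"non-integer values in count matrix: {exc}") from exc
    counts.index.name = None
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    absent = [s for s in counts.columns if s not in meta.index]
    if absent:
        raise DatasetError(f"metadata file lacks sample(s): {absent}")
    lengths = None
    if lengths_path is not None:
        ltab = pd.read_csv(lengths_path, sep="\t")
        lengths = ltab.set_index("gene_id")["length_bp"].astype(np.int64)
    return CountDataset(counts=counts, samples=meta, lengths=lengths)


def write_count_matrix(dataset: CountDataset, outdir: str | Path, prefix: str = "") -> dict:
    """Write counts / metadata / lengths TSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "metadata": outdir / f"{prefix}metadata.tsv",
    }
    dataset.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    dataset.samples.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
    if dataset.lengths is not None:
        paths["lengths"] = outdir / f"{prefix}lengths.tsv"
        dataset.lengths.rename_axis("gene_id").rename("length_bp").to_csv(
            paths["lengths"], sep="\t"
        )
    return paths


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table in the pipeline TSV dialect (NA for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
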