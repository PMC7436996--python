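"""End-to-end pipeline driver: config, synthetic bundles, full runs.

The pipeline chains normalization, RUVr correction, pairwise differential
expression, the specificity cascade, tissue-category classification and
ortholog/druggability stratification, writing every intermediate table as
a TSV so each stage can be inspected and re-run. Identical config and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_candidates,
    compute_congruence,
    stratify_candidates,
)
from .classify import assign_tissue_categories, set_comparisons
from .datasets import (
    REPRODUCTIVE,
    CountDataset,
    read_count_matrix,
    write_count_matrix,
    write_table,
)
from .model import TissueSpecificityScreen
from .screen import ThresholdConfig, candidate_table_frame
from .simulate import (
    SimConfig,
    SyntheticTruth,
    generate_annotation_tables,
    generate_counts,
    generate_ortholog_map,
    ortholog_frame,
    parse_ortholog_frame,
    truth_frame,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, species preset and stage options for one pipeline run."""

    counts: str
    metadata: str
    lengths: str
    outdir: str
    species: str = "human"
    fdr_alpha: float | None = None
    max_nonrepro_tpm: float | None = None
    min_repro_tpm: float | None = None
    ruv_k: int = 1
    de_mode: str = "covariate"
    tpm_source: str = "corrected"
    tagwise_weight: float = 10.0
    prior_count: float = 0.125
    pseudocount: float = 0.5
    global_bh: bool = False
    seed: int = 0
    # optional annotation inputs
    orthologs: str | None = None
    annotations: str | None = None
    prior_lists: str | None = None
    partner_candidates: str | None = None
    truth: str | None = None
    #: reproductive tissue label -> dataset role for classification
    roles: dict[str, str] = field(default_factory=dict)

    def thresholds(self) -> ThresholdConfig:
        base = ThresholdConfig.preset(self.species if self.species in ("human", "mouse") else "human")
        return ThresholdConfig(
            fdr_alpha=self.fdr_alpha if self.fdr_alpha is not None else base.fdr_alpha,
            max_nonrepro_tpm=(
                self.max_nonrepro_tpm
                if self.max_nonrepro_tpm is not None
                else base.max_nonrepro_tpm
            ),
            min_repro_tpm=(
                self.min_repro_tpm if self.min_repro_tpm is not None else base.min_repro_tpm
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def default_roles(repro_tissues: list[str]) -> dict[str, str]:
    """Guess classification roles from reproductive tissue labels."""
    roles = {}
    for t in repro_tissues:
        low = t.lower()
        if "epididymis" in low or low in {"caput", "corpus", "cauda"}:
            seg = low.split("_")[-1] if "_" in low else "whole"
            roles[t] = f"epididymis:{seg}"
        elif "sertoli" in low:
            roles[t] = "sertoli"
        elif any(s in low for s in ("spermatogonia", "spermatocyte", "spermatid", "germ")):
            roles[t] = f"germ_cell:{low}"
        else:
            roles[t] = "testis"
    return roles


# ---------------------------------------------------------------------- #
# synthetic bundle
# ---------------------------------------------------------------------- #

def write_synthetic_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Generate a full synthetic input bundle and write it as TSVs.

    Produces counts, metadata, gene lengths, planted truth, the ortholog
    map, a per-gene annotation table (symbol, family, mouse-model status),
    prior-study lists and the partner-species candidate symbol list implied
    by the planted congruence flags.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_counts(config)
    omap, congruent = generate_ortholog_map(config, truth)
    ann = generate_annotation_tables(config, truth, omap)

    paths = write_count_matrix(dataset, outdir)
    paths["truth"] = outdir / "truth.tsv"
    write_table(truth_frame(truth), paths["truth"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    write_table(ortholog_frame(omap), paths["orthologs"])

    ann_df = pd.DataFrame(
        {
            "gene_id": ann.families.index,
            "symbol": ann.symbols,
            "family": ann.families,
            "model_status": ann.model_status,
        }
    )
    paths["annotations"] = outdir / "annotations.tsv"
    write_table(ann_df, paths["annotations"])

    prior_rows = [
        {"list_name": name, "species": sp, "symbol": s}
        for name, sp, symbols in ann.prior_lists
        for s in sorted(symbols)
    ]
    paths["prior_lists"] = outdir / "prior_lists.tsv"
    write_table(
        pd.DataFrame(prior_rows, columns=["list_name", "species", "symbol"]),
        paths["prior_lists"],
    )

    # partner-species candidate symbols implied by planted congruence
    tmap = omap.records.set_index("source_gene")["target_symbols"]
    partner = sorted(
        tmap[g][0] for g in congruent.index[congruent] if len(tmap.get(g, []))
    )
    paths["partner_candidates"] = outdir / "partner_candidates.tsv"
    write_table(pd.DataFrame({"symbol": partner}), paths["partner_candidates"])
    return {k: str(v) for k, v in paths.items()}


def synthetic_pipeline_config(
    sim: SimConfig, datadir: str | Path, outdir: str | Path
) -> PipelineConfig:
    paths = write_synthetic_bundle(sim, datadir)
    return PipelineConfig(
        counts=paths["counts"],
        metadata=paths["metadata"],
        lengths=paths["lengths"],
        orthologs=paths["orthologs"],
        annotations=paths["annotations"],
        prior_lists=paths["prior_lists"],
        partner_candidates=paths["partner_candidates"],
        truth=paths["truth"],
        outdir=str(outdir),
        species=sim.species,
        seed=sim.rng_seed,
    )


# ---------------------------------------------------------------------- #
# the run
# ---------------------------------------------------------------------- #

def run_pipeline(config: PipelineConfig):
    """Execute every stage and write the full output bundle.

    Returns the fitted :class:`~reprospec.model.ScreenResults`. Stage
    failures propagate wrapped with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    dataset = stage(
        "read", lambda: read_count_matrix(config.counts, config.metadata, config.lengths)
    )
    model = TissueSpecificityScreen(
        dataset,
        species=config.species if config.species in ("human", "mouse") else "human",
        thresholds=config.thresholds(),
        ruv_k=config.ruv_k,
        de_mode=config.de_mode,
        tpm_source=config.tpm_source,
        tagwise_weight=config.tagwise_weight,
        prior_count=config.prior_count,
        pseudocount=config.pseudocount,
        global_bh=config.global_bh,
    )
    res = stage("screen", model.fit)

    write_table(res.expression_summary, outdir / "expression_summary.tsv")
    write_table(res.de_results, outdir / "de_results.tsv")
    write_table(candidate_table_frame(res.candidate_table), outdir / "candidates.tsv")
    write_table(res.candidate_table.provenance, outdir / "candidate_provenance.tsv")
    write_table(res.tmm.rename("tmm_factor").rename_axis("sample_id").reset_index(), outdir / "tmm_factors.tsv")
    write_table(res.pca_scores.rename_axis("sample_id").reset_index(), outdir / "pca_scores.tsv")
    if res.pca_variance is not None:
        write_table(
            res.pca_variance.rename_axis("component").reset_index(),
            outdir / "pca_variance.tsv",
        )
    if res.factors.k > 0:
        write_table(res.factors.w.rename_axis("sample_id").reset_index(), outdir / "ruv_w.tsv")
        write_table(res.factors.alpha.rename_axis("gene_id").reset_index(), outdir / "ruv_alpha.tsv")

    # classification of candidates by dataset role
    sets = res.candidate_sets()
    roles = config.roles or default_roles(list(sets))
    classification = stage("classify", lambda: assign_tissue_categories(sets, roles))
    write_table(
        classification.table.rename_axis("gene").reset_index(),
        outdir / "classification.tsv",
    )
    overlap = set_comparisons(sets)
    write_table(overlap.pairwise, outdir / "overlap_pairwise.tsv")
    write_table(overlap.regions, outdir / "overlap_regions.tsv")

    # annotation and stratification (optional inputs)
    strat = None
    if config.orthologs and config.annotations:
        def _annotate():
            omap = parse_ortholog_frame(pd.read_csv(config.orthologs, sep="\t"))
            ann_df = pd.read_csv(config.annotations, sep="\t").set_index("gene_id")
            prior = []
            if config.prior_lists:
                pl = pd.read_csv(config.prior_lists, sep="\t")
                for (name, sp), grp in pl.groupby(["list_name", "species"]):
                    prior.append((name, sp, set(grp["symbol"])))
            partner: set[str] = set()
            if config.partner_candidates:
                pc = pd.read_csv(config.partner_candidates, sep="\t")
                partner = set(pc["symbol"].astype(str)) if len(pc) else set()
            cands = res.candidates
            congruent = compute_congruence(cands, omap, partner)
            annotation = annotate_candidates(
                cands,
                ann_df["symbol"],
                omap,
                prior,
                ann_df["family"],
                ann_df["model_status"],
                congruent,
            )
            epi = {
                g
                for g in cands
                if classification.table.at[g, "category"]
                in ("epididymis_only", "testis_and_epididymis")
            }
            return annotation, stratify_candidates(annotation, epi)

        annotation, strat = stage("annotate", _annotate)
        write_table(
            annotation.table.rename_axis("gene").reset_index(),
            outdir / "candidate_annotation.tsv",
        )
        write_table(strat.flat(), outdir / "stratification.tsv")

    # run log with config hash for provenance
    cfg_yaml = config.to_yaml()
    log = {
        "reprospec_version": __version__,
        "python": sys.version.split()[0],
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "n_genes": int(len(dataset.gene_ids)),
        "n_samples": int(len(dataset.sample_ids)),
        "n_candidates": int(len(res.candidates)),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    (outdir / "config_used.yaml").write_text(cfg_yaml)
    return res


# ---------------------------------------------------------------------- #
# benchmark against planted truth
# ---------------------------------------------------------------------- #

def load_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    df["target_tissue"] = df["target_tissue"].fillna("")
    return SyntheticTruth(
        genes=df[["planted_class", "target_tissue"]],
        batch_score=pd.Series(dtype=float),
        gene_batch_loading=pd.Series(dtype=float),
    )


def benchmark(config: PipelineConfig):
    """Run the pipeline and score the candidate set against planted truth."""
    if not config.truth:
        raise PipelineError("benchmark requires a truth file")
    res = run_pipeline(config)
    truth = load_truth(config.truth)
    metrics = res.benchmark(truth)
    write_table(metrics, Path(config.outdir) / "benchmark.tsv")
    return metrics, res
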