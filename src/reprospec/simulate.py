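"""Seeded synthetic multi-tissue RNA-seq generator with planted truth.

The generator emulates the statistical structure of an aggregated bulk
RNA-seq tissue panel: negative-binomial counts with gene-wise dispersion,
uneven library sizes, per-batch multiplicative effects (study-of-origin
artifacts), replicate groups per tissue, and planted gene classes whose
expression profiles are known exactly:

``ubiquitous``
    expressed in every tissue (log-normal abundance, mild tissue jitter);
``repro_specific:<tissue>``
    high in one reproductive tissue (mean TPM at least three times the
    reproductive detection threshold), essentially silent elsewhere;
``repro_leaky``
    high in a reproductive tissue but with one non-reproductive tissue
    expressed just above the non-reproductive ceiling — should be rejected;
``repro_lowexpr``
    reproductive-restricted but below the reproductive TPM floor — should
    be rejected;
``silent``
    zero everywhere.

Abundances are specified on the TPM scale per tissue; expected counts are
obtained by multiplying by gene length and rescaling to the sample's library
size, so the planted TPM values are (up to sampling noise and batch effects)
the values the pipeline's TPM computation recovers.

The batch model is rank one across samples: each batch ``b`` has a scalar
score ``z_b`` and each gene a loading ``beta_g``; sample ``s`` in batch ``b``
is multiplied by ``2**(beta_g * z_b)``. This is the structure the RUVr stage
is designed to estimate and remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import NON_REPRODUCTIVE, REPRODUCTIVE, CountDataset

#: the ten drug-target families used for candidate stratification
TARGET_FAMILIES = (
    "enzyme",
    "epigenetic",
    "GPCR",
    "oGPCR",
    "ion_channel",
    "kinase",
    "nuclear_receptor",
    "transcription_factor",
    "transporter",
    "unknown",
)

MODEL_STATUSES = ("no_model", "model_exists", "model_infertility_phenotype")

ORTHOLOG_BINS = ("0", "1_same_symbol", "1_diff_symbol", "2_3", "4_10", "gt_10")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TissueSpec:
    """One block of replicate samples for a tissue in one batch."""

    label: str
    cls: str  # reproductive_target | non_reproductive
    n_replicates: int
    batch: str


def default_tissues() -> list[TissueSpec]:
    """Two reproductive targets and four somatic tissues, five replicates
    each, split 3/2 across two batches so batch is not confounded with
    tissue (as when replicates come from two studies of origin)."""
    out = []
    for label, cls in [
        ("testis", REPRODUCTIVE),
        ("epididymis", REPRODUCTIVE),
        ("brain", NON_REPRODUCTIVE),
        ("liver", NON_REPRODUCTIVE),
        ("kidney", NON_REPRODUCTIVE),
        ("muscle", NON_REPRODUCTIVE),
    ]:
        out.append(TissueSpec(label, cls, 3, "batch1"))
        out.append(TissueSpec(label, cls, 2, "batch2"))
    return out


def default_class_fractions() -> dict[str, float]:
    return {
        "ubiquitous": 0.55,
        "repro_specific:testis": 0.08,
        "repro_specific:epididymis": 0.07,
        "repro_leaky": 0.05,
        "repro_lowexpr": 0.05,
        "silent": 0.20,
    }


def default_ortholog_bin_probs() -> dict[str, float]:
    return {
        "0": 0.17,
        "1_same_symbol": 0.45,
        "1_diff_symbol": 0.13,
        "2_3": 0.12,
        "4_10": 0.08,
        "gt_10": 0.05,
    }


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    n_genes: int = 2000
    tissues: list[TissueSpec] = field(default_factory=default_tissues)
    class_fractions: dict[str, float] = field(default_factory=default_class_fractions)
    #: log-normal abundance of ubiquitous genes (natural-log params, TPM scale)
    baseline_log_mean: float = np.log(20.0)
    baseline_log_sd: float = 1.3
    #: per-tissue multiplicative jitter of ubiquitous genes (log2 SD)
    tissue_jitter_log2_sd: float = 0.25
    #: gene-wise NB dispersion phi: median and natural-log SD of a log-normal
    dispersion_median: float = 0.05
    dispersion_log_sd: float = 0.7
    #: SD of gene loadings of the rank-1 batch effect, in log2 units
    batch_log2_sd: float = 0.5
    library_size_range: tuple[float, float] = (3e5, 8e5)
    gene_length_range: tuple[int, int] = (500, 5000)
    #: reproductive-specific genes: mean TPM band in the target tissue
    specific_tpm_range: tuple[float, float] = (30.0, 300.0)
    #: leaky genes: non-reproductive leak band (just above the 1.0 ceiling)
    leaky_nonrepro_tpm_range: tuple[float, float] = (1.0, 10.0)
    #: low-expression reproductive genes: below the 10.0 reproductive floor
    lowexpr_tpm_range: tuple[float, float] = (2.0, 9.0)
    #: residual TPM of "silent" tissues of planted non-ubiquitous genes
    off_target_tpm: float = 0.02
    species: str = "human"
    rng_seed: int = 0
    # ortholog / annotation generation
    ortholog_bin_probs: dict[str, float] = field(
        default_factory=default_ortholog_bin_probs
    )
    congruent_fraction: float = 0.5
    prior_list_fraction: float = 0.3
    family_probs: dict[str, float] | None = None
    model_status_probs: dict[str, float] | None = None

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if not self.tissues:
            raise SimConfigError("at least one tissue is required")
        classes = {t.cls for t in self.tissues}
        if REPRODUCTIVE not in classes or NON_REPRODUCTIVE not in classes:
            raise SimConfigError(
                "need at least one reproductive and one non-reproductive tissue"
            )
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"class fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise SimConfigError("class fractions must be non-negative")
        repro_labels = {t.label for t in self.tissues if t.cls == REPRODUCTIVE}
        for cls in self.class_fractions:
            if cls.startswith("repro_specific:"):
                target = cls.split(":", 1)[1]
                if target not in repro_labels:
                    raise SimConfigError(
                        f"specific class targets unknown reproductive tissue '{target}'"
                    )
            elif cls not in {"ubiquitous", "repro_leaky", "repro_lowexpr", "silent"}:
                raise SimConfigError(f"unknown planted class '{cls}'")
        if self.dispersion_median <= 0 or self.dispersion_log_sd < 0:
            raise SimConfigError("dispersion parameters must be positive")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise SimConfigError("gene length range must be positive and ordered")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise SimConfigError("library size range must be positive and ordered")
        if self.batch_log2_sd < 0 or self.tissue_jitter_log2_sd < 0:
            raise SimConfigError("scale parameters must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted per-gene classes and per-sample batch scores."""

    genes: pd.DataFrame  # index gene_id; columns: planted_class, target_tissue
    batch_score: pd.Series  # per sample: z_{batch(s)}
    gene_batch_loading: pd.Series  # per gene: beta_g (log2 units)

    def genes_of_class(self, prefix: str) -> pd.Index:
        mask = self.genes["planted_class"].str.startswith(prefix)
        return self.genes.index[mask]

    @property
    def specific_genes(self) -> pd.Index:
        return self.genes_of_class("repro_specific:")

    @property
    def reject_genes(self) -> pd.Index:
        """Genes that must NOT pass the screen: ubiquitous, leaky, low-expression."""
        mask = self.genes["planted_class"].isin(
            ["ubiquitous", "repro_leaky", "repro_lowexpr"]
        )
        return self.genes.index[mask]


# ---------------------------------------------------------------------- #
# counts
# ---------------------------------------------------------------------- #

def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    counter: dict[str, int] = {}
    for spec in config.tissues:
        for _ in range(spec.n_replicates):
            i = counter.get(spec.label, 0) + 1
            counter[spec.label] = i
            rows.append(
                {
                    "sample_id": f"{spec.label}_{i:02d}",
                    "tissue": spec.label,
                    "class": spec.cls,
                    "batch": spec.batch,
                    "species": config.species,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _planted_tpm_profile(
    config: SimConfig, classes: np.ndarray, tissue_labels: list[str], rng
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(gene, tissue) mean TPM matrix plus the target-tissue array."""
    n = config.n_genes
    nt = len(tissue_labels)
    t_index = {t: j for j, t in enumerate(tissue_labels)}
    repro = [t.label for t in config.tissues if t.cls == REPRODUCTIVE]
    nonrepro = [t.label for t in config.tissues if t.cls == NON_REPRODUCTIVE]
    repro = list(dict.fromkeys(repro))
    nonrepro = list(dict.fromkeys(nonrepro))

    tpm = np.zeros((n, nt))
    target = np.array([""] * n, dtype=object)
    floor = config.off_target_tpm

    def loguniform(lo, hi, size=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    ubiq = classes == "ubiquitous"
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    jitter = 2.0 ** rng.normal(0.0, config.tissue_jitter_log2_sd, (n, nt))
    tpm[ubiq] = base[ubiq, None] * jitter[ubiq]

    for g in np.flatnonzero(~ubiq):
        cls = classes[g]
        if cls == "silent":
            continue
        tpm[g, :] = floor
        if cls.startswith("repro_specific:"):
            tt = cls.split(":", 1)[1]
            tpm[g, t_index[tt]] = loguniform(*config.specific_tpm_range)
            target[g] = tt
        elif cls == "repro_leaky":
            tt = repro[rng.integers(len(repro))]
            leak = nonrepro[rng.integers(len(nonrepro))]
            tpm[g, t_index[tt]] = loguniform(*config.specific_tpm_range)
            lo, hi = config.leaky_nonrepro_tpm_range
            # keep clear of the ceiling so the planted class is unambiguous
            tpm[g, t_index[leak]] = loguniform(max(lo * 1.5, lo + 0.5), hi)
            target[g] = tt
        elif cls == "repro_lowexpr":
            tt = repro[rng.integers(len(repro))]
            tpm[g, t_index[tt]] = loguniform(*config.lowexpr_tpm_range)
            target[g] = tt

    # rescale ubiquitous genes so each tissue's TPM column totals 1e6 and the
    # planted bands are realized TPM values, not just relative abundances
    planted_sum = tpm[~ubiq].sum(axis=0)
    ubiq_sum = tpm[ubiq].sum(axis=0)
    if ubiq.any():
        remainder = 1e6 - planted_sum
        if (remainder <= 0).any():
            raise SimConfigError("planted abundance exceeds the TPM budget")
        tpm[ubiq] *= remainder / np.where(ubiq_sum > 0, ubiq_sum, 1.0)
    return tpm, target


def generate_counts(config: SimConfig) -> tuple[CountDataset, SyntheticTruth]:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    gene_ids = [f"{config.species[:1].upper()}G{i:05d}" for i in range(config.n_genes)]
    meta = _sample_frame(config)
    tissue_labels = list(dict.fromkeys(meta["tissue"]))

    labels = list(config.class_fractions)
    probs = np.array([config.class_fractions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(labels, size=config.n_genes, p=probs)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    phi = config.dispersion_median * np.exp(
        rng.normal(0.0, config.dispersion_log_sd, config.n_genes)
    )

    tpm, target = _planted_tpm_profile(config, classes, tissue_labels, rng)

    lib_lo, lib_hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), len(meta)))

    batches = list(dict.fromkeys(meta["batch"]))
    z = pd.Series(rng.normal(0.0, 1.0, len(batches)), index=batches)
    # standardize batch scores over the sample panel: batch effects are pure
    # contrasts (zero per-gene expected offset, so planted TPM bands remain
    # expectations of the realized data) and batch_log2_sd is exactly the
    # per-gene log2 SD of the batch term
    per_sample = np.array([z[b] for b in meta["batch"]], dtype=float)
    if len(batches) > 1 and per_sample.std() > 0:
        z = (z - per_sample.mean()) / per_sample.std()
    else:
        z = z * 0.0
    beta = rng.normal(0.0, config.batch_log2_sd, config.n_genes)

    tj = np.array([tissue_labels.index(t) for t in meta["tissue"]])
    weights = tpm * (lengths[:, None] / 1e3)  # expected count shares per tissue
    col_w = weights.sum(axis=0)
    mu = np.empty((config.n_genes, len(meta)))
    for s in range(len(meta)):
        if col_w[tj[s]] > 0:
            base = weights[:, tj[s]] * (lib[s] / col_w[tj[s]])
        else:  # fully silent tissue profile
            base = np.zeros(config.n_genes)
        factor = 2.0 ** (beta * z[meta["batch"].iloc[s]])
        mu[:, s] = base * factor

    # gamma-Poisson draw; phi below 1e-8 is numerically Poisson
    shape = np.where(phi > 1e-8, 1.0 / np.maximum(phi, 1e-8), np.inf)
    mix = np.ones_like(mu)
    od = phi > 1e-8
    if od.any():
        mix[od] = rng.gamma(shape[od, None], 1.0 / shape[od, None], (od.sum(), len(meta)))
    counts = rng.poisson(mu * mix)

    dataset = CountDataset(
        counts=pd.DataFrame(counts, index=gene_ids, columns=meta.index),
        samples=meta,
        lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {"planted_class": classes, "target_tissue": target}, index=gene_ids
        ),
        batch_score=pd.Series(
            [z[b] for b in meta["batch"]], index=meta.index, name="batch_score"
        ),
        gene_batch_loading=pd.Series(beta, index=gene_ids, name="batch_loading"),
    )
    return dataset, truth


# ---------------------------------------------------------------------- #
# ortholog map
# ---------------------------------------------------------------------- #

@dataclass
class OrthologMap:
    """Ortholog records for one species pair.

    ``records`` has one row per source gene: source_gene, source_symbol,
    target_symbols (list of symbols in the other species), source_db.
    """

    records: pd.DataFrame
    species_pair: tuple[str, str]

    def targets_of(self, gene: str) -> list[str]:
        row = self.records.loc[self.records["source_gene"] == gene]
        if row.empty:
            return []
        return list(row.iloc[0]["target_symbols"])


def _mouse_case(symbol: str) -> str:
    return symbol[:1].upper() + symbol[1:].lower()


def generate_ortholog_map(
    config: SimConfig, truth: SyntheticTruth, seed: int | None = None
) -> tuple[OrthologMap, pd.Series]:
    """Assign every gene an ortholog-multiplicity bin and target symbols.

    Returns the map plus a boolean per-gene Series marking which
    reproductive-specific genes were planted as cross-species congruent
    (their first ortholog is reproductive-specific in the partner species).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 101 if seed is None else seed)
    bins = list(config.ortholog_bin_probs)
    probs = np.array([config.ortholog_bin_probs[b] for b in bins], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise SimConfigError("ortholog bin probabilities must be non-negative")
    probs = probs / probs.sum()

    genes = truth.genes.index
    chosen = rng.choice(bins, size=len(genes), p=probs)
    other = "mouse" if config.species == "human" else "human"

    rows = []
    for i, gene in enumerate(genes):
        symbol = f"SYM{i:05d}"
        b = chosen[i]
        if b == "0":
            targets: list[str] = []
        elif b == "1_same_symbol":
            targets = [_mouse_case(symbol) if other == "mouse" else symbol.upper()]
        elif b == "1_diff_symbol":
            targets = [f"Alt{i:05d}" if other == "mouse" else f"ALT{i:05d}"]
        else:
            k = {
                "2_3": rng.integers(2, 4),
                "4_10": rng.integers(4, 11),
                "gt_10": rng.integers(11, 94),
            }[b]
            targets = [f"Fam{i:05d}{chr(97 + j % 26)}{j // 26}" for j in range(k)]
        rows.append(
            {
                "source_gene": gene,
                "source_symbol": symbol,
                "target_symbols": targets,
                "source_db": "synthetic_biomart",
            }
        )
    records = pd.DataFrame(rows)

    congruent = pd.Series(False, index=genes, name="congruent")
    specific = truth.specific_genes
    has_t = records.set_index("source_gene")["target_symbols"].map(len) > 0
    eligible = [g for g in specific if has_t[g]]
    n_con = int(round(config.congruent_fraction * len(eligible)))
    if n_con:
        pick = rng.choice(len(eligible), size=n_con, replace=False)
        congruent[[eligible[i] for i in pick]] = True
    return OrthologMap(records=records, species_pair=(config.species, other)), congruent


# ---------------------------------------------------------------------- #
# annotation tables
# ---------------------------------------------------------------------- #

@dataclass
class AnnotationTables:
    """Per-gene lookup tables for the stratification stage."""

    families: pd.Series  # gene -> drug-target family
    model_status: pd.Series  # gene -> mouse-model status
    prior_lists: list[tuple[str, str, set[str]]]  # (name, species, symbols)
    symbols: pd.Series  # gene -> own symbol


def generate_annotation_tables(
    config: SimConfig,
    truth: SyntheticTruth,
    ortholog_map: OrthologMap | None = None,
    seed: int | None = None,
) -> AnnotationTables:
    """Draw drug-target families, mouse-model statuses and prior-study lists.

    The prior list samples a configured fraction of the planted reproductive-
    specific genes (by their own symbols), so novelty flagging has a known
    answer.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 202 if seed is None else seed)
    genes = truth.genes.index
    symbols = pd.Series([f"SYM{i:05d}" for i in range(len(genes))], index=genes)

    fam_probs = config.family_probs or {
        "enzyme": 0.18,
        "epigenetic": 0.05,
        "GPCR": 0.05,
        "oGPCR": 0.03,
        "ion_channel": 0.05,
        "kinase": 0.08,
        "nuclear_receptor": 0.02,
        "transcription_factor": 0.09,
        "transporter": 0.10,
        "unknown": 0.35,
    }
    unknown = set(fam_probs) - set(TARGET_FAMILIES)
    if unknown:
        raise SimConfigError(f"unknown target families: {sorted(unknown)}")
    fams = list(fam_probs)
    fp = np.array([fam_probs[f] for f in fams], dtype=float)
    families = pd.Series(rng.choice(fams, size=len(genes), p=fp / fp.sum()), index=genes)

    ms_probs = config.model_status_probs or {
        "no_model": 0.45,
        "model_exists": 0.40,
        "model_infertility_phenotype": 0.15,
    }
    ms = list(ms_probs)
    mp = np.array([ms_probs[m] for m in ms], dtype=float)
    model_status = pd.Series(rng.choice(ms, size=len(genes), p=mp / mp.sum()), index=genes)

    specific = list(truth.specific_genes)
    n_prior = int(round(config.prior_list_fraction * len(specific)))
    prior_symbols: set[str] = set()
    if n_prior:
        pick = rng.choice(len(specific), size=n_prior, replace=False)
        prior_symbols = {symbols[specific[i]] for i in pick}
    prior_lists = (
        [("synthetic_prior_study", config.species, prior_symbols)] if n_prior else []
    )
    return AnnotationTables(
        families=families,
        model_status=model_status,
        prior_lists=prior_lists,
        symbols=symbols,
    )


# ---------------------------------------------------------------------- #
# serialization helpers (deterministic row order)
# ---------------------------------------------------------------------- #

def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    return truth.genes.rename_axis("gene_id").reset_index()


def ortholog_frame(omap: OrthologMap) -> pd.DataFrame:
    df = omap.records.copy()
    df["target_symbols"] = df["target_symbols"].map(";".join)
    df["species_pair"] = "->".join(omap.species_pair)
    return df


def parse_ortholog_frame(df: pd.DataFrame) -> OrthologMap:
    df = df.copy()
    df["target_symbols"] = (
        df["target_symbols"].fillna("").map(lambda s: [t for t in s.split(";") if t])
    )
    pair = tuple(df["species_pair"].iloc[0].split("->")) if "species_pair" in df else ("human", "mouse")
    return OrthologMap(
        records=df[["source_gene", "source_symbol", "target_symbols", "source_db"]],
        species_pair=pair,  # type: ignore[arg-type]
    )
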