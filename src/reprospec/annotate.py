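"""Ortholog consolidation, novelty flagging and candidate stratification.

Ortholog maps from several sources (e.g. Ensembl BioMart and MGI exports)
are consolidated per stable gene id by unioning target-symbol sets. Each
candidate is then binned by ortholog multiplicity, flagged novel against
prior-study gene lists (after cross-species symbol conversion), assigned a
drug-target family and a mouse-model status, and finally stratified into
the nested scheme: total -> has/lacks ortholog -> novel/previously
identified -> model/no model -> the congruent-novel-no-model priority set.

Human/mouse "same symbol" comparison is case-insensitive by default, since
the species differ only by capitalization convention for most one-to-one
orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import MODEL_STATUSES, ORTHOLOG_BINS, TARGET_FAMILIES, OrthologMap


class AnnotateError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# ortholog map consolidation and binning
# ---------------------------------------------------------------------- #

def consolidate_ortholog_sources(maps: list[OrthologMap]) -> OrthologMap:
    """Union target-symbol sets per source gene across sources.

    All inputs must describe the same species pair; duplicates are removed
    by exact symbol match and the output is keyed by the stable gene id.
    """
    if not maps:
        raise AnnotateError("no ortholog sources supplied")
    pair = maps[0].species_pair
    for m in maps[1:]:
        if m.species_pair != pair:
            raise AnnotateError(
                f"conflicting species pairs: {pair} vs {m.species_pair}"
            )
    targets: dict[str, list[str]] = {}
    symbols: dict[str, str] = {}
    dbs: dict[str, list[str]] = {}
    for m in maps:
        for _, row in m.records.iterrows():
            g = row["source_gene"]
            symbols.setdefault(g, row["source_symbol"])
            cur = targets.setdefault(g, [])
            for t in row["target_symbols"]:
                if t not in cur:
                    cur.append(t)
            db = dbs.setdefault(g, [])
            if row["source_db"] not in db:
                db.append(row["source_db"])
    records = pd.DataFrame(
        {
            "source_gene": list(targets),
            "source_symbol": [symbols[g] for g in targets],
            "target_symbols": [targets[g] for g in targets],
            "source_db": ["+".join(dbs[g]) for g in targets],
        }
    )
    return OrthologMap(records=records, species_pair=pair)


def bin_ortholog_multiplicity(
    own_symbol: str, targets: list[str], case_insensitive: bool = True
) -> str:
    """Multiplicity bin: 0 / 1 (same or different symbol) / 2-3 / 4-10 / >10."""
    n = len(targets)
    if n == 0:
        return "0"
    if n == 1:
        a, b = own_symbol, targets[0]
        same = a.lower() == b.lower() if case_insensitive else a == b
        return "1_same_symbol" if same else "1_diff_symbol"
    if n <= 3:
        return "2_3"
    if n <= 10:
        return "4_10"
    return "gt_10"


# ---------------------------------------------------------------------- #
# novelty against prior studies
# ---------------------------------------------------------------------- #

def flag_novelty(
    candidate_symbols: pd.Series,
    prior_lists: list[tuple[str, str, set[str]]],
    ortholog_map: OrthologMap,
) -> pd.Series:
    """True where a candidate is absent from every prior list.

    ``candidate_symbols`` maps gene id -> own symbol. A candidate is not
    novel iff its own symbol, or any consolidated ortholog symbol, appears
    (case-insensitively) in any prior list; prior lists tagged with the
    partner species are matched through the ortholog map, same-species
    lists directly. Monotone: growing the prior lists never increases the
    novel count.
    """
    own_species, other_species = ortholog_map.species_pair
    tmap = ortholog_map.records.set_index("source_gene")["target_symbols"]
    novel = pd.Series(True, index=candidate_symbols.index, name="novel")
    for _, species, symbols in prior_lists:
        lowered = {s.lower() for s in symbols}
        for gene, sym in candidate_symbols.items():
            if not novel[gene]:
                continue
            if species == own_species:
                if sym.lower() in lowered:
                    novel[gene] = False
            elif species == other_species:
                for t in tmap.get(gene, []):
                    if t.lower() in lowered:
                        novel[gene] = False
                        break
    return novel


def compute_congruence(
    genes: pd.Index,
    ortholog_map: OrthologMap,
    partner_candidate_symbols: set[str],
) -> pd.Series:
    """True where any ortholog symbol is a candidate in the partner species.

    This is the cross-species congruence flag: a gene screened as
    reproductive tract-specific whose ortholog was independently screened
    as specific in the other species. Symbol comparison is
    case-insensitive.
    """
    partner = {s.lower() for s in partner_candidate_symbols}
    tmap = ortholog_map.records.set_index("source_gene")["target_symbols"]
    out = pd.Series(False, index=genes, name="congruent")
    for g in genes:
        out[g] = any(t.lower() in partner for t in tmap.get(g, []))
    return out


# ---------------------------------------------------------------------- #
# legacy probe-id re-identification bookkeeping
# ---------------------------------------------------------------------- #

LEGACY_STATUSES = (
    "same_symbol",
    "updated_symbol",
    "newly_identified",
    "lost_mapping",
    "unidentified",
)


@dataclass
class LegacyRemapReport:
    """Per-probe re-identification status; statuses partition the probes."""

    table: pd.DataFrame  # index probe; column status

    def counts(self) -> pd.Series:
        return self.table["status"].value_counts().reindex(
            LEGACY_STATUSES, fill_value=0
        )


def classify_legacy_ids(
    probes: list[str],
    old_map: dict[str, str | None],
    new_map: dict[str, str | None],
) -> LegacyRemapReport:
    """Compare historical probe->symbol mappings with current ones."""
    rows = []
    for p in probes:
        if p not in old_map or p not in new_map:
            raise AnnotateError(f"probe '{p}' absent from a mapping")
        old, new = old_map[p], new_map[p]
        if old is not None and new is not None:
            status = "same_symbol" if old == new else "updated_symbol"
        elif old is None and new is not None:
            status = "newly_identified"
        elif old is not None:
            status = "lost_mapping"
        else:
            status = "unidentified"
        rows.append({"probe": p, "status": status})
    return LegacyRemapReport(table=pd.DataFrame(rows).set_index("probe"))


# ---------------------------------------------------------------------- #
# per-candidate annotation and stratification
# ---------------------------------------------------------------------- #

@dataclass
class CandidateAnnotation:
    """Per-candidate annotation table feeding the stratification scheme."""

    table: pd.DataFrame
    # columns: symbol, ortholog_bin, has_ortholog, novel, family,
    #          model_status, congruent


def annotate_candidates(
    candidates: pd.Index,
    symbols: pd.Series,
    ortholog_map: OrthologMap,
    prior_lists: list[tuple[str, str, set[str]]],
    families: pd.Series,
    model_status: pd.Series,
    congruent: pd.Series,
) -> CandidateAnnotation:
    """Assemble the full annotation table for a candidate list."""
    missing = candidates.difference(symbols.index)
    if len(missing):
        raise AnnotateError(f"candidates without symbols: {list(missing[:10])}")
    tmap = ortholog_map.records.set_index("source_gene")["target_symbols"]
    bins = []
    for g in candidates:
        targets = tmap.get(g, [])
        bins.append(bin_ortholog_multiplicity(symbols[g], list(targets)))
    novel = flag_novelty(symbols[candidates], prior_lists, ortholog_map)
    bad_fam = set(families[candidates]) - set(TARGET_FAMILIES)
    if bad_fam:
        raise AnnotateError(f"unknown target families: {sorted(bad_fam)}")
    bad_ms = set(model_status[candidates]) - set(MODEL_STATUSES)
    if bad_ms:
        raise AnnotateError(f"unknown model statuses: {sorted(bad_ms)}")
    table = pd.DataFrame(
        {
            "symbol": symbols[candidates],
            "ortholog_bin": pd.Categorical(bins, categories=ORTHOLOG_BINS),
            "has_ortholog": [b != "0" for b in bins],
            "novel": novel[candidates],
            "family": families[candidates],
            "model_status": model_status[candidates],
            "congruent": congruent.reindex(candidates).fillna(False).astype(bool),
        },
        index=candidates,
    )
    if (table["congruent"] & ~table["has_ortholog"]).any():
        raise AnnotateError("congruence without an ortholog is inconsistent")
    return CandidateAnnotation(table=table)


@dataclass
class Stratum:
    name: str
    genes: list[str]
    epi_genes: list[str]  # epididymis-involved subset (parenthetical counts)
    children: list["Stratum"] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.genes)

    @property
    def epi_count(self) -> int:
        return len(self.epi_genes)


@dataclass
class StratificationReport:
    """Nested candidate strata mirroring the bubble scheme.

    total -> has_ortholog / no_ortholog; has_ortholog -> novel / known;
    novel -> no_model / model; no_model -> priority (congruent). Counts at
    each level sum to the parent's by construction. Epididymis-involved
    sub-counts are carried per stratum.
    """

    root: Stratum

    def flat(self) -> pd.DataFrame:
        rows: list[dict] = []

        def walk(node: Stratum, parent: str):
            rows.append(
                {
                    "stratum": node.name,
                    "parent": parent,
                    "n_genes": node.count,
                    "n_epididymis_involved": node.epi_count,
                    "genes": ";".join(sorted(node.genes)),
                }
            )
            for c in node.children:
                walk(c, node.name)

        walk(self.root, "")
        return pd.DataFrame(rows)

    def find(self, name: str) -> Stratum:
        def walk(node: Stratum):
            if node.name == name:
                return node
            for c in node.children:
                found = walk(c)
                if found is not None:
                    return found
            return None

        node = walk(self.root)
        if node is None:
            raise KeyError(name)
        return node


def stratify_candidates(
    annotation: CandidateAnnotation,
    epididymis_involved: set[str] | None = None,
) -> StratificationReport:
    """Build the nested ortholog/novelty/model/priority strata.

    ``epididymis_involved`` marks genes classified as epididymis-specific or
    testis-and-epididymis; their counts are reported alongside each stratum.
    """
    t = annotation.table
    if t.isna().any().any():
        raise AnnotateError("unannotated candidates present")
    epi = epididymis_involved or set()

    def stratum(name: str, genes: pd.Index) -> Stratum:
        gl = list(genes)
        return Stratum(name=name, genes=gl, epi_genes=[g for g in gl if g in epi])

    root = stratum("total", t.index)
    has_o = stratum("has_ortholog", t.index[t["has_ortholog"]])
    no_o = stratum("no_ortholog", t.index[~t["has_ortholog"]])
    root.children = [has_o, no_o]

    ho = t.loc[t["has_ortholog"]]
    novel = stratum("novel", ho.index[ho["novel"]])
    known = stratum("previously_identified", ho.index[~ho["novel"]])
    has_o.children = [novel, known]

    nv = ho.loc[ho["novel"]]
    no_model = stratum("novel_no_model", nv.index[nv["model_status"] == "no_model"])
    with_model = stratum(
        "novel_with_model", nv.index[nv["model_status"] != "no_model"]
    )
    novel.children = [no_model, with_model]

    nm = nv.loc[nv["model_status"] == "no_model"]
    priority = stratum("priority_congruent", nm.index[nm["congruent"]])
    non_congruent = stratum("not_congruent", nm.index[~nm["congruent"]])
    no_model.children = [priority, non_congruent]
    return StratificationReport(root=root)
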