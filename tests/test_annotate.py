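import numpy as np
import pandas as pd
import pytest

from reprospec.annotate import (
    AnnotateError,
    LEGACY_STATUSES,
    annotate_candidates,
    bin_ortholog_multiplicity,
    classify_legacy_ids,
    compute_congruence,
    consolidate_ortholog_sources,
    flag_novelty,
    stratify_candidates,
)
from reprospec.simulate import OrthologMap


def make_map(records, pair=("human", "mouse")):
    return OrthologMap(
        records=pd.DataFrame(
            [
                {"source_gene": g, "source_symbol": s, "target_symbols": t,
                 "source_db": db}
                for g, s, t, db in records
            ]
        ),
        species_pair=pair,
    )


# ------------------------------------------------------------------ #
# consolidation
# ------------------------------------------------------------------ #

def test_union_of_sources():
    m1 = make_map([("A", "A1", ["x"], "biomart")])
    m2 = make_map([("A", "A1", ["x", "y"], "mgi")])
    out = consolidate_ortholog_sources([m1, m2])
    assert out.targets_of("A") == ["x", "y"]
    assert out.records.iloc[0]["source_db"] == "biomart+mgi"


def test_disjoint_sources_concatenate():
    m1 = make_map([("A", "A1", ["x"], "biomart")])
    m2 = make_map([("B", "B1", ["y"], "mgi")])
    out = consolidate_ortholog_sources([m1, m2])
    assert out.targets_of("A") == ["x"] and out.targets_of("B") == ["y"]


def test_conflicting_species_pairs_rejected():
    m1 = make_map([("A", "A1", ["x"], "d1")])
    m2 = make_map([("A", "A1", ["x"], "d2")], pair=("human", "rat"))
    with pytest.raises(AnnotateError, match="species"):
        consolidate_ortholog_sources([m1, m2])


@pytest.mark.parametrize("seed", range(3))
def test_consolidation_matches_naive_union_oracle(seed):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(15)]
    symbols = [f"T{i}" for i in range(20)]
    maps, expected = [], {}
    for db in ("src1", "src2", "src3"):
        recs = []
        for g in genes:
            t = [s for s in symbols if rng.random() < 0.15]
            recs.append((g, g.lower(), t, db))
            cur = expected.setdefault(g, [])
            for s in t:
                if s not in cur:
                    cur.append(s)
        maps.append(make_map(recs))
    out = consolidate_ortholog_sources(maps)
    for g in genes:
        assert out.targets_of(g) == expected[g]


# ------------------------------------------------------------------ #
# multiplicity bins
# ------------------------------------------------------------------ #

@pytest.mark.parametrize(
    "targets,expected",
    [
        ([], "0"),
        (["Symb"], "1_same_symbol"),
        (["Other"], "1_diff_symbol"),
        (["a", "b"], "2_3"),
        (["a", "b", "c"], "2_3"),
        (["a", "b", "c", "d"], "4_10"),
        ([f"t{i}" for i in range(10)], "4_10"),
        ([f"t{i}" for i in range(11)], "gt_10"),
        ([f"t{i}" for i in range(12)], "gt_10"),
    ],
)
def test_multiplicity_bins(targets, expected):
    assert bin_ortholog_multiplicity("SYMB", targets) == expected


def test_case_sensitive_mode():
    assert bin_ortholog_multiplicity("SYMB", ["Symb"], case_insensitive=False) == "1_diff_symbol"


# ------------------------------------------------------------------ #
# novelty
# ------------------------------------------------------------------ #

def test_empty_prior_lists_all_novel():
    omap = make_map([("A", "SYMA", ["Syma"], "d")])
    novel = flag_novelty(pd.Series({"A": "SYMA"}), [], omap)
    assert bool(novel["A"])


def test_mouse_prior_list_matches_through_ortholog():
    omap = make_map([("A", "SYMA", ["Syma"], "d")])
    prior = [("schultz", "mouse", {"Syma"})]
    novel = flag_novelty(pd.Series({"A": "SYMA"}), prior, omap)
    assert not bool(novel["A"])


def test_same_species_prior_list_matches_own_symbol():
    omap = make_map([("A", "SYMA", [], "d")])
    prior = [("djureinovic", "human", {"syma"})]  # case-insensitive
    novel = flag_novelty(pd.Series({"A": "SYMA"}), prior, omap)
    assert not bool(novel["A"])


def test_growing_prior_lists_never_increases_novel_count():
    rng = np.random.default_rng(0)
    genes = {f"G{i}": f"SYM{i}" for i in range(30)}
    omap = make_map([(g, s, [s.capitalize()], "d") for g, s in genes.items()])
    symbols = pd.Series(genes)
    small = {f"SYM{i}" for i in range(30) if rng.random() < 0.2}
    big = small | {f"SYM{i}" for i in range(30) if rng.random() < 0.3}
    n_small = flag_novelty(symbols, [("p", "human", small)], omap).sum()
    n_big = flag_novelty(symbols, [("p", "human", big)], omap).sum()
    assert n_big <= n_small


# ------------------------------------------------------------------ #
# legacy probe remapping
# ------------------------------------------------------------------ #

def test_legacy_statuses():
    probes = ["p1", "p2", "p3", "p4", "p5"]
    old = {"p1": "g1", "p2": "g1", "p3": None, "p4": "gx", "p5": None}
    new = {"p1": "g1", "p2": "g2", "p3": "g3", "p4": None, "p5": None}
    rep = classify_legacy_ids(probes, old, new)
    assert rep.table["status"].tolist() == [
        "same_symbol", "updated_symbol", "newly_identified",
        "lost_mapping", "unidentified",
    ]


def test_legacy_statuses_partition_probes():
    rng = np.random.default_rng(1)
    probes = [f"p{i}" for i in range(200)]
    sym = lambda: None if rng.random() < 0.4 else f"g{rng.integers(50)}"
    old = {p: sym() for p in probes}
    new = {p: sym() for p in probes}
    rep = classify_legacy_ids(probes, old, new)
    counts = rep.counts()
    assert counts.sum() == len(probes)
    assert set(rep.table["status"]) <= set(LEGACY_STATUSES)


def test_legacy_missing_probe_errors():
    with pytest.raises(AnnotateError, match="p2"):
        classify_legacy_ids(["p1", "p2"], {"p1": "g"}, {"p1": "g", "p2": "g"})


# ------------------------------------------------------------------ #
# stratification
# ------------------------------------------------------------------ #

def annotation_fixture(n=40, seed=2):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i}" for i in range(n)])
    symbols = pd.Series([f"SYM{i}" for i in range(n)], index=genes)
    recs = []
    for i, g in enumerate(genes):
        t = [f"T{i}"] if rng.random() < 0.7 else []
        recs.append((g, symbols[g], t, "d"))
    omap = make_map(recs)
    prior = [("prior", "human", {symbols.iloc[i] for i in range(n) if rng.random() < 0.3})]
    families = pd.Series(rng.choice(["enzyme", "kinase", "unknown"], n), index=genes)
    model = pd.Series(
        rng.choice(["no_model", "model_exists", "model_infertility_phenotype"], n),
        index=genes,
    )
    partner = {f"T{i}" for i in range(n) if rng.random() < 0.5}
    congruent = compute_congruence(genes, omap, partner)
    return annotate_candidates(genes, symbols, omap, prior, families, model, congruent)


def test_strata_counts_sum_to_parent():
    ann = annotation_fixture()
    rep = stratify_candidates(ann)
    flat = rep.flat().set_index("stratum")
    for parent in ["total", "has_ortholog", "novel", "novel_no_model"]:
        children = flat[flat["parent"] == parent]
        assert children["n_genes"].sum() == flat.at[parent, "n_genes"]
        assert (
            children["n_epididymis_involved"].sum()
            == flat.at[parent, "n_epididymis_involved"]
        )


def test_no_orthologs_means_no_downstream_strata():
    n = 10
    genes = pd.Index([f"G{i}" for i in range(n)])
    symbols = pd.Series([f"S{i}" for i in range(n)], index=genes)
    omap = make_map([(g, symbols[g], [], "d") for g in genes])
    ann = annotate_candidates(
        genes, symbols, omap, [],
        pd.Series("unknown", index=genes),
        pd.Series("no_model", index=genes),
        pd.Series(False, index=genes),
    )
    rep = stratify_candidates(ann)
    assert rep.find("has_ortholog").count == 0
    assert rep.find("priority_congruent").count == 0
    assert rep.find("no_ortholog").count == n


def test_planted_priority_genes_land_in_priority_stratum():
    """Genes planted as congruent + novel + no-model appear exactly in the
    priority stratum."""
    genes = pd.Index(["G0", "G1", "G2", "G3"])
    symbols = pd.Series(["S0", "S1", "S2", "S3"], index=genes)
    omap = make_map([
        ("G0", "S0", ["T0"], "d"),  # congruent, novel, no model -> priority
        ("G1", "S1", ["T1"], "d"),  # not congruent
        ("G2", "S2", ["T2"], "d"),  # previously identified
        ("G3", "S3", [], "d"),      # no ortholog
    ])
    prior = [("p", "human", {"S2"})]
    congruent = compute_congruence(genes, omap, {"T0"})
    ann = annotate_candidates(
        genes, symbols, omap, prior,
        pd.Series("kinase", index=genes),
        pd.Series("no_model", index=genes),
        congruent,
    )
    rep = stratify_candidates(ann, epididymis_involved={"G0"})
    assert rep.find("priority_congruent").genes == ["G0"]
    assert rep.find("priority_congruent").epi_genes == ["G0"]
    assert rep.find("not_congruent").genes == ["G1"]
    assert rep.find("previously_identified").genes == ["G2"]
    assert rep.find("no_ortholog").genes == ["G3"]


def test_congruence_requires_ortholog_consistency():
    genes = pd.Index(["G0"])
    omap = make_map([("G0", "S0", [], "d")])
    with pytest.raises(AnnotateError, match="congruence"):
        annotate_candidates(
            genes, pd.Series({"G0": "S0"}), omap, [],
            pd.Series("unknown", index=genes),
            pd.Series("no_model", index=genes),
            pd.Series(True, index=genes),
        )
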