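import numpy as np
import pandas as pd
import pytest

from reprospec.screen import (
    MaxTissueAssignment,
    ScreenError,
    ThresholdConfig,
    apply_specificity_filters,
    build_candidate_table,
    max_nonrepro_tissue,
)


def de_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "repro_tissue", "nonrepro_tissue", "log2fc", "pvalue", "fdr"]
    )


def summary_frame(mean_tpm: dict):
    rows = [
        {"gene": g, "group": grp, "mean_tpm": v, "sd_tpm": 0.0,
         "mean_log2cpm": 0.0, "singleton": False}
        for (g, grp), v in mean_tpm.items()
    ]
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ #
# max-tissue selection
# ------------------------------------------------------------------ #

def test_min_log2fc_tissue_selected():
    de = de_frame([
        ("g1", "testis", "liver", 6.1, 1e-8, 1e-7),
        ("g1", "testis", "brain", 1.2, 1e-3, 5e-3),
    ])
    tpm = summary_frame({("g1", "liver"): 0.2, ("g1", "brain"): 8.0,
                         ("g1", "testis"): 50.0})
    a = max_nonrepro_tissue(de, tpm.pivot(index="gene", columns="group", values="mean_tpm"))
    assert a.max_tissue == "brain"
    assert a.log2fc == 1.2
    assert a.max_tissue_tpm == 8.0
    assert a.repro_tpm == 50.0


def test_exact_tie_breaks_lexicographically():
    de = de_frame([
        ("g1", "testis", "liver", 2.0, 1e-3, 1e-2),
        ("g1", "testis", "brain", 2.0, 1e-3, 1e-2),
    ])
    tpm = summary_frame({("g1", "liver"): 1.0, ("g1", "brain"): 1.0,
                         ("g1", "testis"): 30.0})
    a = max_nonrepro_tissue(de, tpm.pivot(index="gene", columns="group", values="mean_tpm"))
    assert a.max_tissue == "brain"


def test_min_log2fc_agrees_with_max_tpm_without_batch_effects():
    """With no batch structure, the tissue minimizing log2FC is the tissue
    maximizing mean TPM for nearly all expressed genes."""
    from reprospec.model import TissueSpecificityScreen
    from reprospec.simulate import SimConfig, generate_counts

    ds, _ = generate_counts(
        SimConfig(n_genes=2000, rng_seed=7, batch_log2_sd=0.0,
                  tissue_jitter_log2_sd=0.6)
    )
    res = TissueSpecificityScreen(ds, ruv_k=0, tpm_source="raw").fit()
    tpm = res.expression_summary.pivot(index="gene", columns="group", values="mean_tpm")
    nonrepro = ["brain", "kidney", "liver", "muscle"]
    prov = res.candidate_table.provenance
    prov = prov[prov["repro_tissue"] == "testis"].set_index("gene")
    top = tpm[nonrepro].max(axis=1)
    second = tpm[nonrepro].apply(lambda r: r.nlargest(2).iloc[-1], axis=1)
    # restrict to expressed genes with an unambiguous maximum; near-ties can
    # legitimately be resolved either way by the two selection rules
    clear = (top > 5.0) & (second < 0.66 * top)
    agree = [
        prov.at[g, "max_tissue"] == tpm.loc[g, nonrepro].idxmax()
        for g in tpm.index[clear]
    ]
    assert len(agree) > 50
    assert np.mean(agree) >= 0.99


# ------------------------------------------------------------------ #
# filters: paper thresholds, inclusive boundaries
# ------------------------------------------------------------------ #

def assignment(fdr, max_tpm, repro_tpm, fc=5.0):
    return MaxTissueAssignment(
        gene="g", repro_tissue="testis", max_tissue="liver",
        log2fc=fc, fdr=fdr, max_tissue_tpm=max_tpm, repro_tpm=repro_tpm,
    )


def test_human_passing_gene_emits_fc():
    fc, failed = apply_specificity_filters(
        assignment(0.04, 0.9, 12.0), ThresholdConfig.preset("human")
    )
    assert fc == 5.0 and failed == []


def test_human_boundary_values_inclusive():
    fc, failed = apply_specificity_filters(
        assignment(0.05, 1.0, 10.0), ThresholdConfig.preset("human")
    )
    assert fc == 5.0 and failed == []


def test_mouse_thresholds_differ_from_human():
    a = assignment(0.01, 1.5, 8.0)
    fc_mouse, failed_mouse = apply_specificity_filters(a, ThresholdConfig.preset("mouse"))
    fc_human, failed_human = apply_specificity_filters(a, ThresholdConfig.preset("human"))
    assert fc_mouse == 5.0 and failed_mouse == []
    assert fc_human == 0.0 and set(failed_human) == {"max_nonrepro_tpm", "min_repro_tpm"}


@pytest.mark.parametrize(
    "fdr,max_tpm,repro_tpm,expect_failed",
    [
        (0.0500000001, 1.0, 10.0, ["fdr"]),
        (0.05, 1.0000001, 10.0, ["max_nonrepro_tpm"]),
        (0.05, 1.0, 9.9999999, ["min_repro_tpm"]),
    ],
)
def test_just_over_boundary_fails_named_filter(fdr, max_tpm, repro_tpm, expect_failed):
    fc, failed = apply_specificity_filters(
        assignment(fdr, max_tpm, repro_tpm), ThresholdConfig.preset("human")
    )
    assert fc == 0.0 and failed == expect_failed


def test_negative_tpm_rejected():
    with pytest.raises(ScreenError):
        apply_specificity_filters(assignment(0.01, -1.0, 20.0), ThresholdConfig.preset("human"))


# ------------------------------------------------------------------ #
# candidate table
# ------------------------------------------------------------------ #

def brute_force_table(de, tpm_lookup, thresholds):
    """Triple-nested-loop oracle over genes x repro groups x filters."""
    genes = sorted(de["gene"].unique())
    repro = sorted(de["repro_tissue"].unique())
    fc = pd.DataFrame(0.0, index=genes, columns=repro)
    for g in genes:
        for r in repro:
            rows = de[(de["gene"] == g) & (de["repro_tissue"] == r)]
            best = None
            for _, row in rows.iterrows():
                key = (row["log2fc"], row["nonrepro_tissue"])
                if best is None or key < (best["log2fc"], best["nonrepro_tissue"]):
                    best = row
            ok = (
                best["fdr"] <= thresholds.fdr_alpha
                and tpm_lookup[(g, best["nonrepro_tissue"])] <= thresholds.max_nonrepro_tpm
                and tpm_lookup[(g, r)] >= thresholds.min_repro_tpm
            )
            if ok:
                fc.at[g, r] = best["log2fc"]
    return fc


def random_instance(seed, n_genes=50):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    repro = ["testis", "epididymis"]
    nonrepro = ["brain", "liver", "kidney", "muscle"]
    rows = []
    tpm = {}
    for g in genes:
        for r in repro:
            tpm[(g, r)] = float(rng.choice([0.0, 5.0, 10.0, 50.0]))
            for n in nonrepro:
                rows.append(
                    (g, r, n, float(rng.choice([-2.0, 0.0, 1.5, 6.0])),
                     float(rng.random()), float(rng.choice([0.01, 0.05, 0.2])))
                )
        for n in nonrepro:
            tpm[(g, n)] = float(rng.choice([0.0, 0.5, 1.0, 3.0]))
    return de_frame(rows), tpm


def to_summary(tpm_lookup):
    return summary_frame(tpm_lookup)


@pytest.mark.parametrize("seed", range(5))
def test_candidate_table_matches_brute_force(seed):
    de, tpm = random_instance(seed)
    th = ThresholdConfig.preset("human")
    table = build_candidate_table(de, to_summary(tpm), th)
    expected = brute_force_table(de, tpm, th)
    pd.testing.assert_frame_equal(
        table.log2fc.sort_index()[expected.columns], expected.sort_index(),
        check_names=False,
    )


def test_infinite_repro_threshold_gives_no_candidates():
    de, tpm = random_instance(99)
    th = ThresholdConfig(fdr_alpha=0.05, max_nonrepro_tpm=1.0, min_repro_tpm=np.inf)
    table = build_candidate_table(de, to_summary(tpm), th)
    assert len(table.candidates) == 0
    assert (table.log2fc == 0).all().all()


def test_relaxing_thresholds_never_removes_candidates():
    de, tpm = random_instance(3)
    strict = ThresholdConfig(fdr_alpha=0.03, max_nonrepro_tpm=0.5, min_repro_tpm=20.0)
    loose = ThresholdConfig(fdr_alpha=0.1, max_nonrepro_tpm=2.0, min_repro_tpm=5.0)
    c_strict = build_candidate_table(de, to_summary(tpm), strict).candidate_set()
    c_loose = build_candidate_table(de, to_summary(tpm), loose).candidate_set()
    assert c_strict <= c_loose


def test_every_zero_entry_has_recorded_failure_or_untested():
    de, tpm = random_instance(4)
    th = ThresholdConfig.preset("human")
    table = build_candidate_table(de, to_summary(tpm), th)
    prov = table.provenance.set_index(["gene", "repro_tissue"])
    for g in table.log2fc.index:
        for r in table.log2fc.columns:
            if table.log2fc.at[g, r] == 0:
                row = prov.loc[(g, r)]
                assert (not row["passed"]) or row["log2fc"] == 0
                if not row["passed"]:
                    assert row["failed_filters"] != ""


def test_missing_comparison_errors():
    de, tpm = random_instance(5)
    de = de.drop(de.index[(de["gene"] == "g0") & (de["nonrepro_tissue"] == "brain")])
    with pytest.raises(ScreenError, match="missing comparisons"):
        build_candidate_table(de, to_summary(tpm), ThresholdConfig.preset("human"))


def test_inconsistent_gene_universe_errors():
    de, tpm = random_instance(6)
    tpm = {k: v for k, v in tpm.items() if k[0] != "g0"}
    with pytest.raises(ScreenError, match="not in summaries"):
        build_candidate_table(de, to_summary(tpm), ThresholdConfig.preset("human"))
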