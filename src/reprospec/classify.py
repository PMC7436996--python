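"""Set-algebra classification of candidates into tissue categories.

Each dataset contributing candidates has a declared role: ``testis``
(whole testis), ``germ_cell:<stage>`` (purified germ cells, e.g.
spermatogonia, spermatocytes, spermatids), ``sertoli``, or
``epididymis:<segment>`` (caput/corpus/cauda or whole). A candidate's
category is decided by which roles it was identified through:

- ``testis_and_epididymis``: any testis-side dataset (whole testis, germ
  cells, or Sertoli cells) together with any epididymis dataset;
- ``epididymis_only``: epididymis datasets and nothing testis-side;
- ``testis_only``: whole-testis involvement without epididymis;
- ``sertoli_only``: Sertoli cells but no whole testis and no germ cells;
- ``germ_cell_only``: germ cells but no whole testis (a stage sub-label
  records exclusive-stage vs multi-stage identification);
- ``mixed_other``: any remaining combination, so the partition is total.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

CATEGORIES = (
    "testis_only",
    "germ_cell_only",
    "sertoli_only",
    "epididymis_only",
    "testis_and_epididymis",
    "mixed_other",
)

_ROLE_KINDS = {"testis", "germ_cell", "sertoli", "epididymis"}


class ClassifyError(ValueError):
    pass


def _parse_role(role: str) -> tuple[str, str]:
    kind, _, sub = role.partition(":")
    if kind not in _ROLE_KINDS:
        raise ClassifyError(f"unknown dataset role '{role}'")
    return kind, sub


@dataclass
class ClassificationResult:
    """Disjoint category per candidate plus germ-cell stage sub-labels."""

    table: pd.DataFrame  # index gene; columns category, stage_label, datasets

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def genes_in(self, category: str) -> set[str]:
        return set(self.table.index[self.table["category"] == category])


def assign_tissue_categories(
    candidate_sets: dict[str, set[str]],
    dataset_roles: dict[str, str],
) -> ClassificationResult:
    """Classify every candidate by the roles of the datasets it appears in.

    ``candidate_sets`` maps dataset name -> set of candidate genes;
    ``dataset_roles`` maps the same names to role strings. The result is
    invariant to dataset ordering, and a dataset in which a gene is not a
    candidate never affects that gene's category.
    """
    undeclared = set(candidate_sets) - set(dataset_roles)
    if undeclared:
        raise ClassifyError(f"datasets without a declared role: {sorted(undeclared)}")
    roles = {name: _parse_role(dataset_roles[name]) for name in candidate_sets}

    all_genes = sorted(set().union(*candidate_sets.values()) if candidate_sets else set())
    rows = []
    for gene in all_genes:
        hits = sorted(name for name, s in candidate_sets.items() if gene in s)
        kinds = {roles[name][0] for name in hits}
        stages = sorted({roles[name][1] for name in hits if roles[name][0] == "germ_cell"})
        testis_side = bool(kinds & {"testis", "germ_cell", "sertoli"})
        has_epi = "epididymis" in kinds

        if has_epi and testis_side:
            category = "testis_and_epididymis"
        elif has_epi:
            category = "epididymis_only"
        elif "testis" in kinds:
            category = "testis_only"
        elif "sertoli" in kinds and "germ_cell" not in kinds:
            category = "sertoli_only"
        elif "germ_cell" in kinds:
            category = "germ_cell_only"
        else:
            category = "mixed_other"

        if stages:
            stage_label = f"{stages[0]}_only" if len(stages) == 1 else "multi_stage"
        else:
            stage_label = ""
        rows.append(
            {
                "gene": gene,
                "category": category,
                "stage_label": stage_label,
                "datasets": ";".join(hits),
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "category", "stage_label", "datasets"])
    return ClassificationResult(table=table.set_index("gene"))


# ---------------------------------------------------------------------- #
# overlap reports (Venn logic)
# ---------------------------------------------------------------------- #

@dataclass
class OverlapReport:
    """Pairwise overlaps and the full membership-region decomposition."""

    pairwise: pd.DataFrame  # set_a, set_b, n_shared, n_unique_a, n_unique_b, ...
    regions: pd.DataFrame  # one row per non-empty membership pattern


def set_comparisons(named_sets: dict[str, set[str]]) -> OverlapReport:
    """Exact intersections/differences between named candidate gene lists."""
    names = list(named_sets)
    pair_rows = []
    for a, b in combinations(names, 2):
        sa, sb = named_sets[a], named_sets[b]
        shared = sa & sb
        pair_rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_shared": len(shared),
                "n_unique_a": len(sa - sb),
                "n_unique_b": len(sb - sa),
                "shared": ";".join(sorted(shared)),
                "unique_a": ";".join(sorted(sa - sb)),
                "unique_b": ";".join(sorted(sb - sa)),
            }
        )
    universe = set().union(*named_sets.values()) if named_sets else set()
    region_members: dict[tuple[str, ...], list[str]] = {}
    for gene in sorted(universe):
        pattern = tuple(n for n in names if gene in named_sets[n])
        region_members.setdefault(pattern, []).append(gene)
    region_rows = [
        {
            "member_of": ";".join(pattern),
            "n_genes": len(genes),
            "genes": ";".join(genes),
        }
        for pattern, genes in sorted(region_members.items())
    ]
    return OverlapReport(
        pairwise=pd.DataFrame(
            pair_rows,
            columns=[
                "set_a", "set_b", "n_shared", "n_unique_a", "n_unique_b",
                "shared", "unique_a", "unique_b",
            ],
        ),
        regions=pd.DataFrame(region_rows, columns=["member_of", "n_genes", "genes"]),
    )


def combine_lists(named_sets: dict[str, set[str]], names: list[str]) -> set[str]:
    """Union of several per-dataset candidate lists (a "combined" list)."""
    out: set[str] = set()
    for n in names:
        out |= named_sets[n]
    return out
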