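"""Lineage classification of retrocopy-overlapped genes from ortholog presence.

Consumes a binary gene x species presence/absence matrix whose species are
labelled focal / fish / tetrapod.  A gene is lineage-specific when no
ortholog exists in any non-focal species, and tetrapod-lost when an
ortholog exists in at least one fish species (an all-fish-required mode is
available) but in no tetrapod.  The two classes are disjoint by
construction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exprstats import kruskal_wallis

GROUPS = ("focal", "fish", "tetrapod")


def read_presence_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a presence TSV with a '#group' header line labelling each species."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#group"):
        raise ValueError(f"{path}: expected a '#group' header line")
    group_labels = first.split("\t")[1:]
    df = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    if len(group_labels) != df.shape[1]:
        raise ValueError(f"{path}: group header does not match species columns")
    groups = dict(zip(df.columns, group_labels))
    _validate(df, groups)
    return df.astype(bool), groups


def _validate(matrix: pd.DataFrame, groups: Mapping[str, str]) -> None:
    bad = {s: g for s, g in groups.items() if g not in GROUPS}
    if bad:
        raise ValueError(f"unknown species group labels: {bad}")
    focal = [s for s, g in groups.items() if g == "focal"]
    if len(focal) != 1:
        raise ValueError(f"need exactly one focal species, got {focal}")
    if len(matrix) and not matrix[focal[0]].astype(bool).all():
        missing = matrix.index[~matrix[focal[0]].astype(bool)].tolist()[:5]
        raise ValueError(f"focal species absent for genes {missing}")


def classify_lineage_specific(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> set[str]:
    """Genes with no ortholog in any non-focal species."""
    _validate(matrix, groups)
    if matrix.empty:
        return set()
    non_focal = [s for s, g in groups.items() if g != "focal"]
    return set(matrix.index[~matrix[non_focal].any(axis=1)])


def classify_tetrapod_lost(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    require_all_fish: bool = False,
) -> set[str]:
    """Genes with fish orthologs but none in any tetrapod."""
    _validate(matrix, groups)
    if matrix.empty:
        return set()
    fish = [s for s, g in groups.items() if g == "fish"]
    tetrapods = [s for s, g in groups.items() if g == "tetrapod"]
    in_fish = matrix[fish].all(axis=1) if require_all_fish else matrix[fish].any(axis=1)
    in_tetrapod = matrix[tetrapods].any(axis=1)
    return set(matrix.index[in_fish & ~in_tetrapod])


def compare_gene_sets(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    properties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean/median of each numeric property per set plus a rank-test p-value.

    Both frames carry one row per gene with shared numeric columns (exon
    counts, expression measures, dS, omega, ...).  Group differences are
    assessed with the Kruskal-Wallis test (equivalent to a two-sided
    rank-sum test for two groups).
    """
    if len(set_b) == 0 or len(set_a) == 0:
        raise ValueError("empty comparison set")
    props = list(properties) if properties is not None else [
        c for c in set_a.columns if c in set_b.columns
        and pd.api.types.is_numeric_dtype(set_a[c])
    ]
    rows = []
    for prop in props:
        a = set_a[prop].dropna().to_numpy(dtype=float)
        b = set_b[prop].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            h, p = float("nan"), float("nan")
        else:
            h, p = kruskal_wallis(a, b)
        rows.append(
            {
                "property": prop,
                "mean_a": a.mean() if len(a) else float("nan"),
                "median_a": float(pd.Series(a).median()) if len(a) else float("nan"),
                "mean_b": b.mean() if len(b) else float("nan"),
                "median_b": float(pd.Series(b).median()) if len(b) else float("nan"),
                "H": h,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
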