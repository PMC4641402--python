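"""Expression quantification bookkeeping and expression-linked statistics.

Works on fragment-count or FPKM tables (retrocopy x tissue).  FPKM is
fragments per kilobase of transcript per million mapped fragments; a
retrocopy is called expressed in a tissue when FPKM exceeds a threshold
(default 0), and its expression frequency is the number of such tissues.
Downstream summaries bin retrocopies by dS (a proxy for copy age) and test
group differences with tie-corrected Kruskal-Wallis and 2x2 Pearson
chi-square statistics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def compute_fpkm(
    counts: pd.DataFrame,
    transcript_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library_size/1e6)) per cell."""
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing transcript lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every tissue")
    denom = np.outer(lengths / 1e3, libs / 1e6)
    return counts / denom


def expression_calls(fpkm: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Per-retrocopy expression profile table.

    Columns: one boolean ``expressed_<tissue>`` per tissue,
    ``expression_frequency`` (tissues with FPKM > threshold), ``expressed``
    (frequency > 0), and ``mean_log_fpkm`` = mean log10(FPKM + 1) across
    tissues.
    """
    expressed = fpkm > threshold
    out = expressed.add_prefix("expressed_")
    out["expression_frequency"] = expressed.sum(axis=1)
    out["expressed"] = out["expression_frequency"] > 0
    out["mean_log_fpkm"] = np.log10(fpkm + 1.0).mean(axis=1)
    return out


def bin_by_ds(
    records: pd.DataFrame,
    bin_width: float = 0.2,
    young_cutoff: float = 0.6,
) -> tuple[pd.DataFrame, float]:
    """Per-dS-bin functionality percentages, plus the fraction of young copies.

    ``records`` needs columns dS, intact, significant_purifying,
    gene_overlapped, expressed, mean_log_fpkm, expression_frequency.  Rows
    with undefined dS are excluded (reported via the returned frame's attrs)
    and bins are half-open [k*w, (k+1)*w).
    """
    defined = records[np.isfinite(records["dS"])].copy()
    n_undefined = len(records) - len(defined)
    if defined.empty:
        empty = pd.DataFrame(
            columns=[
                "ds_lo", "ds_hi", "n_retrocopies", "pct_intact",
                "pct_significant_purifying", "pct_gene_overlapped",
                "pct_expressed", "mean_log_fpkm", "mean_expression_frequency",
            ]
        )
        empty.attrs["n_undefined_ds"] = n_undefined
        return empty, float("nan")
    idx = np.floor(defined["dS"] / bin_width).astype(int)
    rows = []
    for k in sorted(idx.unique()):
        sub = defined[idx == k]
        rows.append(
            {
                "ds_lo": k * bin_width,
                "ds_hi": (k + 1) * bin_width,
                "n_retrocopies": len(sub),
                "pct_intact": 100.0 * sub["intact"].mean(),
                "pct_significant_purifying": 100.0 * sub["significant_purifying"].mean(),
                "pct_gene_overlapped": 100.0 * sub["gene_overlapped"].mean(),
                "pct_expressed": 100.0 * sub["expressed"].mean(),
                "mean_log_fpkm": sub["mean_log_fpkm"].mean(),
                "mean_expression_frequency": sub["expression_frequency"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_undefined_ds"] = n_undefined
    frac_young = float((defined["dS"] < young_cutoff).mean())
    return out, frac_young


def kruskal_wallis(
    *groups: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis test with tie correction.

    ``asymptotic`` (default) refers H to chi-square with k-1 df, matching
    R's kruskal.test.  ``exact`` enumerates every assignment of the pooled
    values to the group sizes and reports P(H >= observed); only feasible
    for small samples.  Fully tied data (H undefined, no evidence of
    difference) returns (0, 1).
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(cleaned) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p_asym = stats.kruskal(*cleaned)
    if method == "asymptotic":
        return float(h), float(p_asym)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    return float(h), _exact_kw_pvalue(cleaned, float(h))


def _exact_kw_pvalue(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p-value for the Kruskal-Wallis H statistic."""
    from itertools import combinations

    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    tie_term = _tie_correction(pooled)

    def h_of(rank_groups: list[np.ndarray]) -> float:
        h = 12.0 / (n * (n + 1)) * sum(
            r.sum() ** 2 / len(r) for r in rank_groups
        ) - 3 * (n + 1)
        return h / tie_term if tie_term > 0 else 0.0

    hits = total = 0
    all_idx = frozenset(range(n))

    def recurse(remaining: frozenset, k: int, acc: list[np.ndarray]) -> None:
        nonlocal hits, total
        if k == len(sizes) - 1:
            acc.append(ranks[sorted(remaining)])
            total += 1
            if h_of(acc) >= h_obs - 1e-12:
                hits += 1
            acc.pop()
            return
        for combo in combinations(sorted(remaining), sizes[k]):
            acc.append(ranks[list(combo)])
            recurse(remaining - set(combo), k + 1, acc)
            acc.pop()

    recurse(all_idx, 0, [])
    return hits / total


def _tie_correction(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    n = len(pooled)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def chisq_association(
    flag_a: Sequence[bool],
    flag_b: Sequence[bool],
    correction: bool = False,
) -> tuple[float, float]:
    """2x2 Pearson chi-square (1 df) between two boolean indicators.

    No continuity correction by default.  A degenerate table (an all-true or
    all-false margin) carries no association evidence and returns (0, 1).
    """
    a = np.asarray(flag_a, dtype=bool)
    b = np.asarray(flag_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("indicator vectors must be the same length")
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def tissue_bias_tables(
    profiles: pd.DataFrame,
    fpkm: pd.DataFrame,
    ds: pd.Series,
    omega: pd.Series,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-tissue expressed and uniquely-expressed counts with dS/omega means.

    A copy counts as uniquely expressed in a tissue when that is the only
    tissue where its FPKM exceeds the threshold.
    """
    expressed = fpkm > threshold
    freq = expressed.sum(axis=1)
    rows = []
    for tissue in fpkm.columns:
        in_tissue = expressed[tissue]
        unique = in_tissue & (freq == 1)
        rows.append(
            {
                "tissue": tissue,
                "n_expressed": int(in_tissue.sum()),
                "n_uniquely_expressed": int(unique.sum()),
                "mean_dS_expressed": float(ds[in_tissue].mean()) if in_tissue.any() else np.nan,
                "mean_omega_expressed": float(omega[in_tissue].mean()) if in_tissue.any() else np.nan,
                "mean_dS_unique": float(ds[unique].mean()) if unique.any() else np.nan,
                "mean_omega_unique": float(omega[unique].mean()) if unique.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def expression_frequency_table(
    profiles: pd.DataFrame,
    fpkm: pd.DataFrame,
    ds: pd.Series,
    omega: pd.Series,
) -> pd.DataFrame:
    """Summary by expression frequency: n, mean/median log10(FPKM+1)
    (per retrocopy per tissue), mean/median dS and dN/dS."""
    logf = np.log10(fpkm + 1.0)
    rows = []
    for freq in sorted(profiles["expression_frequency"].unique()):
        sel = profiles["expression_frequency"] == freq
        vals = logf.loc[sel].to_numpy().ravel()
        rows.append(
            {
                "expression_frequency": int(freq),
                "n": int(sel.sum()),
                "mean_log_fpkm": float(vals.mean()) if vals.size else np.nan,
                "median_log_fpkm": float(np.median(vals)) if vals.size else np.nan,
                "mean_dS": float(ds[sel].mean()),
                "median_dS": float(ds[sel].median()),
                "mean_dN_dS": float(omega[sel].mean()),
                "median_dN_dS": float(omega[sel].median()),
            }
        )
    return pd.DataFrame(rows)
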