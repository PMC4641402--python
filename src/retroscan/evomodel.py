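"""Codon-level evolutionary statistics for parent-retrocopy pairs.

For each pair this module provides: intact-ORF calling (no frameshifts, no
premature stop codons), Nei-Gojobori (1986) style counting estimates of dN
and dS with Jukes-Cantor correction, a pairwise codon-model likelihood-ratio
test of the null hypothesis omega = omega0 (default 0.5, the neutrality
reference used for retrocopy functionality calls), and Benjamini-Hochberg
FDR correction across pairs.

The LRT uses a GY94-style model with equal codon frequencies and fixed
kappa, maximising over branch length t with omega fixed (null) or over
(t, omega) jointly (alternative); the statistic 2*(lnL_alt - lnL_null) is
referred to chi-square with one degree of freedom.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._codon import (
    CODON_INDEX,
    N_SENSE,
    STOP_CODONS,
    ng86_difference_counts,
    ng86_site_counts,
    transition_matrix,
)

MIN_CODON_COLUMNS = 10


class InsufficientDataError(ValueError):
    """Too few retained codon columns for estimation."""


@dataclasses.dataclass
class CodonAlignment:
    """Gap-free, stop-free codon columns of a parent-retrocopy alignment."""

    pairs: list[tuple[str, str]]
    excluded_columns: int = 0

    def __post_init__(self) -> None:
        for p, r in self.pairs:
            if p not in CODON_INDEX or r not in CODON_INDEX:
                raise ValueError(f"invalid retained codon column ({p}, {r})")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclasses.dataclass
class EvoStats:
    retro_id: str
    parent_id: str
    dN: float
    dS: float
    omega: float
    S_sites: float
    N_sites: float
    ds_defined: bool
    dn_defined: bool
    omega_defined: bool
    lnL_null: float = math.nan
    lnL_alt: float = math.nan
    lrt_stat: float = math.nan
    p_lrt: float = math.nan
    q_fdr: float = math.nan
    intact: bool = False
    n_frameshifts: int = 0
    n_premature_stops: int = 0
    significant_purifying: bool = False


# ---------------------------------------------------------------------------
# intact-ORF calling and codon alignment construction


def check_intact_orf(alignment) -> tuple[bool, int, int]:
    """Call ORF intactness from a protein-genome alignment.

    A retrocopy is intact when the realignment to its parent shows zero
    frameshift events and zero in-frame stop codons before the parent's
    terminal codon position.
    """
    n_fs = len(alignment.frameshift_events)
    n_stops = 0
    pairs = alignment.codon_pairs
    for parent_codon, retro_codon, kind in pairs:
        if kind == "match" and retro_codon is not None and retro_codon.upper() in STOP_CODONS:
            n_stops += 1
    return (n_fs == 0 and n_stops == 0), n_fs, n_stops


def build_codon_alignment(pair) -> CodonAlignment:
    """Extract retained codon columns from a parent-retrocopy pair.

    Columns containing gaps, frameshifted triplets, or stop codons on either
    side are excluded and counted; only clean sense-codon columns feed the
    dN/dS machinery.
    """
    kept: list[tuple[str, str]] = []
    excluded = 0
    for parent_codon, retro_codon, kind in pair.alignment.codon_pairs:
        if (
            kind != "match"
            or parent_codon is None
            or retro_codon is None
            or parent_codon.upper() not in CODON_INDEX
            or retro_codon.upper() not in CODON_INDEX
        ):
            excluded += 1
            continue
        kept.append((parent_codon.upper(), retro_codon.upper()))
    return CodonAlignment(kept, excluded)


# ---------------------------------------------------------------------------
# NG86 counting estimator


def _jukes_cantor(p: float) -> float:
    """d = -3/4 ln(1 - 4p/3); returns nan at or beyond saturation."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_dnds(aln: CodonAlignment) -> dict:
    """NG86-style dN, dS and omega for a codon alignment.

    Per-codon synonymous site fractions come from single-base mutation
    enumeration under the standard code; multi-base codon differences are
    averaged over minimal mutational pathways; proportions are corrected by
    the Jukes-Cantor transform.  dS (resp. dN) is flagged undefined when the
    corresponding proportion reaches saturation (p >= 3/4), and omega when
    either d is undefined or dS = 0.
    """
    if len(aln) < MIN_CODON_COLUMNS:
        raise InsufficientDataError(
            f"need >= {MIN_CODON_COLUMNS} retained codon columns, got {len(aln)}"
        )
    syn_sites = ng86_site_counts()
    diff = ng86_difference_counts()
    S = N = Sd = Nd = 0.0
    for parent_codon, retro_codon in aln.pairs:
        i = CODON_INDEX[parent_codon]
        j = CODON_INDEX[retro_codon]
        s_i = (syn_sites[i] + syn_sites[j]) / 2.0
        S += s_i
        N += 3.0 - s_i
        if i != j:
            Sd += diff[i, j, 0]
            Nd += diff[i, j, 1]
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    ds_defined = not math.isnan(dS)
    dn_defined = not math.isnan(dN)
    omega_defined = ds_defined and dn_defined and dS > 0
    omega = dN / dS if omega_defined else math.nan
    return {
        "dN": dN,
        "dS": dS,
        "omega": omega,
        "S_sites": S,
        "N_sites": N,
        "ds_defined": ds_defined,
        "dn_defined": dn_defined,
        "omega_defined": omega_defined,
    }


# ---------------------------------------------------------------------------
# fixed-omega likelihood-ratio test


def _pair_count_arrays(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts: dict[tuple[int, int], int] = {}
    for p, r in aln.pairs:
        key = (CODON_INDEX[p], CODON_INDEX[r])
        counts[key] = counts.get(key, 0) + 1
    keys = sorted(counts)
    ii = np.array([k[0] for k in keys], dtype=int)
    jj = np.array([k[1] for k in keys], dtype=int)
    nn = np.array([counts[k] for k in keys], dtype=float)
    return ii, jj, nn


def _loglik(ii, jj, nn, t: float, kappa: float, omega: float) -> float:
    p = transition_matrix(t, kappa=kappa, omega=omega)
    probs = p[ii, jj] / N_SENSE
    return float(np.sum(nn * np.log(np.maximum(probs, 1e-300))))


_T_BOUNDS = (1e-9, 40.0)
_OMEGA_BOUNDS = (1e-4, 30.0)


def _profile_t(ii, jj, nn, kappa: float, omega: float) -> tuple[float, float]:
    res = minimize_scalar(
        lambda logt: -_loglik(ii, jj, nn, math.exp(logt), kappa, omega),
        bounds=(math.log(_T_BOUNDS[0]), math.log(_T_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return math.exp(res.x), -res.fun


def lrt_fixed_omega(
    aln: CodonAlignment,
    omega0: float = 0.5,
    kappa: float = 2.0,
) -> dict:
    """Pairwise codon-model LRT of H0: omega = omega0 vs free omega.

    Returns lnL_null, lnL_alt, lrt_stat (clipped at zero) and the chi-square
    (1 df) p-value; non-convergence is flagged rather than raised.
    """
    if len(aln) < MIN_CODON_COLUMNS:
        raise InsufficientDataError(
            f"need >= {MIN_CODON_COLUMNS} retained codon columns, got {len(aln)}"
        )
    ii, jj, nn = _pair_count_arrays(aln)
    converged = True
    try:
        t_null, lnL_null = _profile_t(ii, jj, nn, kappa, omega0)

        def neg_profile(logw: float) -> float:
            return -_profile_t(ii, jj, nn, kappa, math.exp(logw))[1]

        res_w = minimize_scalar(
            neg_profile,
            bounds=(math.log(_OMEGA_BOUNDS[0]), math.log(_OMEGA_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        omega_hat = math.exp(res_w.x)
        t_alt, lnL_alt = _profile_t(ii, jj, nn, kappa, omega_hat)
        # the null is nested in the alternative, so lnL_alt can never be
        # genuinely below lnL_null; enforce against optimiser tolerance
        if lnL_alt < lnL_null:
            lnL_alt, t_alt, omega_hat = lnL_null, t_null, omega0
    except (ValueError, FloatingPointError):
        converged = False
        lnL_null = lnL_alt = math.nan
        t_null = t_alt = omega_hat = math.nan
    lrt_stat = max(0.0, 2.0 * (lnL_alt - lnL_null)) if converged else math.nan
    p = float(chi2.sf(lrt_stat, df=1)) if converged else math.nan
    return {
        "lnL_null": lnL_null,
        "lnL_alt": lnL_alt,
        "lrt_stat": lrt_stat,
        "p": p,
        "t_null": t_null,
        "t_alt": t_alt,
        "omega_mle": omega_hat,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# multiple testing and functionality calls


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    mask = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def call_significant_purifying(
    records: Iterable[EvoStats],
    omega_threshold: float = 0.5,
    q_threshold: float = 0.05,
) -> list[bool]:
    """Flag pairs under significant purifying selection.

    A pair is flagged when the FDR-adjusted LRT q-value is below q_threshold
    AND the point estimate of omega is below omega_threshold (the LRT alone
    is two-sided; the point-estimate condition makes the call one-sided).
    """
    flags = []
    for rec in records:
        flag = (
            not math.isnan(rec.q_fdr)
            and rec.q_fdr < q_threshold
            and rec.omega_defined
            and rec.omega < omega_threshold
        )
        rec.significant_purifying = flag
        flags.append(flag)
    return flags


def stats_table(records: Iterable[EvoStats]) -> pd.DataFrame:
    """Per-pair stats table (retro_id, parent_id, dN, dS, dN/dS, p, q, intact)."""
    rows = []
    for r in records:
        rows.append(
            {
                "retro_id": r.retro_id,
                "parent_id": r.parent_id,
                "dN": r.dN,
                "dS": r.dS,
                "dN_dS": r.omega,
                "p_lrt": r.p_lrt,
                "q_fdr": r.q_fdr,
                "intact": r.intact,
                "n_frameshifts": r.n_frameshifts,
                "n_premature_stops": r.n_premature_stops,
                "significant_purifying": r.significant_purifying,
            }
        )
    return pd.DataFrame(rows)
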