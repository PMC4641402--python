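"""Codon-level machinery shared by the simulator and the evolutionary statistics.

Implements a Goldman–Yang-style codon substitution model restricted to the 61
sense codons of the standard genetic code, with equal codon frequencies.  The
rate matrix for transition/transversion ratio kappa and nonsynonymous rate
multiplier omega is

    q_ij = 0                      if codons i, j differ at > 1 position
    q_ij = kappa^is_transition * omega^is_nonsynonymous   otherwise

scaled so that the expected number of substitutions per codon site per unit
branch length equals one.  With equal frequencies Q is symmetric, so
transition matrices P(t) = exp(Qt) come from a cached eigendecomposition.

Also provides Nei–Gojobori (1986) style synonymous/nonsynonymous site counts
per codon (mutations to stop codons excluded from the per-position fraction)
and pathway-averaged difference counts per codon pair (pathways through stop
codons excluded; if every pathway is blocked, all pathways are used with
steps to/from stops counted as nonsynonymous).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
    if c not in STOP_CODONS
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """Translate one codon; '*' for stops, 'X' for anything ambiguous."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table.get(codon, "X")


def translate(seq: str) -> str:
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def codons_of(seq: str) -> list[str]:
    return [seq[i : i + 3].upper() for i in range(0, len(seq) - len(seq) % 3, 3)]


# ---------------------------------------------------------------------------
# GY94 rate matrix and transition probabilities


def _unscaled_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    q = np.zeros((N_SENSE, N_SENSE))
    for i, ci in enumerate(SENSE_CODONS):
        for j in range(i + 1, N_SENSE):
            cj = SENSE_CODONS[j]
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = kappa if is_transition(ci[k], cj[k]) else 1.0
            if AA_OF_CODON[ci] != AA_OF_CODON[cj]:
                rate *= omega
            q[i, j] = q[j, i] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@lru_cache(maxsize=512)
def _eig(kappa: float, omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the scaled (mean rate 1) symmetric rate matrix."""
    q = _unscaled_rate_matrix(kappa, omega)
    mean_rate = -np.mean(np.diag(q))  # equal codon frequencies
    q /= mean_rate
    w, v = np.linalg.eigh(q)
    return w, v


def transition_matrix(t: float, kappa: float = 2.0, omega: float = 1.0) -> np.ndarray:
    """P(t) = exp(Qt) over the 61 sense codons; rows sum to one."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    w, v = _eig(float(kappa), float(omega))
    p = (v * np.exp(w * t)) @ v.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def expected_ds_dn(t: float, kappa: float = 2.0, omega: float = 1.0) -> tuple[float, float]:
    """Expected synonymous / nonsynonymous substitutions per codon at branch length t.

    Uses the scaled rate matrix: flux through synonymous vs nonsynonymous
    single-step changes, per unit time, times t.
    """
    q = _unscaled_rate_matrix(kappa, omega)
    q /= -np.mean(np.diag(q))
    syn = nonsyn = 0.0
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j or q[i, j] == 0:
                continue
            if AA_OF_CODON[ci] == AA_OF_CODON[cj]:
                syn += q[i, j] / N_SENSE
            else:
                nonsyn += q[i, j] / N_SENSE
    return syn * t, nonsyn * t


# ---------------------------------------------------------------------------
# NG86 site and difference counting


@lru_cache(maxsize=1)
def ng86_site_counts() -> np.ndarray:
    """Per-codon synonymous site count (array over SENSE_CODONS index).

    Each position contributes the fraction of its non-stop single-base
    changes that are synonymous; nonsynonymous sites are 3 minus this.
    """
    syn = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        total = 0.0
        for pos in range(3):
            syn_changes = 0
            valid = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                valid += 1
                if AA_OF_CODON[alt] == AA_OF_CODON[codon]:
                    syn_changes += 1
            if valid:
                total += syn_changes / valid
        syn[i] = total
    return syn


def _pathway_steps(ci: str, cj: str, order: tuple[int, ...]) -> tuple[float, float, bool]:
    """(syn_steps, nonsyn_steps, passes_through_stop) along one mutational order."""
    syn = nonsyn = 0.0
    through_stop = False
    cur = ci
    for pos in order:
        nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
        aa_cur = "*" if cur in STOP_CODONS else AA_OF_CODON[cur]
        aa_nxt = "*" if nxt in STOP_CODONS else AA_OF_CODON[nxt]
        if nxt in STOP_CODONS or cur in STOP_CODONS:
            through_stop = True
        if aa_cur == aa_nxt and aa_cur != "*":
            syn += 1
        else:
            nonsyn += 1
        cur = nxt
    return syn, nonsyn, through_stop


@lru_cache(maxsize=1)
def ng86_difference_counts() -> np.ndarray:
    """(61, 61, 2) array of pathway-averaged (syn, nonsyn) difference counts."""
    out = np.zeros((N_SENSE, N_SENSE, 2))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = tuple(k for k in range(3) if ci[k] != cj[k])
            paths = [
                _pathway_steps(ci, cj, order)
                for order in itertools.permutations(diff)
            ]
            clean = [(s, n) for s, n, blocked in paths if not blocked]
            if not clean:
                clean = [(s, n) for s, n, _ in paths]
            syn = sum(s for s, _ in clean) / len(clean)
            nonsyn = sum(n for _, n in clean) / len(clean)
            out[i, j, 0] = syn
            out[i, j, 1] = nonsyn
    return out


def random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, N_SENSE, size=n)
    return [SENSE_CODONS[i] for i in idx]


def evolve_codons(
    codons: list[str],
    t: float,
    omega: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
) -> list[str]:
    """Sample descendant codons site-independently under P(t)."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    if t == 0:
        return list(codons)
    p = transition_matrix(t, kappa=kappa, omega=omega)
    cum = np.cumsum(p, axis=1)
    out = []
    u = rng.random(len(codons))
    for k, codon in enumerate(codons):
        i = CODON_INDEX[codon]
        j = int(np.searchsorted(cum[i], u[k], side="right"))
        out.append(SENSE_CODONS[min(j, N_SENSE - 1)])
    return out
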