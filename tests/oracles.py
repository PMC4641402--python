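"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (plain loops,
exhaustive enumeration, no reuse of package internals) so it can stand as
an independent check of the implementation.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

BASES = "TCAG"

# standard genetic code, written out independently of the package
_CODON_TABLE = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(BASES, BASES, BASES)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AAS[_i]

SENSE = [c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"]


def aa(codon: str) -> str:
    return _CODON_TABLE[codon]


def syn_sites_of_codon(codon: str) -> float:
    """Synonymous site count: per position, the synonymous fraction of
    non-stop single-base changes."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if aa(alt) == "*":
                continue
            valid += 1
            if aa(alt) == aa(codon):
                syn += 1
        if valid:
            total += syn / valid
    return total


def pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) substitution counts over minimal mutational
    pathways between two codons, skipping pathways through stop codons
    (falling back to all pathways when every one is blocked)."""
    positions = [k for k in range(3) if c1[k] != c2[k]]
    results, blocked_results = [], []
    for order in itertools.permutations(positions):
        cur, syn, nonsyn, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if aa(nxt) == "*" or aa(cur) == "*":
                blocked = True
            if aa(nxt) == aa(cur) and aa(cur) != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked_results if blocked else results).append((syn, nonsyn))
    use = results or blocked_results
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def ng86_pair(codon_pairs: list[tuple[str, str]]):
    """Brute-force NG86 dN/dS over a codon alignment."""
    S = N = Sd = Nd = 0.0
    for a, b in codon_pairs:
        s = (syn_sites_of_codon(a) + syn_sites_of_codon(b)) / 2
        S += s
        N += 3 - s
        if a != b:
            ds_, dn_ = pathway_diffs(a, b)
            Sd += ds_
            Nd += dn_
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pN), jc(pS), S, N, Sd, Nd


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric table, by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def kruskal_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H, computed from scratch."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    rank_list = [0.0] * n
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            rank_list[k] = avg
        i = j
    sums = [0.0] * len(groups)
    counts = [0] * len(groups)
    for (val, gi), r in zip(pooled, rank_list):
        sums[gi] += r
        counts[gi] += 1
    h = 12.0 / (n * (n + 1)) * sum(
        s * s / c for s, c in zip(sums, counts)
    ) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t ** 3 - t
        i = j
    correction = 1 - ties / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def brute_force_overlap_calls(retro_loci, genes):
    """Quadratic scan replicating the overlap classification contract."""
    out = {}
    for retro_id, iv in retro_loci:
        hit_ids, exon_hit = [], False
        for g in genes:
            gi = g.interval
            if gi.scaffold == iv.scaffold and gi.start < iv.end and iv.start < gi.end:
                hit_ids.append(g.gene_id)
                for ex in g.exons:
                    if ex.start < iv.end and iv.start < ex.end:
                        exon_hit = True
        if not hit_ids:
            cls = "none"
        elif exon_hit:
            cls = "exon_overlapped"
        else:
            cls = "non_exon_overlapped"
        out[retro_id] = (sorted(hit_ids), cls)
    return out


def protein_genome_align_score(
    peptide: str,
    region: str,
    blosum,
    aa_index,
    fs_pen: float,
    intron_open: float,
    min_intron: int,
    residue_gap: float,
) -> float:
    """Exhaustive memoized recursion for the local protein-genome alignment
    score (small instances only)."""

    def aa_of(j):  # amino acid of triplet ending at j
        codon = region[j - 3 : j].upper()
        return _CODON_TABLE.get(codon)

    @lru_cache(maxsize=None)
    def best_ending(i: int, j: int) -> float:
        """Best score of an alignment consuming exactly i residues and
        ending at region offset j (may be a fresh local start)."""
        cands = [0.0] if i == 0 else [-math.inf]
        if i > 0:
            pa = peptide[i - 1]
            for step, has_codon, _ in ((3, True, 0), (1, False, 0), (2, False, 0),
                                       (4, True, 0), (5, True, 0)):
                if j - step < 0:
                    continue
                sc = best_ending(i - 1, j - step)
                if has_codon:
                    a = aa_of(j)
                    if a is None:
                        continue
                    sc += blosum[aa_index[pa], aa_index.get(a, aa_index["X"])]
                if step != 3:
                    sc -= fs_pen
                cands.append(sc)
            cands.append(best_ending(i - 1, j) - residue_gap)
        for j2 in range(0, j - min_intron + 1):
            cands.append(best_ending(i, j2) - intron_open) if i > 0 else None
        return max(0.0, max(cands))

    best = 0.0
    for i in range(len(peptide) + 1):
        for j in range(len(region) + 1):
            best = max(best, best_ending(i, j))
    return best
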