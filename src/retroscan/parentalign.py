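"""Parent assignment and frameshift/intron-aware protein-to-genome realignment.

Each surviving candidate locus is assigned a parent peptide by scoring its
translation against every peptide (a best hit to a single-exon protein marks
the locus as a DNA-based duplication of an intronless gene and discards it).
The locus is then expanded by 10 kb on each flank and realigned to the
parent with a dynamic program whose states cover codon match/mismatch
(3 nt), frameshift advances of 1/2/4/5 nt, residue deletion, and
length-independent genomic gaps >= ``min_intron_len`` that are recorded as
inferred introns.  Final exclusion rules: alignments of <= 50 residues,
identity <= 70 %, or any inferred intron are dropped; accepted pairs must
additionally show the parent's introns demonstrably absent (parent has >= 2
introns and the alignment spans >= 2 of their positions), and pairs sharing
a parent peptide are removed so the result is one-to-one.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats import GenomicInterval
from .hitsearch import CandidateLocus
from ._codon import translate

NEG = -1e30


@dataclasses.dataclass
class AlignParams:
    frameshift_penalty: float = 15.0
    intron_open: float = 20.0
    min_intron_len: int = 30
    residue_gap: float = 10.0
    matrix: str = "BLOSUM62"
    score_floor: float = 25.0


@dataclasses.dataclass
class ParentInfo:
    """What the aligner needs to know about one candidate parent peptide."""

    peptide_id: str
    peptide: str
    cds: str  # spliced coding sequence, no terminal stop codon
    exon_count: int
    intron_cds_offsets: tuple[float, ...] = ()  # nt offsets of introns within the CDS

    @property
    def intron_residue_positions(self) -> tuple[float, ...]:
        return tuple(off / 3.0 for off in self.intron_cds_offsets)


@dataclasses.dataclass
class ProteinGenomeAlignment:
    parent_id: str
    locus: GenomicInterval
    aligned_length_aa: int
    percent_identity: float
    frameshift_events: list[tuple[int, int]]  # (genomic position, phase shift)
    inferred_introns: list[GenomicInterval]
    codon_pairs: list[tuple[str | None, str | None, str]]
    score: float
    query_start: int  # 0-based residue range of the parent covered
    query_end: int


@dataclasses.dataclass
class ParentDecision:
    locus: CandidateLocus
    parent_id: str | None
    reason: str  # ok | dna_duplication | no_parent
    score: float
    tied_ids: tuple[str, ...] = ()


@dataclasses.dataclass
class ParentRetroPair:
    retro_id: str
    parent_id: str
    alignment: ProteinGenomeAlignment
    parent_exon_count: int
    spanned_parent_introns: int


# ---------------------------------------------------------------------------
# parent ranking


def _locus_translation(locus: CandidateLocus, genome: dict[str, str]) -> str:
    """Concatenated in-frame translations of the member hits, in query order."""
    pieces = []
    seq = genome[locus.interval.scaffold]
    for hit in sorted(locus.member_hits, key=lambda h: (h.query_start, h.interval.start)):
        sub = seq[hit.interval.start : hit.interval.end].upper()
        if hit.interval.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        sub = sub[: len(sub) - len(sub) % 3]
        pieces.append(translate(sub))
    return "".join(pieces)


def _protein_aligner(matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def rank_parent_candidates(
    locus: CandidateLocus,
    parents: dict[str, ParentInfo],
    genome: dict[str, str],
    params: AlignParams | None = None,
) -> ParentDecision:
    """Pick the parent peptide for a candidate locus.

    All peptides (including single-exon proteins) are scored by local protein
    alignment of the locus translation.  If the single best-scoring peptide
    is single-exon, the locus is a putative DNA-based duplication of an
    intronless gene and is discarded; otherwise the best multi-exon peptide
    becomes the parent.  Ties break to the lexicographically smaller id and
    are recorded on the decision.
    """
    params = params or AlignParams()
    query = _locus_translation(locus, genome)
    if not query:
        return ParentDecision(locus, None, "no_parent", 0.0)
    aligner = _protein_aligner(params.matrix)
    scores = {}
    for pid, info in parents.items():
        try:
            scores[pid] = float(aligner.score(info.peptide, query))
        except ValueError:  # non-alphabet residue
            scores[pid] = 0.0
    best_score = max(scores.values())
    if best_score < params.score_floor:
        return ParentDecision(locus, None, "no_parent", best_score)
    best_ids = sorted(pid for pid, s in scores.items() if s == best_score)
    multi = [pid for pid in best_ids if parents[pid].exon_count > 1]
    if not multi:
        return ParentDecision(
            locus, None, "dna_duplication", best_score, tuple(best_ids)
        )
    chosen = multi[0]
    tied = tuple(best_ids) if len(best_ids) > 1 else ()
    return ParentDecision(locus, chosen, "ok", best_score, tied)


# ---------------------------------------------------------------------------
# flank expansion


def expand_flanks(
    locus: GenomicInterval, scaffold_length: int, flank: int = 10000
) -> GenomicInterval:
    """Widen a locus by ``flank`` bases each side, clamped to the scaffold."""
    return GenomicInterval(
        locus.scaffold,
        max(0, locus.start - flank),
        min(scaffold_length, locus.end + flank),
        locus.strand,
    )


# ---------------------------------------------------------------------------
# frameshift/intron-aware DP


# DP transitions to cell (i residues, j nucleotides): (nt consumed, has codon,
# phase shift).  4/5 nt steps align the trailing triplet and flag a frameshift.
_STEPS = (
    (3, True, 0),
    (1, False, -2),
    (2, False, -1),
    (4, True, +1),
    (5, True, +2),
)


def _codon_aa_indices(region: str, aa_index: dict[str, int]) -> np.ndarray:
    """Index of the amino acid encoded by the triplet ending at j (or -1)."""
    n = len(region)
    out = np.full(n + 1, -1, dtype=np.int32)
    for j in range(3, n + 1):
        out[j] = aa_index.get(translate(region[j - 3 : j]), aa_index.get("X", -1))
    return out


def align_protein_to_genome(
    peptide: str,
    cds: str,
    region: str,
    params: AlignParams | None = None,
) -> tuple | None:
    """Locally align a parent peptide (with its CDS codons) to a genomic region.

    Returns ``None`` when no alignment reaches the score floor, otherwise a
    region-relative raw alignment: (score, query_start, query_end,
    region_start, region_end, columns, frameshifts, introns) where
    ``columns`` is a list of (parent_codon | None, region_triplet | None,
    kind) and intron/frameshift positions are region offsets.
    """
    params = params or AlignParams()
    if len(region) < 3:
        return None
    region = region.upper()
    m, n = len(peptide), len(region)
    mat = substitution_matrices.load(params.matrix)
    aa_index = {aa: i for i, aa in enumerate(str(mat.alphabet))}
    smat = np.array(mat)
    cod_aa = _codon_aa_indices(region, aa_index)
    valid = cod_aa >= 0

    L = params.min_intron_len
    fs = params.frameshift_penalty
    final = np.zeros((m + 1, n + 1), dtype=np.float64)
    # row 0: zero everywhere (local alignment may start at any coordinate)
    for i in range(1, m + 1):
        prev = final[i - 1].astype(np.float64)
        pi = aa_index.get(peptide[i - 1], aa_index.get("X"))
        cod_score = np.where(valid, smat[pi, np.maximum(cod_aa, 0)], NEG)
        core = np.full(n + 1, NEG)
        for step, has_codon, _shift in _STEPS:
            cand = np.full(n + 1, NEG)
            cand[step:] = prev[:-step]
            if has_codon:
                cand = cand + cod_score
            if step != 3:
                cand = cand - fs
            np.maximum(core, cand, out=core)
        np.maximum(core, prev - params.residue_gap, out=core)
        if n + 1 > L:
            prefix = np.maximum.accumulate(core)
            intron_cand = np.full(n + 1, NEG)
            intron_cand[L:] = prefix[:-L] - params.intron_open
            np.maximum(core, intron_cand, out=core)
        np.maximum(core, 0.0, out=core)
        final[i] = core

    best = float(final.max())
    if best < params.score_floor:
        return None
    i, j = np.unravel_index(int(final.argmax()), final.shape)
    i, j = int(i), int(j)
    end_i, end_j = i, j

    columns: list[tuple[str | None, str | None, str]] = []
    frameshifts: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    tol = 1e-4

    def cod_sc(resi: int, jj: int) -> float:
        if cod_aa[jj] < 0:
            return NEG
        return float(smat[aa_index.get(peptide[resi], aa_index.get("X")), cod_aa[jj]])

    while i > 0:
        v = float(final[i, j])
        if v < tol:
            break  # local-alignment start (Smith-Waterman convention)
        moved = False
        # codon / frameshift / deletion steps from row i-1
        for step, has_codon, shift in _STEPS:
            if j - step < 0:
                continue
            cand = float(final[i - 1, j - step])
            if has_codon:
                cand += cod_sc(i - 1, j)
            if step != 3:
                cand -= fs
            if abs(cand - v) < tol and cand > NEG / 2:
                parent_codon = cds[3 * (i - 1) : 3 * i] if cds else None
                triplet = region[j - 3 : j] if has_codon else None
                kind = "match" if step == 3 else "frameshift"
                columns.append((parent_codon, triplet, kind))
                if step != 3:
                    frameshifts.append((j - step, shift))
                i, j = i - 1, j - step
                moved = True
                break
        if moved:
            continue
        cand = float(final[i - 1, j]) - params.residue_gap
        if abs(cand - v) < tol:
            columns.append((cds[3 * (i - 1) : 3 * i] if cds else None, None, "deletion"))
            i -= 1
            moved = True
            continue
        # intron: same row, origin at least min_intron_len to the left
        if j >= L:
            row = final[i, : j - L + 1]
            origins = np.where(np.abs(row - (v + params.intron_open)) < tol)[0]
            if origins.size:
                j2 = int(origins[-1])
                introns.append((j2, j))
                j = j2
                moved = True
                continue
        if abs(v) < tol:
            break  # local start
        raise AssertionError("traceback failed to find an incoming transition")

    start_i, start_j = i, j
    columns.reverse()
    frameshifts.reverse()
    introns.reverse()
    return (best, start_i, end_i, start_j, end_j, columns, frameshifts, introns)


def realign_locus(
    retro_id: str,
    parent: ParentInfo,
    window: GenomicInterval,
    genome: dict[str, str],
    params: AlignParams | None = None,
) -> ProteinGenomeAlignment | None:
    """Realign a parent to an expanded genomic window, in genome coordinates.

    For minus-strand loci the window is reverse-complemented before the DP
    and all reported coordinates are mapped back to the forward strand.
    """
    params = params or AlignParams()
    seq = genome[window.scaffold][window.start : window.end]
    if window.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    raw = align_protein_to_genome(parent.peptide, parent.cds, seq, params)
    if raw is None:
        return None
    score, qi0, qi1, rj0, rj1, columns, fss, intr = raw

    def to_genome(a: int, b: int) -> tuple[int, int]:
        if window.strand == "+":
            return window.start + a, window.start + b
        return window.end - b, window.end - a

    g0, g1 = to_genome(rj0, rj1)
    locus = GenomicInterval(window.scaffold, g0, g1, window.strand)
    fs_events = []
    for pos, shift in fss:
        gpos = window.start + pos if window.strand == "+" else window.end - pos
        fs_events.append((gpos, shift))
    intron_ivs = []
    for a, b in intr:
        ga, gb = to_genome(a, b)
        intron_ivs.append(GenomicInterval(window.scaffold, ga, gb, window.strand))
    match_cols = [
        (p, r) for p, r, kind in columns if r is not None and p is not None
    ]
    ident = (
        100.0
        * sum(1 for p, r in match_cols if translate(p) == translate(r))
        / len(match_cols)
        if match_cols
        else 0.0
    )
    return ProteinGenomeAlignment(
        parent_id=parent.peptide_id,
        locus=locus,
        aligned_length_aa=qi1 - qi0,
        percent_identity=ident,
        frameshift_events=sorted(fs_events),
        inferred_introns=sorted(intron_ivs, key=lambda iv: iv.start),
        codon_pairs=columns,
        score=score,
        query_start=qi0,
        query_end=qi1,
    )


# ---------------------------------------------------------------------------
# final filters and one-to-one reduction


def count_spanned_parent_introns(
    alignment: ProteinGenomeAlignment, parent: ParentInfo
) -> int:
    """Parent intron positions lying strictly inside the aligned residue range."""
    return sum(
        1
        for pos in parent.intron_residue_positions
        if alignment.query_start < pos < alignment.query_end
    )


def apply_final_filters(
    alignments: Sequence[tuple[str, ProteinGenomeAlignment]],
    parents: dict[str, ParentInfo],
    min_len_aa: int = 50,
    min_identity: float = 70.0,
    intron_mode: str = "parent_spanned",
) -> list[ParentRetroPair]:
    """Apply the final exclusion rules to realigned candidates.

    Keeps alignments with > ``min_len_aa`` aligned residues, identity
    > ``min_identity`` percent and (default mode ``parent_spanned``) zero
    inferred introns, a parent with >= 3 exons, and >= 2 parent intron
    positions spanned by the alignment — the mechanistic reading of
    "the parent's introns are demonstrably absent".  Mode
    ``max_one_retained`` instead allows at most one inferred intron and
    drops the parent-structure requirements.
    """
    if intron_mode not in ("parent_spanned", "max_one_retained"):
        raise ValueError(f"unknown intron_mode {intron_mode!r}")
    pairs = []
    for retro_id, aln in alignments:
        if aln.aligned_length_aa <= min_len_aa:
            continue
        if aln.percent_identity <= min_identity:
            continue
        parent = parents[aln.parent_id]
        spanned = count_spanned_parent_introns(aln, parent)
        if intron_mode == "parent_spanned":
            if aln.inferred_introns:
                continue
            if parent.exon_count < 3 or spanned < 2:
                continue
        else:
            if len(aln.inferred_introns) > 1:
                continue
        pairs.append(
            ParentRetroPair(
                retro_id=retro_id,
                parent_id=aln.parent_id,
                alignment=aln,
                parent_exon_count=parent.exon_count,
                spanned_parent_introns=spanned,
            )
        )
    return pairs


def dedupe_shared_parents(pairs: Sequence[ParentRetroPair]) -> list[ParentRetroPair]:
    """Drop every pair whose parent occurs more than once; result is one-to-one."""
    counts = Counter(p.parent_id for p in pairs)
    return [p for p in pairs if counts[p.parent_id] == 1]


def pairs_table(pairs: Iterable[ParentRetroPair]) -> pd.DataFrame:
    rows = [
        {
            "retro_id": p.retro_id,
            "parent_id": p.parent_id,
            "scaffold": p.alignment.locus.scaffold,
            "start": p.alignment.locus.start,
            "end": p.alignment.locus.end,
            "strand": p.alignment.locus.strand,
            "aligned_aa": p.alignment.aligned_length_aa,
            "identity": round(p.alignment.percent_identity, 3),
            "frameshifts": len(p.alignment.frameshift_events),
            "introns": len(p.alignment.inferred_introns),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)
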