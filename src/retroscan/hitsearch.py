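"""Translated-homology screening of peptides against a repeat-masked genome.

The screen finds protein-vs-genome hits on both strands via six-frame
translation (a lightweight seed-and-extend search; externally produced
BLAST-style tabular hits can be imported instead), then applies the
candidate-screening rules: adjacent hits from the same peptide closer than
40 bp are merged, merged loci with aligned regions > 50 amino acids and
identity > 30 % are kept, and among overlapping loci only the longest is
retained.

Soft-masked (lowercase) and hard-masked (N) genome sequence is excluded
from seeding, mirroring a search against a repeat-masked assembly.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from . import formats
from .formats import GenomicInterval
from ._codon import translate

_DNA = set("ACGT")


@dataclasses.dataclass
class SearchParams:
    """Knobs of the built-in translated search (tBLASTn-like contract)."""

    word_size: int = 4
    matrix: str = "BLOSUM62"
    xdrop: float = 20.0
    min_score: float = 50.0


@dataclasses.dataclass
class TranslatedHit:
    query_id: str
    interval: GenomicInterval
    percent_identity: float
    aligned_length_aa: int
    query_start: int  # 1-based inclusive residue positions, as in BLAST tabular
    query_end: int
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"identity out of range: {self.percent_identity}")
        if self.aligned_length_aa < 1:
            raise ValueError("aligned length must be >= 1 residue")


@dataclasses.dataclass
class CandidateLocus:
    interval: GenomicInterval
    member_hits: list[TranslatedHit]
    merged_aligned_length_aa: int
    merged_identity: float
    source_query: str


# ---------------------------------------------------------------------------
# built-in translated search


@dataclasses.dataclass(frozen=True)
class _Frame:
    scaffold: str
    strand: str
    offset: int          # 0, 1 or 2
    protein: str         # translated frame
    seedable: np.ndarray  # per-residue: True if all three bases unmasked
    scaffold_len: int

    def genome_interval(self, res_start: int, res_end: int) -> GenomicInterval:
        """Map a half-open residue range in this frame to genome coordinates."""
        if self.strand == "+":
            return GenomicInterval(
                self.scaffold, self.offset + 3 * res_start,
                self.offset + 3 * res_end, "+",
            )
        return GenomicInterval(
            self.scaffold,
            self.scaffold_len - self.offset - 3 * res_end,
            self.scaffold_len - self.offset - 3 * res_start,
            "-",
        )


def _score_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {aa: i for i, aa in enumerate(alphabet)}
    arr = np.array(mat)
    return arr, index


def _frames_of(scaffold: str, seq: str) -> list[_Frame]:
    n = len(seq)
    upper = seq.upper()
    unmasked = np.frombuffer(seq.encode(), dtype=np.uint8)
    # a base is seedable when uppercase A/C/G/T
    base_ok = np.isin(unmasked, np.frombuffer(b"ACGT", dtype=np.uint8))
    frames = []
    rc = str(Seq(upper).reverse_complement())
    rc_ok = base_ok[::-1]
    for strand, s, ok in (("+", upper, base_ok), ("-", rc, rc_ok)):
        for off in range(3):
            naa = (n - off) // 3
            if naa <= 0:
                continue
            prot = translate(s[off : off + 3 * naa])
            cod_ok = ok[off : off + 3 * naa].reshape(naa, 3).all(axis=1)
            frames.append(_Frame(scaffold, strand, off, prot, cod_ok, n))
    return frames


def _seed_index(peptides: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for pid, pep in peptides.items():
        for q in range(len(pep) - k + 1):
            index[pep[q : q + k]].append((pid, q))
    return index


def _extend_gapless(
    pep: str, prot: str, q: int, s: int, k: int,
    scores: np.ndarray, aa_index: dict[str, int], xdrop: float,
) -> tuple[int, int, int, int, float]:
    """X-drop gapless extension around a seed; returns (q0, q1, s0, s1, score)."""

    def sc(a: str, b: str) -> float:
        ia = aa_index.get(a)
        ib = aa_index.get(b)
        if ia is None or ib is None:
            return -4.0
        return scores[ia, ib]

    core = sum(sc(pep[q + t], prot[s + t]) for t in range(k))
    # extend right
    best = run = 0.0
    best_len = 0
    t = 0
    while q + k + t < len(pep) and s + k + t < len(prot):
        run += sc(pep[q + k + t], prot[s + k + t])
        t += 1
        if run > best:
            best, best_len = run, t
        elif best - run > xdrop:
            break
    right, right_len = best, best_len
    # extend left
    best = run = 0.0
    best_len = 0
    t = 0
    while q - 1 - t >= 0 and s - 1 - t >= 0:
        run += sc(pep[q - 1 - t], prot[s - 1 - t])
        t += 1
        if run > best:
            best, best_len = run, t
        elif best - run > xdrop:
            break
    left, left_len = best, best_len
    return (
        q - left_len, q + k + right_len,
        s - left_len, s + k + right_len,
        core + left + right,
    )


def search_translated(
    peptides: dict[str, str],
    genome: dict[str, str],
    params: SearchParams | None = None,
) -> list[TranslatedHit]:
    """Six-frame translated search of peptides against the masked genome.

    Seeds are exact ``word_size``-mers found only in fully unmasked codons;
    each seed is extended gaplessly in both directions under an X-drop rule
    and reported when the raw substitution-matrix score reaches
    ``min_score``.  Output order is (scaffold, start, query_id).
    """
    params = params or SearchParams()
    if not peptides:
        return []
    for name, seq in genome.items():
        if set(seq.upper()) - (_DNA | {"N"}):
            bad = sorted(set(seq.upper()) - (_DNA | {"N"}))
            raise ValueError(f"scaffold {name!r}: non-DNA characters {bad}")
    scores, aa_index = _score_matrix(params.matrix)
    k = params.word_size
    index = _seed_index(peptides, k)
    hits: list[TranslatedHit] = []
    for scaffold, seq in genome.items():
        for frame in _frames_of(scaffold, seq):
            prot = frame.protein
            seedable = frame.seedable
            # per (query, diagonal) rightmost extension end, to skip seeds
            # already covered by a previous extension on the same diagonal
            covered: dict[tuple[str, int], int] = {}
            for s in range(len(prot) - k + 1):
                if not seedable[s : s + k].all():
                    continue
                word = prot[s : s + k]
                for pid, q in index.get(word, ()):
                    diag = s - q
                    if covered.get((pid, diag), -1) >= s + k:
                        continue
                    q0, q1, s0, s1, score = _extend_gapless(
                        peptides[pid], prot, q, s, k, scores, aa_index, params.xdrop
                    )
                    covered[(pid, diag)] = s1
                    if score < params.min_score:
                        continue
                    length = q1 - q0
                    ident = sum(
                        1 for t in range(length) if peptides[pid][q0 + t] == prot[s0 + t]
                    )
                    hits.append(
                        TranslatedHit(
                            query_id=pid,
                            interval=frame.genome_interval(s0, s1),
                            percent_identity=100.0 * ident / length,
                            aligned_length_aa=length,
                            query_start=q0 + 1,
                            query_end=q1,
                            score=score,
                        )
                    )
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (h.interval.scaffold, h.interval.start, h.query_id))
    return hits


def _dedupe_hits(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Keep the best-scoring hit per (query, scaffold, strand, interval)."""
    best: dict[tuple, TranslatedHit] = {}
    for h in hits:
        key = (h.query_id, h.interval.scaffold, h.interval.strand,
               h.interval.start, h.interval.end)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return list(best.values())


# ---------------------------------------------------------------------------
# external tabular hits


def import_tabular_hits(path: str | Path) -> list[TranslatedHit]:
    """Import 12-column BLAST-style tabular hits.

    Minus-strand hits are encoded upstream as sstart > send and normalised
    here into a forward-coordinate interval with strand '-'.  No filtering
    is applied at import; screening thresholds act later.
    """
    df = formats.read_blast_tab(path)
    hits = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        if sstart <= send:
            strand, lo, hi = "+", sstart, send
        else:
            strand, lo, hi = "-", send, sstart
        interval = GenomicInterval(str(row.sseqid), lo - 1, hi, strand)
        hits.append(
            TranslatedHit(
                query_id=str(row.qseqid),
                interval=interval,
                percent_identity=float(row.pident),
                aligned_length_aa=int(row.length),
                query_start=int(row.qstart),
                query_end=int(row.qend),
                score=float(row.bitscore),
                evalue=float(row.evalue),
            )
        )
    return hits


def export_tabular_hits(hits: Iterable[TranslatedHit], path: str | Path) -> None:
    rows = []
    for h in hits:
        if h.interval.strand == "+":
            sstart, send = h.interval.start + 1, h.interval.end
        else:
            sstart, send = h.interval.end, h.interval.start + 1
        rows.append(
            (
                h.query_id, h.interval.scaffold, round(h.percent_identity, 2),
                h.aligned_length_aa, 0, 0, h.query_start, h.query_end,
                sstart, send, h.evalue if h.evalue is not None else 0.0, h.score,
            )
        )
    formats.write_blast_tab(
        pd.DataFrame(rows, columns=formats.BLAST_TAB_COLUMNS), path
    )


# ---------------------------------------------------------------------------
# merge / filter / overlap resolution


def merge_adjacent_hits(
    hits: Sequence[TranslatedHit], max_gap: int = 40, per_query: bool = True
) -> list[CandidateLocus]:
    """Transitively merge same-strand hits separated by < ``max_gap`` bases.

    The distance between two hits is the number of bases strictly between
    their genomic intervals; merging is per (scaffold, strand, query) by
    default so hits from different parent peptides never coalesce.
    The merged identity is the aligned-length-weighted mean of member
    identities, and the merged locus spans the union of its members.
    """
    groups: dict[tuple, list[TranslatedHit]] = defaultdict(list)
    for h in hits:
        key = (h.interval.scaffold, h.interval.strand) + (
            (h.query_id,) if per_query else ()
        )
        groups[key].append(h)
    loci: list[CandidateLocus] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda h: (h.interval.start, h.interval.end))
        cluster: list[TranslatedHit] = []
        cluster_end = None
        for h in members:
            if cluster and h.interval.start - cluster_end < max_gap:
                cluster.append(h)
                cluster_end = max(cluster_end, h.interval.end)
            else:
                if cluster:
                    loci.append(_make_locus(cluster))
                cluster = [h]
                cluster_end = h.interval.end
        if cluster:
            loci.append(_make_locus(cluster))
    loci.sort(key=lambda c: (c.interval.scaffold, c.interval.start, c.source_query))
    return loci


def _make_locus(members: list[TranslatedHit]) -> CandidateLocus:
    start = min(h.interval.start for h in members)
    end = max(h.interval.end for h in members)
    total_aa = sum(h.aligned_length_aa for h in members)
    ident = (
        sum(h.percent_identity * h.aligned_length_aa for h in members) / total_aa
    )
    first = members[0]
    return CandidateLocus(
        interval=GenomicInterval(
            first.interval.scaffold, start, end, first.interval.strand
        ),
        member_hits=list(members),
        merged_aligned_length_aa=total_aa,
        merged_identity=ident,
        source_query=first.query_id,
    )


def filter_candidate_loci(
    loci: Iterable[CandidateLocus],
    min_len_aa: int = 50,
    min_identity: float = 30.0,
) -> list[CandidateLocus]:
    """Keep loci with aligned region > min_len_aa residues AND identity
    > min_identity percent (both strictly greater)."""
    return [
        c for c in loci
        if c.merged_aligned_length_aa > min_len_aa and c.merged_identity > min_identity
    ]


def resolve_overlaps(loci: Sequence[CandidateLocus]) -> list[CandidateLocus]:
    """Among overlapping loci keep only the longest.

    Overlap is strand- and query-agnostic; resolution operates on connected
    components of the interval-overlap graph (for intervals on a line these
    are exactly the clusters of a coordinate sweep).  Ties break by lower
    start, then lexicographic query id.  The result is pairwise
    non-overlapping.
    """
    by_scaffold: dict[str, list[CandidateLocus]] = defaultdict(list)
    for c in loci:
        by_scaffold[c.interval.scaffold].append(c)
    kept: list[CandidateLocus] = []
    for scaffold in sorted(by_scaffold):
        group = sorted(by_scaffold[scaffold], key=lambda c: (c.interval.start, c.interval.end))
        cluster: list[CandidateLocus] = []
        cluster_end = None
        for c in group:
            if cluster and c.interval.start < cluster_end:
                cluster.append(c)
                cluster_end = max(cluster_end, c.interval.end)
            else:
                if cluster:
                    kept.append(_pick_longest(cluster))
                cluster = [c]
                cluster_end = c.interval.end
        if cluster:
            kept.append(_pick_longest(cluster))
    kept.sort(key=lambda c: (c.interval.scaffold, c.interval.start, c.source_query))
    return kept


def _pick_longest(cluster: list[CandidateLocus]) -> CandidateLocus:
    return min(
        cluster,
        key=lambda c: (-c.interval.length, c.interval.start, c.source_query),
    )


def loci_table(loci: Iterable[CandidateLocus]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": c.interval.scaffold,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "query_id": c.source_query,
            "aligned_length_aa": c.merged_aligned_length_aa,
            "identity": round(c.merged_identity, 3),
            "n_members": len(c.member_hits),
        }
        for c in loci
    ]
    return pd.DataFrame(rows)
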