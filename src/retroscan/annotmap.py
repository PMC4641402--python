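"""Mapping retrocopy loci onto gene models and classifying overlaps.

A retrocopy overlaps a gene when the two intervals share at least one base
(strand-agnostic by default, since retrocopies insert in either
orientation); it is exon-overlapped when it intersects any exon of any
overlapped gene, otherwise non-exon-overlapped.  The distinct overlapped
genes are the "retrocopy-overlapped genes" fed to GO and orthology
analyses.
"""

from __future__ import annotations

import dataclasses
import heapq
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .formats import FormatError, GenomicInterval


@dataclasses.dataclass
class AnnotatedGene:
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclasses.dataclass
class OverlapCall:
    retro_id: str
    overlapped_gene_ids: list[str]
    overlap_class: str  # none | non_exon_overlapped | exon_overlapped

    def __post_init__(self) -> None:
        if (self.overlap_class == "none") != (not self.overlapped_gene_ids):
            raise ValueError("class 'none' iff the overlapped gene list is empty")


def read_gene_models(path: str | Path) -> list[AnnotatedGene]:
    """Read genes with exon children from GFF3 (1-based inclusive on disk).

    Exons are attached through their mRNA parent when present; an exon
    outside its gene span is a validation error.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: failed to parse GFF3: {exc}") from exc
    genes: list[AnnotatedGene] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand or "+")
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            eiv = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand or "+")
            if (
                eiv.scaffold != iv.scaffold
                or eiv.start < iv.start
                or eiv.end > iv.end
            ):
                raise FormatError(
                    f"{path}: exon [{exon.start},{exon.end}] outside gene "
                    f"{gene.id} span [{gene.start},{gene.end}]"
                )
            exons.append(eiv)
        genes.append(AnnotatedGene(gene.id, iv, exons))
    return genes


def map_retro_to_genes(
    retro_loci: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[AnnotatedGene],
    strand_aware: bool = False,
) -> list[OverlapCall]:
    """Classify each retrocopy locus against the gene models.

    Implemented as a per-scaffold sweep over start-sorted genes and loci
    with an end-ordered active set; overlap is >= 1 shared base.
    """
    genes_by_scaffold: dict[str, list[AnnotatedGene]] = defaultdict(list)
    for g in genes:
        genes_by_scaffold[g.interval.scaffold].append(g)
    for lst in genes_by_scaffold.values():
        lst.sort(key=lambda g: g.interval.start)
    calls = []
    loci_sorted = sorted(retro_loci, key=lambda r: (r[1].scaffold, r[1].start))
    active: dict[str, list] = defaultdict(list)  # heap of (end, idx) per scaffold
    next_gene: dict[str, int] = defaultdict(int)
    for retro_id, iv in loci_sorted:
        glist = genes_by_scaffold.get(iv.scaffold, [])
        heap = active[iv.scaffold]
        i = next_gene[iv.scaffold]
        while i < len(glist) and glist[i].interval.start < iv.end:
            heapq.heappush(heap, (glist[i].interval.end, i))
            i += 1
        next_gene[iv.scaffold] = i
        while heap and heap[0][0] <= iv.start:
            heapq.heappop(heap)
        hit_ids, exon_hit = [], False
        for _end, gi in heap:
            g = glist[gi]
            if not g.interval.overlaps(iv):
                continue
            if strand_aware and g.interval.strand != iv.strand:
                continue
            hit_ids.append(g.gene_id)
            if any(ex.overlaps(iv) for ex in g.exons):
                exon_hit = True
        hit_ids.sort()
        if not hit_ids:
            cls = "none"
        elif exon_hit:
            cls = "exon_overlapped"
        else:
            cls = "non_exon_overlapped"
        calls.append(OverlapCall(retro_id, hit_ids, cls))
    order = {rid: k for k, (rid, _) in enumerate(retro_loci)}
    calls.sort(key=lambda c: order[c.retro_id])
    return calls


def summarize_overlap(calls: Iterable[OverlapCall]) -> dict[str, int]:
    """Counts of exon/non-exon overlapped retrocopies and distinct genes."""
    exon = non_exon = 0
    genes: set[str] = set()
    for c in calls:
        if c.overlap_class == "exon_overlapped":
            exon += 1
        elif c.overlap_class == "non_exon_overlapped":
            non_exon += 1
        genes.update(c.overlapped_gene_ids)
    return {
        "exon_overlapped": exon,
        "non_exon_overlapped": non_exon,
        "overlapped_retrocopies": exon + non_exon,
        "overlapped_genes": len(genes),
    }


def overlap_table(calls: Iterable[OverlapCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.overlapped_gene_ids:
            for gid in c.overlapped_gene_ids:
                rows.append({"retro_id": c.retro_id, "gene_id": gid,
                             "overlap_class": c.overlap_class})
        else:
            rows.append({"retro_id": c.retro_id, "gene_id": "",
                         "overlap_class": "none"})
    return pd.DataFrame(rows)
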