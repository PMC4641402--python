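import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from retroscan.formats import GenomicInterval, convert_coordinates
from retroscan.hitsearch import CandidateLocus, TranslatedHit
from retroscan.parentalign import (
    AlignParams,
    ParentInfo,
    ParentRetroPair,
    ProteinGenomeAlignment,
    align_protein_to_genome,
    apply_final_filters,
    count_spanned_parent_introns,
    dedupe_shared_parents,
    expand_flanks,
    rank_parent_candidates,
    realign_locus,
)
from retroscan._codon import random_sense_codons, translate

import oracles


def _random_cds(n_codons, seed):
    rng = np.random.default_rng(seed)
    return "ATG" + "".join(random_sense_codons(n_codons - 1, rng))


class TestExpandFlanks:
    def test_ten_kb_each_side(self):
        iv = GenomicInterval("s", 14999, 16000)  # 1-based [15000,16000]
        out = expand_flanks(iv, scaffold_length=100000, flank=10000)
        assert convert_coordinates(out.start, out.end, "internal", "gff3") == (5000, 26000)

    def test_clamped_at_scaffold_edges(self):
        iv = GenomicInterval("s", 2999, 4000)  # 1-based [3000,4000]
        out = expand_flanks(iv, scaffold_length=500000, flank=10000)
        assert convert_coordinates(out.start, out.end, "internal", "gff3") == (1, 14000)

    def test_zero_flank_is_identity(self):
        iv = GenomicInterval("s", 100, 200)
        assert expand_flanks(iv, 1000, flank=0) == iv


class TestAlignProteinToGenome:
    def test_exact_cds_aligns_perfectly(self):
        cds = _random_cds(50, 0)
        pep = translate(cds)
        score, qi0, qi1, rj0, rj1, cols, fss, introns = align_protein_to_genome(
            pep, cds, cds
        )
        assert (qi0, qi1) == (0, len(pep))
        assert (rj0, rj1) == (0, len(cds))
        assert fss == [] and introns == []
        assert all(k == "match" for _, _, k in cols)

    def test_single_deleted_base_is_one_frameshift(self):
        cds = _random_cds(60, 1)
        pep = translate(cds)
        mutated = cds[:100] + cds[101:]
        _, qi0, qi1, _, _, cols, fss, introns = align_protein_to_genome(
            pep, cds, mutated
        )
        assert len(fss) == 1
        assert introns == []
        # flanking codons still aligned: nearly the whole peptide is covered
        assert qi1 - qi0 >= len(pep) - 2

    def test_long_insert_recorded_as_intron(self):
        cds = _random_cds(60, 2)
        pep = translate(cds)
        insert = "GT" + "ACGT" * 124 + "AG"  # 500 bp
        region = cds[:90] + insert + cds[90:]
        _, _, _, _, _, cols, fss, introns = align_protein_to_genome(pep, cds, region)
        assert fss == []
        assert len(introns) == 1
        a, b = introns[0]
        assert b - a == 500
        match_cols = [(p, t) for p, t, k in cols if t is not None]
        assert all(translate(p) == translate(t) for p, t in match_cols)

    def test_score_matches_exhaustive_oracle_on_small_instances(self):
        """The vectorised DP score equals an exhaustive memoized recursion
        on instances up to 12 codons x 60 nt, over random sequences and
        constructed frameshift/intron cases."""
        mat = substitution_matrices.load("BLOSUM62")
        aa_index = {aa: i for i, aa in enumerate(str(mat.alphabet))}
        blosum = np.array(mat)
        params = AlignParams(min_intron_len=10)
        rng = np.random.default_rng(3)
        cases = []
        for k in range(8):
            n_codons = int(rng.integers(4, 13))
            cds = "ATG" + "".join(random_sense_codons(n_codons - 1, rng))
            region = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 61))))
            cases.append((translate(cds), region))
        fs_cds = _random_cds(10, 5)
        cases.append((translate(fs_cds), fs_cds[:14] + fs_cds[15:]))  # deletion
        intron_cds = _random_cds(8, 6)
        cases.append(
            (translate(intron_cds), intron_cds[:12] + "T" * 15 + intron_cds[12:])
        )
        for pep, region in cases:
            got = align_protein_to_genome(pep, None, region,
                                          AlignParams(min_intron_len=10, score_floor=-1))
            got_score = got[0] if got else 0.0
            want = oracles.protein_genome_align_score(
                pep, region, blosum, aa_index,
                params.frameshift_penalty, params.intron_open,
                params.min_intron_len, params.residue_gap,
            )
            assert got_score == pytest.approx(want, abs=1e-6), (pep, region)

    def test_below_floor_returns_none(self):
        assert align_protein_to_genome("MKW", "ATGAAATGG", "CCCCCCCCC",
                                       AlignParams(score_floor=25.0)) is None


class TestRealignLocus:
    def test_minus_strand_round_trip(self):
        cds = _random_cds(60, 7)
        pep = translate(cds)
        genome = {"s1": "A" * 400 + str(Seq(cds).reverse_complement()) + "C" * 400}
        info = ParentInfo("p", pep, cds, 3, (60, 120))
        aln = realign_locus(
            "r", info, GenomicInterval("s1", 0, len(genome["s1"]), "-"), genome
        )
        assert aln.percent_identity == 100.0
        assert (aln.locus.start, aln.locus.end) == (400, 400 + len(cds))
        assert aln.frameshift_events == [] and aln.inferred_introns == []


def _locus_for(genome, query_id, start, end, strand="+"):
    hit = TranslatedHit(
        query_id=query_id,
        interval=GenomicInterval("s1", start, end, strand),
        percent_identity=100.0,
        aligned_length_aa=(end - start) // 3,
        query_start=1,
        query_end=(end - start) // 3,
        score=200.0,
    )
    return CandidateLocus(
        interval=hit.interval, member_hits=[hit],
        merged_aligned_length_aa=hit.aligned_length_aa,
        merged_identity=100.0, source_query=query_id,
    )


class TestRankParentCandidates:
    def _parents(self):
        cds_a = _random_cds(60, 10)
        cds_b = _random_cds(60, 11)
        return {
            "multi": ParentInfo("multi", translate(cds_a), cds_a, 4, (45, 90, 135)),
            "single": ParentInfo("single", translate(cds_b), cds_b, 1, ()),
        }

    def test_exact_multi_exon_match_wins(self):
        parents = self._parents()
        genome = {"s1": "ACGT" * 25 + parents["multi"].cds + "ACGT" * 25}
        locus = _locus_for(genome, "multi", 100, 100 + len(parents["multi"].cds))
        decision = rank_parent_candidates(locus, parents, genome)
        assert decision.reason == "ok"
        assert decision.parent_id == "multi"

    def test_single_exon_best_hit_is_discarded_as_dna_duplication(self):
        parents = self._parents()
        genome = {"s1": "ACGT" * 25 + parents["single"].cds + "ACGT" * 25}
        locus = _locus_for(genome, "single", 100, 100 + len(parents["single"].cds))
        decision = rank_parent_candidates(locus, parents, genome)
        assert decision.reason == "dna_duplication"
        assert decision.parent_id is None

    def test_tie_between_multi_exon_peptides_breaks_lexicographically(self):
        cds = _random_cds(60, 12)
        parents = {
            "pB": ParentInfo("pB", translate(cds), cds, 3, (60, 120)),
            "pA": ParentInfo("pA", translate(cds), cds, 3, (60, 120)),
        }
        genome = {"s1": "ACGT" * 25 + cds + "ACGT" * 25}
        locus = _locus_for(genome, "pA", 100, 100 + len(cds))
        decision = rank_parent_candidates(locus, parents, genome)
        assert decision.parent_id == "pA"
        assert set(decision.tied_ids) == {"pA", "pB"}

    def test_no_scoring_parent_reported(self):
        parents = self._parents()
        genome = {"s1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"}
        locus = _locus_for(genome, "x", 0, 36)
        decision = rank_parent_candidates(locus, parents, genome)
        assert decision.reason == "no_parent"


def _mk_alignment(parent_id, length_aa=80, identity=90.0, introns=(),
                  q0=0, q1=None):
    q1 = q1 if q1 is not None else length_aa
    return ProteinGenomeAlignment(
        parent_id=parent_id,
        locus=GenomicInterval("s", 0, 3 * length_aa),
        aligned_length_aa=length_aa,
        percent_identity=identity,
        frameshift_events=[],
        inferred_introns=[GenomicInterval("s", a, b) for a, b in introns],
        codon_pairs=[],
        score=300.0,
        query_start=q0,
        query_end=q1,
    )


def _parent(pid="p", exons=5, peptide_len=100):
    offsets = tuple(3 * peptide_len * k // exons for k in range(1, exons))
    return ParentInfo(pid, "M" * peptide_len, "ATG" * peptide_len, exons, offsets)


class TestFinalFilters:
    def test_identity_at_seventy_percent_is_excluded(self):
        parents = {"p": _parent()}
        out = apply_final_filters([("r1", _mk_alignment("p", identity=70.0))], parents)
        assert out == []

    def test_passing_alignment_is_kept_with_spanned_introns(self):
        parents = {"p": _parent(exons=5)}
        aln = _mk_alignment("p", length_aa=71, identity=90.0, q0=0, q1=100)
        (pair,) = apply_final_filters([("r1", aln)], parents)
        assert pair.parent_exon_count == 5
        assert pair.spanned_parent_introns == 4

    def test_any_inferred_intron_excludes(self):
        parents = {"p": _parent()}
        aln = _mk_alignment("p", length_aa=71, identity=90.0, introns=[(10, 200)])
        assert apply_final_filters([("r1", aln)], parents) == []

    def test_short_alignment_excluded(self):
        parents = {"p": _parent()}
        assert apply_final_filters([("r1", _mk_alignment("p", length_aa=50))], parents) == []

    def test_alignment_spanning_too_few_introns_excluded(self):
        parents = {"p": _parent(exons=5, peptide_len=100)}
        # covers only the first fifth of the parent: no intron position inside
        aln = _mk_alignment("p", length_aa=60, identity=90.0, q0=0, q1=15)
        assert apply_final_filters([("r1", aln)], parents) == []

    def test_max_one_retained_mode_allows_one_intron(self):
        parents = {"p": _parent(exons=2)}
        aln = _mk_alignment("p", length_aa=71, identity=90.0, introns=[(10, 200)])
        (pair,) = apply_final_filters(
            [("r1", aln)], parents, intron_mode="max_one_retained"
        )
        assert pair.retro_id == "r1"

    def test_spanned_intron_counting_is_strict(self):
        parent = _parent(exons=3, peptide_len=90)  # introns at residues 30, 60
        aln = _mk_alignment("p", q0=30, q1=61)
        assert count_spanned_parent_introns(aln, parent) == 1


class TestDedupeSharedParents:
    def _pair(self, rid, pid):
        return ParentRetroPair(rid, pid, _mk_alignment(pid), 5, 2)

    def test_shared_parent_removes_all_sharers(self):
        pairs = [self._pair("R1", "P1"), self._pair("R2", "P1"), self._pair("R3", "P2")]
        out = dedupe_shared_parents(pairs)
        assert [(p.retro_id, p.parent_id) for p in out] == [("R3", "P2")]

    def test_unique_parents_unchanged(self):
        pairs = [self._pair("R1", "P1"), self._pair("R2", "P2")]
        assert dedupe_shared_parents(pairs) == pairs

    def test_three_sharing_one_parent_all_removed(self):
        pairs = [self._pair(f"R{i}", "P1") for i in range(3)]
        assert dedupe_shared_parents(pairs) == []
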