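import random

import pytest
from Bio.Seq import Seq

from retroscan.formats import GenomicInterval
from retroscan.hitsearch import (
    CandidateLocus,
    SearchParams,
    TranslatedHit,
    filter_candidate_loci,
    import_tabular_hits,
    merge_adjacent_hits,
    resolve_overlaps,
    search_translated,
)

PARAMS = SearchParams(word_size=4, min_score=20.0)


def _encode(peptide: str) -> str:
    codon = {
        "M": "ATG", "K": "AAA", "V": "GTT", "L": "CTT", "H": "CAT",
        "W": "TGG", "E": "GAA", "F": "TTT", "D": "GAT", "Y": "TAT",
    }
    return "".join(codon[a] for a in peptide)


def _hit(query, scaffold, start, end, strand="+", ident=90.0, length=None,
         qstart=1):
    length = length if length is not None else max(1, (end - start) // 3)
    return TranslatedHit(
        query_id=query,
        interval=GenomicInterval(scaffold, start, end, strand),
        percent_identity=ident,
        aligned_length_aa=length,
        query_start=qstart,
        query_end=qstart + length - 1,
        score=100.0,
    )


class TestSearchTranslated:
    def test_exact_match_found_at_full_identity(self):
        pep = {"p1": "MKVLHWEFDY"}
        genome = {"s1": "ACGT" * 10 + _encode(pep["p1"]) + "TTAC" * 10}
        hits = search_translated(pep, genome, PARAMS)
        exact = [h for h in hits if h.percent_identity == 100.0]
        assert len(exact) == 1
        h = exact[0]
        assert h.aligned_length_aa == 10
        assert h.interval.start == 40 and h.interval.end == 70
        assert h.interval.strand == "+"

    def test_soft_masked_encoding_is_not_seeded(self):
        pep = {"p1": "MKVLHWEFDY"}
        genome = {"s1": "ACGT" * 10 + _encode(pep["p1"]).lower() + "TTAC" * 10}
        assert search_translated(pep, genome, PARAMS) == []

    def test_reverse_strand_hit_matches_forward_identity(self):
        pep = {"p1": "MKVLHWEFDY"}
        enc = _encode(pep["p1"])
        fwd = {"s1": "ACGT" * 10 + enc + "TTAC" * 10}
        rev = {"s1": "ACGT" * 10 + str(Seq(enc).reverse_complement()) + "TTAC" * 10}
        hf = [h for h in search_translated(pep, fwd, PARAMS) if h.percent_identity == 100][0]
        hr = [h for h in search_translated(pep, rev, PARAMS) if h.percent_identity == 100][0]
        assert hr.interval.strand == "-"
        assert hr.percent_identity == hf.percent_identity
        assert (hr.interval.start, hr.interval.end) == (hf.interval.start, hf.interval.end)

    def test_empty_peptides_and_bad_genome(self):
        assert search_translated({}, {"s": "ACGT"}, PARAMS) == []
        with pytest.raises(ValueError, match="non-DNA"):
            search_translated({"p": "MKVLH"}, {"s": "ACGU"}, PARAMS)


class TestImportTabular:
    def test_minus_strand_normalised(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t88.0\t100\t10\t0\t1\t100\t900\t601\t1e-20\t200\n")
        (hit,) = import_tabular_hits(p)
        assert hit.interval.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (600, 900)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert import_tabular_hits(p) == []

    def test_low_identity_retained_at_import(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t30.0\t100\t10\t0\t1\t100\t601\t900\t1e-20\t200\n")
        (hit,) = import_tabular_hits(p)
        assert hit.percent_identity == 30.0


class TestMergeAdjacentHits:
    def test_gap_below_forty_merges(self):
        hits = [_hit("q", "s", 99, 200), _hit("q", "s", 238, 300)]  # gap 38
        loci = merge_adjacent_hits(hits, max_gap=40)
        assert len(loci) == 1
        assert (loci[0].interval.start, loci[0].interval.end) == (99, 300)

    def test_gap_of_exactly_forty_does_not_merge(self):
        hits = [_hit("q", "s", 99, 200), _hit("q", "s", 240, 300)]  # gap 40
        assert len(merge_adjacent_hits(hits, max_gap=40)) == 2

    def test_transitive_merge_matches_brute_force(self):
        """Chains of close hits collapse into one locus exactly as a
        brute-force transitive closure predicts."""
        rnd = random.Random(4)
        for _ in range(30):
            spans = []
            pos = 0
            for _ in range(rnd.randint(2, 8)):
                pos += rnd.randint(0, 80)
                w = rnd.randint(10, 120)
                spans.append((pos, pos + w))
                pos += w
            hits = [_hit("q", "s", a, b) for a, b in spans]
            loci = merge_adjacent_hits(hits, max_gap=40)
            # brute-force closure: union-find over pairs with gap < 40
            parent = list(range(len(spans)))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i, (a1, b1) in enumerate(spans):
                for j, (a2, b2) in enumerate(spans):
                    if i < j:
                        gap = max(a2 - b1, a1 - b2)
                        if gap < 40:
                            parent[find(i)] = find(j)
            n_components = len({find(i) for i in range(len(spans))})
            assert len(loci) == n_components

    def test_merge_is_order_independent(self):
        hits = [
            _hit("q", "s", 0, 50), _hit("q", "s", 60, 100),
            _hit("q", "s", 300, 400), _hit("q2", "s", 70, 120),
        ]
        a = merge_adjacent_hits(hits)
        b = merge_adjacent_hits(list(reversed(hits)))
        key = lambda c: (c.interval.start, c.interval.end, c.source_query)
        assert [key(c) for c in a] == [key(c) for c in b]

    def test_identity_is_length_weighted(self):
        hits = [
            _hit("q", "s", 0, 300, ident=100.0, length=100),
            _hit("q", "s", 310, 370, ident=40.0, length=20),
        ]
        (locus,) = merge_adjacent_hits(hits)
        assert locus.merged_identity == pytest.approx((100 * 100 + 40 * 20) / 120)
        assert locus.merged_aligned_length_aa == 120


class TestFilterCandidateLoci:
    def _locus(self, length_aa, ident):
        return CandidateLocus(
            interval=GenomicInterval("s", 0, 3 * length_aa),
            member_hits=[], merged_aligned_length_aa=length_aa,
            merged_identity=ident, source_query="q",
        )

    @pytest.mark.parametrize(
        "length,ident,kept",
        [(51, 31.0, True), (50, 90.0, False), (200, 30.0, False)],
    )
    def test_strict_thresholds(self, length, ident, kept):
        out = filter_candidate_loci([self._locus(length, ident)])
        assert bool(out) is kept


class TestResolveOverlaps:
    def _locus(self, start, end, query="q"):
        return CandidateLocus(
            interval=GenomicInterval("s", start, end),
            member_hits=[], merged_aligned_length_aa=(end - start) // 3,
            merged_identity=90.0, source_query=query,
        )

    def test_longest_of_two_overlapping_wins(self):
        out = resolve_overlaps([self._locus(0, 300), self._locus(200, 700)])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (200, 700)

    def test_disjoint_loci_all_retained(self):
        out = resolve_overlaps([self._locus(0, 100), self._locus(200, 300)])
        assert len(out) == 2

    def test_chain_resolves_per_connected_component(self):
        a = self._locus(0, 10)
        b = self._locus(5, 25)
        c = self._locus(20, 50)  # a-b overlap, b-c overlap, a-c disjoint
        out = resolve_overlaps([a, b, c])
        assert len(out) == 1
        assert out[0].interval.length == 30

    def test_output_pairwise_non_overlapping_on_random_sets(self):
        rnd = random.Random(9)
        for _ in range(20):
            loci = [
                self._locus(s := rnd.randint(0, 2000), s + rnd.randint(1, 400))
                for _ in range(15)
            ]
            out = resolve_overlaps(loci)
            for i, a in enumerate(out):
                for b in out[i + 1 :]:
                    assert not a.interval.overlaps(b.interval)

    def test_matches_brute_force_component_maxima(self):
        """The survivor set equals picking the longest locus from each
        connected component of the brute-force overlap graph."""
        rnd = random.Random(17)
        for _ in range(20):
            loci = [
                self._locus(s := rnd.randint(0, 1000), s + rnd.randint(1, 300),
                            query=f"q{k}")
                for k in range(10)
            ]
            out = resolve_overlaps(loci)
            # brute force components
            n = len(loci)
            adj = {i: set() for i in range(n)}
            for i in range(n):
                for j in range(i + 1, n):
                    if loci[i].interval.overlaps(loci[j].interval):
                        adj[i].add(j)
                        adj[j].add(i)
            seen, expected = set(), []
            for i in range(n):
                if i in seen:
                    continue
                comp, stack = [], [i]
                while stack:
                    k = stack.pop()
                    if k in seen:
                        continue
                    seen.add(k)
                    comp.append(k)
                    stack.extend(adj[k])
                expected.append(
                    min(
                        (loci[k] for k in comp),
                        key=lambda c: (-c.interval.length, c.interval.start,
                                       c.source_query),
                    )
                )
            key = lambda c: (c.interval.start, c.interval.end, c.source_query)
            assert sorted(map(key, out)) == sorted(map(key, expected))
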