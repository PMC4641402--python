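import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from retroscan import goenrich
from retroscan.formats import read_fasta
from retroscan.syndata import (
    ConfigError,
    SimulationConfig,
    evolve_retrocopy,
    generate_parent_genes,
    simulate_dataset,
    simulate_expression,
    simulate_go_and_orthology,
    truth_table,
    write_dataset,
)
from retroscan._codon import STOP_CODONS, translate

from conftest import small_config


class TestConfigValidation:
    def test_probabilities_must_be_in_unit_interval(self):
        with pytest.raises(ConfigError):
            SimulationConfig(frameshift_prob=1.5)

    def test_weights_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimulationConfig(age_distribution=((0.1, -1.0),))

    def test_exon_count_minimum(self):
        with pytest.raises(ConfigError):
            SimulationConfig(exon_count_range=(0, 3))


class TestGenerateParentGenes:
    def test_forced_exon_count_gives_two_introns(self):
        cfg = small_config(n_parent_genes=1, n_single_exon_genes=0,
                           n_retrocopies=0, n_dna_duplication_decoys=0,
                           exon_count_range=(3, 3))
        _, genes, _ = generate_parent_genes(cfg)
        assert genes[0].exon_count == 3
        assert len(genes[0].intron_cds_offsets) == 2

    def test_peptides_match_spliced_cds_translation(self):
        """Independent re-splicing oracle: extract exons from the genome by
        coordinate, splice, reverse-complement minus-strand genes, translate
        with Biopython, and compare codon-by-codon with the emitted
        peptides."""
        cfg = small_config(n_parent_genes=20, n_retrocopies=0,
                           n_dna_duplication_decoys=0)
        genome, genes, peptides = generate_parent_genes(cfg)
        assert len([g for g in genes if g.exon_count > 1]) == 20
        for g in genes:
            spliced = "".join(
                genome[g.scaffold][a:b].upper() for a, b in g.exons
            )
            if g.strand == "-":
                spliced = str(Seq(spliced).reverse_complement())
            assert len(spliced) % 3 == 0
            assert spliced.startswith("ATG")
            assert spliced[-3:] in STOP_CODONS
            aa = str(Seq(spliced[:-3]).translate())
            assert "*" not in aa
            assert aa == peptides[g.gene_id]

    def test_same_seed_gives_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(simulate_dataset(small_config()), tmp_path / sub)
        for name in ("genome.fa", "genes.gff3", "peptides.fa", "truth.tsv",
                     "counts.tsv", "gene2go.tsv", "presence.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_soft_masking_present_at_requested_level(self):
        cfg = small_config(masked_fraction=0.1)
        genome, _, _ = generate_parent_genes(cfg)
        total = sum(len(s) for s in genome.values())
        masked = sum(sum(c.islower() for c in s) for s in genome.values())
        assert 0.05 <= masked / total <= 0.12


class TestEvolveRetrocopy:
    def test_zero_branch_length_is_identity(self, rng):
        cds = "ATG" + "AAATTTGGG" * 20
        assert evolve_retrocopy(cds, 0.0, 1.0, 0, 0, rng) == cds

    def test_requested_stop_is_injected(self, rng):
        cds = "ATG" + "AAATTTGGG" * 20
        out = evolve_retrocopy(cds, 0.0, 1.0, 0, 1, rng)
        aa = translate(out)
        assert "*" in aa[:-1] or aa.endswith("*")

    def test_frameshift_changes_length_mod_three(self, rng):
        cds = "ATG" + "AAATTTGGG" * 20
        out = evolve_retrocopy(cds, 0.0, 1.0, 1, 0, rng)
        assert len(out) != len(cds) or len(out) % 3 != 0

    @pytest.mark.parametrize("t,omega", [(-0.1, 1.0), (0.5, 0.0), (0.5, -1.0)])
    def test_invalid_parameters_rejected(self, t, omega, rng):
        with pytest.raises(ValueError):
            evolve_retrocopy("ATGAAATTTGGGAAATTTGGGAAATTTGGGTTT", t, omega, 0, 0, rng)


class TestPlanting:
    def test_genome_length_grows_by_insert_lengths(self, small_dataset):
        cfg = small_dataset.config
        base_genome, _, _ = generate_parent_genes(cfg)
        base_len = sum(len(s) for s in base_genome.values())
        planted_len = sum(len(s) for s in small_dataset.genome.values())
        inserted = sum(len(t.insert_seq) for t in small_dataset.truths)
        assert planted_len == base_len + inserted

    def test_intronic_copies_lie_inside_gene_but_outside_exons(self, small_dataset):
        gene_by_id = {g.gene_id: g for g in small_dataset.genes}
        checked = 0
        for t in small_dataset.truths:
            if t.insertion_context != "intronic" or t.is_dna_duplication_decoy:
                continue
            host = [
                g for g in small_dataset.genes
                if g.scaffold == t.locus.scaffold and g.start < t.locus.start
                and t.locus.end < g.end
            ]
            assert host, f"{t.copy_id} not inside any gene span"
            for g in host:
                for a, b in g.exons:
                    assert t.locus.end <= a or b <= t.locus.start
            checked += 1
        assert checked >= 1
        assert gene_by_id  # models remained addressable after planting

    def test_decoys_retain_parent_introns(self, small_dataset):
        gene_by_id = {g.gene_id: g for g in small_dataset.genes}
        for t in small_dataset.truths:
            if not t.is_dna_duplication_decoy:
                continue
            parent = gene_by_id[t.true_parent_id]
            assert parent.exon_count >= 3
            # the insert carries the full genomic gene, introns included
            assert len(t.insert_seq) > len(parent.cds)

    def test_truth_table_has_unique_ids(self, small_dataset):
        df = truth_table(small_dataset.truths)
        assert len(df) == len(small_dataset.truths)
        assert df["copy_id"].is_unique
        assert (df["start"] >= 0).all()


class TestExpression:
    def _truths(self, n):
        from retroscan.syndata import SyntheticTruth

        return [
            SyntheticTruth(f"c{i}", "g", true_t=i / n, true_omega=0.5,
                           n_planted_frameshifts=0, n_planted_stops=0,
                           insertion_context="intergenic",
                           is_dna_duplication_decoy=False)
            for i in range(n)
        ]

    def test_zero_probability_gives_all_zero_counts(self):
        cfg = small_config(base_expression_prob=0.0, testis_bias_factor=1.0)
        counts, _ = simulate_expression(self._truths(50), cfg)
        assert (counts.to_numpy() == 0).all()

    def test_unbiased_testis_is_unremarkable(self):
        from scipy.stats import binomtest

        cfg = small_config(testis_bias_factor=1.0, base_expression_prob=0.2)
        counts, _ = simulate_expression(
            self._truths(500), cfg, np.random.default_rng(0)
        )
        expressed = (counts > 0).sum(axis=0)
        testis = int(expressed.iloc[-1])
        others = int(expressed.iloc[:-1].sum())
        res = binomtest(testis, testis + others, 1 / len(cfg.tissues))
        assert res.pvalue > 0.01

    def test_biased_testis_has_largest_expressed_count(self):
        cfg = small_config(testis_bias_factor=5.0)
        counts, _ = simulate_expression(
            self._truths(500), cfg, np.random.default_rng(1)
        )
        expressed = (counts > 0).sum(axis=0)
        assert expressed.idxmax() == "testis"

    def test_duplicate_tissues_rejected(self):
        cfg = small_config(tissues=("a", "a", "b"))
        with pytest.raises(ConfigError):
            simulate_expression(self._truths(5), cfg)


class TestGoAndOrthology:
    def test_propagated_root_count_equals_annotated_genes(self, tmp_path):
        cfg = small_config()
        gene_ids = [f"gene_{i:04d}" for i in range(1, 21)]
        gene2go, obo, _, _ = simulate_go_and_orthology(gene_ids, cfg)
        obo_path = tmp_path / "mini.obo"
        obo_path.write_text(obo)
        dag = goenrich.load_ontology(obo_path)
        mapping = {
            g: set(sub["go_id"]) for g, sub in gene2go.groupby("gene_id")
        }
        closure = goenrich.propagate_annotations(mapping, dag)
        at_root = sum(1 for terms in closure.values() if "GO:0000001" in terms)
        assert at_root == len(mapping)

    def test_enriched_subset_concentrates_in_designated_term(self):
        cfg = small_config()
        gene_ids = [f"g{i}" for i in range(40)]
        gene2go, _, _, truth = simulate_go_and_orthology(gene_ids, cfg)
        annotated = set(
            gene2go[gene2go["go_id"] == truth.enriched_term]["gene_id"]
        )
        assert set(truth.enriched_genes) <= annotated

    def test_presence_matrix_shape_and_focal_column(self):
        cfg = small_config()
        gene_ids = [f"g{i}" for i in range(30)]
        _, _, presence, _ = simulate_go_and_orthology(gene_ids, cfg)
        assert list(presence.index) == gene_ids
        assert presence["coelacanth"].all()
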