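"""Synthetic genomes with planted retrocopies and full ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-scaffold genome carrying multi-exon parent genes (plus a few
intronless genes, so the peptide set contains single-exon proteins), planted
retrocopies of controlled age (branch length t, in expected substitutions
per codon site) and dN/dS (omega) under a GY94-style codon model with equal
codon frequencies and kappa = 2, optional frameshifts and premature stop
codons, insertion into intergenic/intronic/exonic contexts,
intron-retaining DNA-based duplication decoys, soft repeat masking,
per-tissue expression counts with a testis bias, a small GO DAG with a
planted enriched term, and a cross-species ortholog presence/absence matrix.

Identical configurations (including the seed) yield byte-identical output
files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import formats
from .formats import GenomicInterval
from .parentalign import ParentInfo
from ._codon import (
    SENSE_CODONS,
    STOP_CODONS,
    evolve_codons,
    codons_of,
    translate,
)

TISSUES_DEFAULT = (
    "gills", "kidneys", "pectoral_fins", "pelvic_fins",
    "pharynx", "tail_muscle", "testis",
)

SPECIES_GROUPS = {
    "coelacanth": "focal",
    "elephant_shark": "fish",
    "fugu": "fish",
    "zebrafish": "fish",
    "gar": "fish",
    "clawed_frog": "tetrapod",
    "anole_lizard": "tetrapod",
    "zebra_finch": "tetrapod",
    "mouse": "tetrapod",
    "human": "tetrapod",
}

_STOPS = tuple(sorted(STOP_CODONS))


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Branch lengths are expected substitutions per codon site; the age and
    omega distributions are (value, weight) mixtures sampled independently
    per planted copy.  The default age mixture concentrates mass at small t
    (a burst of young copies) and the omega mixture below one, matching the
    regime the screen is built for.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 200_000
    n_parent_genes: int = 40
    exon_count_range: tuple[int, int] = (3, 7)
    n_single_exon_genes: int = 5
    n_retrocopies: int = 30
    age_distribution: tuple[tuple[float, float], ...] = (
        (0.05, 2.0), (0.1, 2.0), (0.2, 2.0), (0.3, 1.5),
        (0.4, 1.0), (0.6, 1.0), (0.8, 0.5),
    )
    omega_distribution: tuple[tuple[float, float], ...] = (
        (0.1, 3.0), (0.2, 2.0), (0.3, 2.0), (0.5, 2.0), (0.8, 1.0),
    )
    frameshift_prob: float = 0.3
    premature_stop_prob: float = 0.3
    insertion_context_probs: dict = dataclasses.field(
        default_factory=lambda: {"intergenic": 0.5, "intronic": 0.3, "exonic": 0.2}
    )
    n_dna_duplication_decoys: int = 5
    masked_fraction: float = 0.08
    tissues: tuple[str, ...] = TISSUES_DEFAULT
    testis_bias_factor: float = 3.0
    kappa: float = 2.0
    cds_codon_range: tuple[int, int] = (120, 320)
    intron_length_range: tuple[int, int] = (200, 1200)
    base_expression_prob: float = 0.08
    mean_expressed_count: float = 200.0
    nb_dispersion: float = 2.0
    library_size: int = 1_000_000
    enriched_set_size: int = 12

    def __post_init__(self) -> None:
        for name in ("frameshift_prob", "premature_stop_prob", "masked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_distribution", "omega_distribution"):
            for value, weight in getattr(self, name):
                if weight <= 0:
                    raise ConfigError(f"{name} weights must be positive")
                if value < 0 or (name == "omega_distribution" and value <= 0):
                    raise ConfigError(f"{name} values out of range")
        if self.exon_count_range[0] < 1:
            raise ConfigError("exon_count_range minimum must be >= 1")
        probs = self.insertion_context_probs
        if set(probs) != {"intergenic", "intronic", "exonic"}:
            raise ConfigError("insertion_context_probs needs the three context keys")
        if any(not 0 <= p <= 1 for p in probs.values()) or sum(probs.values()) <= 0:
            raise ConfigError("bad insertion context probabilities")
        if len(self.tissues) < 1:
            raise ConfigError("need at least one tissue")


@dataclasses.dataclass
class SyntheticTruth:
    copy_id: str
    true_parent_id: str
    true_t: float
    true_omega: float
    n_planted_frameshifts: int
    n_planted_stops: int
    insertion_context: str
    is_dna_duplication_decoy: bool
    locus: GenomicInterval | None = None
    insert_seq: str = ""


@dataclasses.dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]  # genome coords, 0-based half-open, sorted
    cds: str                      # spliced CDS including the stop codon
    intron_cds_offsets: tuple[int, ...]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def cds_nostop(self) -> str:
        return self.cds[:-3]

    @property
    def peptide(self) -> str:
        return translate(self.cds_nostop)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _sample_mixture(rng: np.random.Generator, mixture) -> float:
    values = [v for v, _ in mixture]
    weights = np.array([w for _, w in mixture], dtype=float)
    weights /= weights.sum()
    return float(values[rng.choice(len(values), p=weights)])


# ---------------------------------------------------------------------------
# parent genes


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal sense codons + one stop codon."""
    internal = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in internal) + stop


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    scaffold: str,
    start: int,
    strand: str,
    config: SimulationConfig,
    exon_count: int,
) -> tuple[GeneModel, str]:
    """Assemble one gene; returns the model and its genomic sequence."""
    lo, hi = config.cds_codon_range
    n_codons = int(rng.integers(lo, hi + 1))
    cds = _random_cds(rng, n_codons)
    total = len(cds)
    if exon_count > 1:
        min_exon = 45
        cuts = None
        for _ in range(200):
            trial = sorted(
                int(c) for c in rng.integers(min_exon, total - min_exon, size=exon_count - 1)
            )
            if all(b - a >= min_exon for a, b in zip([0] + trial, trial + [total])):
                cuts = trial
                break
        if cuts is None:  # fall back to even splits when the CDS is tight
            cuts = [round(total * k / exon_count) for k in range(1, exon_count)]
    else:
        cuts = []
    bounds = [0] + list(cuts) + [total]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    ilo, ihi = config.intron_length_range
    introns = [
        "GT" + _random_dna(rng, int(rng.integers(ilo, ihi + 1)) - 4) + "AG"
        for _ in range(exon_count - 1)
    ]
    # exon positions within the coding-orientation gene sequence
    pieces, exon_spans, pos = [], [], 0
    for k, ex in enumerate(exon_seqs):
        pieces.append(ex)
        exon_spans.append((pos, pos + len(ex)))
        pos += len(ex)
        if k < len(introns):
            pieces.append(introns[k])
            pos += len(introns[k])
    gene_seq = "".join(pieces)
    glen = len(gene_seq)
    if strand == "-":
        from Bio.Seq import Seq

        gene_seq = str(Seq(gene_seq).reverse_complement())
        exon_spans = [(glen - b, glen - a) for a, b in exon_spans]
        exon_spans.sort()
    exons = [(start + a, start + b) for a, b in exon_spans]
    model = GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        strand=strand,
        start=start,
        end=start + glen,
        exons=exons,
        cds=cds,
        intron_cds_offsets=tuple(cuts),
    )
    return model, gene_seq


def generate_parent_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], dict[str, str]]:
    """Generate the genome, gene models and peptide set.

    Multi-exon genes come first (``gene_0001`` ...), then intronless genes.
    Genes are laid out left to right with random intergenic spacers; after
    placement, intergenic blocks are soft-masked (lowercase) up to roughly
    ``masked_fraction`` of the genome.
    """
    rng = _rng(config, 1)
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    genome = {s: list(_random_dna(rng, config.scaffold_length)) for s in scaffolds}
    genes: list[GeneModel] = []
    n_total = config.n_parent_genes + config.n_single_exon_genes
    per_scaffold = int(np.ceil(n_total / config.n_scaffolds))
    gene_index = 0
    for scaffold in scaffolds:
        cursor = int(rng.integers(2000, 6000))
        for _ in range(per_scaffold):
            if gene_index >= n_total:
                break
            gene_id = f"gene_{gene_index + 1:04d}"
            if gene_index < config.n_parent_genes:
                exon_count = int(
                    rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1)
                )
            else:
                exon_count = 1
            strand = "+" if rng.random() < 0.5 else "-"
            model, gene_seq = _build_gene(
                rng, gene_id, scaffold, cursor, strand, config, exon_count
            )
            if model.end + 2000 > config.scaffold_length:
                raise ConfigError(
                    f"scaffold_length {config.scaffold_length} too short for the "
                    f"requested gene load on {scaffold}"
                )
            genome[scaffold][model.start : model.end] = list(gene_seq)
            genes.append(model)
            gene_index += 1
            cursor = model.end + int(rng.integers(3000, 9000))
    if gene_index < n_total:
        raise ConfigError("not enough scaffold space to host all requested genes")
    genome_str = {s: "".join(chars) for s, chars in genome.items()}
    genome_str = _apply_soft_masking(rng, genome_str, genes, config)
    peptides = {g.gene_id: g.peptide for g in genes}
    return genome_str, genes, peptides


def _apply_soft_masking(
    rng: np.random.Generator,
    genome: dict[str, str],
    genes: list[GeneModel],
    config: SimulationConfig,
) -> dict[str, str]:
    """Lowercase intergenic blocks until ~masked_fraction of bases are masked."""
    if config.masked_fraction <= 0:
        return genome
    total = sum(len(s) for s in genome.values())
    target = int(config.masked_fraction * total)
    margin = 500
    out = {s: list(seq) for s, seq in genome.items()}
    free: list[tuple[str, int, int]] = []
    for scaffold, seq in genome.items():
        spans = sorted(
            (g.start - margin, g.end + margin) for g in genes if g.scaffold == scaffold
        )
        cursor = 0
        for a, b in spans:
            if a - cursor > 2000:
                free.append((scaffold, cursor, a))
            cursor = max(cursor, b)
        if len(seq) - cursor > 2000:
            free.append((scaffold, cursor, len(seq)))
    masked = 0
    order = rng.permutation(len(free))
    for idx in order:
        if masked >= target:
            break
        scaffold, a, b = free[idx]
        # mask the middle half of the free block, leaving room for insertions
        width = min((b - a) // 2, target - masked)
        if width < 200:
            continue
        start = a + (b - a - width) // 2
        out[scaffold][start : start + width] = [
            c.lower() for c in out[scaffold][start : start + width]
        ]
        masked += width
    return {s: "".join(chars) for s, chars in out.items()}


# ---------------------------------------------------------------------------
# retrocopy evolution


def evolve_retrocopy(
    parent_cds: str,
    t: float,
    omega: float,
    frameshifts: int,
    stops: int,
    rng: np.random.Generator,
    kappa: float = 2.0,
) -> str:
    """Evolve a spliced CDS into a retrocopy sequence.

    Substitutions act codon-wise under the GY94-style process (rate
    multiplier omega on amino-acid-changing single-base steps, expected t
    substitutions per codon site); requested premature stop codons and
    1-2 nt frameshift indels are then injected.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    codons = codons_of(parent_cds[: len(parent_cds) - len(parent_cds) % 3])
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("parent CDS for evolution must be stop-free")
    evolved = evolve_codons(codons, t, omega, rng, kappa=kappa)
    n_codons = len(evolved)
    if stops > 0:
        if n_codons < stops + 2:
            raise ValueError("CDS too short for requested premature stops")
        positions = rng.choice(np.arange(1, n_codons - 1), size=stops, replace=False)
        for pos in positions:
            evolved[int(pos)] = _STOPS[rng.integers(0, len(_STOPS))]
    seq = "".join(evolved)
    for _ in range(frameshifts):
        size = int(rng.integers(1, 3))
        pos = int(rng.integers(6, len(seq) - 6))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + size :]
        else:
            seq = seq[:pos] + _random_dna(rng, size) + seq[pos:]
    return seq


# ---------------------------------------------------------------------------
# planting


def _shift_genes(genes: list[GeneModel], scaffold: str, pos: int, length: int) -> None:
    for g in genes:
        if g.scaffold != scaffold or g.end <= pos:
            continue
        if g.start >= pos:
            g.start += length
            g.end += length
            g.exons = [(a + length, b + length) for a, b in g.exons]
        else:  # insertion inside the gene span
            g.end += length
            new_exons = []
            for a, b in g.exons:
                if a >= pos:
                    new_exons.append((a + length, b + length))
                elif b > pos:  # insertion inside this exon
                    new_exons.append((a, b + length))
                else:
                    new_exons.append((a, b))
            g.exons = new_exons


def _pick_insertion_site(
    rng: np.random.Generator,
    genome: dict[str, str],
    genes: list[GeneModel],
    context: str,
) -> tuple[str, int]:
    if context in ("intronic", "exonic"):
        candidates = [g for g in genes if g.exon_count >= (2 if context == "intronic" else 1)]
        if not candidates:
            raise ConfigError(f"no gene available for {context} insertion")
        for _ in range(200):
            g = candidates[int(rng.integers(0, len(candidates)))]
            if context == "intronic":
                introns = [
                    (b0, a1)
                    for (_, b0), (a1, _) in zip(g.exons, g.exons[1:])
                    if a1 - b0 > 20
                ]
                if not introns:
                    continue
                a, b = introns[int(rng.integers(0, len(introns)))]
                return g.scaffold, int(rng.integers(a + 5, b - 5))
            exons = [(a, b) for a, b in g.exons if b - a > 20]
            if not exons:
                continue
            a, b = exons[int(rng.integers(0, len(exons)))]
            return g.scaffold, int(rng.integers(a + 5, b - 5))
        raise ConfigError(f"could not find a {context} insertion site")
    # intergenic: unmasked background away from genes
    scaffolds = sorted(genome)
    for _ in range(500):
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        seq = genome[scaffold]
        pos = int(rng.integers(1000, len(seq) - 1000))
        margin = 100
        window = seq[pos - margin : pos + margin]
        if window != window.upper():
            continue
        if any(
            g.scaffold == scaffold and g.start - margin < pos < g.end + margin
            for g in genes
        ):
            continue
        return scaffold, pos
    raise ConfigError("could not find an intergenic insertion site")


def plant_retrocopies(
    genome: dict[str, str],
    genes: list[GeneModel],
    truths: Sequence[SyntheticTruth],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[SyntheticTruth]]:
    """Insert prepared copy sequences into the genome.

    Each truth carries its insert sequence and requested context; insertion
    shifts downstream gene/exon coordinates and previously planted loci
    consistently, and genome length grows by exactly the summed insert
    lengths.
    """
    genome = dict(genome)
    placed: list[SyntheticTruth] = []
    for truth in truths:
        for _ in range(100):
            scaffold, pos = _pick_insertion_site(rng, genome, genes, truth.insertion_context)
            clear = all(
                not (p.locus.scaffold == scaffold
                     and p.locus.start - 50 < pos < p.locus.end + 50)
                for p in placed
            )
            if clear:
                break
        else:
            raise ConfigError("could not place a copy away from earlier insertions")
        seq = truth.insert_seq
        if rng.random() < 0.5:
            from Bio.Seq import Seq

            seq = str(Seq(seq).reverse_complement())
            strand = "-"
        else:
            strand = "+"
        genome[scaffold] = genome[scaffold][:pos] + seq + genome[scaffold][pos:]
        _shift_genes(genes, scaffold, pos, len(seq))
        for prev in placed:
            if prev.locus.scaffold == scaffold and prev.locus.start >= pos:
                prev.locus = GenomicInterval(
                    scaffold, prev.locus.start + len(seq),
                    prev.locus.end + len(seq), prev.locus.strand,
                )
        truth.locus = GenomicInterval(scaffold, pos, pos + len(seq), strand)
        placed.append(truth)
    return genome, list(truths)


def truth_table(truths: Iterable[SyntheticTruth]) -> pd.DataFrame:
    rows = [
        {
            "copy_id": t.copy_id,
            "true_parent_id": t.true_parent_id,
            "true_t": t.true_t,
            "true_omega": t.true_omega,
            "n_planted_frameshifts": t.n_planted_frameshifts,
            "n_planted_stops": t.n_planted_stops,
            "insertion_context": t.insertion_context,
            "is_dna_duplication_decoy": t.is_dna_duplication_decoy,
            "scaffold": t.locus.scaffold if t.locus else "",
            "start": t.locus.start if t.locus else -1,
            "end": t.locus.end if t.locus else -1,
            "strand": t.locus.strand if t.locus else ".",
        }
        for t in truths
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truths: Sequence[SyntheticTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-copy, per-tissue fragment counts with age- and testis-dependence.

    The probability that a copy is expressed in a tissue increases with the
    copy's age rank and is multiplied by ``testis_bias_factor`` in the last
    (testis) column; expressed entries draw overdispersed negative-binomial
    counts.  Returns the counts table and per-tissue library sizes.
    """
    if len(set(config.tissues)) != len(config.tissues):
        raise ConfigError("duplicate tissue names")
    rng = rng if rng is not None else _rng(config, 3)
    non_decoy = [t for t in truths if not t.is_dna_duplication_decoy]
    order = np.argsort([t.true_t for t in non_decoy], kind="stable")
    rank = {non_decoy[int(i)].copy_id: r for r, i in enumerate(order)}
    n = max(len(non_decoy) - 1, 1)
    counts = np.zeros((len(truths), len(config.tissues)), dtype=int)
    for i, truth in enumerate(truths):
        frac = rank.get(truth.copy_id, 0) / n
        base = config.base_expression_prob * (0.5 + frac)
        for j, _tissue in enumerate(config.tissues):
            p = base * (config.testis_bias_factor if j == len(config.tissues) - 1 else 1.0)
            p = min(p, 1.0)
            if rng.random() < p:
                mu = config.mean_expressed_count * float(rng.lognormal(0.0, 0.8))
                r = config.nb_dispersion
                counts[i, j] = rng.negative_binomial(r, r / (r + mu)) + 1
    df = pd.DataFrame(
        counts, index=[t.copy_id for t in truths], columns=list(config.tissues)
    )
    df.index.name = "copy_id"
    lib = pd.Series(
        [config.library_size] * len(config.tissues),
        index=list(config.tissues),
        name="library_size",
    )
    return df, lib


# ---------------------------------------------------------------------------
# GO and orthology


@dataclasses.dataclass
class GoTruth:
    enriched_term: str
    enriched_genes: tuple[str, ...]


_GO_LEVEL2 = ["GO:0000002", "GO:0000003", "GO:0000004", "GO:0000005"]
_GO_LEAVES = [f"GO:00000{i:02d}" for i in range(10, 18)]
GO_ROOT = "GO:0000001"


def _obo_text() -> str:
    blocks = ["format-version: 1.2\nontology: synthetic_mini\n"]
    blocks.append(
        f"[Term]\nid: {GO_ROOT}\nname: biological_process root (synthetic)\n"
        "namespace: biological_process\n"
    )
    for term in _GO_LEVEL2:
        blocks.append(
            f"[Term]\nid: {term}\nname: synthetic mid-level process {term[-2:]}\n"
            f"namespace: biological_process\nis_a: {GO_ROOT}\n"
        )
    for i, term in enumerate(_GO_LEAVES):
        parent = _GO_LEVEL2[i % len(_GO_LEVEL2)]
        blocks.append(
            f"[Term]\nid: {term}\nname: synthetic leaf process {term[-2:]}\n"
            f"namespace: biological_process\nis_a: {parent}\n"
        )
    return "\n".join(blocks)


def simulate_go_and_orthology(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, str, pd.DataFrame, GoTruth]:
    """Gene-to-GO annotations, a mini OBO ontology, and a presence matrix.

    Annotations for a designated gene subset concentrate in one designated
    leaf term (the planted enrichment); the presence/absence matrix labels
    species with the focal/fish/tetrapod groups used by the lineage
    classification.
    """
    rng = rng if rng is not None else _rng(config, 4)
    gene_ids = list(gene_ids)
    # the planted subset must be a proper subset of the universe or there is
    # no enrichment to recover
    k = max(1, min(config.enriched_set_size, len(gene_ids) // 3))
    enriched_genes = tuple(
        sorted(
            np.array(gene_ids)[rng.choice(len(gene_ids), size=k, replace=False)].tolist()
        )
    )
    enriched_term = _GO_LEAVES[0]
    other_leaves = _GO_LEAVES[1:]
    rows = []
    for gene in gene_ids:
        n_terms = int(rng.integers(1, 4))
        terms = set(
            np.array(other_leaves)[
                rng.choice(len(other_leaves), size=n_terms, replace=False)
            ].tolist()
        )
        if gene in enriched_genes:
            terms.add(enriched_term)
        elif rng.random() < 0.05:
            terms.add(enriched_term)
        for term in sorted(terms):
            rows.append({"gene_id": gene, "go_id": term})
    gene2go = pd.DataFrame(rows)

    species = list(SPECIES_GROUPS)
    presence = pd.DataFrame(False, index=gene_ids, columns=species)
    presence["coelacanth"] = True
    for gene in gene_ids:
        u = rng.random()
        if u < 0.15:
            pass  # lineage-specific: absent in every non-focal species
        elif u < 0.25:
            fish = [s for s, g in SPECIES_GROUPS.items() if g == "fish"]
            chosen = rng.choice(len(fish), size=int(rng.integers(1, len(fish) + 1)),
                                replace=False)
            for i in chosen:
                presence.loc[gene, fish[int(i)]] = True
        else:
            for s in species[1:]:
                presence.loc[gene, s] = bool(rng.random() < 0.85)
    presence.index.name = "gene_id"
    return gene2go, _obo_text(), presence, GoTruth(enriched_term, enriched_genes)


# ---------------------------------------------------------------------------
# dataset driver and writers


@dataclasses.dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    peptides: dict[str, str]
    parents: dict[str, ParentInfo]
    truths: list[SyntheticTruth]
    counts: pd.DataFrame
    library_sizes: pd.Series
    gene2go: pd.DataFrame
    obo_text: str
    presence: pd.DataFrame
    go_truth: GoTruth


def parent_info_of(gene: GeneModel) -> ParentInfo:
    return ParentInfo(
        peptide_id=gene.gene_id,
        peptide=gene.peptide,
        cds=gene.cds_nostop,
        exon_count=gene.exon_count,
        intron_cds_offsets=gene.intron_cds_offsets,
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every simulation stage in order with seed-derived substreams."""
    genome, genes, peptides = generate_parent_genes(config)
    rng = _rng(config, 2)
    multi_exon = [g for g in genes if g.exon_count >= 3]
    if len(multi_exon) < config.n_retrocopies + config.n_dna_duplication_decoys:
        raise ConfigError(
            "not enough multi-exon genes for the requested copies and decoys"
        )
    chosen = rng.choice(
        len(multi_exon),
        size=config.n_retrocopies + config.n_dna_duplication_decoys,
        replace=False,
    )
    truths: list[SyntheticTruth] = []
    for i in range(config.n_retrocopies):
        parent = multi_exon[int(chosen[i])]
        t = _sample_mixture(rng, config.age_distribution)
        omega = _sample_mixture(rng, config.omega_distribution)
        n_fs = int(rng.random() < config.frameshift_prob)
        n_stop = int(rng.random() < config.premature_stop_prob)
        seq = evolve_retrocopy(
            parent.cds_nostop, t, omega, n_fs, n_stop, rng, kappa=config.kappa
        )
        context = _sample_context(rng, config)
        truths.append(
            SyntheticTruth(
                copy_id=f"retro_{i + 1:03d}",
                true_parent_id=parent.gene_id,
                true_t=t,
                true_omega=omega,
                n_planted_frameshifts=n_fs,
                n_planted_stops=n_stop,
                insertion_context=context,
                is_dna_duplication_decoy=False,
                insert_seq=seq + parent.cds[-3:],
            )
        )
    for i in range(config.n_dna_duplication_decoys):
        parent = multi_exon[int(chosen[config.n_retrocopies + i])]
        gene_seq = genome[parent.scaffold][parent.start : parent.end]
        truths.append(
            SyntheticTruth(
                copy_id=f"decoy_{i + 1:03d}",
                true_parent_id=parent.gene_id,
                true_t=0.0,
                true_omega=1.0,
                n_planted_frameshifts=0,
                n_planted_stops=0,
                insertion_context="intergenic",
                is_dna_duplication_decoy=True,
                insert_seq=gene_seq.upper(),
            )
        )
    genome, truths = plant_retrocopies(genome, genes, truths, rng)
    counts, lib = simulate_expression(truths, config)
    gene2go, obo, presence, go_truth = simulate_go_and_orthology(
        [g.gene_id for g in genes], config
    )
    parents = {g.gene_id: parent_info_of(g) for g in genes}
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        peptides=peptides,
        parents=parents,
        truths=truths,
        counts=counts,
        library_sizes=lib,
        gene2go=gene2go,
        obo_text=obo,
        presence=presence,
        go_truth=go_truth,
    )


def _sample_context(rng: np.random.Generator, config: SimulationConfig) -> str:
    keys = ["intergenic", "intronic", "exonic"]
    probs = np.array([config.insertion_context_probs[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return keys[int(rng.choice(3, p=probs))]


def gene_models_to_gff3(genes: Iterable[GeneModel]) -> list[tuple]:
    rows = []
    for g in genes:
        attrs = f"ID={g.gene_id}"
        rows.append((g.scaffold, "retroscan_sim", "gene", g.start, g.end, ".", g.strand, ".", attrs))
        rows.append(
            (g.scaffold, "retroscan_sim", "mRNA", g.start, g.end, ".", g.strand, ".",
             f"ID={g.gene_id}.t1;Parent={g.gene_id}")
        )
        for k, (a, b) in enumerate(g.exons):
            rows.append(
                (g.scaffold, "retroscan_sim", "exon", a, b, ".", g.strand, ".",
                 f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}.t1")
            )
    return rows


def write_dataset(data: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artefact of a dataset; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "peptides": outdir / "peptides.fa",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "counts": outdir / "counts.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "gene2go": outdir / "gene2go.tsv",
        "obo": outdir / "ontology.obo",
        "presence": outdir / "presence.tsv",
        "parents": outdir / "parents.tsv",
    }
    formats.write_fasta(data.genome, paths["genome"])
    formats.write_fasta(data.peptides, paths["peptides"])
    formats.write_gff3(gene_models_to_gff3(data.genes), paths["genes"])
    formats.write_tsv(truth_table(data.truths), paths["truth"])
    data.counts.reset_index().to_csv(paths["counts"], sep="\t", index=False)
    data.library_sizes.reset_index().to_csv(
        paths["library_sizes"], sep="\t", index=False, header=["tissue", "library_size"]
    )
    formats.write_tsv(data.gene2go, paths["gene2go"])
    paths["obo"].write_text(data.obo_text)
    with open(paths["presence"], "w") as fh:
        fh.write("#group\t" + "\t".join(SPECIES_GROUPS[s] for s in data.presence.columns) + "\n")
        data.presence.reset_index().to_csv(fh, sep="\t", index=False)
    parents_df = pd.DataFrame(
        [
            {
                "peptide_id": p.peptide_id,
                "exon_count": p.exon_count,
                "cds": p.cds,
                "intron_cds_offsets": ",".join(str(o) for o in p.intron_cds_offsets),
            }
            for p in data.parents.values()
        ]
    )
    formats.write_tsv(parents_df, paths["parents"])
    return paths
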