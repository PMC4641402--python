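"""Config-driven orchestration of the retrocopy pipeline.

Stages run in screening -> parent alignment -> evolutionary statistics ->
annotation overlap -> expression -> GO enrichment -> orthology order, each
writing its table into the output directory.  The run manifest records the
config hash, seed, version and per-stage record counts, so filter attrition
is auditable, plus the four functionality criteria (intact ORF, omega
significantly < 0.5, gene overlap, expression) and all 16 regions of their
Venn partition.

In synthetic mode the input bundle is generated first (with ground truth);
in real-input mode every input is read from the configured paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, annotmap, evomodel, exprstats, formats, goenrich, ortho
from . import hitsearch, parentalign, syndata
from .formats import GenomicInterval


class InputError(ValueError):
    """A missing or malformed pipeline input; names the failing stage."""


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "retroscan_out"
    mode: str = "synthetic"  # synthetic | real-input
    seed: int = 0
    # screening
    merge_gap: int = 40
    screen_min_len_aa: int = 50
    screen_min_identity: float = 30.0
    word_size: int = 4
    xdrop: float = 20.0
    min_score: float = 50.0
    # parent alignment
    flank: int = 10000
    final_min_len_aa: int = 50
    final_min_identity: float = 70.0
    frameshift_penalty: float = 15.0
    intron_open: float = 20.0
    min_intron_len: int = 30
    intron_mode: str = "parent_spanned"
    # evolutionary statistics
    omega0: float = 0.5
    q_threshold: float = 0.05
    kappa: float = 2.0
    # expression
    fpkm_threshold: float = 0.0
    bin_width: float = 0.2
    young_cutoff: float = 0.6
    # GO
    go_alpha: float = 0.01
    # synthetic generator overrides ({} -> SimulationConfig defaults + seed)
    sim: dict = dataclasses.field(default_factory=dict)
    # real-input paths (unused in synthetic mode)
    genome_path: str = ""
    peptides_path: str = ""
    parents_path: str = ""
    gff3_path: str = ""
    hits_path: str = ""
    counts_path: str = ""
    library_sizes_path: str = ""
    gene2go_path: str = ""
    obo_path: str = ""
    presence_path: str = ""
    truth_path: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real-input"):
            raise InputError(f"unknown run mode {self.mode!r}")
        for name in ("merge_gap", "screen_min_len_aa", "final_min_len_aa", "flank"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # the output location is not a run parameter
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sim_config(config: PipelineConfig) -> syndata.SimulationConfig:
    kwargs = dict(config.sim)
    kwargs.setdefault("seed", config.seed)
    kwargs.setdefault("kappa", config.kappa)
    if "insertion_context_probs" in kwargs:
        kwargs["insertion_context_probs"] = dict(kwargs["insertion_context_probs"])
    for key in ("age_distribution", "omega_distribution", "tissues",
                "exon_count_range", "cds_codon_range", "intron_length_range"):
        if key in kwargs:
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, (list, tuple)) else v for v in kwargs[key]
            )
    return syndata.SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# stage functions (library API; the CLI wraps these)


def stage_screen(
    peptides: dict[str, str],
    genome: dict[str, str],
    config: PipelineConfig,
    hits: list[hitsearch.TranslatedHit] | None = None,
) -> tuple[list[hitsearch.TranslatedHit], list[hitsearch.CandidateLocus], dict]:
    if hits is None:
        params = hitsearch.SearchParams(
            word_size=config.word_size, xdrop=config.xdrop, min_score=config.min_score
        )
        hits = hitsearch.search_translated(peptides, genome, params)
    merged = hitsearch.merge_adjacent_hits(hits, max_gap=config.merge_gap)
    filtered = hitsearch.filter_candidate_loci(
        merged, config.screen_min_len_aa, config.screen_min_identity
    )
    resolved = hitsearch.resolve_overlaps(filtered)
    counts = {
        "hits": len(hits),
        "merged_loci": len(merged),
        "filtered_loci": len(filtered),
        "resolved_loci": len(resolved),
    }
    return hits, resolved, counts


def stage_align(
    loci: list[hitsearch.CandidateLocus],
    parents: dict[str, parentalign.ParentInfo],
    genome: dict[str, str],
    config: PipelineConfig,
) -> tuple[list[parentalign.ParentRetroPair], dict]:
    params = parentalign.AlignParams(
        frameshift_penalty=config.frameshift_penalty,
        intron_open=config.intron_open,
        min_intron_len=config.min_intron_len,
    )
    decisions = []
    alignments: list[tuple[str, parentalign.ProteinGenomeAlignment]] = []
    n_dna_dup = n_no_parent = n_failed = 0
    for k, locus in enumerate(loci):
        retro_id = f"retro_{k + 1:04d}"
        decision = parentalign.rank_parent_candidates(locus, parents, genome, params)
        decisions.append((retro_id, decision))
        if decision.reason == "dna_duplication":
            n_dna_dup += 1
            continue
        if decision.reason == "no_parent":
            n_no_parent += 1
            continue
        window = parentalign.expand_flanks(
            locus.interval, len(genome[locus.interval.scaffold]), config.flank
        )
        aln = parentalign.realign_locus(
            retro_id, parents[decision.parent_id], window, genome, params
        )
        if aln is None:
            n_failed += 1
            continue
        alignments.append((retro_id, aln))
    pairs = parentalign.apply_final_filters(
        alignments, parents,
        min_len_aa=config.final_min_len_aa,
        min_identity=config.final_min_identity,
        intron_mode=config.intron_mode,
    )
    deduped = parentalign.dedupe_shared_parents(pairs)
    counts = {
        "parent_assigned": len(alignments) + n_failed,
        "dna_duplication_discarded": n_dna_dup,
        "no_parent": n_no_parent,
        "alignment_failed": n_failed,
        "passed_final_filters": len(pairs),
        "pairs_one_to_one": len(deduped),
    }
    return deduped, counts


def stage_evolve(
    pairs: list[parentalign.ParentRetroPair], config: PipelineConfig
) -> list[evomodel.EvoStats]:
    records = []
    for pair in pairs:
        intact, n_fs, n_stops = evomodel.check_intact_orf(pair.alignment)
        rec = evomodel.EvoStats(
            retro_id=pair.retro_id,
            parent_id=pair.parent_id,
            dN=math.nan, dS=math.nan, omega=math.nan,
            S_sites=0.0, N_sites=0.0,
            ds_defined=False, dn_defined=False, omega_defined=False,
            intact=intact, n_frameshifts=n_fs, n_premature_stops=n_stops,
        )
        aln = evomodel.build_codon_alignment(pair)
        try:
            est = evomodel.estimate_dnds(aln)
            rec.dN, rec.dS, rec.omega = est["dN"], est["dS"], est["omega"]
            rec.S_sites, rec.N_sites = est["S_sites"], est["N_sites"]
            rec.ds_defined = est["ds_defined"]
            rec.dn_defined = est["dn_defined"]
            rec.omega_defined = est["omega_defined"]
            lrt = evomodel.lrt_fixed_omega(aln, omega0=config.omega0, kappa=config.kappa)
            rec.lnL_null, rec.lnL_alt = lrt["lnL_null"], lrt["lnL_alt"]
            rec.lrt_stat, rec.p_lrt = lrt["lrt_stat"], lrt["p"]
        except evomodel.InsufficientDataError:
            pass
        records.append(rec)
    qs = evomodel.bh_fdr([r.p_lrt for r in records])
    for rec, q in zip(records, qs):
        rec.q_fdr = float(q)
    evomodel.call_significant_purifying(
        records, omega_threshold=config.omega0, q_threshold=config.q_threshold
    )
    return records


def _truth_loci(truth_df: pd.DataFrame) -> list[tuple[str, GenomicInterval]]:
    out = []
    for row in truth_df.itertuples(index=False):
        if row.start >= 0:
            out.append(
                (row.copy_id,
                 GenomicInterval(row.scaffold, int(row.start), int(row.end),
                                 row.strand if row.strand in "+-" else "+"))
            )
    return out


def match_loci_to_truth(
    pairs: list[parentalign.ParentRetroPair], truth_df: pd.DataFrame
) -> dict[str, str]:
    """Map each detected retrocopy to the planted copy it best overlaps."""
    truth = _truth_loci(truth_df)
    mapping = {}
    for pair in pairs:
        iv = pair.alignment.locus
        best, best_ov = None, 0
        for copy_id, tiv in truth:
            if tiv.overlaps(iv):
                ov = min(iv.end, tiv.end) - max(iv.start, tiv.start)
                if ov > best_ov:
                    best, best_ov = copy_id, ov
        if best is not None:
            mapping[pair.retro_id] = best
    return mapping


def stage_express(
    pairs: list[parentalign.ParentRetroPair],
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    config: PipelineConfig,
    truth_df: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM and expression profiles for the detected pairs.

    With a truth table (synthetic mode) counts are joined through the
    planted copy overlapping each detected locus; otherwise the counts table
    must be indexed by retro id.
    """
    idx = [p.retro_id for p in pairs]
    joined = pd.DataFrame(0, index=idx, columns=counts.columns, dtype=float)
    if truth_df is not None:
        mapping = match_loci_to_truth(pairs, truth_df)
        for rid, cid in mapping.items():
            if cid in counts.index:
                joined.loc[rid] = counts.loc[cid]
    else:
        shared = [i for i in idx if i in counts.index]
        joined.loc[shared] = counts.loc[shared].astype(float)
    lengths = pd.Series(
        {p.retro_id: p.alignment.locus.length for p in pairs}, dtype=float
    )
    fpkm = exprstats.compute_fpkm(joined, lengths, library_sizes)
    profiles = exprstats.expression_calls(fpkm, threshold=config.fpkm_threshold)
    return fpkm, profiles


def report_venn(flags: pd.DataFrame) -> tuple[dict[str, int], dict[str, int]]:
    """All 16 region counts of the four functionality criteria.

    ``flags`` has boolean columns intact, significant_purifying,
    gene_overlapped, expressed.  Region keys are 4-bit strings in that
    column order; also returns summary counts (per-criterion totals, union,
    intersection).
    """
    cols = ["intact", "significant_purifying", "gene_overlapped", "expressed"]
    regions = {
        "".join(bits): 0 for bits in
        (format(i, "04b") for i in range(16))
    }
    for row in flags[cols].itertuples(index=False):
        key = "".join("1" if v else "0" for v in row)
        regions[key] += 1
    any_flag = flags[cols].any(axis=1)
    all_flags = flags[cols].all(axis=1)
    summary = {
        "total": len(flags),
        **{f"n_{c}": int(flags[c].sum()) for c in cols},
        "union": int(any_flag.sum()),
        "intersection": int(all_flags.sum()),
    }
    return regions, summary


# ---------------------------------------------------------------------------
# full run


def _load_real_inputs(config: PipelineConfig) -> dict[str, Any]:
    def need(path: str, stage: str) -> str:
        if not path or not Path(path).exists():
            raise InputError(f"stage {stage}: missing input {path!r}")
        return path

    genome = formats.read_fasta(need(config.genome_path, "screen"))
    peptides = formats.read_fasta(need(config.peptides_path, "screen"))
    parents_df = formats.read_tsv(need(config.parents_path, "align"))
    parents = {}
    for row in parents_df.itertuples(index=False):
        offsets = tuple(
            int(x) for x in str(row.intron_cds_offsets).split(",") if x not in ("", "nan")
        )
        cds = str(row.cds)
        parents[str(row.peptide_id)] = parentalign.ParentInfo(
            peptide_id=str(row.peptide_id),
            peptide=str(getattr(row, "peptide", "")) or _translate_cds(cds),
            cds=cds,
            exon_count=int(row.exon_count),
            intron_cds_offsets=offsets,
        )
    out = {
        "genome": genome,
        "peptides": peptides,
        "parents": parents,
        "genes_gff3": need(config.gff3_path, "overlap"),
        "counts": formats.read_tsv(need(config.counts_path, "express")).set_index("copy_id"),
        "library_sizes": formats.read_tsv(
            need(config.library_sizes_path, "express")
        ).set_index("tissue")["library_size"],
        "gene2go": goenrich.read_gene2go(need(config.gene2go_path, "go")),
        "obo": need(config.obo_path, "go"),
        "presence": need(config.presence_path, "ortho"),
        "truth": formats.read_tsv(config.truth_path) if config.truth_path else None,
        "hits": (
            hitsearch.import_tabular_hits(config.hits_path)
            if config.hits_path else None
        ),
    }
    return out


def _translate_cds(cds: str) -> str:
    from ._codon import translate

    return translate(cds)


STAGE_ORDER = ("screen", "align", "evolve", "overlap", "express", "go", "ortho")


def run_pipeline(config: PipelineConfig, upto: str | None = None) -> dict[str, Any]:
    """Execute the stages in order; returns the result bundle.

    ``upto`` stops after the named stage (one of STAGE_ORDER), writing the
    partial manifest.  Writes all stage tables plus ``manifest.json`` under
    ``config.outdir``.  Identical configs (and seeds) produce byte-identical
    output trees.
    """
    if upto is not None and upto not in STAGE_ORDER:
        raise InputError(f"unknown stage {upto!r}; expected one of {STAGE_ORDER}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
    }

    if config.mode == "synthetic":
        data = syndata.simulate_dataset(_sim_config(config))
        input_paths = syndata.write_dataset(data, outdir / "inputs")
        genome, peptides, parents = data.genome, data.peptides, data.parents
        genes_gff3 = input_paths["genes"]
        counts, library_sizes = data.counts, data.library_sizes
        gene2go = {
            g: set(sub["go_id"]) for g, sub in data.gene2go.groupby("gene_id")
        }
        obo_path, presence_path = input_paths["obo"], input_paths["presence"]
        truth_df = syndata.truth_table(data.truths)
        external_hits = None
        manifest["stages"]["simulate"] = {
            "genes": len(data.genes),
            "planted_copies": sum(1 for t in data.truths if not t.is_dna_duplication_decoy),
            "decoys": sum(1 for t in data.truths if t.is_dna_duplication_decoy),
        }
    else:
        inputs = _load_real_inputs(config)
        genome, peptides, parents = inputs["genome"], inputs["peptides"], inputs["parents"]
        genes_gff3 = inputs["genes_gff3"]
        counts, library_sizes = inputs["counts"], inputs["library_sizes"]
        gene2go, obo_path, presence_path = inputs["gene2go"], inputs["obo"], inputs["presence"]
        truth_df = inputs["truth"]
        external_hits = inputs["hits"]

    def _finish(partial: dict[str, Any]) -> dict[str, Any]:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        partial["manifest"] = manifest
        return partial

    # screening
    hits, loci, screen_counts = stage_screen(peptides, genome, config, external_hits)
    manifest["stages"]["screen"] = screen_counts
    hitsearch.export_tabular_hits(hits, outdir / "hits.tsv")
    formats.write_bed(
        [(c.interval, f"locus_{k + 1:04d}") for k, c in enumerate(loci)],
        outdir / "candidate_loci.bed",
    )
    formats.write_tsv(hitsearch.loci_table(loci), outdir / "candidate_loci.tsv")
    if upto == "screen":
        return _finish({"hits": hits, "loci": loci})

    # parent alignment
    pairs, align_counts = stage_align(loci, parents, genome, config)
    manifest["stages"]["align"] = align_counts
    formats.write_tsv(parentalign.pairs_table(pairs), outdir / "pairs.tsv")
    formats.write_gff3(
        [
            (p.alignment.locus.scaffold, "retroscan", "retrocopy",
             p.alignment.locus.start, p.alignment.locus.end, ".",
             p.alignment.locus.strand, ".",
             f"ID={p.retro_id};parent_gene={p.parent_id}")
            for p in pairs
        ],
        outdir / "retrocopies.gff3",
    )
    if upto == "align":
        return _finish({"hits": hits, "loci": loci, "pairs": pairs})

    # evolutionary statistics
    records = stage_evolve(pairs, config)
    manifest["stages"]["evolve"] = {
        "pairs": len(records),
        "intact": sum(r.intact for r in records),
        "significant_purifying": sum(r.significant_purifying for r in records),
        "ds_undefined": sum(not r.ds_defined for r in records),
    }
    formats.write_tsv(evomodel.stats_table(records), outdir / "evostats.tsv")
    if upto == "evolve":
        return _finish({"pairs": pairs, "records": records})

    # annotation overlap
    genes = annotmap.read_gene_models(genes_gff3)
    retro_loci = [(p.retro_id, p.alignment.locus) for p in pairs]
    calls = annotmap.map_retro_to_genes(retro_loci, genes)
    overlap_summary = annotmap.summarize_overlap(calls)
    manifest["stages"]["overlap"] = overlap_summary
    formats.write_tsv(annotmap.overlap_table(calls), outdir / "overlap.tsv")
    if upto == "overlap":
        return _finish({"pairs": pairs, "records": records, "calls": calls})

    # expression
    fpkm, profiles = stage_express(pairs, counts, library_sizes, config, truth_df)
    manifest["stages"]["express"] = {
        "expressed": int(profiles["expressed"].sum()),
    }
    fpkm.rename_axis("retro_id").reset_index().to_csv(
        outdir / "fpkm.tsv", sep="\t", index=False
    )
    profiles.rename_axis("retro_id").reset_index().to_csv(
        outdir / "expression_profiles.tsv", sep="\t", index=False
    )

    # combined per-retrocopy record table and expression statistics
    call_by_id = {c.retro_id: c for c in calls}
    rec_rows = []
    for rec in records:
        call = call_by_id[rec.retro_id]
        prof = profiles.loc[rec.retro_id]
        rec_rows.append(
            {
                "retro_id": rec.retro_id,
                "parent_id": rec.parent_id,
                "dN": rec.dN, "dS": rec.dS, "dN_dS": rec.omega,
                "p_lrt": rec.p_lrt, "q_fdr": rec.q_fdr,
                "intact": rec.intact,
                "significant_purifying": rec.significant_purifying,
                "overlap_class": call.overlap_class,
                "gene_overlapped": call.overlap_class != "none",
                "expressed": bool(prof["expressed"]),
                "expression_frequency": int(prof["expression_frequency"]),
                "mean_log_fpkm": float(prof["mean_log_fpkm"]),
            }
        )
    rec_df = pd.DataFrame(rec_rows)
    formats.write_tsv(rec_df, outdir / "records.tsv")

    if len(rec_df):
        binned, frac_young = exprstats.bin_by_ds(
            rec_df, bin_width=config.bin_width, young_cutoff=config.young_cutoff
        )
        formats.write_tsv(binned, outdir / "ds_bins.tsv")
        ds = rec_df.set_index("retro_id")["dS"]
        om = rec_df.set_index("retro_id")["dN_dS"]
        formats.write_tsv(
            exprstats.tissue_bias_tables(profiles, fpkm, ds, om, config.fpkm_threshold),
            outdir / "tissue_bias.tsv",
        )
        formats.write_tsv(
            exprstats.expression_frequency_table(profiles, fpkm, ds, om),
            outdir / "expression_frequency.tsv",
        )
        assoc = {}
        for crit in ("intact", "significant_purifying", "gene_overlapped"):
            chi2_val, p = exprstats.chisq_association(
                rec_df["expressed"], rec_df[crit]
            )
            assoc[crit] = {"chi2": round(chi2_val, 4), "p": p}
        manifest["stages"]["express"]["chisq_vs_expressed"] = assoc
        manifest["stages"]["express"]["fraction_young_ds"] = (
            None if math.isnan(frac_young) else round(frac_young, 4)
        )
    if upto == "express":
        return _finish(
            {"pairs": pairs, "records": records, "calls": calls,
             "profiles": profiles, "fpkm": fpkm, "record_table": rec_df}
        )

    # GO enrichment: parent genes vs retrocopy-overlapped genes
    dag = goenrich.load_ontology(obo_path)
    closure = goenrich.propagate_annotations(gene2go, dag)
    universe = sorted(gene2go)
    overlapped_genes = sorted(
        {g for c in calls for g in c.overlapped_gene_ids if g in gene2go}
    )
    parent_genes = sorted({r.parent_id for r in records if r.parent_id in gene2go})
    go_results = {}
    for label, test_set in (("parent", parent_genes), ("overlapped", overlapped_genes)):
        results = (
            goenrich.fisher_enrichment(test_set, universe, closure, dag, config.go_alpha)
            if test_set else []
        )
        go_results[label] = results
        formats.write_tsv(
            goenrich.enrichment_table(results), outdir / f"go_{label}.tsv"
        )
    manifest["stages"]["go"] = {
        label: len(res) for label, res in go_results.items()
    }
    if upto == "go":
        return _finish(
            {"pairs": pairs, "records": records, "calls": calls,
             "profiles": profiles, "fpkm": fpkm, "record_table": rec_df,
             "go": go_results}
        )

    # orthology
    presence, groups = ortho.read_presence_matrix(presence_path)
    all_overlapped = sorted({g for c in calls for g in c.overlapped_gene_ids})
    sub = presence.loc[[g for g in all_overlapped if g in presence.index]]
    specific = ortho.classify_lineage_specific(sub, groups)
    lost = ortho.classify_tetrapod_lost(sub, groups)
    manifest["stages"]["ortho"] = {
        "overlapped_genes": len(sub),
        "coelacanth_specific": len(specific),
        "tetrapod_lost": len(lost),
    }
    (outdir / "ortho_specific.txt").write_text("".join(f"{g}\n" for g in sorted(specific)))
    (outdir / "ortho_lost.txt").write_text("".join(f"{g}\n" for g in sorted(lost)))

    # venn
    regions, venn_summary = report_venn(rec_df) if len(rec_df) else report_venn(
        pd.DataFrame(columns=["intact", "significant_purifying",
                              "gene_overlapped", "expressed"])
    )
    manifest["venn_regions"] = regions
    manifest["venn_summary"] = venn_summary

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "manifest": manifest,
        "pairs": pairs,
        "records": records,
        "record_table": rec_df,
        "calls": calls,
        "profiles": profiles,
        "fpkm": fpkm,
        "go": go_results,
        "specific": specific,
        "lost": lost,
        "truth": truth_df,
    }
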