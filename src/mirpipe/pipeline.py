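"""End-to-end pipeline orchestration with a single structured config.

Stage order mirrors the experiment: (optional) simulate -> clean -> collapse
-> map -> annotate -> known/novel miRNA -> TPM filter -> differential
expression -> target prediction -> reports.  Every stage writes a TSV and
logs its counts; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import diffexpr as de
from . import novel as nv
from . import preprocess as pp
from . import synth
from . import targets as tg
from .sequtil import dna, rna

logger = logging.getLogger("mirpipe")


@dataclass
class PipelineConfig:
    """All paths and thresholds of one pipeline run.

    Threshold defaults are the study's stated parameters wherever one
    exists (mismatch limits, TPM filter, DE gates, hairpin criteria); the
    cleaning knobs the study leaves unstated (quality, length bounds,
    adapter policy) carry documented defaults.
    """

    outdir: str = "results/pipeline"
    # inputs (populated by simulate, or pointing at user files)
    fastq_ctl: str = ""
    fastq_def: str = ""
    genome_fasta: str = ""
    mature_reference_fasta: str = ""
    transcripts_fasta: str = ""
    # simulation
    simulate: bool = True
    genome_length: int = 60_000
    n_known_mirnas: int = 12
    n_novel_hairpins: int = 6
    n_genes: int = 4
    n_repeats: int = 2
    library_depth: int = 100_000
    sequencing_error_rate: float = 0.005
    # cleaning
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_quality: float = 20.0
    length_bounds: tuple = (18, 30)
    # annotation
    known_mismatch_limit: int = 2
    require_genome_hit_for_known: bool = False
    # novel miRNA (hairpin criteria)
    mireap: nv.MireapParams = field(default_factory=nv.MireapParams)
    # differential expression
    tpm_filter: float = 10.0
    pseudo_tpm: float = 0.01
    p_cutoff: float = 0.01
    lfc_cutoff: float = 1.5
    fold_change_scale: str = "log2"
    # targets
    gu_blocks_adjacency: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["mireap"] = dataclasses.asdict(self.mireap)
        d["length_bounds"] = list(self.length_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "mireap" in d:
            d["mireap"] = nv.MireapParams(**d["mireap"])
        if "length_bounds" in d:
            d["length_bounds"] = tuple(d["length_bounds"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a machine-readable summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    bundle = None
    if config.simulate:
        spec = synth.SyntheticGenomeSpec(
            genome_length=config.genome_length,
            n_known_mirnas=config.n_known_mirnas,
            n_novel_hairpins=config.n_novel_hairpins,
            n_genes=config.n_genes,
            n_repeats=config.n_repeats,
            seed=config.seed,
        )
        bundle = synth.build_genome(spec)
        profile = synth.default_profile(bundle, seed=config.seed,
                                        depth=config.library_depth)
        profile = dataclasses.replace(
            profile, adapter_sequence=config.adapter,
            sequencing_error_rate=config.sequencing_error_rate)
        config.fastq_ctl = str(out / "ctl.fastq")
        config.fastq_def = str(out / "def.fastq")
        counts = synth.simulate_libraries(bundle, profile,
                                          config.fastq_ctl, config.fastq_def)
        counts.to_csv(out / "simulated_counts.tsv", sep="\t", index=False)
        bundle.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        _write_bundle(bundle, out)
        config.genome_fasta = str(out / "genome.fa")
        config.mature_reference_fasta = str(out / "known_mirnas.fa")
        config.transcripts_fasta = str(out / "transcripts.fa")
        summary["stages"]["simulate"] = {"features": len(bundle.truth)}
        logger.info("simulate: %d truth features", len(bundle.truth))

    for fieldname in ("genome_fasta", "fastq_ctl", "fastq_def",
                      "mature_reference_fasta"):
        path = getattr(config, fieldname)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config field '{fieldname}' missing or "
                                    f"does not exist: {path!r}")

    # clean + collapse
    clean_ctl, stats_ctl = pp.clean_reads(config.fastq_ctl, config.adapter,
                                          config.min_quality, config.length_bounds)
    clean_def, stats_def = pp.clean_reads(config.fastq_def, config.adapter,
                                          config.min_quality, config.length_bounds)
    tags = pp.collapse_tags(clean_ctl, clean_def)
    pp.write_collapsed_fasta(tags, out / "tags.fa")
    pp.length_distribution(tags).to_csv(out / "length_distribution.tsv", sep="\t")
    summary["stages"]["clean"] = {
        "raw_ctl": stats_ctl.raw_reads, "clean_ctl": stats_ctl.clean_reads,
        "discard_ctl": dict(stats_ctl.discarded),
        "raw_def": stats_def.raw_reads, "clean_def": stats_def.clean_reads,
        "discard_def": dict(stats_def.discarded),
        "unique_tags": len(tags),
    }
    logger.info("clean: ctl %d->%d, def %d->%d, %d unique tags",
                stats_ctl.raw_reads, stats_ctl.clean_reads,
                stats_def.raw_reads, stats_def.clean_reads, len(tags))

    # map + annotate
    genome = ann.load_fasta(config.genome_fasta)
    hits = ann.map_perfect(tags, genome)
    mature_ref = ann.load_fasta(config.mature_reference_fasta)
    assignments = ann.match_known_mirnas(tags, mature_ref,
                                         config.known_mismatch_limit)
    if bundle is not None:
        ncrna_refs = bundle.ncrna_refs
        repeats = [ann.Interval(*r[:3], name=r[3], strand=r[4])
                   for r in bundle.repeat_intervals]
        exons = [ann.Interval(c, s, e, name=n, strand=st)
                 for (c, s, e, n, st, t) in bundle.gene_features if t == "exon"]
        introns = [ann.Interval(c, s, e, name=n, strand=st)
                   for (c, s, e, n, st, t) in bundle.gene_features if t == "intron"]
    else:
        ncrna_refs, repeats, exons, introns = {}, [], [], []
    records = ann.annotate_cascade(tags, ncrna_refs, assignments, repeats,
                                   exons, introns, hits,
                                   config.require_genome_hit_for_known)
    table1 = ann.summarize_table1(records, stats_ctl.clean_reads,
                                  stats_def.clean_reads)
    table1.to_csv(out / "table1_summary.tsv", sep="\t")
    per_tag = pd.DataFrame([
        {"tag": r.tag.sequence, "count_ctl": r.tag.count_ctl,
         "count_def": r.tag.count_def, "category": r.category,
         "evidence": r.evidence, "n_hits": len(r.genomic_hits)}
        for r in records])
    per_tag.to_csv(out / "annotation.tsv", sep="\t", index=False)
    summary["stages"]["annotate"] = {
        cat: int((per_tag["category"] == cat).sum()) for cat in ann.CATEGORIES}
    logger.info("annotate: %s", summary["stages"]["annotate"])

    # known miRNA expression
    known_counts: dict[str, list[int]] = {}
    for rec in records:
        if rec.category == "known_miRNA":
            rid = rec.evidence.split(" ")[0]
            c = known_counts.setdefault(rid, [0, 0])
            c[0] += rec.tag.count_ctl
            c[1] += rec.tag.count_def

    # novel miRNA prediction from unannotated mapped tags
    unann = [r.tag for r in records
             if r.category == "unannotated" and r.genomic_hits]
    candidates = nv.predict_novel(unann, hits, genome, config.mireap)
    cand_rows = [{
        "locus": f"{c.locus[0]}:{c.locus[1]}-{c.locus[2]}({c.locus[3]})",
        "mature": c.mature, "arm": c.mature_arm, "star": c.star,
        "mfe": c.fold.mfe, "paired": c.duplex_paired_bases,
        "bulge": c.duplex_bulge_max, "asymmetry": c.duplex_asymmetry,
        "gap": c.mature_star_gap,
        "count_ctl": c.mature_counts[0], "count_def": c.mature_counts[1]}
        for c in candidates]
    pd.DataFrame(cand_rows).to_csv(out / "novel_candidates.tsv", sep="\t",
                                   index=False)
    summary["stages"]["novel"] = {"candidates": len(candidates)}
    logger.info("novel: %d accepted hairpin candidates", len(candidates))
    for i, c in enumerate(candidates, start=1):
        known_counts[f"novel_mir_{i:03d}"] = list(c.mature_counts)

    # differential expression
    recs = de.build_records({k: tuple(v) for k, v in known_counts.items()},
                            stats_ctl.clean_reads, stats_def.clean_reads,
                            config.pseudo_tpm)
    kept = de.low_expression_filter(recs, config.tpm_filter)
    called = de.call_differential(kept, config.p_cutoff, config.lfc_cutoff,
                                  config.fold_change_scale)
    de_table = pd.DataFrame([{
        "id": r.id, "x": r.x, "y": r.y, "tpm_ctl": r.tpm_ctl,
        "tpm_def": r.tpm_def, "log2fc": r.log2fc,
        "p_point": r.test.p_point, "tail_lower": r.test.tail_lower,
        "tail_upper": r.test.tail_upper, "p_reported": r.test.p_reported,
        "significant": r.significant, "direction": r.direction}
        for r in called])
    de_table.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    n_up = sum(1 for r in called if r.direction == "up")
    n_down = sum(1 for r in called if r.direction == "down")
    summary["stages"]["diffexpr"] = {
        "tested": len(called), "filtered_out": len(recs) - len(kept),
        "up": n_up, "down": n_down}
    logger.info("diffexpr: %d tested, %d up / %d down", len(called), n_up, n_down)

    # target prediction for significant miRNAs
    sig_seqs = {}
    mature_by_id = {k: rna(dna(v)) for k, v in mature_ref.items()}
    novel_by_id = {f"novel_mir_{i:03d}": c.mature
                   for i, c in enumerate(candidates, start=1)}
    for r in called:
        if r.significant:
            seq = mature_by_id.get(r.id) or novel_by_id.get(r.id)
            if seq:
                sig_seqs[r.id] = seq
    transcripts = {}
    if config.transcripts_fasta and Path(config.transcripts_fasta).exists():
        transcripts = ann.load_fasta(config.transcripts_fasta)
    predictions = []
    if sig_seqs and transcripts:
        predictions = tg.scan_transcripts(sig_seqs, transcripts,
                                          config.gu_blocks_adjacency)
    pred_rows = [{
        "mirna_id": p.mirna_id, "transcript_id": p.transcript_id,
        "start": p.start, "end": p.end,
        "score": p.duplex.mismatch_score,
        "mfe_duplex": p.duplex.mfe_duplex, "mfe_perfect": p.duplex.mfe_perfect,
        "ratio": p.duplex.mfe_ratio} for p in predictions]
    pd.DataFrame(pred_rows).to_csv(out / "target_predictions.tsv", sep="\t",
                                   index=False)
    summary["stages"]["targets"] = {"predictions": len(predictions)}
    logger.info("targets: %d predictions", len(predictions))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_bundle(bundle: synth.GenomeBundle, out: Path) -> None:
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    with open(out / "known_mirnas.fa", "w") as fh:
        for rid, seq in sorted(bundle.known_mirnas.items()):
            fh.write(f">{rid}\n{seq}\n")
    with open(out / "ncrna.fa", "w") as fh:
        for cls, refs in sorted(bundle.ncrna_refs.items()):
            for rid, seq in sorted(refs.items()):
                fh.write(f">{rid} {cls}\n{seq}\n")
    with open(out / "transcripts.fa", "w") as fh:
        for tid, seq in sorted(bundle.transcripts.items()):
            fh.write(f">{tid}\n{seq}\n")
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for (chrom, s, e, name, strand, ftype) in bundle.gene_features:
            fh.write(f"{chrom}\tmirpipe\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                     f"ID={name}\n")
    with open(out / "repeats.bed", "w") as fh:
        for (chrom, s, e, name, strand) in bundle.repeat_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
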