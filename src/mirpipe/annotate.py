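"""Perfect-match genome mapping and the priority annotation cascade.

Tags are mapped to the genome requiring exact full-length matches on either
strand, then classified by a priority cascade: housekeeping ncRNA classes
first (rRNA > tRNA > snRNA > snoRNA, by substring containment in the
reference sequences), then known miRNA (ungapped match to a mature
reference with at most two mismatches), then repeat, exon and intron by
genomic overlap; whatever remains is unannotated.  Each tag lands in exactly
one category, so the categories partition the tag set and the per-library
totals reconcile with the clean-read totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .preprocess import SequenceTag
from .sequtil import dna, revcomp

CATEGORIES = [
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "known_miRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
]

NCRNA_ORDER = ["rRNA", "tRNA", "snRNA", "snoRNA"]


@dataclass(frozen=True)
class GenomicHit:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass
class AnnotationRecord:
    tag: SequenceTag
    category: str
    evidence: str = ""
    genomic_hits: list = field(default_factory=list)


def load_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def map_perfect(tags: list[SequenceTag], genome: dict[str, str]) -> dict[str, list[GenomicHit]]:
    """All exact full-length hits of each tag on both genome strands."""
    hits: dict[str, list[GenomicHit]] = {t.sequence: [] for t in tags}
    for chrom, seq in genome.items():
        for tag in tags:
            for query, strand in ((tag.sequence, "+"), (revcomp(tag.sequence), "-")):
                pos = seq.find(query)
                while pos != -1:
                    hits[tag.sequence].append(
                        GenomicHit(chrom, pos, pos + len(query), strand)
                    )
                    pos = seq.find(query, pos + 1)
    return hits


def match_known_mirnas(
    tags: list[SequenceTag],
    mature_reference: dict[str, str],
    max_mismatches: int = 2,
) -> dict[str, tuple[str, int]]:
    """Assign tags to known mature miRNAs by ungapped same-length comparison.

    Each tag goes to the reference with the fewest mismatches, provided that
    count is <= ``max_mismatches``; ties break on reference id.  Reference
    sequences may be RNA (U); they are compared in DNA space.
    """
    by_len: dict[int, list[tuple[str, np.ndarray]]] = {}
    for rid, seq in sorted(mature_reference.items()):
        arr = np.frombuffer(dna(seq).encode(), dtype=np.uint8)
        by_len.setdefault(len(seq), []).append((rid, arr))

    assignments: dict[str, tuple[str, int]] = {}
    for tag in tags:
        refs = by_len.get(len(tag.sequence))
        if not refs:
            continue
        tarr = np.frombuffer(tag.sequence.encode(), dtype=np.uint8)
        best_id, best_mm = None, max_mismatches + 1
        for rid, rarr in refs:
            mm = int((tarr != rarr).sum())
            if mm < best_mm:
                best_id, best_mm = rid, mm
        if best_id is not None and best_mm <= max_mismatches:
            assignments[tag.sequence] = (best_id, best_mm)
    return assignments


def _contained(tag_seq: str, references: dict[str, str]) -> str | None:
    rc = revcomp(tag_seq)
    for rid, seq in sorted(references.items()):
        if tag_seq in seq or rc in seq:
            return rid
    return None


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    name: str = ""


def read_bed(path: str | Path) -> list[Interval]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        fields = list(row)
        name = str(fields[3]) if len(fields) > 3 else ""
        strand = str(fields[5]) if len(fields) > 5 else "."
        out.append(Interval(str(fields[0]), int(fields[1]), int(fields[2]), strand, name))
    return out


def read_gff_features(path: str | Path, types: tuple[str, ...]) -> list[Interval]:
    """Read selected feature types from GFF3 (1-based inclusive -> half-open)."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    out = []
    for row in df.itertuples(index=False):
        if row.type not in types:
            continue
        if row.strand not in ("+", "-"):
            raise ValueError(f"GFF feature without strand: {row.chrom}:{row.start}-{row.end}")
        out.append(Interval(str(row.chrom), int(row.start) - 1, int(row.end),
                            str(row.strand), str(row.attributes)))
    return out


def _overlap(hit: GenomicHit, iv: Interval) -> bool:
    return hit.chrom == iv.chrom and hit.start < iv.end and iv.start < hit.end


def annotate_cascade(
    tags: list[SequenceTag],
    ncrna_refs: dict[str, dict[str, str]],
    known_assignments: dict[str, tuple[str, int]],
    repeats: list[Interval],
    exons: list[Interval],
    introns: list[Interval],
    genomic_hits: dict[str, list[GenomicHit]],
    require_genome_hit_for_known: bool = False,
) -> list[AnnotationRecord]:
    """Classify every tag by the first matching cascade stage.

    Stage order: rRNA > tRNA > snRNA > snoRNA > known miRNA > repeat >
    exon (sense, then antisense) > intron (sense, then antisense) >
    unannotated.  By default a known-miRNA assignment does not require a
    genomic hit (the reference may cover family members absent from the
    assembly); ``require_genome_hit_for_known`` enforces one.
    """
    records = []
    for tag in tags:
        hits = genomic_hits.get(tag.sequence, [])
        category, evidence = None, ""

        for cls in NCRNA_ORDER:
            refs = ncrna_refs.get(cls, {})
            rid = _contained(tag.sequence, refs)
            if rid is not None:
                category, evidence = cls, rid
                break

        if category is None and tag.sequence in known_assignments:
            if hits or not require_genome_hit_for_known:
                rid, mm = known_assignments[tag.sequence]
                category, evidence = "known_miRNA", f"{rid} ({mm} mm)"

        if category is None and hits:
            for iv_list, cat_sense, cat_anti in (
                (repeats, "repeat", "repeat"),
                (exons, "exon_sense", "exon_antisense"),
                (introns, "intron_sense", "intron_antisense"),
            ):
                sense = anti = None
                for hit in hits:
                    for iv in iv_list:
                        if _overlap(hit, iv):
                            if iv.strand == "." or hit.strand == iv.strand:
                                sense = sense or iv
                            else:
                                anti = anti or iv
                if sense is not None:
                    category, evidence = cat_sense, sense.name
                    break
                if anti is not None:
                    category, evidence = cat_anti, anti.name
                    break

        if category is None:
            category = "unannotated"
        records.append(AnnotationRecord(tag=tag, category=category,
                                        evidence=evidence, genomic_hits=hits))
    return records


def load_table1_counts() -> pd.DataFrame:
    """Published per-category read counts of the two citrus leaf libraries
    (Mg-sufficient control vs Mg-deficient), as printed; used to recompute
    the printed category percentages through ``category_percentage``."""
    import importlib.resources

    path = importlib.resources.files("mirpipe.data") / "table1_counts.tsv"
    return pd.read_csv(path, sep="\t").set_index("category")


def category_percentage(count: int, clean_reads: int) -> float:
    """Category share of the library, as a percentage rounded to 2 decimals."""
    if clean_reads <= 0:
        raise ValueError("clean read total must be positive")
    return round(count / clean_reads * 100.0, 2)


def summarize_table1(records: list[AnnotationRecord],
                     clean_ctl: int, clean_def: int) -> pd.DataFrame:
    """Per-category unique/total counts and percentages for both libraries.

    Percentages are computed against each library's clean-read total
    (unique percentages against the unique-tag total).  With an empty
    library the percentage columns are left absent (NaN).
    """
    rows = {cat: {"unique_ctl": 0, "total_ctl": 0, "unique_def": 0, "total_def": 0}
            for cat in CATEGORIES}
    mapped = {"unique_ctl": 0, "total_ctl": 0, "unique_def": 0, "total_def": 0}
    uniq_ctl = uniq_def = 0
    for rec in records:
        t = rec.tag
        if t.count_ctl > 0:
            uniq_ctl += 1
            rows[rec.category]["unique_ctl"] += 1
            rows[rec.category]["total_ctl"] += t.count_ctl
            if rec.genomic_hits:
                mapped["unique_ctl"] += 1
                mapped["total_ctl"] += t.count_ctl
        if t.count_def > 0:
            uniq_def += 1
            rows[rec.category]["unique_def"] += 1
            rows[rec.category]["total_def"] += t.count_def
            if rec.genomic_hits:
                mapped["unique_def"] += 1
                mapped["total_def"] += t.count_def

    table = {"clean_reads": {"unique_ctl": uniq_ctl, "total_ctl": clean_ctl,
                             "unique_def": uniq_def, "total_def": clean_def},
             "mapped_to_genome": mapped}
    table.update(rows)
    df = pd.DataFrame.from_dict(table, orient="index")
    for col, denom in (("unique_ctl", uniq_ctl), ("total_ctl", clean_ctl),
                       ("unique_def", uniq_def), ("total_def", clean_def)):
        if denom > 0:
            df[f"pct_{col}"] = [category_percentage(v, denom) for v in df[col]]
        else:
            df[f"pct_{col}"] = float("nan")
    return df
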