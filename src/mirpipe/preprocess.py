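"""Read cleaning, tag collapsing and length distributions.

Raw sRNA reads carry the 3' sequencing adapter; cleaning trims it at the
leftmost exact occurrence of an adapter prefix (>= 8 nt by default), drops
low-quality reads (mean Phred below the cutoff, or any N), and drops reads
whose trimmed insert falls outside the retention length bounds
(default 18-30 nt).  Clean reads are then collapsed to unique tags with
per-library counts — the unit every downstream stage works on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .sequtil import dna

DEFAULT_MIN_QUALITY = 20.0
DEFAULT_LENGTH_BOUNDS = (18, 30)
DEFAULT_ADAPTER_MIN_PREFIX = 8


@dataclass(frozen=True)
class SequenceTag:
    """A unique collapsed sRNA sequence with its count in each library."""

    sequence: str
    count_ctl: int = 0
    count_def: int = 0

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"tag contains non-ACGT characters: {self.sequence}")
        if self.count_ctl < 0 or self.count_def < 0:
            raise ValueError("tag counts must be non-negative")

    @property
    def total(self) -> int:
        return self.count_ctl + self.count_def


@dataclass
class LibraryStats:
    raw_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    discarded: Counter = field(default_factory=Counter)

    def conservation_ok(self) -> bool:
        return self.raw_reads == self.clean_reads + sum(self.discarded.values())


def trim_adapter(seq: str, adapter: str, min_prefix: int = DEFAULT_ADAPTER_MIN_PREFIX) -> str:
    """Trim at the leftmost exact match of the longest adapter prefix.

    Prefixes are tried from the full adapter down to ``min_prefix`` nt; a
    read with no hit is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    best = -1
    for plen in range(min(len(adapter), len(seq)), min_prefix - 1, -1):
        pos = seq.find(adapter[:plen])
        if pos != -1 and (best == -1 or pos < best):
            best = pos
    return seq if best == -1 else seq[:best]


def clean_reads(
    fastq_path: str | Path,
    adapter: str,
    min_quality: float = DEFAULT_MIN_QUALITY,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    adapter_min_prefix: int = DEFAULT_ADAPTER_MIN_PREFIX,
) -> tuple[list[str], LibraryStats]:
    """Clean one FASTQ library; returns retained insert sequences and stats.

    Removal reasons tallied: ``quality`` (mean Phred below cutoff),
    ``n_base`` (any N), ``length`` (trimmed insert outside bounds).
    """
    lo, hi = length_bounds
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if lo > hi:
        raise ValueError("length bounds must satisfy min <= max")
    stats = LibraryStats()
    kept: list[str] = []
    try:
        records = SeqIO.parse(str(fastq_path), "fastq")
        for idx, rec in enumerate(records):
            stats.raw_reads += 1
            seq = dna(str(rec.seq))
            quals = rec.letter_annotations["phred_quality"]
            if quals and sum(quals) / len(quals) < min_quality:
                stats.discarded["quality"] += 1
                continue
            if "N" in seq:
                stats.discarded["n_base"] += 1
                continue
            insert = trim_adapter(seq, dna(adapter), adapter_min_prefix)
            if not lo <= len(insert) <= hi:
                stats.discarded["length"] += 1
                continue
            kept.append(insert)
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record near index {stats.raw_reads} in {fastq_path}: {exc}"
        ) from exc
    stats.clean_reads = len(kept)
    return kept, stats


def collapse_tags(clean_ctl: list[str], clean_def: list[str]) -> list[SequenceTag]:
    """Collapse clean reads from the two libraries into unique tags."""
    c1 = Counter(clean_ctl)
    c2 = Counter(clean_def)
    return [
        SequenceTag(seq, c1.get(seq, 0), c2.get(seq, 0))
        for seq in sorted(set(c1) | set(c2))
    ]


def length_distribution(tags: list[SequenceTag]) -> pd.DataFrame:
    """Per-length unique/total tag counts and fractions, per library.

    Fractions are NaN (absent) for a library with zero clean reads.
    """
    rows = {}
    for tag in tags:
        row = rows.setdefault(
            len(tag.sequence),
            {"unique": 0, "total_ctl": 0, "total_def": 0},
        )
        row["unique"] += 1
        row["total_ctl"] += tag.count_ctl
        row["total_def"] += tag.count_def
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "length"
    if df.empty:
        return pd.DataFrame(
            columns=["unique", "total_ctl", "total_def", "frac_ctl", "frac_def"]
        )
    for lib in ("ctl", "def"):
        total = df[f"total_{lib}"].sum()
        df[f"frac_{lib}"] = df[f"total_{lib}"] / total if total > 0 else float("nan")
    return df


def write_collapsed_fasta(tags: list[SequenceTag], path: str | Path) -> None:
    """Write tags as FASTA with counts in the header: ``tag<N>_x<ctl>_y<def>``."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count_ctl}_y{tag.count_def}\n{tag.sequence}\n")
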