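"""Synthetic genome, references and paired sRNA libraries with known truth.

The generator emulates the structure of a plant leaf sRNA experiment with
one pooled library per condition: a single-chromosome genome carrying
designed miRNA hairpins (known and novel), housekeeping ncRNA genes
(rRNA/tRNA/snRNA/snoRNA), protein-coding genes with exons and introns, and
repeat elements; read tags drawn from those features plus an unmappable
class; and two libraries sampled multinomially from TPM-derived
proportions, with per-feature log2 fold changes applied to the treatment
library.  Hairpin precursors are built as near-perfect inverted repeats
(stem >= 20 bp, loop 8-12 nt) so that acceptance under the default folding
engine is guaranteed by construction and verified at build time.

Everything is deterministic given the generator and profile seeds: identical inputs
produce byte-identical FASTA/FASTQ/GFF/BED/TSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fold import fold
from .novel import MireapParams, _evaluate_window
from .sequtil import revcomp, rna

BASES = np.array(list("ACGT"))

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
NCRNA_GENE_LENGTH = {"rRNA": 120, "tRNA": 75, "snRNA": 100, "snoRNA": 90}


class PlacementError(ValueError):
    """Raised when the genome is too small to place a feature class."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    genome_length: int = 60_000
    n_known_mirnas: int = 12
    n_novel_hairpins: int = 6
    n_ncrna_fragments: dict = field(
        default_factory=lambda: {"rRNA": 4, "tRNA": 3, "snRNA": 2, "snoRNA": 2}
    )
    n_genes: int = 4
    n_repeats: int = 2
    n_unmapped_tags: int = 4
    flank_gc: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_known_mirnas, self.n_novel_hairpins, self.n_genes,
                  self.n_repeats, self.n_unmapped_tags,
                  *self.n_ncrna_fragments.values()]
        if any(c < 0 for c in counts):
            raise ValueError("all feature counts must be >= 0")
        if not 0.0 <= self.flank_gc <= 1.0:
            raise ValueError("flank_gc must be in [0, 1]")
        if self.genome_length < 0:
            raise ValueError("genome_length must be >= 0")


@dataclass(frozen=True)
class ExpressionProfile:
    baseline_tpm: dict          # feature_id -> TPM
    log2_fold_change: dict      # feature_id -> lfc (0 for null features)
    library_depth_ctl: int = 100_000
    library_depth_def: int = 100_000
    sequencing_error_rate: float = 0.005
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    low_quality_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.baseline_tpm.values()):
            raise ValueError("baseline TPMs must be >= 0")
        if self.library_depth_ctl < 0 or self.library_depth_def < 0:
            raise ValueError("library depths must be >= 0")
        if not 0.0 <= self.sequencing_error_rate <= 0.05:
            raise ValueError("sequencing error rate must be in [0, 0.05]")


@dataclass
class TruthFeature:
    feature_id: str
    feature_class: str
    tag: str                      # the sequence emitted as reads (DNA)
    chrom: str = "chr1"
    start: int = -1               # 0-based half-open tag locus; -1 = unmapped
    end: int = -1
    strand: str = "."
    precursor_start: int = -1
    precursor_end: int = -1
    mature_arm: str = ""


@dataclass
class GenomeBundle:
    genome: dict                  # chrom -> sequence
    known_mirnas: dict            # id -> mature RNA sequence
    ncrna_refs: dict              # class -> {id: DNA sequence}
    gene_features: list           # GFF-style rows (tuples)
    repeat_intervals: list        # (chrom, start, end, name, strand)
    transcripts: dict             # transcript id -> spliced DNA sequence
    truth: list                   # list[TruthFeature]
    embedded_targets: list = field(default_factory=list)
    # (transcript_id, mirna_id, start, end) 0-based half-open on the transcript

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth])


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def design_hairpin(rng: np.random.Generator, mature_len: int | None = None
                   ) -> tuple[str, str, str, int]:
    """Design one inverted-repeat precursor.

    Returns (precursor, mature, arm, mature_offset_in_precursor).  The stem
    is a perfect inverted repeat of the mature (star length = mature length
    after the 2-nt Dicer overhangs), loop 8-12 nt.
    """
    L = int(mature_len) if mature_len is not None else int(rng.integers(21, 23))
    while True:
        mature = _random_seq(rng, L)
        wobble_sites = [i for i in range(3, L - 3) if mature[i] in "TG"]
        if wobble_sites:
            break
    # one G:U wobble in the star arm keeps the stem fully paired but breaks
    # exact reverse-complementarity, so the mature tag maps to a single locus
    star = list(revcomp(mature))
    i = wobble_sites[int(rng.integers(len(wobble_sites)))]
    j = L - 1 - i
    star[j] = "G" if mature[i] == "T" else "T"
    star_seq = "".join(star)
    loop = _random_seq(rng, int(rng.integers(8, 13)))
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + star_seq
        offset = 0
    else:
        precursor = star_seq + loop + mature
        offset = len(star_seq) + len(loop)
    return precursor, mature, arm, offset


def _wobbled_complement_site(mature_dna: str) -> str | None:
    """Reverse-complement target site with one G:U wobble (DNA space).

    The wobble is placed away from miRNA positions 10-11 (which must stay
    Watson-Crick for the target rules) at a miRNA position whose base is U
    or G; returns None if no such position exists.
    """
    L = len(mature_dna)
    site = list(revcomp(mature_dna))
    candidates = [k for k in list(range(2, 8)) + list(range(12, L - 2))
                  if mature_dna[k] in "TG"]
    if not candidates:
        return None
    k = candidates[0]
    j = L - 1 - k
    site[j] = "G" if mature_dna[k] == "T" else "T"
    return "".join(site)


def hairpin_is_acceptable(precursor: str, mature_offset: int, mature_len: int,
                          flank_left: str, flank_right: str,
                          params: MireapParams = MireapParams()) -> bool:
    """Verify a designed precursor passes the acceptance criteria when folded
    with its genomic flanks attached (build-time contract)."""
    window = flank_left + precursor + flank_right
    _, _, reasons = _evaluate_window(
        window, len(flank_left) + mature_offset, mature_len, params, fold
    )
    return not reasons


def weaken_hairpin(bundle: "GenomeBundle", feature: "TruthFeature",
                   params: MireapParams = MireapParams()) -> dict | None:
    """Build an MFE-weakened mutant of one designed precursor.

    The mature tag is preserved; every other precursor base is replaced,
    left to right, by a homopolymer background (C, falling back to A when
    the mature is G-rich enough to pair a cytosine background) until the
    precursor folds weaker than the acceptance threshold.  Returns the
    mutant as an isolated single-chromosome genome ``{"chrM": block}``, or
    None when the mature alone sustains a structure below the threshold so
    no such mutant exists.
    """
    g = bundle.genome[feature.chrom]
    block = g[feature.precursor_start:feature.precursor_end]
    oriented = list(block if feature.strand == "+" else revcomp(block))
    rel0 = feature.start - feature.precursor_start
    rel1 = feature.end - feature.precursor_start
    o0, o1 = ((rel0, rel1) if feature.strand == "+"
              else (len(block) - rel1, len(block) - rel0))

    chosen = None
    for bg in ("C", "A"):
        full = [c if o0 <= i < o1 else bg for i, c in enumerate(oriented)]
        if fold(rna("".join(full))).mfe > params.max_precursor_mfe:
            chosen = bg
            break
    if chosen is None:
        return None
    for i in [i for i in range(len(oriented)) if not o0 <= i < o1]:
        if fold(rna("".join(oriented))).mfe > params.max_precursor_mfe:
            break
        oriented[i] = chosen
    assert fold(rna("".join(oriented))).mfe > params.max_precursor_mfe
    mutant = ("".join(oriented) if feature.strand == "+"
              else revcomp("".join(oriented)))
    return {"chrM": mutant}


def _count_occurrences(genome_seq: str, tag: str) -> int:
    return genome_seq.count(tag) + genome_seq.count(revcomp(tag))


def build_genome(spec: SyntheticGenomeSpec) -> GenomeBundle:
    """Construct the genome bundle for a spec; deterministic in spec.seed."""
    rng = np.random.default_rng(spec.seed)
    params = MireapParams()
    flank = params.flank

    blocks = []  # (feature_id, class, block_seq, meta)

    def add_hairpin(fid, cls):
        for _ in range(40):
            precursor, mature, arm, offset = design_hairpin(rng)
            left = _random_seq(rng, flank, spec.flank_gc)
            right = _random_seq(rng, flank, spec.flank_gc)
            if hairpin_is_acceptable(precursor, offset, len(mature), left, right):
                strand = "+" if rng.random() < 0.5 else "-"
                blocks.append((fid, cls, left + precursor + right,
                               {"mature": mature, "arm": arm, "offset": flank + offset,
                                "strand": strand}))
                return
        raise RuntimeError(f"could not design an acceptable hairpin for {fid}")

    for i in range(spec.n_known_mirnas):
        add_hairpin(f"known_mir_{i+1:03d}", "known_miRNA")
    for i in range(spec.n_novel_hairpins):
        add_hairpin(f"novel_hairpin_{i+1:03d}", "novel_hairpin")

    for cls in NCRNA_CLASSES:
        n = spec.n_ncrna_fragments.get(cls, 0)
        for i in range(n):
            gene = _random_seq(rng, NCRNA_GENE_LENGTH[cls])
            frag_len = int(rng.integers(20, 25))
            off = int(rng.integers(0, len(gene) - frag_len + 1))
            blocks.append((f"{cls}_{i+1:03d}", f"{cls}_fragment", gene,
                           {"frag_off": off, "frag_len": frag_len, "strand": "+"}))

    known_matures = [(fid, meta["mature"]) for fid, cls, _, meta in blocks
                     if cls == "known_miRNA"]

    for i in range(spec.n_genes):
        exon1 = _random_seq(rng, 120)
        intron = _random_seq(rng, 90)
        exon2 = _random_seq(rng, 120)
        target_of = ""
        site_off = -1
        if known_matures:
            # embed one near-perfect target site (single G:U wobble) of a
            # known miRNA in exon 2, emulating plant-style coding-region sites
            mid, mature = known_matures[i % len(known_matures)]
            site = _wobbled_complement_site(mature)
            if site is not None:
                site_off = 30
                exon2 = exon2[:site_off] + site + exon2[site_off + len(site):]
                target_of = mid
        strand = "+" if rng.random() < 0.5 else "-"
        for kind, src in (("exon", exon1), ("intron", intron)):
            frag_len = int(rng.integers(20, 25))
            off = int(rng.integers(0, len(src) - frag_len + 1))
            blocks.append((f"gene_{i+1:03d}_{kind}", f"{kind}_fragment",
                           None, {"frag_off": off, "frag_len": frag_len}))
        blocks.append((f"gene_{i+1:03d}", "gene", exon1 + intron + exon2,
                       {"exon1": len(exon1), "intron": len(intron),
                        "exon2": len(exon2), "strand": strand,
                        "target_of": target_of, "site_off": site_off,
                        "site_len": len(site) if target_of else 0}))

    for i in range(spec.n_repeats):
        rep = _random_seq(rng, 150)
        frag_len = int(rng.integers(20, 25))
        off = int(rng.integers(0, len(rep) - frag_len + 1))
        blocks.append((f"repeat_{i+1:03d}", "repeat_fragment", rep,
                       {"frag_off": off, "frag_len": frag_len, "strand": "+"}))

    placeable = [(fid, cls, seq, meta) for fid, cls, seq, meta in blocks
                 if seq is not None]
    min_gap = 15
    need = sum(len(seq) for _, _, seq, _ in placeable) + min_gap * (len(placeable) + 1)
    if need > spec.genome_length:
        # name the first class that no longer fits
        acc = min_gap
        for fid, cls, seq, _ in placeable:
            acc += len(seq) + min_gap
            if acc > spec.genome_length:
                raise PlacementError(
                    f"genome_length {spec.genome_length} too small to place "
                    f"feature class '{cls}' ({fid}); need >= {need}"
                )

    n_place = len(placeable)
    slack = spec.genome_length - sum(len(s) for _, _, s, _ in placeable) \
        - min_gap * (n_place + 1)
    if n_place > 0:
        extra = rng.multinomial(slack, np.full(n_place + 1, 1.0 / (n_place + 1)))
        gaps = extra + min_gap
    else:
        gaps = np.array([spec.genome_length])

    pieces: list[str] = []
    truth: list[TruthFeature] = []
    known_mirnas: dict[str, str] = {}
    ncrna_refs: dict[str, dict[str, str]] = {c: {} for c in NCRNA_CLASSES}
    gene_features: list[tuple] = []
    repeat_intervals: list[tuple] = []
    transcripts: dict[str, str] = {}
    embedded: list[tuple] = []
    frag_meta: dict[str, dict] = {fid: meta for fid, cls, seq, meta in blocks
                                  if seq is None}

    pos = 0
    for k, (fid, cls, seq, meta) in enumerate(placeable):
        gap = _random_seq(rng, int(gaps[k]), spec.flank_gc)
        pieces.append(gap)
        pos += len(gap)
        start = pos
        strand = meta.get("strand", "+")
        placed = seq if strand == "+" else revcomp(seq)
        pieces.append(placed)
        pos += len(placed)
        end = pos

        if cls in ("known_miRNA", "novel_hairpin"):
            off, mlen = meta["offset"], len(meta["mature"])
            if strand == "+":
                t0, t1 = start + off, start + off + mlen
            else:
                t0, t1 = end - off - mlen, end - off
            truth.append(TruthFeature(fid, cls, meta["mature"], "chr1", t0, t1,
                                      strand, start, end, meta["arm"]))
            if cls == "known_miRNA":
                known_mirnas[fid] = rna(meta["mature"])
        elif cls.endswith("_fragment") and cls.split("_")[0] in NCRNA_CLASSES:
            base = cls.split("_")[0]
            ncrna_refs[base][fid] = seq
            o, fl = meta["frag_off"], meta["frag_len"]
            tag = seq[o:o + fl]
            if strand == "+":
                t0, t1 = start + o, start + o + fl
            else:
                t0, t1 = end - o - fl, end - o
            truth.append(TruthFeature(fid + "_frag", base + "_fragment", tag,
                                      "chr1", t0, t1, strand))
        elif cls == "gene":
            e1, il, e2 = meta["exon1"], meta["intron"], meta["exon2"]
            gene_features.append(("chr1", start, end, fid, strand, "gene"))
            if strand == "+":
                ex1 = (start, start + e1)
                inr = (start + e1, start + e1 + il)
                ex2 = (start + e1 + il, end)
            else:
                ex2 = (start, start + e2)
                inr = (start + e2, start + e2 + il)
                ex1 = (start + e2 + il, end)
            gene_features.append(("chr1", ex1[0], ex1[1], fid + ".exon1", strand, "exon"))
            gene_features.append(("chr1", inr[0], inr[1], fid + ".intron1", strand, "intron"))
            gene_features.append(("chr1", ex2[0], ex2[1], fid + ".exon2", strand, "exon"))
            transcripts[fid + ".t1"] = seq[:e1] + seq[e1 + il:]
            if meta.get("target_of"):
                s0 = e1 + meta["site_off"]
                embedded.append((fid + ".t1", meta["target_of"],
                                 s0, s0 + meta["site_len"]))
            for kind, src_off, src_len in (("exon", 0, e1), ("intron", e1, il)):
                fmeta = frag_meta[f"{fid}_{kind}"]
                o, fl = fmeta["frag_off"], fmeta["frag_len"]
                tag = seq[src_off + o: src_off + o + fl]
                if strand == "+":
                    t0 = start + src_off + o
                else:
                    t0 = end - (src_off + o + fl)
                tag_genomic = tag if strand == "+" else tag
                truth.append(TruthFeature(f"{fid}_{kind}_frag", f"{kind}_fragment",
                                          tag_genomic, "chr1", t0, t0 + fl, strand))
        elif cls == "repeat_fragment":
            repeat_intervals.append(("chr1", start, end, fid, strand))
            o, fl = meta["frag_off"], meta["frag_len"]
            tag = seq[o:o + fl]
            if strand == "+":
                t0, t1 = start + o, start + o + fl
            else:
                t0, t1 = end - o - fl, end - o
            truth.append(TruthFeature(fid + "_frag", "repeat_fragment", tag,
                                      "chr1", t0, t1, strand))

    tail = _random_seq(rng, spec.genome_length - pos, spec.flank_gc)
    pieces.append(tail)
    genome_seq = "".join(pieces)
    assert len(genome_seq) == spec.genome_length
    genome = {"chr1": genome_seq}

    for i in range(spec.n_unmapped_tags):
        for _ in range(50):
            tag = _random_seq(rng, 21)
            if _count_occurrences(genome_seq, tag) == 0:
                truth.append(TruthFeature(f"unmapped_{i+1:03d}", "unmapped", tag))
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw an unmappable tag")

    # every mapped truth tag must occur exactly once genome-wide so that the
    # simulator's emission counts are recoverable per locus
    for t in truth:
        if t.feature_class != "unmapped":
            n_occ = _count_occurrences(genome_seq, t.tag)
            if n_occ != 1:
                raise RuntimeError(
                    f"truth tag for {t.feature_id} occurs {n_occ} times; "
                    "use a larger genome or another seed"
                )

    return GenomeBundle(genome=genome, known_mirnas=known_mirnas,
                        ncrna_refs=ncrna_refs, gene_features=gene_features,
                        repeat_intervals=repeat_intervals,
                        transcripts=transcripts, truth=truth,
                        embedded_targets=embedded)


def default_profile(bundle: GenomeBundle, seed: int = 0,
                    depth: int = 100_000,
                    de_fraction: float = 0.5,
                    lfc_magnitude: float = 3.0) -> ExpressionProfile:
    """A realistic default profile over all truth features.

    miRNA-class features get baseline TPMs log-uniform in [50, 5000]; other
    classes in [20, 2000].  Half of the miRNA features (alternating) receive
    +/- ``lfc_magnitude`` log2 fold changes; everything else is null.
    """
    rng = np.random.default_rng(seed)
    tpm, lfc = {}, {}
    mir_ids = [t.feature_id for t in bundle.truth
               if t.feature_class in ("known_miRNA", "novel_hairpin")]
    for t in bundle.truth:
        lo, hi = (50, 5000) if t.feature_id in mir_ids else (20, 2000)
        tpm[t.feature_id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lfc[t.feature_id] = 0.0
    n_de = int(len(mir_ids) * de_fraction)
    for j, mid in enumerate(mir_ids[:n_de]):
        lfc[mid] = lfc_magnitude if j % 2 == 0 else -lfc_magnitude
    return ExpressionProfile(baseline_tpm=tpm, log2_fold_change=lfc,
                             library_depth_ctl=depth, library_depth_def=depth,
                             seed=seed)


def expected_proportions(profile: ExpressionProfile) -> tuple[pd.Series, pd.Series]:
    ids = sorted(profile.baseline_tpm)
    base = pd.Series({i: profile.baseline_tpm[i] for i in ids}, dtype=float)
    shifted = base * np.power(2.0, pd.Series(
        {i: profile.log2_fold_change.get(i, 0.0) for i in ids}, dtype=float))
    p_ctl = base / base.sum() if base.sum() > 0 else base
    p_def = shifted / shifted.sum() if shifted.sum() > 0 else shifted
    return p_ctl, p_def


def simulate_libraries(bundle: GenomeBundle, profile: ExpressionProfile,
                       fastq_ctl: str | Path, fastq_def: str | Path
                       ) -> pd.DataFrame:
    """Sample the two libraries and write FASTQ; returns the count table.

    The returned frame has, per feature: the exact sampling means
    (``expected_ctl/def``) and the multinomially drawn emission counts
    (``count_ctl/def``).
    """
    truth_by_id = {t.feature_id: t for t in bundle.truth}
    missing = [i for i in profile.baseline_tpm if i not in truth_by_id]
    if missing:
        raise ValueError(f"profiled features absent from bundle: {missing[:5]}")

    rng = np.random.default_rng(profile.seed)
    p_ctl, p_def = expected_proportions(profile)
    ids = list(p_ctl.index)

    rows = []
    counts = {}
    for lib, depth, p in (("ctl", profile.library_depth_ctl, p_ctl),
                          ("def", profile.library_depth_def, p_def)):
        if depth > 0 and p.sum() > 0:
            counts[lib] = rng.multinomial(depth, p.values)
        else:
            counts[lib] = np.zeros(len(ids), dtype=int)

    for j, fid in enumerate(ids):
        rows.append({
            "feature_id": fid,
            "feature_class": truth_by_id[fid].feature_class,
            "tag": truth_by_id[fid].tag,
            "expected_ctl": profile.library_depth_ctl * p_ctl.iloc[j],
            "expected_def": profile.library_depth_def * p_def.iloc[j],
            "count_ctl": int(counts["ctl"][j]),
            "count_def": int(counts["def"][j]),
        })
    table = pd.DataFrame(rows)

    for lib, path in (("ctl", fastq_ctl), ("def", fastq_def)):
        _write_library(rng, table, counts[lib], profile, Path(path), lib)
    return table


def _write_library(rng: np.random.Generator, table: pd.DataFrame,
                   counts: np.ndarray, profile: ExpressionProfile,
                   path: Path, lib: str) -> None:
    adapter = profile.adapter_sequence
    err = profile.sequencing_error_rate
    with open(path, "w") as fh:
        ridx = 0
        for j, row in table.iterrows():
            base_read = row["tag"] + adapter
            n = int(counts[j])
            if n == 0:
                continue
            n_err = rng.binomial(len(base_read), err, size=n)
            lowq = rng.random(n) < profile.low_quality_fraction
            for k in range(n):
                read = base_read
                if n_err[k] > 0:
                    arr = list(read)
                    pos = rng.choice(len(arr), size=min(n_err[k], len(arr)),
                                     replace=False)
                    for p in pos:
                        choices = [b for b in "ACGT" if b != arr[p]]
                        arr[p] = choices[int(rng.integers(3))]
                    read = "".join(arr)
                qual = ("+" if lowq[k] else "I") * len(read)
                fh.write(f"@{lib}_read{ridx}\n{read}\n+\n{qual}\n")
                ridx += 1


def simulate_count_pairs(tpms: np.ndarray, lfcs: np.ndarray,
                         depth_ctl: int, depth_def: int, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Count-level simulation (no reads): multinomial draws per library.

    Used for exact-test calibration and power studies where sequence-level
    noise is irrelevant.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(tpms, dtype=float)
    shifted = base * np.power(2.0, np.asarray(lfcs, dtype=float))
    x = rng.multinomial(depth_ctl, base / base.sum())
    y = rng.multinomial(depth_def, shifted / shifted.sum())
    return x, y
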