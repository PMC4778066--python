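"""Novel miRNA prediction from unannotated, genome-mapped tags.

A candidate mature tag is anchored at each of its genomic loci (at most 20
loci per tag), a precursor window is extracted under both arm assumptions
(mature on the 5' or on the 3' arm, with the star arm allowed up to 300 nt
away plus 20-nt flanks), folded with the configured engine, and accepted
only when the hairpin satisfies all of:

* precursor MFE <= -18 kcal/mol (under the engine's own energy model);
* mature length 18-25 nt, star-arm length 20-23 nt;
* >= 16 of the mature bases paired to the star arm;
* largest bulge inside the mature/star duplex <= 4 nt;
* mature/star duplex asymmetry <= 4 nt;
* gap (loop) between mature and star <= 300 nt;

where the star is read off the fold as the duplex partner of the mature with
2-nt 3' overhangs on both arms — the signature of a Dicer-processed duplex.
Sequenced star evidence is not required unless ``require_star_tag`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .annotate import GenomicHit
from .fold import FoldResult, fold
from .preprocess import SequenceTag
from .sequtil import revcomp, rna


@dataclass(frozen=True)
class MireapParams:
    min_mature_len: int = 18
    max_mature_len: int = 25
    min_star_len: int = 20
    max_star_len: int = 23
    max_copy_number: int = 20          # genomic loci per tag
    max_precursor_mfe: float = -18.0   # kcal/mol
    max_mature_star_gap: int = 300     # nt between mature and star
    min_duplex_pairs: int = 16
    max_duplex_bulge: int = 4
    max_duplex_asymmetry: int = 4
    flank: int = 20


@dataclass
class HairpinCandidate:
    locus: tuple[str, int, int, str]   # precursor chrom/start/end/strand (0-based half-open)
    precursor: str                     # RNA
    fold: FoldResult
    mature: str                        # RNA
    mature_arm: str                    # "5p" | "3p"
    mature_counts: tuple[int, int]
    star: str | None
    duplex_paired_bases: int
    duplex_bulge_max: int
    duplex_asymmetry: int
    mature_star_gap: int
    rejected: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.rejected


def filter_mature_length(
    tags: list[SequenceTag], bounds: tuple[int, int] = (18, 25)
) -> list[SequenceTag]:
    lo, hi = bounds
    return [t for t in tags if lo <= len(t.sequence) <= hi]


def _duplex_diagnostics(fold_res: FoldResult, m0: int, m1: int):
    """Read mature/star duplex geometry off the precursor fold.

    ``m0:m1`` is the mature span (half-open, precursor coordinates).
    Returns (star_span or None, paired, bulge_max, asymmetry, gap).
    """
    table = fold_res.pair_table()
    partners = [table[i] for i in range(m0, m1) if table[i] != -1]
    if not partners:
        return None, 0, m1 - m0, m1 - m0, -1
    paired = len(partners)

    # largest unpaired run strictly inside the paired part of the mature
    idx = [i for i in range(m0, m1) if table[i] != -1]
    bulge_mature = 0
    for a, b in zip(idx, idx[1:]):
        bulge_mature = max(bulge_mature, b - a - 1)

    core_lo, core_hi = min(partners), max(partners)
    sidx = [i for i in range(core_lo, core_hi + 1) if table[i] != -1]
    bulge_star = 0
    for a, b in zip(sidx, sidx[1:]):
        bulge_star = max(bulge_star, b - a - 1)
    bulge = max(bulge_mature, bulge_star)

    mature_core = idx[-1] - idx[0] + 1
    star_core = core_hi - core_lo + 1
    asymmetry = abs(mature_core - star_core)

    # Dicer duplex geometry: the star pairs the mature minus its last 2 nt
    # (the mature's 3' overhang) and itself carries a 2-nt 3' overhang.
    inner = [table[i] for i in range(m0, max(m0, m1 - 2)) if table[i] != -1]
    star_core_lo = min(inner) if inner else core_lo
    n = len(fold_res.sequence)
    if core_lo >= m1:         # star is the 3' arm; its 3' end points right
        star_lo = star_core_lo
        star_hi = min(core_hi + 2, n - 1)
        gap = star_lo - m1
    else:                     # star is the 5' arm; its 3' end points right too
        star_lo = star_core_lo
        star_hi = min(core_hi + 2, m0 - 1)
        gap = m0 - star_hi - 1
    star_span = (star_lo, star_hi + 1)
    return star_span, paired, bulge, asymmetry, gap


def _evaluate_window(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    params: MireapParams,
    fold_fn: Callable[[str], FoldResult],
) -> tuple[FoldResult, dict, list[str]]:
    fr = fold_fn(rna(window_seq))
    star_span, paired, bulge, asym, gap = _duplex_diagnostics(
        fr, mature_offset, mature_offset + mature_len
    )
    reasons = []
    if fr.mfe > params.max_precursor_mfe:
        reasons.append(f"mfe {fr.mfe:.1f} > {params.max_precursor_mfe}")
    if paired < params.min_duplex_pairs:
        reasons.append(f"paired {paired} < {params.min_duplex_pairs}")
    if bulge > params.max_duplex_bulge:
        reasons.append(f"bulge {bulge} > {params.max_duplex_bulge}")
    if asym > params.max_duplex_asymmetry:
        reasons.append(f"asymmetry {asym} > {params.max_duplex_asymmetry}")
    if gap < 0 or gap > params.max_mature_star_gap:
        reasons.append(f"gap {gap} outside [0, {params.max_mature_star_gap}]")
    star = None
    if star_span is not None:
        star = rna(window_seq[star_span[0]: star_span[1]])
        if not params.min_star_len <= len(star) <= params.max_star_len:
            reasons.append(f"star length {len(star)} outside "
                           f"[{params.min_star_len}, {params.max_star_len}]")
    diag = {"star": star, "star_span": star_span, "paired": paired,
            "bulge": bulge, "asymmetry": asym, "gap": gap}
    return fr, diag, reasons


def predict_novel(
    tags: list[SequenceTag],
    genomic_hits: dict[str, list[GenomicHit]],
    genome: dict[str, str],
    params: MireapParams = MireapParams(),
    fold_fn: Callable[[str], FoldResult] = fold,
    require_star_tag: bool = False,
    keep_rejected: bool = False,
) -> list[HairpinCandidate]:
    """Predict hairpin candidates for unannotated mapped tags.

    Returns accepted candidates deduplicated by precursor locus (and all
    evaluated candidates, with rejection reasons, when ``keep_rejected``).
    """
    tag_seqs = {t.sequence for t in tags}
    candidates: list[HairpinCandidate] = []
    seen_loci: set[tuple] = set()
    for tag in filter_mature_length(tags, (params.min_mature_len, params.max_mature_len)):
        hits = genomic_hits.get(tag.sequence, [])
        if not hits or len(hits) > params.max_copy_number:
            continue
        for hit in hits:
            chrom_seq = genome[hit.chrom]
            L = len(tag.sequence)
            # candidate precursor extents: the star may sit anywhere up to
            # max_space away, so try short windows first and grow — the
            # smallest extent satisfying the criteria defines the precursor
            max_reach = (params.max_mature_star_gap + params.max_star_len
                         + params.flank)
            reaches = [r for r in (60, 120, 220) if r < max_reach] + [max_reach]
            best: HairpinCandidate | None = None
            for arm in ("5p", "3p"):
                for reach in reaches:
                    # flank on the mature side, reach on the star side
                    if (arm == "5p") == (hit.strand == "+"):
                        w0 = max(0, hit.start - params.flank)
                        w1 = min(len(chrom_seq), hit.end + reach)
                    else:
                        w0 = max(0, hit.start - reach)
                        w1 = min(len(chrom_seq), hit.end + params.flank)
                    window = chrom_seq[w0:w1]
                    if hit.strand == "+":
                        offset = hit.start - w0
                    else:
                        window = revcomp(window)
                        offset = w1 - hit.end
                    fr, diag, reasons = _evaluate_window(window, offset, L,
                                                         params, fold_fn)
                    if not reasons:
                        break
                if require_star_tag and diag["star"] is not None:
                    from .sequtil import dna as _dna
                    if _dna(diag["star"]) not in tag_seqs:
                        reasons.append("star not sequenced")
                cand = HairpinCandidate(
                    locus=(hit.chrom, w0, w1, hit.strand),
                    precursor=rna(window),
                    fold=fr,
                    mature=rna(tag.sequence),
                    mature_arm=arm,
                    mature_counts=(tag.count_ctl, tag.count_def),
                    star=diag["star"],
                    duplex_paired_bases=diag["paired"],
                    duplex_bulge_max=diag["bulge"],
                    duplex_asymmetry=diag["asymmetry"],
                    mature_star_gap=diag["gap"],
                    rejected=reasons,
                )
                if best is None or (cand.accepted and not best.accepted):
                    best = cand
                if cand.accepted:
                    break
            if best is None:
                continue
            locus_key = (hit.chrom, hit.start, hit.end, hit.strand)
            if best.accepted:
                if locus_key in seen_loci:
                    continue
                seen_loci.add(locus_key)
                candidates.append(best)
            elif keep_rejected:
                candidates.append(best)
    return candidates
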