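#!/usr/bin/env python
"""Identify known and novel miRNAs and check recovery against the truth.

Known miRNAs: tags matched to the mature reference with <= 2 mismatches.
Novel miRNAs: unannotated genome-mapped tags pushed through the hairpin
predictor (MFE <= -18 kcal/mol, >= 16 duplex pairs, bulge/asymmetry <= 4,
star 20-23 nt within 300 nt).  Reports recovery of the designed loci.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, cleaned_tags, study_inputs  # noqa: E402

from mirpipe.annotate import (  # noqa: E402
    Interval,
    annotate_cascade,
    map_perfect,
    match_known_mirnas,
)
from mirpipe.novel import predict_novel  # noqa: E402
from mirpipe.sequtil import rna  # noqa: E402


def main() -> None:
    bundle, profile, _, fq_ctl, fq_def = study_inputs()
    tags, stats_ctl, stats_def = cleaned_tags(profile, fq_ctl, fq_def)
    hits = map_perfect(tags, bundle.genome)
    assignments = match_known_mirnas(tags, bundle.known_mirnas)

    known_ids = {mid for mid, _ in assignments.values()}
    print(f"known miRNAs detected: {len(known_ids)} / {len(bundle.known_mirnas)}")

    exons = [Interval(c, s, e, st, n) for (c, s, e, n, st, t)
             in bundle.gene_features if t == "exon"]
    introns = [Interval(c, s, e, st, n) for (c, s, e, n, st, t)
               in bundle.gene_features if t == "intron"]
    repeats = [Interval(r[0], r[1], r[2], r[4], r[3])
               for r in bundle.repeat_intervals]
    records = annotate_cascade(tags, bundle.ncrna_refs, assignments,
                               repeats, exons, introns, hits)
    unann = [r.tag for r in records
             if r.category == "unannotated" and r.genomic_hits]
    print(f"unannotated mapped tags fed to the hairpin predictor: {len(unann)}")

    candidates = predict_novel(unann, hits, bundle.genome)
    rows = [{"locus": f"{c.locus[0]}:{c.locus[1]}-{c.locus[2]}({c.locus[3]})",
             "mature": c.mature, "arm": c.mature_arm, "mfe": c.fold.mfe,
             "paired": c.duplex_paired_bases, "gap": c.mature_star_gap,
             "count_ctl": c.mature_counts[0], "count_def": c.mature_counts[1]}
            for c in candidates]
    pd.DataFrame(rows).to_csv(RESULTS / "novel_candidates.tsv", sep="\t",
                              index=False)

    truth_matures = {rna(t.tag) for t in bundle.truth
                     if t.feature_class == "novel_hairpin"}
    recovered = truth_matures & {c.mature for c in candidates}
    print(f"novel hairpin candidates: {len(candidates)} "
          f"(designed loci recovered: {len(recovered)}/{len(truth_matures)})")


if __name__ == "__main__":
    main()
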