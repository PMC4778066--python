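"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same deterministic study inputs (seed 1):
a 60-kb synthetic genome with 12 known-miRNA and 6 novel hairpin loci,
4 genes, ncRNA/repeat features, and two pooled libraries of 100,000 reads
(one per condition, no replicates — matching a single-pooled-sample design).
FASTQ goes to scratch/ (bulky, regenerable); tables go to results/analysis/.
"""

from __future__ import annotations

from pathlib import Path

from mirpipe.preprocess import clean_reads, collapse_tags
from mirpipe.synth import (
    SyntheticGenomeSpec,
    build_genome,
    default_profile,
    simulate_libraries,
)

SEED = 1
DEPTH = 100_000

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "analysis"


def study_inputs():
    """Deterministic bundle + simulated libraries (cached on disk)."""
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    bundle = build_genome(SyntheticGenomeSpec(seed=SEED))
    profile = default_profile(bundle, seed=SEED, depth=DEPTH)
    fq_ctl, fq_def = SCRATCH / "ctl.fastq", SCRATCH / "def.fastq"
    counts = simulate_libraries(bundle, profile, fq_ctl, fq_def)
    return bundle, profile, counts, fq_ctl, fq_def


def cleaned_tags(profile, fq_ctl, fq_def):
    kept_ctl, stats_ctl = clean_reads(fq_ctl, profile.adapter_sequence)
    kept_def, stats_def = clean_reads(fq_def, profile.adapter_sequence)
    return collapse_tags(kept_ctl, kept_def), stats_ctl, stats_def
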