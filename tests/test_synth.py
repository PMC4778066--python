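"""Synthetic genome/library generator: determinism, truth, sampling noise."""

import dataclasses

import numpy as np
import pytest

from mirpipe.fold import fold
from mirpipe.novel import MireapParams
from mirpipe.sequtil import rna
from mirpipe.synth import (
    ExpressionProfile,
    PlacementError,
    SyntheticGenomeSpec,
    build_genome,
    expected_proportions,
    simulate_libraries,
)

EMPTY = dict(n_known_mirnas=0, n_novel_hairpins=0, n_genes=0, n_repeats=0,
             n_unmapped_tags=0,
             n_ncrna_fragments={c: 0 for c in ("rRNA", "tRNA", "snRNA", "snoRNA")})


def test_empty_spec_yields_background_only():
    b = build_genome(SyntheticGenomeSpec(genome_length=500, seed=3, **EMPTY))
    assert len(b.genome["chr1"]) == 500
    assert b.truth == [] and b.known_mirnas == {}


def test_build_is_deterministic():
    a = build_genome(SyntheticGenomeSpec(seed=1))
    b = build_genome(SyntheticGenomeSpec(seed=1))
    assert a.genome == b.genome
    assert a.truth_frame().equals(b.truth_frame())
    c = build_genome(SyntheticGenomeSpec(seed=2))
    assert c.genome != a.genome


def test_placement_failure_names_class():
    with pytest.raises(PlacementError, match="known_miRNA"):
        build_genome(SyntheticGenomeSpec(genome_length=300, seed=1))


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticGenomeSpec(n_genes=-1)
    with pytest.raises(ValueError):
        SyntheticGenomeSpec(flank_gc=1.5)
    with pytest.raises(ValueError):
        ExpressionProfile({}, {}, sequencing_error_rate=0.2)


def test_novel_hairpins_refold_below_threshold(bundle):
    """Every emitted precursor re-folds to MFE <= -18 kcal/mol."""
    truth = {t.feature_id: t for t in bundle.truth}
    hairpins = [t for t in bundle.truth
                if t.feature_class in ("novel_hairpin", "known_miRNA")]
    assert sum(t.feature_class == "novel_hairpin" for t in hairpins) == 6
    for t in hairpins:
        seq = bundle.genome[t.chrom][t.precursor_start:t.precursor_end]
        if t.strand == "-":
            from mirpipe.sequtil import revcomp
            seq = revcomp(seq)
        assert fold(rna(seq)).mfe <= MireapParams().max_precursor_mfe
        # the mature tag sits inside its precursor on the recorded strand
        assert t.precursor_start <= t.start < t.end <= t.precursor_end
    assert truth  # non-empty


def test_truth_tags_unique_in_genome(bundle):
    g = bundle.genome["chr1"]
    from mirpipe.sequtil import revcomp
    for t in bundle.truth:
        n = g.count(t.tag) + g.count(revcomp(t.tag))
        assert n == (0 if t.feature_class == "unmapped" else 1)


def test_depth_zero_gives_empty_fastq(bundle, tmp_path):
    prof = ExpressionProfile(
        baseline_tpm={t.feature_id: 100.0 for t in bundle.truth},
        log2_fold_change={}, library_depth_ctl=0, library_depth_def=0, seed=0)
    simulate_libraries(bundle, prof, tmp_path / "c.fq", tmp_path / "d.fq")
    assert (tmp_path / "c.fq").read_text() == ""
    assert (tmp_path / "d.fq").read_text() == ""


def test_profiled_feature_must_exist(bundle, tmp_path):
    prof = ExpressionProfile(baseline_tpm={"nope": 1.0}, log2_fold_change={})
    with pytest.raises(ValueError, match="absent from bundle"):
        simulate_libraries(bundle, prof, tmp_path / "c.fq", tmp_path / "d.fq")


def test_expected_counts_and_sampling_noise(bundle, tmp_path):
    """A feature at TPM 1000 of a 10000-TPM pool at depth 1e5 has expected
    count 1e4; the observed draw stays within 4 sigma (p > 0.999)."""
    ids = [t.feature_id for t in bundle.truth][:10]
    prof = ExpressionProfile(
        baseline_tpm={i: 1000.0 for i in ids},
        log2_fold_change={i: 0.0 for i in ids},
        library_depth_ctl=100_000, library_depth_def=100_000,
        sequencing_error_rate=0.0, seed=21)
    table = simulate_libraries(bundle, prof, tmp_path / "c.fq", tmp_path / "d.fq")
    expected = 100_000 / 10
    sigma = np.sqrt(expected * 0.9)
    for row in table.itertuples(index=False):
        assert row.expected_ctl == pytest.approx(expected)
        assert row.expected_def == pytest.approx(expected)
        assert abs(row.count_ctl - expected) < 4 * sigma
        assert abs(row.count_def - expected) < 4 * sigma


def test_proportions_sum_to_one_and_fold_change_monotonicity(bundle):
    prof = ExpressionProfile(
        baseline_tpm={t.feature_id: 50.0 for t in bundle.truth},
        log2_fold_change={bundle.truth[0].feature_id: 1.0})
    p_ctl, p_def = expected_proportions(prof)
    assert p_ctl.sum() == pytest.approx(1.0)
    assert p_def.sum() == pytest.approx(1.0)
    fid = bundle.truth[0].feature_id
    base = p_def[fid]
    stronger = dataclasses.replace(
        prof, log2_fold_change={fid: 2.0})
    _, p_def2 = expected_proportions(stronger)
    assert p_def2[fid] > base  # raising lfc never lowers the expected count


def test_simulation_deterministic(bundle, tmp_path):
    prof = ExpressionProfile(
        baseline_tpm={t.feature_id: 100.0 for t in bundle.truth},
        log2_fold_change={}, library_depth_ctl=2000, library_depth_def=2000,
        seed=5)
    simulate_libraries(bundle, prof, tmp_path / "c1.fq", tmp_path / "d1.fq")
    simulate_libraries(bundle, prof, tmp_path / "c2.fq", tmp_path / "d2.fq")
    assert (tmp_path / "c1.fq").read_bytes() == (tmp_path / "c2.fq").read_bytes()
    assert (tmp_path / "d1.fq").read_bytes() == (tmp_path / "d2.fq").read_bytes()
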