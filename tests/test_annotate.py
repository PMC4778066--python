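"""Genome mapping, known-miRNA matching, the cascade, and library accounting."""

import pytest

from mirpipe.annotate import (
    Interval,
    annotate_cascade,
    category_percentage,
    load_table1_counts,
    map_perfect,
    match_known_mirnas,
    summarize_table1,
)
from mirpipe.preprocess import SequenceTag
from mirpipe.sequtil import revcomp


@pytest.fixture()
def toy_genome():
    import numpy as np
    rng = np.random.default_rng(5)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=400))}


def test_map_perfect_both_strands(toy_genome):
    g = toy_genome["chr1"]
    plus = SequenceTag(g[100:124])
    minus = SequenceTag(revcomp(g[200:222]))
    absent = SequenceTag("A" * 25)
    hits = map_perfect([plus, minus, absent], toy_genome)
    (h,) = hits[plus.sequence]
    assert (h.start, h.end, h.strand) == (100, 124, "+")
    (h,) = hits[minus.sequence]
    assert (h.start, h.end, h.strand) == (200, 222, "-")
    assert hits[absent.sequence] == []


def test_match_known_mirnas_mismatch_ladder():
    ref = {"mirA": "ACGUACGUACGUACGUACGUA"}  # RNA reference, DNA comparison
    base = "ACGTACGTACGTACGTACGTA"
    two = "TTGTACGTACGTACGTACGTA"
    three = "TTTTACGTACGTACGTACGTA"
    tags = [SequenceTag(s) for s in (base, two, three)]
    got = match_known_mirnas(tags, ref, max_mismatches=2)
    assert got[base] == ("mirA", 0)
    assert got[two] == ("mirA", 2)
    assert three not in got


def _cascade(tag, **kw):
    defaults = dict(ncrna_refs={}, known_assignments={}, repeats=[], exons=[],
                    introns=[], genomic_hits={tag.sequence: []})
    defaults.update(kw)
    return annotate_cascade([tag], **defaults)[0]


def test_cascade_priority(toy_genome):
    g = toy_genome["chr1"]
    tag = SequenceTag(g[100:124])
    hits = map_perfect([tag], toy_genome)
    exon = [Interval("chr1", 90, 150, "+", "gene1.exon1")]
    # matches an rRNA reference AND overlaps an exon: rRNA wins
    rec = _cascade(tag, ncrna_refs={"rRNA": {"rrna1": g[80:160]}},
                   exons=exon, genomic_hits=hits)
    assert rec.category == "rRNA"
    # known-miRNA assignment beats a repeat overlap
    rec = _cascade(tag, known_assignments={tag.sequence: ("mirA", 0)},
                   repeats=[Interval("chr1", 90, 150, "+", "rep1")],
                   genomic_hits=hits)
    assert rec.category == "known_miRNA"
    # repeat beats exon
    rec = _cascade(tag, repeats=[Interval("chr1", 90, 150, "+", "rep1")],
                   exons=exon, genomic_hits=hits)
    assert rec.category == "repeat"
    # exon strand agreement -> sense; opposite -> antisense
    rec = _cascade(tag, exons=exon, genomic_hits=hits)
    assert rec.category == "exon_sense"
    rec = _cascade(tag, exons=[Interval("chr1", 90, 150, "-", "g.e")],
                   genomic_hits=hits)
    assert rec.category == "exon_antisense"
    # nothing matches -> unannotated
    assert _cascade(tag, genomic_hits=hits).category == "unannotated"


def test_cascade_priority_is_order_independent(toy_genome):
    """Later-stage references cannot steal tags claimed by earlier stages."""
    g = toy_genome["chr1"]
    tag = SequenceTag(g[100:124])
    hits = map_perfect([tag], toy_genome)
    everything = dict(
        ncrna_refs={"rRNA": {"r1": g[80:160]}, "tRNA": {"t1": g[80:160]}},
        known_assignments={tag.sequence: ("mirA", 0)},
        repeats=[Interval("chr1", 90, 150, "+", "rep")],
        exons=[Interval("chr1", 90, 150, "+", "ex")],
        introns=[Interval("chr1", 90, 150, "+", "in")],
        genomic_hits=hits,
    )
    assert _cascade(tag, **everything).category == "rRNA"
    without_rrna = dict(everything)
    without_rrna["ncrna_refs"] = {"tRNA": {"t1": g[80:160]}}
    assert _cascade(tag, **without_rrna).category == "tRNA"


def test_partition_invariant(bundle, simulated):
    """Category totals (incl. unannotated) sum to clean reads per library."""
    from mirpipe.preprocess import clean_reads, collapse_tags

    kept_c, st_c = clean_reads(simulated["fastq_ctl"],
                               simulated["profile"].adapter_sequence)
    kept_d, st_d = clean_reads(simulated["fastq_def"],
                               simulated["profile"].adapter_sequence)
    tags = collapse_tags(kept_c, kept_d)
    hits = map_perfect(tags, bundle.genome)
    assignments = match_known_mirnas(tags, bundle.known_mirnas)
    exons = [Interval(c, s, e, st, n) for (c, s, e, n, st, t)
             in bundle.gene_features if t == "exon"]
    introns = [Interval(c, s, e, st, n) for (c, s, e, n, st, t)
               in bundle.gene_features if t == "intron"]
    repeats = [Interval(r[0], r[1], r[2], r[4], r[3])
               for r in bundle.repeat_intervals]
    records = annotate_cascade(tags, bundle.ncrna_refs, assignments,
                               repeats, exons, introns, hits)
    df = summarize_table1(records, st_c.clean_reads, st_d.clean_reads)
    cats = df.drop(index=["clean_reads", "mapped_to_genome"])
    assert cats["total_ctl"].sum() == st_c.clean_reads
    assert cats["total_def"].sum() == st_d.clean_reads
    assert cats["unique_ctl"].sum() == df.loc["clean_reads", "unique_ctl"]


def test_gff_without_strand_errors(tmp_path):
    from mirpipe.annotate import read_gff_features
    gff = tmp_path / "x.gff3"
    gff.write_text("chr1\tsrc\texon\t1\t10\t.\t.\t.\tID=e1\n")
    with pytest.raises(ValueError, match="without strand"):
        read_gff_features(gff, ("exon",))


@pytest.mark.parametrize("count, clean, pct", [
    (2_280_530, 20_328_011, 11.22),   # printed miRNA share, control library
    (4_888_886, 22_218_850, 22.00),   # printed miRNA share, deficiency library
])
def test_percentage_formula_reproduces_printed_values(count, clean, pct):
    assert category_percentage(count, clean) == pct


def test_summarize_on_printed_counts():
    """The percentage formula over the published count table reproduces the
    printed category percentages."""
    t1 = load_table1_counts()
    clean_ctl = int(t1.loc["clean_reads", "total_ctl"])
    clean_def = int(t1.loc["clean_reads", "total_def"])
    assert category_percentage(int(t1.loc["rRNA", "total_ctl"]), clean_ctl) == 37.87
    assert category_percentage(int(t1.loc["unannotated", "total_def"]), clean_def) == 53.17


def test_empty_library_all_zero():
    df = summarize_table1([], 0, 0)
    assert (df[["unique_ctl", "total_ctl", "unique_def", "total_def"]]
            .iloc[1:].to_numpy() == 0).all()
    assert df["pct_total_ctl"].isna().all()
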