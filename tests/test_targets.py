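"""Duplex alignment, the six target rules, and transcript scanning."""

import pytest

from mirpipe.sequtil import rna
from mirpipe.targets import align_duplex, apply_rules, scan_transcripts
from oracles import rule_check_window

WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
GU_PARTNER = {"G": "U", "U": "G"}
MM_PARTNER = {"A": "G", "U": "C", "G": "G", "C": "C"}


def build_site(mirna: str, states: dict[int, str]) -> str:
    """Target site (5'->3') realizing the requested per-position states
    (1-based miRNA positions; default WC)."""
    site_rev = []
    for k, m in enumerate(mirna, start=1):
        state = states.get(k, "WC")
        partner = {"WC": WC_PARTNER, "GU": GU_PARTNER, "MM": MM_PARTNER}[state][m]
        site_rev.append(partner)
    return "".join(reversed(site_rev))


# AU-only miRNA (U at odd, A at even positions): every WC stack is -2 and
# every wobble stack -1, which keeps single-rule violations from dragging
# the MFE ratio below rule (f)'s bar
MIR = "UA" * 10 + "U"


def test_perfect_complement_all_rules_pass():
    site = build_site(MIR, {})
    dup = align_duplex(MIR, site)
    assert all(s == "WC" for s in dup.position_states)
    assert dup.mismatch_score == 0.0
    assert dup.mfe_duplex == dup.mfe_perfect
    flags = apply_rules(dup)
    assert all(flags.values()) and dup.mfe_ratio == pytest.approx(1.0)


def test_gu_scores_half():
    dup = align_duplex(MIR, build_site(MIR, {5: "GU"}))
    assert dup.position_states[4] == "GU"
    assert dup.mismatch_score == 0.5


def test_adjacent_mm_plus_gu_scores():
    dup = align_duplex(MIR, build_site(MIR, {14: "MM", 15: "MM", 5: "GU"}))
    assert dup.mismatch_score == 2.5


def test_empty_sequences_error():
    with pytest.raises(ValueError):
        align_duplex("", "ACGU")


@pytest.mark.parametrize("states, broken", [
    # nine wobbles: score 4.5 > 4 but every other rule still satisfied
    ({k: "GU" for k in (1, 3, 5, 7, 9, 13, 15, 17, 19)}, "a"),
    # adjacent mismatches inside positions 2-12
    ({5: "MM", 6: "MM"}, "c"),
    # a single mismatch at position 10
    ({10: "MM"}, "d"),
    # 2.5 + 0.5 mismatch weight within positions 1-12, total still <= 4
    ({1: "GU", 3: "GU", 5: "GU", 7: "GU", 9: "MM"}, "e"),
    # four isolated mismatches: score 4 passes (a) but kills the MFE ratio
    ({3: "MM", 6: "MM", 14: "MM", 17: "MM"}, "f"),
])
def test_single_rule_violations_flip_exactly_one_flag(states, broken):
    mir = MIR
    # GU states need U or G at the miRNA position; MIR is U at odd positions
    dup = align_duplex(mir, build_site(mir, states))
    flags = apply_rules(dup)
    assert flags[broken] is False
    others = {r: v for r, v in flags.items() if r != broken}
    assert all(others.values()), f"unexpected extra failures: {others}"


def test_rule_b_allows_two_but_not_three_adjacent():
    two = apply_rules(align_duplex(MIR, build_site(MIR, {14: "MM", 15: "MM"})))
    assert two["b"] is True
    three = apply_rules(align_duplex(
        MIR, build_site(MIR, {14: "MM", 15: "MM", 16: "MM"})))
    assert three["b"] is False


def test_gu_does_not_block_adjacency_by_default():
    mir = "UAUAUUAUAUAUAUAUAUAUA"  # U at positions 5 and 6
    dup = align_duplex(mir, build_site(mir, {5: "GU", 6: "GU"}))
    assert apply_rules(dup)["c"] is True
    assert apply_rules(dup, gu_blocks_adjacency=True)["c"] is False


def test_added_mismatch_never_lowers_score():
    base = align_duplex(MIR, build_site(MIR, {5: "GU"}))
    worse = align_duplex(MIR, build_site(MIR, {5: "GU", 14: "MM"}))
    assert worse.mismatch_score > base.mismatch_score


def test_scan_finds_embedded_sites():
    site = build_site(MIR, {})
    t = "ACCGGA" * 10 + site + "UUUCCA" * 5
    preds = scan_transcripts({"m1": MIR}, {"t1": t})
    assert len(preds) == 1
    assert preds[0].start == 61 and preds[0].end == 60 + len(MIR)
    # two disjoint perfect sites -> two predictions in coordinate order
    t2 = site + "ACCGGA" * 8 + site
    preds = scan_transcripts({"m1": MIR}, {"t2": t2})
    assert [p.start for p in preds] == [1, len(site) + 48 + 1]


def test_scan_empty_when_no_window_passes():
    preds = scan_transcripts({"m1": "GGGGGGGGGGGGGGGGGGGGG"},
                             {"t1": "G" * 120})
    assert preds == []
    with pytest.raises(ValueError):
        scan_transcripts({"m1": MIR}, {})


def test_scan_matches_exhaustive_window_oracle(bundle):
    """Scan output equals an independently coded per-window rule check on
    transcripts <= 200 nt (after collapsing overlapping windows)."""
    mirnas = dict(list(bundle.known_mirnas.items())[:6])
    transcripts = {tid: seq[:200] for tid, seq in bundle.transcripts.items()}
    preds = scan_transcripts(mirnas, transcripts)
    reported = {(p.mirna_id, p.transcript_id, p.start) for p in preds}
    for mid, mir in mirnas.items():
        mir = rna(mir)
        L = len(mir)
        for tid, tseq in transcripts.items():
            tseq = rna(tseq)
            oracle_pass = [pos for pos in range(len(tseq) - L + 1)
                           if rule_check_window(mir, tseq[pos:pos + L])]
            # every reported window passes the oracle
            for (m, t, start) in reported:
                if m == mid and t == tid:
                    assert (start - 1) in oracle_pass
            # every oracle-passing window is reported or overlaps a report
            starts = sorted(start - 1 for (m, t, start) in reported
                            if m == mid and t == tid)
            for pos in oracle_pass:
                assert any(abs(pos - s) < L for s in starts)
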