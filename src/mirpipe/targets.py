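"""Plant miRNA target prediction: duplex alignment and the six rules.

A miRNA is aligned antiparallel against a candidate target site; each miRNA
position (numbered 1..L from the miRNA 5' end) gets a state: WC
(Watson-Crick pair), GU (wobble, weighted 0.5 mismatch), MM (mismatch,
weight 1) or BULGE (unpaired/inserted base, weight 1).  A prediction must
pass all of:

  (a) total mismatch score <= 4;
  (b) no run of more than two adjacent mismatch/bulge positions;
  (c) no adjacent mismatches within positions 2-12;
  (d) positions 10-11 strictly Watson-Crick (a wobble is half a mismatch,
      hence "no mismatches" excludes it);
  (e) mismatch score over positions 1-12 <= 2.5;
  (f) duplex MFE > 75% of the MFE of the miRNA paired to its perfect
      complement (same stacked-pair energy model as the folding engine,
      restricted to intermolecular stacks).

GU wobbles never count toward adjacency in (b)/(c) by default (a partial
mismatch does not block); a strict mode treats them as adjacency-blocking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import STACK_ENERGY
from .sequtil import rna

RULE_IDS = ("a", "b", "c", "d", "e", "f")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

STATE_WEIGHT = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "BULGE": 1.0}


@dataclass(frozen=True)
class DuplexAlignment:
    mirna: str                 # RNA, 5'->3'
    site: str                  # target site, RNA, 5'->3'
    position_states: tuple    # per miRNA position 1..L (plus BULGE entries)
    mismatch_score: float
    mfe_duplex: float
    mfe_perfect: float

    @property
    def mfe_ratio(self) -> float:
        return self.mfe_duplex / self.mfe_perfect if self.mfe_perfect < 0 else 0.0


@dataclass(frozen=True)
class TargetPrediction:
    mirna_id: str
    transcript_id: str
    start: int                 # 1-based inclusive on the transcript
    end: int
    duplex: DuplexAlignment
    rule_flags: dict

    @property
    def passed(self) -> bool:
        return all(self.rule_flags.values())


def _pair_state(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "WC"
    if (m, t) in _GU:
        return "GU"
    return "MM"


def _states_same_length(mir: str, site: str) -> list[str]:
    # antiparallel: miRNA position k (0-based from 5') faces site position L-1-k
    L = len(mir)
    return [_pair_state(mir[k], site[L - 1 - k]) for k in range(L)]


def _duplex_energies(mir: str, states: list[str]) -> tuple[float, float]:
    """Intermolecular stacked-pair energies of this duplex and of the
    miRNA:perfect-complement duplex (all WC, same model)."""
    paired = [s in ("WC", "GU") for s in states]
    e = 0.0
    k = 0
    for k in range(len(mir) - 1):
        if paired[k] and paired[k + 1]:
            # stack energy keyed by the 5'-most pair of the step
            comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
            partner = comp[mir[k]] if states[k] == "WC" else (
                "U" if mir[k] == "G" else "G")
            e += STACK_ENERGY[(mir[k], partner)]
    perfect = 0.0
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for k in range(len(mir) - 1):
        perfect += STACK_ENERGY[(mir[k], comp[mir[k]])]
    return e, perfect


def align_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Align a miRNA against a target site (both 5'->3', antiparallel).

    Equal lengths align position-by-position; a length difference of one is
    absorbed by a single bulge placed to minimise the mismatch score.  Larger
    differences are rejected (one bulge can only absorb one nucleotide).
    """
    mir, st = rna(mirna), rna(site)
    if not mir or not st:
        raise ValueError("empty sequence")
    diff = len(st) - len(mir)
    if abs(diff) > 1:
        raise ValueError("length difference > 1 not supported (single-bulge policy)")

    if diff == 0:
        states = _states_same_length(mir, st)
    elif diff == 1:
        # extra target base: bulge on the target side; try every position
        best = None
        for b in range(len(st)):
            reduced = st[:b] + st[b + 1:]
            s = _states_same_length(mir, reduced)
            # bulge sits between miRNA positions; append as an extra state
            cand = s + ["BULGE"]
            score = sum(STATE_WEIGHT[x] for x in cand)
            if best is None or score < best[1]:
                best = (cand, score)
        states = best[0]
    else:
        # missing target base: one miRNA base bulged out
        best = None
        for b in range(len(mir)):
            reduced = mir[:b] + mir[b + 1:]
            s = _states_same_length(reduced, st)
            cand = s[:b] + ["BULGE"] + s[b:]
            score = sum(STATE_WEIGHT[x] for x in cand)
            if best is None or score < best[1]:
                best = (cand, score)
        states = best[0]

    score = sum(STATE_WEIGHT[s] for s in states)
    mir_states = [s for s in states][: len(mir)] if diff >= 0 else states
    e_duplex, e_perfect = _duplex_energies(mir, mir_states[: len(mir)])
    return DuplexAlignment(
        mirna=mir, site=st, position_states=tuple(states),
        mismatch_score=score, mfe_duplex=e_duplex, mfe_perfect=e_perfect,
    )


def apply_rules(duplex: DuplexAlignment,
                gu_blocks_adjacency: bool = False,
                max_adjacent: int = 2) -> dict:
    """Evaluate rules (a)-(f); returns {rule: bool}."""
    states = list(duplex.position_states)
    bad = {"MM", "BULGE"}
    if gu_blocks_adjacency:
        bad = bad | {"GU"}

    def longest_bad_run(sub):
        run = best = 0
        for s in sub:
            run = run + 1 if s in bad else 0
            best = max(best, run)
        return best

    # positions 1..L of the miRNA (bulge states participate in adjacency)
    flags = {}
    flags["a"] = duplex.mismatch_score <= 4.0
    flags["b"] = longest_bad_run(states) <= max_adjacent
    flags["c"] = longest_bad_run(states[1:12]) <= 1
    flags["d"] = all(s == "WC" for s in states[9:11])
    flags["e"] = sum(STATE_WEIGHT[s] for s in states[:12]) <= 2.5
    flags["f"] = (duplex.mfe_perfect < 0
                  and duplex.mfe_duplex / duplex.mfe_perfect > 0.75)
    return flags


def scan_transcripts(mirnas: dict[str, str], transcripts: dict[str, str],
                     gu_blocks_adjacency: bool = False) -> list[TargetPrediction]:
    """Scan every same-length window of every transcript for target sites.

    Transcripts are DNA or RNA, 5'->3'.  Overlapping passing windows of one
    miRNA on one transcript are merged to the best-scoring one (ties to the
    leftmost).  Results sorted by (transcript, position, miRNA id).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    hits: list[TargetPrediction] = []
    for mid in sorted(mirnas):
        mir = rna(mirnas[mid])
        L = len(mir)
        for tid in sorted(transcripts):
            tseq = rna(transcripts[tid])
            window_hits = []
            for pos in range(0, len(tseq) - L + 1):
                site = tseq[pos: pos + L]
                dup = align_duplex(mir, site)
                flags = apply_rules(dup, gu_blocks_adjacency)
                if all(flags.values()):
                    window_hits.append(TargetPrediction(
                        mirna_id=mid, transcript_id=tid,
                        start=pos + 1, end=pos + L, duplex=dup,
                        rule_flags=flags,
                    ))
            hits.extend(_merge_overlapping(window_hits))
    return sorted(hits, key=lambda h: (h.transcript_id, h.start, h.mirna_id))


def _merge_overlapping(preds: list[TargetPrediction]) -> list[TargetPrediction]:
    merged: list[TargetPrediction] = []
    for p in preds:  # already in coordinate order
        if merged and p.start <= merged[-1].end:
            if p.duplex.mismatch_score < merged[-1].duplex.mismatch_score:
                merged[-1] = p
        else:
            merged.append(p)
    return merged
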