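"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive enumeration,
exact rational arithmetic, direct rule re-implementation) and share nothing
with the package's implementations beyond the published constants.
"""

from __future__ import annotations

import math
from fractions import Fraction

# --- folding: exhaustive enumeration over all nested structures ------------

_PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0,
           ("U", "A"): -2.0, ("G", "U"): -1.0, ("U", "G"): -1.0}
_MIN_LOOP = 3


def _structures(seq: str, i: int, j: int):
    """Yield every nested pair set on seq[i..j] (loop >= 3), each once."""
    if i >= j:
        yield []
        return
    yield from _structures(seq, i + 1, j)
    for k in range(i + _MIN_LOOP + 1, j + 1):
        if (seq[i], seq[k]) in _PAIR_E:
            for inner in _structures(seq, i + 1, k - 1):
                for outer in _structures(seq, k + 1, j):
                    yield [(i, k)] + inner + outer


def _pairset_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    pset = set(pairs)
    return sum(_PAIR_E[(seq[i], seq[j])]
               for (i, j) in pairs if (i + 1, j - 1) in pset)


def brute_force_mfe(seq: str) -> float:
    """Minimum stacked-pair energy over every nested structure of seq."""
    seq = seq.upper().replace("T", "U")
    best = 0.0
    for pairs in _structures(seq, 0, len(seq) - 1):
        e = _pairset_energy(seq, pairs)
        if e < best:
            best = e
    return best


# --- exact count test: rational arithmetic --------------------------------

def exact_test_rational(x: int, y: int, N1: int, N2: int
                        ) -> tuple[float, float, float]:
    """(p_point, tail_lower, tail_upper) as exact rationals -> float."""
    r = Fraction(N2, N1)
    one = Fraction(1)

    def pmf(yy: int) -> Fraction:
        return (r ** yy * math.comb(x + yy, yy)
                / (one + r) ** (x + yy + 1))

    lower = sum(pmf(t) for t in range(y + 1))
    point = pmf(y)
    upper = one - lower + point
    return float(point), float(lower), float(upper)


# --- target rules: independent checker ------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def rule_check_window(mirna: str, site: str) -> bool:
    """Independent pass/fail decision for one same-length duplex window."""
    L = len(mirna)
    assert len(site) == L
    states = []
    for k in range(L):
        pair = (mirna[k], site[L - 1 - k])
        if pair in _WC:
            states.append("WC")
        elif pair in _GU:
            states.append("GU")
        else:
            states.append("MM")
    w = {"WC": 0.0, "GU": 0.5, "MM": 1.0}
    score = sum(w[s] for s in states)
    if score > 4:
        return False
    run = 0
    for s in states:
        run = run + 1 if s == "MM" else 0
        if run > 2:
            return False
    for k in range(1, 11):  # adjacent pair (k, k+1) fully inside pos 2..12
        if states[k] == "MM" and states[k + 1] == "MM":
            return False
    if states[9] != "WC" or states[10] != "WC":
        return False
    if sum(w[s] for s in states[:12]) > 2.5:
        return False
    # duplex energy: stack step k counted when positions k, k+1 both pair,
    # keyed by the 5'-most pair
    def step_e(k: int, st) -> float:
        partner = {"A": "U", "U": "A", "G": "C", "C": "G"}[mirna[k]] \
            if st[k] == "WC" else ("U" if mirna[k] == "G" else "G")
        return _PAIR_E[(mirna[k], partner)]

    e = sum(step_e(k, states) for k in range(L - 1)
            if states[k] != "MM" and states[k + 1] != "MM")
    perfect = sum(step_e(k, ["WC"] * L) for k in range(L - 1))
    return perfect < 0 and e / perfect > 0.75
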