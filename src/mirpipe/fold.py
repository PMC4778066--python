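"""RNA secondary-structure folding under a simplified stacked-pair energy model.

The default engine finds the minimum-free-energy *nested* structure (no
pseudoknots) where the only energy contributions are helix stacking steps:
a base pair (i, j) whose inner neighbour (i+1, j-1) is also paired
contributes the stacking energy of the outer pair's type,

    GC/CG: -3.0   AU/UA: -2.0   GU/UG: -1.0   (kcal/mol)

Hairpin loops shorter than 3 nt are forbidden; there are no dangling-end,
loop-size or multiloop terms.  Isolated (unstacked) pairs therefore carry
zero energy and the traceback omits them, so an unpairable sequence folds to
the all-dot structure with an MFE of exactly 0.

Absolute energies from this model are *not* comparable to Turner-parameter
thermodynamic folders; every threshold used downstream (the -18 kcal/mol
precursor gate, the duplex-MFE ratio) is interpreted under this same model.
Any backend honouring the ``FoldResult`` contract may be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

RNA_ALPHABET = set("ACGU")

# stacking energy keyed by the outer pair (5' base, 3' base)
STACK_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

MIN_HAIRPIN_LOOP = 3  # minimum unpaired nt closed by a pair

_INF = 1e9


@dataclass(frozen=True)
class FoldResult:
    """Minimum-energy structure of one RNA sequence."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length must equal sequence length")

    def pair_table(self) -> list[int]:
        """Partner index per position (-1 if unpaired), from the dot-bracket."""
        stack: list[int] = []
        table = [-1] * len(self.structure)
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        if stack:
            raise ValueError("unbalanced structure")
        return table


def can_pair(a: str, b: str) -> bool:
    return (a, b) in STACK_ENERGY


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _fold_tables(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Fill the W (unconstrained) and V (i paired to j) DP tables.

    W[i, j]: MFE of subsequence i..j.
    V[i, j]: MFE of i..j given (i, j) paired; +inf when the pair is illegal.
    """
    n = len(seq)
    W = np.zeros((n + 1, n + 1))
    V = np.full((n + 1, n + 1), _INF)
    pairable = np.zeros((n, n), dtype=bool)
    stack_e = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if can_pair(seq[i], seq[j]):
                pairable[i, j] = True
                stack_e[i, j] = STACK_ENERGY[(seq[i], seq[j])]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                v = W[i + 1, j - 1]
                if pairable[i + 1, j - 1]:
                    v = min(v, stack_e[i, j] + V[i + 1, j - 1])
                V[i, j] = v
            # W: leave i or j unpaired, or bifurcate with (k, j) paired
            w = min(W[i + 1, j], W[i, j - 1])
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                if pairable[k, j]:
                    left = W[i, k - 1] if k > i else 0.0
                    w = min(w, left + V[k, j])
            W[i, j] = w
    return W, V


try:  # optional JIT: identical semantics, needed only for long precursors
    from numba import njit as _njit

    _fold_tables_jit = None

    def _build_jit():
        @_njit(cache=False)
        def core(codes, pairable, stack_e):  # pragma: no cover - numba body
            n = codes.shape[0]
            W = np.zeros((n + 1, n + 1))
            V = np.full((n + 1, n + 1), _INF)
            for span in range(MIN_HAIRPIN_LOOP + 1, n):
                for i in range(0, n - span):
                    j = i + span
                    if pairable[i, j]:
                        v = W[i + 1, j - 1]
                        if pairable[i + 1, j - 1]:
                            s = stack_e[i, j] + V[i + 1, j - 1]
                            if s < v:
                                v = s
                        V[i, j] = v
                    w = W[i + 1, j]
                    if W[i, j - 1] < w:
                        w = W[i, j - 1]
                    for k in range(i, j - MIN_HAIRPIN_LOOP):
                        if pairable[k, j]:
                            left = W[i, k - 1] if k > i else 0.0
                            if left + V[k, j] < w:
                                w = left + V[k, j]
                    W[i, j] = w
            return W, V

        return core

    def _fold_tables_fast(seq: str) -> tuple[np.ndarray, np.ndarray]:
        global _fold_tables_jit
        if _fold_tables_jit is None:
            _fold_tables_jit = _build_jit()
        n = len(seq)
        pairable = np.zeros((n, n), dtype=np.bool_)
        stack_e = np.zeros((n, n))
        for i in range(n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                if can_pair(seq[i], seq[j]):
                    pairable[i, j] = True
                    stack_e[i, j] = STACK_ENERGY[(seq[i], seq[j])]
        W, V = _fold_tables_jit(_encode(seq), pairable, stack_e)
        return W, V

except ImportError:  # pragma: no cover
    _fold_tables_fast = _fold_tables

# pure-python DP is fine below this length; above it the JIT pays off
_JIT_THRESHOLD = 60


def fold(sequence: str) -> FoldResult:
    """Fold an RNA sequence to its minimum-energy nested structure.

    Ties are broken in favour of fewer pairs, so energetically neutral
    isolated pairs are never reported.
    """
    seq = sequence.upper().replace("T", "U") if sequence else ""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    n = len(seq)
    if n == 0:
        return FoldResult("", "", 0.0)
    if n > 1000:
        raise ValueError("sequence longer than 1000 nt")
    tables = _fold_tables_fast if n > _JIT_THRESHOLD else _fold_tables
    W, V = tables(seq)
    structure = ["."] * n
    _traceback_w(seq, W, V, 0, n - 1, structure)
    return FoldResult(seq, "".join(structure), float(W[0, n - 1]))


def _traceback_w(seq, W, V, i, j, out) -> None:
    eps = 1e-7
    while i < j:
        target = W[i, j]
        if target >= -eps:  # nothing stabilising here: leave unpaired
            return
        if W[i + 1, j] <= target + eps:
            i += 1
            continue
        if W[i, j - 1] <= target + eps:
            j -= 1
            continue
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            left = W[i, k - 1] if k > i else 0.0
            if V[k, j] < _INF / 2 and left + V[k, j] <= target + eps:
                _traceback_v(seq, W, V, k, j, out)
                j = k - 1
                break
        else:  # numerical safety net; should be unreachable
            return


def _traceback_v(seq, W, V, i, j, out) -> None:
    eps = 1e-7
    out[i], out[j] = "(", ")"
    stacked = (
        V[i + 1, j - 1] < _INF / 2
        and STACK_ENERGY[(seq[i], seq[j])] + V[i + 1, j - 1] <= V[i, j] + eps
    )
    if stacked:
        _traceback_v(seq, W, V, i + 1, j - 1, out)
    else:
        _traceback_w(seq, W, V, i + 1, j - 1, out)


def fold_energy_of_pairs(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit pair list under the same stacked-pair model.

    Used by the brute-force enumeration oracle in the test suite; kept here
    so oracle and engine share only the energy *table*, not the search.
    """
    pairset = set(pairs)
    e = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pairset:
            e += STACK_ENERGY[(seq[i], seq[j])]
    return e
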