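"""Small sequence helpers shared across the pipeline.

Internal convention: all stored sequences are DNA (T, not U).  Conversion to
and from RNA happens at the miRNA-reference boundary and in reports.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def dna(seq: str) -> str:
    """Normalise to upper-case DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Normalise to upper-case RNA (T -> U)."""
    return seq.upper().replace("T", "U")
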