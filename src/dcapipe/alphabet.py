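"""21-state amino-acid alphabet shared by every module.

State 0 is the gap state; states 1..20 are the twenty standard amino acids
in alphabetical one-letter order.  Ambiguity codes (B, J, O, U, X, Z) carry
no usable coevolutionary signal at the family level and are mapped to the
gap state, keeping the alphabet at exactly 21 states.
"""

from __future__ import annotations

import numpy as np

GAP = 0
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = "-" + AMINO_ACIDS
Q = len(ALPHABET)  # 21

AMBIGUOUS = set("BJOUXZ")

_ENCODE = np.zeros(128, dtype=np.int8)  # unknown bytes -> gap
for _i, _aa in enumerate(AMINO_ACIDS, start=1):
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i
for _c in AMBIGUOUS:
    _ENCODE[ord(_c)] = GAP
    _ENCODE[ord(_c.lower())] = GAP


def encode(seq: str) -> np.ndarray:
    """Encode an aligned sequence string into integer states in {0..20}."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw].astype(np.int8)


def decode(states: np.ndarray) -> str:
    """Decode integer states back to a string ('-' for the gap state)."""
    return "".join(ALPHABET[s] for s in states)
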