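"""The 21-state amino-acid alphabet shared by all pipeline stages.

The gap symbol ``-`` is a full 21st state with code 0; the 20 standard
amino acids follow in alphabetical order with codes 1..20.  Nonstandard
residue letters (``X``, ``B``, ``Z``, ``U``, ``O``, ``J``, ``*``) are mapped
to the gap state so the categorical model stays closed; the mapping is
logged once per load by the callers that encode sequences.
"""

from __future__ import annotations

import numpy as np

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: full alphabet in code order; index into this string == state code
ALPHABET = GAP + AMINO_ACIDS
#: number of states (20 amino acids + gap)
Q = len(ALPHABET)
GAP_CODE = 0

#: letters tolerated on input but collapsed to the gap state
NONSTANDARD = set("XBZUOJ*.")

_CODE_OF = {ch: i for i, ch in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string into uint8 state codes.

    ``.`` is treated as an alternative gap glyph; nonstandard letters map
    to the gap state.  Raises ``KeyError`` for letters outside the tolerated
    set — callers wrap this into a :class:`~pairdca.exceptions.FormatError`.
    """
    codes = np.empty(len(seq), dtype=np.uint8)
    for k, ch in enumerate(seq.upper()):
        if ch in _CODE_OF:
            codes[k] = _CODE_OF[ch]
        elif ch in NONSTANDARD:
            codes[k] = GAP_CODE
        else:
            raise KeyError(ch)
    return codes


def decode_row(codes: np.ndarray) -> str:
    """Decode a vector of state codes back into a string."""
    return "".join(ALPHABET[c] for c in codes)


def one_hot(matrix: np.ndarray, dtype=np.float64) -> np.ndarray:
    """One-hot encode an (M, L) code matrix into (M, L * Q).

    The flat layout groups the Q indicator columns of alignment column 0
    first, then column 1, and so on — the layout every frequency and
    identity computation in the package relies on.
    """
    m, l = matrix.shape
    out = np.zeros((m, l * Q), dtype=dtype)
    rows = np.repeat(np.arange(m), l)
    cols = (np.arange(l) * Q)[None, :] + matrix.astype(np.intp)
    out[rows, cols.ravel()] = 1
    return out
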