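"""2-bit nucleotide encoding shared by the spectrum and vocabulary machinery.

The alphabet is ordered alphabetically (A=0, C=1, G=2, T=3) so that the
integer code of an L-mer (base-4, first letter most significant) sorts
words alphabetically.  Ambiguous letters (N and friends) encode as
:data:`AMBIGUOUS` and are handled by the callers' window-skip rules.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
AMBIGUOUS = np.uint8(255)

_LETTER_TO_CODE = np.full(256, AMBIGUOUS, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _LETTER_TO_CODE[ord(_c)] = _i
    _LETTER_TO_CODE[ord(_c.lower())] = _i

_CODE_TO_LETTER = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement under the A=0,C=1,G=2,T=3 coding is 3 - code
_COMPLEMENT_ASCII = np.arange(256, dtype=np.uint8)
for _a, _b in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A"),
               ("a", "t"), ("c", "g"), ("g", "c"), ("t", "a"),
               ("N", "N"), ("n", "n")]:
    _COMPLEMENT_ASCII[ord(_a)] = ord(_b)


class AlphabetError(ValueError):
    """A sequence letter outside the accepted DNA alphabet."""


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3; other -> 255).

    Case-insensitive; soft-masked (lowercase) letters encode normally.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LETTER_TO_CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for unambiguous codes."""
    if np.any(codes > 3):
        raise AlphabetError("cannot decode ambiguous codes")
    return _CODE_TO_LETTER[codes.astype(np.intp)].tobytes().decode("ascii")


def word_to_code(word: str) -> int:
    """Integer code of an unambiguous L-mer (alphabetical == numeric order)."""
    codes = encode(word)
    if np.any(codes > 3):
        raise AlphabetError(f"word {word!r} contains non-ACGT letters")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def code_to_word(code: int, length: int) -> str:
    letters = []
    for shift in range(2 * (length - 1), -2, -2):
        letters.append(ALPHABET[(code >> shift) & 3])
    return "".join(letters)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N fixed).

    Raises :class:`AlphabetError` on letters outside {A,C,G,T,N} (either case).
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    allowed = _LETTER_TO_CODE[raw] != AMBIGUOUS
    is_n = (raw == ord("N")) | (raw == ord("n"))
    if not np.all(allowed | is_n):
        bad = chr(raw[~(allowed | is_n)][0])
        raise AlphabetError(f"unknown letter {bad!r} in sequence")
    return _COMPLEMENT_ASCII[raw][::-1].tobytes().decode("ascii")


def window_codes(codes: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all sliding windows of `length`, plus a validity mask.

    Returns ``(wcodes, valid)`` with ``len == len(codes) - length + 1``;
    a window is valid iff it contains no ambiguous letter.  Invalid
    windows carry an arbitrary code and must be masked by the caller.
    """
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ambig = codes == AMBIGUOUS
    safe = np.where(ambig, 0, codes).astype(np.int64)
    view = np.lib.stride_tricks.sliding_window_view(safe, length)
    powers = (4 ** np.arange(length - 1, -1, -1)).astype(np.int64)
    wcodes = view @ powers
    bad = np.convolve(ambig.astype(np.int64), np.ones(length, dtype=np.int64), mode="valid")
    return wcodes, bad == 0
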