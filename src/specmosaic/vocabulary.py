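"""Vocabularies: fixed-length word sets with a guaranteed minimum pairwise
Hamming distance, used as mismatch-tolerant probes for compositional spectra.

A vocabulary is produced by a greedy scan of the 4^L word space starting
from a (random) seed L-mer: candidates are examined one by one, a
candidate is included iff it differs from every previously included word
in at least `min_dist` positions, and the scan stops when it returns to
the seed.  Two scan orders are provided:

* ``scan="translated"`` (default): the candidate at offset v is
  seed (+) v, where (+) is letter-wise addition in GF(4) (XOR of the
  2-bit letter codes) and v runs through all L-mers in alphabetical
  order.  Because GF(4) translation preserves Hamming distances, this is
  the greedy lexicode grown from AAA...A translated onto the seed: the
  set size is identical for every seed, and at L=10, min_dist=6 it is
  exactly 256 words — the standard probe set, tolerating r=3 mismatches
  per word with nearly disjoint Hamming balls.

* ``scan="cyclic"``: the literal alphabetical scan of the words
  themselves, wrapping from TTT...T to AAA...A.  Its size does depend on
  the seed (typically ~100 words at L=10, min_dist=6) because integer
  order, unlike GF(4) translation, is not distance-compatible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, product
from pathlib import Path

import numpy as np

from ._encoding import ALPHABET, code_to_word, encode, word_to_code

#: largest word length for which exhaustive 4^L scans/tables are permitted
MAX_EXHAUSTIVE_L = 13


class ParameterError(ValueError):
    """Invalid parameter combination."""


class CapabilityError(ValueError):
    """Request outside the exhaustive-enumeration capability envelope."""


def hamming_distance(w1: str, w2: str) -> int:
    """Number of positions at which two equal-length words differ."""
    if len(w1) != len(w2):
        raise ParameterError(
            f"length mismatch: {len(w1)} vs {len(w2)}")
    return int(np.count_nonzero(encode(w1) != encode(w2)))


@dataclass
class Vocabulary:
    """An ordered word set with minimum pairwise Hamming distance `min_dist`.

    `words` are kept in inclusion order of the greedy scan (seed first).
    """

    words: list[str]
    length: int
    min_dist: int
    seed_word: str
    rng_seed: int | None = None
    alphabet_size: int = 4
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._codes is None:
            self._codes = np.array([word_to_code(w) for w in self.words],
                                   dtype=np.int64)

    def __len__(self) -> int:
        return len(self.words)

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def id(self) -> str:
        return f"L{self.length}d{self.min_dist}s{self.seed_word}"

    def validate(self) -> None:
        """Assert the vocabulary invariants; raise ValueError on violation."""
        seen = set()
        for w in self.words:
            if len(w) != self.length or any(c not in ALPHABET for c in w):
                raise ValueError(f"malformed word {w!r}")
            if w in seen:
                raise ValueError(f"duplicate word {w!r}")
            seen.add(w)
        for a, b in combinations(self.words, 2):
            if hamming_distance(a, b) < self.min_dist:
                raise ValueError(
                    f"words {a} and {b} are closer than min_dist={self.min_dist}")

    # --- serialization -------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"# L={self.length}",
            f"# minDist={self.min_dist}",
            f"# seedWord={self.seed_word}",
            f"# rngSeed={'' if self.rng_seed is None else self.rng_seed}",
        ]
        lines.extend(self.words)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        meta: dict[str, str] = {}
        words: list[str] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                words.append(line.upper())
        if not words:
            raise ValueError(f"no words in vocabulary file {path}")
        length = int(meta.get("L", len(words[0])))
        min_dist = int(meta.get("minDist", 1))
        seed_word = meta.get("seedWord", words[0])
        rng_seed = meta.get("rngSeed") or None
        return cls(words=words, length=length, min_dist=min_dist,
                   seed_word=seed_word,
                   rng_seed=None if rng_seed is None else int(rng_seed))


@lru_cache(maxsize=8)
def _lexicode(length: int, min_dist: int) -> tuple:
    """Greedy lexicode codes grown from AAA...A (cached; seed-independent)."""
    from ._kernels import greedy_scan
    return tuple(int(c) for c in greedy_scan(np.int64(0), length, min_dist))


def generate_vocabulary(length: int, min_dist: int,
                        rng_seed: int | None = None,
                        seed_word: str | None = None,
                        scan: str = "translated") -> Vocabulary:
    """Run the greedy scan (see module docstring) and return the vocabulary.

    The seed word is drawn uniformly from all 4^L L-mers using `rng_seed`
    unless `seed_word` is given explicitly.  Deterministic given either.
    """
    if not (1 <= min_dist <= length):
        raise ParameterError(f"need 1 <= min_dist <= L, got {min_dist}, {length}")
    if length > MAX_EXHAUSTIVE_L:
        raise CapabilityError(
            f"greedy scan enumerates 4^L words; L={length} > {MAX_EXHAUSTIVE_L}")
    if seed_word is not None:
        if len(seed_word) != length:
            raise ParameterError("seed word length != L")
        seed_code = word_to_code(seed_word)
    else:
        rng = np.random.default_rng(rng_seed)
        seed_code = int(rng.integers(0, 4 ** length))
        seed_word = code_to_word(seed_code, length)

    if scan == "translated":
        # GF(4) letter-wise addition == plain XOR of the packed 2-bit codes
        codes = np.array([c ^ seed_code for c in _lexicode(length, min_dist)],
                         dtype=np.int64)
    elif scan == "cyclic":
        from ._kernels import greedy_scan
        codes = greedy_scan(np.int64(seed_code), length, min_dist)
    else:
        raise ParameterError(f"unknown scan mode {scan!r}")
    words = [code_to_word(int(c), length) for c in codes]
    return Vocabulary(words=words, length=length, min_dist=min_dist,
                      seed_word=seed_word, rng_seed=rng_seed,
                      _codes=codes)


def hamming_ball_size(length: int, r: int, alphabet_size: int = 4) -> int:
    """μ: the number of L-mers within Hamming distance r of a fixed word.

    μ = Σ_{i=0..r} C(L, i) · (A − 1)^i, exactly.
    """
    if not (0 <= r <= length) or alphabet_size < 2:
        raise ParameterError(
            f"need 0 <= r <= L and A >= 2, got r={r}, L={length}, A={alphabet_size}")
    return sum(math.comb(length, i) * (alphabet_size - 1) ** i
               for i in range(r + 1))


def enumerate_ball(word: str, r: int) -> set[str]:
    """All L-mers within Hamming distance r of `word` (brute force).

    Exponential in L; guarded to small words.  Used for exact coverage
    accounting and as the enumeration oracle in tests.
    """
    length = len(word)
    if length > 10:
        raise CapabilityError("ball enumeration guarded to L <= 10")
    out: set[str] = set()
    for k in range(r + 1):
        for positions in combinations(range(length), k):
            others = [[c for c in ALPHABET if c != word[p]] for p in positions]
            for repl in product(*others):
                chars = list(word)
                for p, c in zip(positions, repl):
                    chars[p] = c
                out.add("".join(chars))
    return out


def vocabulary_coverage(vocab: Vocabulary, r: int) -> dict:
    """Coverage accounting for a vocabulary at mismatch level r.

    Returns the match multiset size n·μ (every word counts its full ball,
    overlaps counted with multiplicity), the number of distinct L-mers
    covered by at least one word, and the distinct fraction of the 4^L
    word space.  Distinct coverage requires an exhaustive table over the
    word space and is guarded to L <= 13.
    """
    if vocab.length > MAX_EXHAUSTIVE_L:
        raise CapabilityError(
            f"coverage enumeration guarded to L <= {MAX_EXHAUSTIVE_L}")
    mu = hamming_ball_size(vocab.length, r, vocab.alphabet_size)
    from ._kernels import ball_membership_counts
    counts = ball_membership_counts(vocab.codes, vocab.length, r)
    distinct = int(np.count_nonzero(counts))
    total_space = 4 ** vocab.length
    return {
        "matchMultisetSize": len(vocab) * mu,
        "distinctCovered": distinct,
        "coverageFraction": distinct / total_space,
        "mu": mu,
    }
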