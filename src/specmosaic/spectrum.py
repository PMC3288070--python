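"""Compositional spectra: imperfect-match counts of vocabulary words along
a sequence.

A window of length L slides along the sequence one position per step; a
window matches word w_i if its Hamming distance to w_i is at most r.  The
per-word counts m_i over the M scored windows, normalised to frequencies
f_i = m_i / M, form the compositional spectrum of the sequence.  Windows
containing ambiguous letters (N, assembly gaps, hard-masked runs) are
skipped and M is reduced accordingly.

Counting uses a precomputed table mapping every L-mer code to the indices
of all vocabulary words within distance r (a CSR layout over the 4^L
space).  The table path is an optimisation only: it must, and in the
tests does, reproduce the naive per-window comparison exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encoding import AMBIGUOUS, encode, reverse_complement, window_codes
from .vocabulary import (MAX_EXHAUSTIVE_L, CapabilityError, ParameterError,
                         Vocabulary)

__all__ = ["CompositionalSpectrum", "MatchLookup", "count_matches",
           "compute_spectrum", "build_match_lookup", "reverse_complement",
           "EmptyInputError"]


class EmptyInputError(ValueError):
    """Sequence too short (or too ambiguous) to score any window."""


@dataclass
class CompositionalSpectrum:
    """Per-word imperfect-match counts for one sequence."""

    vocab_ref: str
    r: int
    counts: np.ndarray            # int64, one entry per vocabulary word
    M: int                        # number of scored windows
    skipped_windows: int
    source_id: str = ""

    @property
    def frequencies(self) -> np.ndarray:
        if self.M == 0:
            raise EmptyInputError("no scored windows; frequencies undefined")
        return self.counts / self.M

    def to_tsv(self, path: str | Path, words: list[str]) -> None:
        lines = [f"# vocab={self.vocab_ref}", f"# r={self.r}",
                 f"# M={self.M}", f"# skippedWindows={self.skipped_windows}",
                 f"# sourceId={self.source_id}",
                 "word\tcount\tfrequency"]
        freqs = self.counts / self.M if self.M else np.zeros_like(self.counts, dtype=float)
        for w, c, f in zip(words, self.counts, freqs):
            lines.append(f"{w}\t{int(c)}\t{f:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MatchLookup:
    """CSR table: word indices within distance r of every L-mer code."""

    vocab: Vocabulary
    r: int
    offsets: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    @property
    def total_matches(self) -> int:
        """Size of the match multiset: Σ over all L-mers of |word list|."""
        return int(len(self.values))

    def words_for(self, code: int) -> np.ndarray:
        return self.values[self.offsets[code]:self.offsets[code + 1]]


def build_match_lookup(vocab: Vocabulary, r: int) -> MatchLookup:
    """Precompute, for every L-mer, the vocabulary words within distance r."""
    if vocab.length > MAX_EXHAUSTIVE_L:
        raise CapabilityError(
            f"lookup table is 4^L entries; L={vocab.length} > {MAX_EXHAUSTIVE_L}")
    if r < 0 or r > vocab.length:
        raise ParameterError(f"need 0 <= r <= L, got r={r}")
    from ._kernels import ball_membership_counts, fill_ball_membership
    counts = ball_membership_counts(vocab.codes, vocab.length, r)
    offsets = np.zeros(len(counts) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    values = np.empty(offsets[-1], dtype=np.int32)
    fill_ball_membership(vocab.codes, vocab.length, r, offsets, values)
    return MatchLookup(vocab=vocab, r=r, offsets=offsets, values=values)


def count_matches(sequence: str, word: str, r: int) -> int:
    """Number of sliding windows within Hamming distance r of `word`.

    Windows containing non-ACGT letters are skipped.  Naive vectorised
    scan; the definitional reference for the lookup-based path.
    """
    length = len(word)
    if len(sequence) < length:
        raise EmptyInputError(
            f"sequence length {len(sequence)} < word length {length}")
    codes = encode(sequence)
    wcodes = encode(word)
    if np.any(wcodes == AMBIGUOUS):
        raise ParameterError(f"word {word!r} contains non-ACGT letters")
    view = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = ~np.any(view == AMBIGUOUS, axis=1)
    dist = np.count_nonzero(view != wcodes, axis=1)
    return int(np.count_nonzero(valid & (dist <= r)))


def compute_spectrum(sequence: str, vocab: Vocabulary, r: int,
                     lookup: MatchLookup | None = None,
                     source_id: str = "") -> CompositionalSpectrum:
    """Compositional spectrum of `sequence` against `vocab` at mismatch r.

    One pass over the sequence.  If `lookup` is omitted, one is built
    (expensive for L=10: prefer building once and reusing).
    """
    if lookup is None:
        lookup = build_match_lookup(vocab, r)
    elif lookup.vocab is not vocab or lookup.r != r:
        if lookup.r != r or lookup.vocab.words != vocab.words:
            raise ParameterError("lookup table built for a different vocab/r")
    if len(sequence) < vocab.length:
        raise EmptyInputError(
            f"sequence length {len(sequence)} < word length {vocab.length}")
    codes = encode(sequence)
    wcodes, valid = window_codes(codes, vocab.length)
    n_windows = len(wcodes)
    skipped = int(n_windows - np.count_nonzero(valid))
    w = wcodes[valid]
    counts = np.zeros(len(vocab), dtype=np.int64)
    if len(w):
        starts = lookup.offsets[w]
        lens = lookup.offsets[w + 1] - starts
        total = int(lens.sum())
        if total:
            # flattened CSR gather: indices of every (window, word) match
            cum = np.cumsum(lens)
            flat = np.repeat(starts, lens) + np.arange(total) - np.repeat(cum - lens, lens)
            counts = np.bincount(lookup.values[flat], minlength=len(vocab)
                                 ).astype(np.int64)
    return CompositionalSpectrum(vocab_ref=vocab.id, r=r, counts=counts,
                                 M=int(n_windows - skipped),
                                 skipped_windows=skipped, source_id=source_id)
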