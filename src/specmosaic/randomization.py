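"""Composition-preserving reshuffling nulls and sequence-space counting.

Reshuffling a segment keeps its letter multiset but destroys letter
order, so comparing the heterogeneity of natural segments with that of
their reshuffled counterparts isolates the contribution of sequence
*organization* from that of composition.  The combinatorial side
quantifies how many distinct sequences share a given composition: under
within-strand parity (%A = %T, %C = %G) a sequence of length n with n1
A+T and n2 C+G letters has

    N = n! / ((n1/2)!^2 (n2/2)!^2)

distinct arrangements, and (1/n)·log2 N converges to the entropy of the
letter distribution (α/2, α/2, (1−α)/2, (1−α)/2), where α is the GC
content — maximal (2 bits/letter) at α = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heterogeneity import Segment, gc_content, intra_heterogeneity
from .spectrum import MatchLookup, build_match_lookup, compute_spectrum
from ._encoding import reverse_complement
from .vocabulary import ParameterError, Vocabulary

__all__ = ["CompositionCount", "shuffle_sequence", "reshuffled_gc_bin_ho",
           "count_distinct_sequences", "asymptotic_log_n"]


def shuffle_sequence(sequence: str, rng_seed=None,
                     method: str = "fisher_yates") -> str:
    """Random permutation of the letters of `sequence`.

    method "fisher_yates": unbiased uniform permutation (default).
    method "paper_swap": sweep positions left to right, swapping each
    with a uniformly chosen position in the whole sequence.  Both
    preserve the letter multiset exactly; their permutation
    distributions differ (the sweep is not uniform).
    """
    if not sequence:
        raise ParameterError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    if method == "fisher_yates":
        arr = arr[rng.permutation(n)]
    elif method == "paper_swap":
        targets = rng.integers(0, n, size=n)
        for i in range(n):
            j = targets[i]
            arr[i], arr[j] = arr[j], arr[i]
    else:
        raise ParameterError(f"unknown shuffle method {method!r}")
    return arr.tobytes().decode("ascii")


def reshuffled_gc_bin_ho(segments: list[Segment], vocab: Vocabulary, r: int,
                         bin_width: float = 0.01, min_bin_size: int = 10,
                         rng_seed: int = 0,
                         lookup: MatchLookup | None = None,
                         method: str = "fisher_yates",
                         orientation: str = "min") -> pd.DataFrame:
    """Within-GC-bin Ho of natural segments next to that of their
    reshuffled counterparts.

    Each segment is shuffled once with a seeded RNG; bins (half-open,
    width `bin_width`) with fewer than `min_bin_size` segments are
    dropped.  Segments must retain their sequences
    (``segment_sequence(..., keep_sequence=True)``).
    """
    if any(s.sequence is None for s in segments):
        raise ParameterError("segments must retain sequences for reshuffling")
    if lookup is None:
        lookup = build_match_lookup(vocab, r)
    rng = np.random.default_rng(rng_seed)
    shuffled: list[Segment] = []
    for s in segments:
        sseq = shuffle_sequence(s.sequence, rng, method=method)
        seg = Segment(source_id=s.source_id + "(shuffled)", start=s.start,
                      end=s.end, gc=s.gc,
                      spectrum=compute_spectrum(sseq, vocab, r, lookup),
                      spectrum_rc=compute_spectrum(reverse_complement(sseq),
                                                   vocab, r, lookup))
        shuffled.append(seg)

    bins = np.floor(np.array([s.gc for s in segments]) / bin_width).astype(int)
    rows = []
    for b in sorted(set(bins)):
        idx = [k for k, kb in enumerate(bins) if kb == b]
        if len(idx) < min_bin_size:
            continue
        nat = intra_heterogeneity([segments[k] for k in idx],
                                  delta_gc_max=1.0, orientation=orientation)
        shf = intra_heterogeneity([shuffled[k] for k in idx],
                                  delta_gc_max=1.0, orientation=orientation)
        rows.append({"gc_low": b * bin_width, "gc_high": (b + 1) * bin_width,
                     "n_segments": len(idx),
                     "ho_natural": nat.Ht, "ho_shuffled": shf.Ht})
    return pd.DataFrame(rows, columns=["gc_low", "gc_high", "n_segments",
                                       "ho_natural", "ho_shuffled"])


@dataclass
class CompositionCount:
    """Letter composition of a sequence under within-strand parity."""

    n: int            # total length
    n1: int           # A + T letters
    n2: int           # C + G letters

    def __post_init__(self):
        if self.n1 + self.n2 != self.n:
            raise ParameterError("n1 + n2 must equal n")

    @property
    def alpha(self) -> float:
        return self.n2 / self.n

    @classmethod
    def from_sequence(cls, sequence: str) -> "CompositionCount":
        gc = gc_content(sequence)
        n = len(sequence)
        n2 = round(gc * n)
        return cls(n=n, n1=n - n2, n2=n2)


def count_distinct_sequences(comp: CompositionCount) -> int:
    """Exact number N of distinct sequences with composition `comp`,
    assuming %A = %T = n1/2 and %C = %G = n2/2 per strand.

    N = n! / ((n1/2)!^2 (n2/2)!^2), an exact big integer.
    """
    if comp.n1 % 2 or comp.n2 % 2:
        raise ParameterError(
            "closed form assumes strand parity: n1 and n2 must be even")
    p1, p2 = comp.n1 // 2, comp.n2 // 2
    return math.factorial(comp.n) // (
        math.factorial(p1) ** 2 * math.factorial(p2) ** 2)


def asymptotic_log_n(alpha: float) -> float:
    """Limit of (1/n)·log2 N as n grows, at GC content `alpha`.

    Equals the entropy (bits/letter) of the distribution
    (α/2, α/2, (1−α)/2, (1−α)/2): 2 bits at α = 0.5, 1 bit at the
    endpoints (binary A/T or C/G arrangement), strictly increasing on
    (0, 0.5).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")

    def h(p: float) -> float:
        return 0.0 if p == 0.0 else -p * math.log2(p)

    return 2 * h(alpha / 2) + 2 * h((1 - alpha) / 2)
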