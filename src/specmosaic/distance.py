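"""CS distance between compositional spectra.

The distance between two spectra is d = (1 − r_s) / 2, where r_s is the
Spearman rank correlation of the two word-frequency vectors: d = 0 for
identical spectra (r_s = 1) and d = 1 for strictly rank-reversed spectra
(r_s = −1).  Because counts are integers, ties are common; ranks are
average (mid) ranks and r_s is the product-moment correlation of the
ranks, which reduces to the classical 1 − 6Σδ²/(n(n²−1)) form when there
are no ties.

Strand asymmetry is handled by minimising over the four orientation
combinations of the two sequences and their reverse complements:
d = min(d12, d12′, d1′2, d1′2′).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._encoding import reverse_complement
from .spectrum import (CompositionalSpectrum, MatchLookup, compute_spectrum)
from .vocabulary import ParameterError, Vocabulary

__all__ = ["DistanceResult", "spearman_rank_correlation", "oriented_distance",
           "cs_distance", "UndefinedCorrelationError", "rank_vector"]


class UndefinedCorrelationError(ValueError):
    """Rank correlation undefined: a vector has zero rank variance."""


def rank_vector(values: np.ndarray) -> np.ndarray:
    """Average (mid) ranks, centred and scaled to unit norm.

    The dot product of two such vectors is the Spearman correlation.
    Raises :class:`UndefinedCorrelationError` for constant input.
    """
    ranks = rankdata(values, method="average")
    ranks = ranks - ranks.mean()
    norm = np.linalg.norm(ranks)
    if norm == 0:
        raise UndefinedCorrelationError(
            "constant vector: rank correlation undefined")
    return ranks / norm


def spearman_rank_correlation(f1, f2) -> float:
    """Spearman r_s between two equal-length vectors (average ranks)."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape or f1.ndim != 1:
        raise ParameterError("vectors must be 1-D and of equal length")
    if len(f1) < 2:
        raise ParameterError("need at least two entries")
    return float(rank_vector(f1) @ rank_vector(f2))


def oriented_distance(F1: CompositionalSpectrum,
                      F2: CompositionalSpectrum) -> float:
    """Single-orientation CS distance d = (1 − r_s)/2 between two spectra."""
    if F1.vocab_ref != F2.vocab_ref or F1.r != F2.r:
        raise ParameterError(
            "spectra computed against different vocabularies or mismatch levels")
    rs = spearman_rank_correlation(F1.counts, F2.counts)
    return (1.0 - rs) / 2.0


@dataclass
class DistanceResult:
    """The four oriented CS distances and their minimum.

    d12  : S1 vs S2
    d12rc: S1 vs revcomp(S2)
    drc12: revcomp(S1) vs S2
    drc1rc2: revcomp(S1) vs revcomp(S2)
    """

    d12: float
    d12rc: float
    drc12: float
    drc1rc2: float

    @property
    def d(self) -> float:
        return min(self.d12, self.d12rc, self.drc12, self.drc1rc2)


def cs_distance(s1: str, s2: str, vocab: Vocabulary, r: int,
                lookup: MatchLookup | None = None) -> DistanceResult:
    """CS distance between two sequences: min over the four strand
    orientations of the oriented spectral distance."""
    from .spectrum import build_match_lookup
    if lookup is None:
        lookup = build_match_lookup(vocab, r)
    F1 = compute_spectrum(s1, vocab, r, lookup)
    F2 = compute_spectrum(s2, vocab, r, lookup)
    F1rc = compute_spectrum(reverse_complement(s1), vocab, r, lookup)
    F2rc = compute_spectrum(reverse_complement(s2), vocab, r, lookup)
    return DistanceResult(
        d12=oriented_distance(F1, F2),
        d12rc=oriented_distance(F1, F2rc),
        drc12=oriented_distance(F1rc, F2),
        drc1rc2=oriented_distance(F1rc, F2rc),
    )
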