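"""Compositional (Hc), organizational (Ho) and total (Ht) sequence
heterogeneity.

A target sequence is cut into equal, non-overlapping segments (100 kb by
default) and each segment gets a GC content and a compositional spectrum.
Over segment pairs:

* Hc — median absolute GC difference (composition only);
* Ht — median CS distance over all pairs (composition + organization);
* Ho — median CS distance over pairs whose GC contents differ by at most
  `delta_gc_max` (0.02 by default), isolating organization from
  composition.

Inter-sequence heterogeneity uses the cross pairs of two segment lists.
When the number of pairs is very large, a seeded uniform sample of pairs
is scored instead and the sampling error of the median is estimated by
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._encoding import encode, reverse_complement
from .distance import rank_vector
from .spectrum import (CompositionalSpectrum, MatchLookup, build_match_lookup,
                       compute_spectrum)
from .vocabulary import ParameterError, Vocabulary

__all__ = ["Segment", "HeterogeneityScores", "PairSampling", "gc_content",
           "segment_sequence", "intra_heterogeneity",
           "inter_sequence_heterogeneity", "genome_vs_chromosomes",
           "gc_bin_ho", "threshold_sensitivity"]


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T), ignoring ambiguous letters."""
    codes = encode(sequence)
    unambig = codes <= 3
    n = int(np.count_nonzero(unambig))
    if n == 0:
        raise ValueError("no unambiguous letters: GC content undefined")
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / n


@dataclass
class Segment:
    """A fixed-length window of a source sequence."""

    source_id: str
    start: int                      # 0-based, half-open
    end: int
    gc: float
    spectrum: CompositionalSpectrum | None = None
    spectrum_rc: CompositionalSpectrum | None = None
    sequence: str | None = field(default=None, repr=False)


def segment_sequence(sequence: str, window_len: int,
                     max_ambiguous_frac: float = 0.5,
                     source_id: str = "",
                     vocab: Vocabulary | None = None,
                     r: int | None = None,
                     lookup: MatchLookup | None = None,
                     keep_sequence: bool = True) -> list[Segment]:
    """Cut `sequence` into consecutive non-overlapping windows.

    The trailing partial window is discarded; windows whose fraction of
    ambiguous letters exceeds `max_ambiguous_frac` are excluded.  When a
    vocabulary is supplied, each segment's spectrum (and the spectrum of
    its reverse complement) is computed.
    """
    if vocab is not None and window_len < vocab.length:
        raise ParameterError("window shorter than vocabulary word length")
    n_windows = len(sequence) // window_len
    if n_windows == 0:
        warnings.warn(f"sequence {source_id!r} shorter than one window; "
                      "no segments produced")
        return []
    if vocab is not None and lookup is None:
        lookup = build_match_lookup(vocab, r)
    segments: list[Segment] = []
    for k in range(n_windows):
        start, end = k * window_len, (k + 1) * window_len
        sub = sequence[start:end]
        codes = encode(sub)
        ambig_frac = float(np.count_nonzero(codes > 3)) / window_len
        if ambig_frac > max_ambiguous_frac:
            continue
        seg = Segment(source_id=source_id, start=start, end=end,
                      gc=gc_content(sub),
                      sequence=sub if keep_sequence else None)
        if vocab is not None:
            sid = f"{source_id}:{start}-{end}"
            seg.spectrum = compute_spectrum(sub, vocab, r, lookup, source_id=sid)
            seg.spectrum_rc = compute_spectrum(reverse_complement(sub), vocab,
                                               r, lookup, source_id=sid + "(rc)")
        segments.append(seg)
    return segments


@dataclass
class PairSampling:
    """When the pair count exceeds `threshold`, score a uniform seeded
    sample of `sample_size` pairs instead of all pairs."""

    threshold: int = 2_000_000
    sample_size: int = 1_000_000
    rng_seed: int = 0
    bootstrap: int = 50


@dataclass
class HeterogeneityScores:
    Hc: float
    Ho: float                      # NaN when no qualifying pair
    Ht: float
    delta_gc_max: float
    n_pairs_total: int             # pairs actually scored
    n_pairs_gc: int                # scored pairs with |dGC| <= threshold
    pair_fraction: float
    ho_defined: bool = True
    sampled: bool = False
    sample_size: int | None = None
    rng_seed: int | None = None
    median_deviation: float | None = None

    @property
    def ho_ht_ratio(self) -> float:
        return self.Ho / self.Ht if self.ho_defined and self.Ht > 0 else float("nan")


# ---------------------------------------------------------------------------
# pairwise machinery

def _rank_matrices(segments: list[Segment],
                   orientation: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Unit-norm centred rank vectors of segment spectra (and, for the
    min-of-four orientation, of their reverse-complement spectra)."""
    if any(s.spectrum is None for s in segments):
        raise ParameterError("segments carry no spectra; pass a vocabulary "
                             "to segment_sequence")
    R = np.stack([rank_vector(s.spectrum.counts) for s in segments])
    if orientation == "oriented":
        return R, None
    if any(s.spectrum_rc is None for s in segments):
        raise ParameterError("min-of-four distance needs reverse-complement "
                             "spectra")
    Q = np.stack([rank_vector(s.spectrum_rc.counts) for s in segments])
    return R, Q


def _pair_cs_distances(Ra, Qa, Rb, Qb, ii, jj, chunk: int = 65536) -> np.ndarray:
    """CS distances for the pair list (ii[k] from side A, jj[k] from B)."""
    out = np.empty(len(ii), dtype=float)
    for lo in range(0, len(ii), chunk):
        hi = min(lo + chunk, len(ii))
        a, b = ii[lo:hi], jj[lo:hi]
        rs = np.einsum("ij,ij->i", Ra[a], Rb[b])
        if Qa is not None:
            rs = np.maximum(rs, np.einsum("ij,ij->i", Ra[a], Qb[b]))
            rs = np.maximum(rs, np.einsum("ij,ij->i", Qa[a], Rb[b]))
            rs = np.maximum(rs, np.einsum("ij,ij->i", Qa[a], Qb[b]))
        out[lo:hi] = (1.0 - rs) / 2.0
    return out


def _score_pairs(seg_a: list[Segment], seg_b: list[Segment] | None,
                 delta_gc_max: float, pair_sampling: PairSampling | None,
                 orientation: str) -> HeterogeneityScores:
    """Common core: Hc/Ho/Ht over intra pairs (seg_b None) or cross pairs."""
    sampling = pair_sampling or PairSampling()
    intra = seg_b is None
    m = len(seg_a)
    gc_a = np.array([s.gc for s in seg_a])
    if intra:
        if m < 2:
            raise ParameterError("need at least 2 segments")
        n_possible = m * (m - 1) // 2
    else:
        if m == 0 or len(seg_b) == 0:
            raise ParameterError("both segment lists must be non-empty")
        n_possible = m * len(seg_b)
        gc_b = np.array([s.gc for s in seg_b])

    sampled = n_possible > sampling.threshold
    rng = np.random.default_rng(sampling.rng_seed)
    if sampled:
        size = sampling.sample_size
        if intra:
            ii = rng.integers(0, m, size=2 * size)
            jj = rng.integers(0, m, size=2 * size)
            keep = ii != jj
            ii, jj = ii[keep][:size], jj[keep][:size]
        else:
            ii = rng.integers(0, m, size=size)
            jj = rng.integers(0, len(seg_b), size=size)
    else:
        if intra:
            iu = np.triu_indices(m, k=1)
            ii, jj = iu[0], iu[1]
        else:
            grid = np.indices((m, len(seg_b)))
            ii, jj = grid[0].ravel(), grid[1].ravel()

    Ra, Qa = _rank_matrices(seg_a, orientation)
    if intra:
        Rb, Qb, gcb = Ra, Qa, gc_a
    else:
        Rb, Qb = _rank_matrices(seg_b, orientation)
        gcb = gc_b

    dgc = np.abs(gc_a[ii] - gcb[jj])
    d = _pair_cs_distances(Ra, Qa, Rb, Qb, ii, jj)
    qual = dgc <= delta_gc_max

    hc = float(np.median(dgc))
    ht = float(np.median(d))
    n_gc = int(np.count_nonzero(qual))
    ho_defined = n_gc > 0
    ho = float(np.median(d[qual])) if ho_defined else float("nan")

    median_dev = None
    if sampled and sampling.bootstrap:
        boots = [np.median(rng.choice(d, size=len(d), replace=True))
                 for _ in range(sampling.bootstrap)]
        median_dev = float(np.std(boots))

    return HeterogeneityScores(
        Hc=hc, Ho=ho, Ht=ht, delta_gc_max=delta_gc_max,
        n_pairs_total=len(d), n_pairs_gc=n_gc,
        pair_fraction=n_gc / len(d), ho_defined=ho_defined,
        sampled=sampled,
        sample_size=sampling.sample_size if sampled else None,
        rng_seed=sampling.rng_seed if sampled else None,
        median_deviation=median_dev)


def intra_heterogeneity(segments: list[Segment], delta_gc_max: float = 0.02,
                        pair_sampling: PairSampling | None = None,
                        orientation: str = "min") -> HeterogeneityScores:
    """Hc/Ho/Ht over all unordered pairs of one segment list."""
    return _score_pairs(segments, None, delta_gc_max, pair_sampling, orientation)


def inter_sequence_heterogeneity(segments_a: list[Segment],
                                 segments_b: list[Segment],
                                 delta_gc_max: float = 0.02,
                                 pair_sampling: PairSampling | None = None,
                                 orientation: str = "min") -> HeterogeneityScores:
    """Hc/Ho/Ht over the A x B cross pairs of two segment lists."""
    return _score_pairs(segments_a, segments_b, delta_gc_max, pair_sampling,
                        orientation)


def genome_vs_chromosomes(segments_by_chromosome: dict[str, list[Segment]],
                          delta_gc_max: float = 0.02,
                          pair_sampling: PairSampling | None = None,
                          orientation: str = "min") -> pd.DataFrame:
    """Whole-genome scores (pooled segments) vs the median over all
    chromosome pairs of inter-sequence scores."""
    chroms = [c for c, segs in segments_by_chromosome.items() if segs]
    pooled = [s for c in chroms for s in segments_by_chromosome[c]]
    whole = intra_heterogeneity(pooled, delta_gc_max, pair_sampling, orientation)
    rows = [{"scope": "whole-genome", "Hc": whole.Hc, "Ho": whole.Ho,
             "Ht": whole.Ht, "n_pairs": whole.n_pairs_total}]
    if len(chroms) < 2:
        warnings.warn("single chromosome: whole-genome scores only")
    else:
        hcs, hos, hts, npairs = [], [], [], 0
        for a, b in combinations(chroms, 2):
            sc = inter_sequence_heterogeneity(
                segments_by_chromosome[a], segments_by_chromosome[b],
                delta_gc_max, pair_sampling, orientation)
            hcs.append(sc.Hc)
            hos.append(sc.Ho)
            hts.append(sc.Ht)
            npairs += sc.n_pairs_total
        rows.append({"scope": "inter-chromosomal-median",
                     "Hc": float(np.median(hcs)),
                     "Ho": float(np.nanmedian(hos)),
                     "Ht": float(np.median(hts)),
                     "n_pairs": npairs})
    return pd.DataFrame(rows)


def gc_bin_ho(segments: list[Segment], bin_width: float = 0.01,
              min_bin_size: int = 10,
              orientation: str = "min") -> pd.DataFrame:
    """Ho within GC bins.

    Segments are grouped by GC content into half-open bins
    [k·bin_width, (k+1)·bin_width) regardless of chromosomal residence;
    bins with fewer than `min_bin_size` segments are dropped.  Within a
    bin every pair qualifies by construction, so Ho is the plain median
    pairwise CS distance.
    """
    gcs = np.array([s.gc for s in segments])
    bins = np.floor(gcs / bin_width).astype(int)
    rows = []
    for b in sorted(set(bins)):
        members = [s for s, k in zip(segments, bins) if k == b]
        if len(members) < min_bin_size:
            continue
        sc = intra_heterogeneity(members, delta_gc_max=1.0,
                                 orientation=orientation)
        rows.append({"gc_low": b * bin_width, "gc_high": (b + 1) * bin_width,
                     "n_segments": len(members), "ho": sc.Ht})
    if not rows:
        warnings.warn("no GC bin reaches min_bin_size; empty result")
    return pd.DataFrame(rows, columns=["gc_low", "gc_high", "n_segments", "ho"])


def threshold_sensitivity(segments_by_chromosome: dict[str, list[Segment]],
                          thresholds=("none", 0.02, 0.01, 0.005),
                          orientation: str = "min"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of per-chromosome-pair median CS distances under
    different maximal permitted GC differences.

    Returns ``(pairs, summary)``: `pairs` has one row per (threshold,
    chromosome pair) with the median distance over qualifying segment
    pairs; `summary` has the overall participation fraction per
    threshold.  Threshold "none" places no GC restriction and coincides
    with Ht.
    """
    chroms = [c for c, segs in segments_by_chromosome.items() if segs]
    if len(chroms) < 2:
        raise ParameterError("need at least 2 chromosomes")
    mats = {c: _rank_matrices(segments_by_chromosome[c], orientation)
            for c in chroms}
    gcs = {c: np.array([s.gc for s in segments_by_chromosome[c]])
           for c in chroms}
    pair_rows, summary_rows = [], []
    # precompute distances and dGC per chromosome pair once
    cache = {}
    for a, b in combinations(chroms, 2):
        (Ra, Qa), (Rb, Qb) = mats[a], mats[b]
        na, nb = len(gcs[a]), len(gcs[b])
        grid = np.indices((na, nb))
        ii, jj = grid[0].ravel(), grid[1].ravel()
        d = _pair_cs_distances(Ra, Qa, Rb, Qb, ii, jj)
        dgc = np.abs(gcs[a][ii] - gcs[b][jj])
        cache[(a, b)] = (d, dgc)
    for t in thresholds:
        tv = np.inf if (t == "none" or t is None) else float(t)
        n_q = n_tot = 0
        for (a, b), (d, dgc) in cache.items():
            qual = dgc <= tv
            nq = int(np.count_nonzero(qual))
            pair_rows.append({
                "threshold": "none" if np.isinf(tv) else tv,
                "chrom_a": a, "chrom_b": b,
                "median_d": float(np.median(d[qual])) if nq else float("nan"),
                "n_qualifying": nq, "n_pairs": len(d)})
            n_q += nq
            n_tot += len(d)
        summary_rows.append({"threshold": "none" if np.isinf(tv) else tv,
                             "participation": n_q / n_tot})
    return pd.DataFrame(pair_rows), pd.DataFrame(summary_rows)
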