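"""Partitioning a genome sequence into coding / repeat / GDM fractions.

"Coding" covers gene spans (exons and introns), pseudogenes and RNA
genes; repeats are everything annotated as repetitive in the remaining
noncoding part; what is left — noncoding, non-repetitive — is the genome
dark matter (GDM).  Precedence is coding > repeat > GDM: a repeat
overlapping a gene span is assigned to the coding fraction.  Each
fraction's intervals are merged and its subsequences concatenated, and
the concatenation is then segmented and scored by the ordinary
heterogeneity machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .heterogeneity import (HeterogeneityScores, PairSampling,
                            inter_sequence_heterogeneity, intra_heterogeneity,
                            segment_sequence)
from .spectrum import MatchLookup, build_match_lookup
from .vocabulary import ParameterError, Vocabulary

__all__ = ["FractionPartition", "merge_intervals", "subtract_intervals",
           "partition_sequence", "fraction_heterogeneity",
           "chromosome_feature_matrix", "FRACTIONS"]

FRACTIONS = ("coding", "repeat", "gdm")

Interval = tuple[int, int]


def merge_intervals(intervals) -> list[Interval]:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: list[Interval],
                       minus: list[Interval]) -> list[Interval]:
    """Set difference base \\ minus; both must be merged and sorted."""
    out: list[Interval] = []
    mi = 0
    for s, e in base:
        cur = s
        while mi < len(minus) and minus[mi][1] <= cur:
            mi += 1
        k = mi
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


class FractionPartition:
    """The coding / repeat / GDM split of one source sequence."""

    def __init__(self, source_id: str, length: int,
                 coding_intervals: list[Interval],
                 repeat_intervals: list[Interval],
                 gdm_intervals: list[Interval],
                 coding_seq: str, repeat_seq: str, gdm_seq: str):
        self.source_id = source_id
        self.length = length
        self.coding_intervals = coding_intervals
        self.repeat_intervals = repeat_intervals
        self.gdm_intervals = gdm_intervals
        self.coding_seq = coding_seq
        self.repeat_seq = repeat_seq
        self.gdm_seq = gdm_seq

    def sequences(self) -> dict[str, str]:
        return {"coding": self.coding_seq, "repeat": self.repeat_seq,
                "gdm": self.gdm_seq}

    def validate(self) -> None:
        total = sum(e - s for ivs in (self.coding_intervals,
                                      self.repeat_intervals,
                                      self.gdm_intervals) for s, e in ivs)
        if total != self.length:
            raise ValueError(f"partition covers {total} of {self.length} bases")
        for name, seq, ivs in [("coding", self.coding_seq, self.coding_intervals),
                               ("repeat", self.repeat_seq, self.repeat_intervals),
                               ("gdm", self.gdm_seq, self.gdm_intervals)]:
            if len(seq) != sum(e - s for s, e in ivs):
                raise ValueError(f"{name} concatenation length mismatch")


def _validate_intervals(intervals, length: int, what: str) -> None:
    for s, e in intervals:
        if s < 0 or e > length or s >= e:
            raise ParameterError(
                f"{what} interval ({s}, {e}) invalid for length {length}")


def partition_sequence(sequence: str, gene_intervals,
                       repeat_intervals,
                       source_id: str = "") -> FractionPartition:
    """Split a sequence into coding, repeat and GDM fractions.

    `gene_intervals` and `repeat_intervals` are iterables of 0-based
    half-open (start, end) pairs.  Precedence coding > repeat > GDM;
    the three interval sets are disjoint and cover the sequence exactly.
    """
    n = len(sequence)
    genes = merge_intervals(gene_intervals)
    reps = merge_intervals(repeat_intervals)
    _validate_intervals(genes, n, "gene")
    _validate_intervals(reps, n, "repeat")
    coding = genes
    repeat = subtract_intervals(reps, coding)
    occupied = merge_intervals(coding + repeat)
    gdm = subtract_intervals([(0, n)], occupied)

    def concat(ivs):
        return "".join(sequence[s:e] for s, e in ivs)

    part = FractionPartition(source_id=source_id, length=n,
                             coding_intervals=coding,
                             repeat_intervals=repeat, gdm_intervals=gdm,
                             coding_seq=concat(coding),
                             repeat_seq=concat(repeat), gdm_seq=concat(gdm))
    part.validate()
    return part


def fraction_heterogeneity(partition: FractionPartition, vocab: Vocabulary,
                           r: int, window_len: int,
                           delta_gc_max: float = 0.02,
                           lookup: MatchLookup | None = None,
                           pair_sampling: PairSampling | None = None
                           ) -> pd.DataFrame:
    """Hc/Ho/Ht (and Ho/Ht) for each fraction of a partition.

    A fraction shorter than two windows is flagged absent (its scores
    are NaN).  The concatenated fraction sequence is segmented exactly
    like a plain sequence; windows may span concatenation junctions.
    """
    if lookup is None:
        lookup = build_match_lookup(vocab, r)
    rows = []
    for name, seq in partition.sequences().items():
        row = {"fraction": name, "length": len(seq)}
        segs = (segment_sequence(seq, window_len, source_id=name, vocab=vocab,
                                 r=r, lookup=lookup)
                if len(seq) >= 2 * window_len else [])
        if len(segs) < 2:
            row.update({"present": False, "Ht": np.nan, "Ho": np.nan,
                        "Hc": np.nan, "ho_ht_ratio": np.nan, "n_segments": len(segs)})
        else:
            sc = intra_heterogeneity(segs, delta_gc_max, pair_sampling)
            row.update({"present": True, "Ht": sc.Ht, "Ho": sc.Ho, "Hc": sc.Hc,
                        "ho_ht_ratio": sc.ho_ht_ratio, "n_segments": len(segs)})
        rows.append(row)
    return pd.DataFrame(rows)


def chromosome_feature_matrix(partitions_by_chromosome: dict[str, FractionPartition],
                              vocab: Vocabulary, r: int, window_len: int,
                              delta_gc_max: float = 0.02,
                              lookup: MatchLookup | None = None
                              ) -> pd.DataFrame:
    """12 heterogeneity features per chromosome:
    {intra, inter} x {Ho, Hc} x {coding, repeat, gdm}.

    Inter scores are the mean over a chromosome's pairings with all other
    chromosomes.  A fraction too short to segment on some chromosome
    yields NaN in its columns.
    """
    chroms = list(partitions_by_chromosome)
    if len(chroms) < 3:
        raise ParameterError("need at least 3 chromosomes")
    if lookup is None:
        lookup = build_match_lookup(vocab, r)
    segs: dict[tuple[str, str], list] = {}
    for c in chroms:
        for frac, seq in partitions_by_chromosome[c].sequences().items():
            segs[(c, frac)] = segment_sequence(
                seq, window_len, source_id=f"{c}:{frac}",
                vocab=vocab, r=r, lookup=lookup) if len(seq) >= window_len else []

    rows = []
    for c in chroms:
        row: dict = {"chromosome": c}
        for frac in FRACTIONS:
            own = segs[(c, frac)]
            if len(own) >= 2:
                sc = intra_heterogeneity(own, delta_gc_max)
                row[f"intra_Ho_{frac}"] = sc.Ho
                row[f"intra_Hc_{frac}"] = sc.Hc
            else:
                row[f"intra_Ho_{frac}"] = np.nan
                row[f"intra_Hc_{frac}"] = np.nan
            hos, hcs = [], []
            for o in chroms:
                if o == c or not own or not segs[(o, frac)]:
                    continue
                sc = inter_sequence_heterogeneity(own, segs[(o, frac)],
                                                  delta_gc_max)
                hos.append(sc.Ho)
                hcs.append(sc.Hc)
            row[f"inter_Ho_{frac}"] = float(np.nanmean(hos)) if hos else np.nan
            row[f"inter_Hc_{frac}"] = float(np.mean(hcs)) if hcs else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("chromosome")
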