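"""Segmentation and Hc/Ho/Ht heterogeneity statistics."""

from itertools import combinations

import numpy as np
import pytest

from specmosaic import (PairSampling, build_match_lookup,
                        exact_composition_sequence, gc_bin_ho, gc_content,
                        genome_vs_chromosomes, inter_sequence_heterogeneity,
                        intra_heterogeneity, oriented_distance, random_sequence,
                        segment_sequence, threshold_sensitivity)
from specmosaic.vocabulary import ParameterError


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0), ("AATT", 0.0), ("ACGT", 0.5), ("ACGTN", 0.5),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_undefined():
    with pytest.raises(ValueError):
        gc_content("NNN")


class TestSegmentation:
    def test_floor_division(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2500)])
        segs = segment_sequence(seq, 1000)
        assert [(s.start, s.end) for s in segs] == [(0, 1000), (1000, 2000)]

    def test_ambiguous_window_excluded(self):
        seq = "N" * 600 + "ACGT" * 100  # 60% N
        segs = segment_sequence(seq, 1000, max_ambiguous_frac=0.5)
        assert segs == []

    def test_too_short_warns(self):
        with pytest.warns(UserWarning):
            segs = segment_sequence("ACGT" * 10, 1000)
        assert segs == []

    def test_per_segment_gc_matches_recount(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, 50_000,
                                                        p=[0.3, 0.2, 0.2, 0.3])])
        segs = segment_sequence(seq, 5000)
        assert len(segs) == 10
        for s in segs:
            sub = seq[s.start:s.end]
            assert s.gc == pytest.approx(
                (sub.count("G") + sub.count("C")) / len(sub))


def _exact_gc_segment(gc, n, rng):
    ncg = round(gc * n / 2)
    na = n // 2 - ncg
    return exact_composition_sequence(
        {"A": na, "C": ncg, "G": ncg, "T": na}, rng)


class TestIntraHeterogeneity:
    def test_identical_segments_zero(self, small_vocab, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        segs = segment_sequence(seq * 4, 2000, vocab=small_vocab, r=1)
        sc = intra_heterogeneity(segs, 0.02)
        assert sc.Hc == pytest.approx(0.0)
        assert sc.Ho == pytest.approx(0.0)
        assert sc.Ht == pytest.approx(0.0)

    def test_hand_enumerated_gc_pairs(self, small_vocab, rng):
        """4 segments with GC 0.40/0.41/0.45/0.46: 6 pairs, 2 qualify at
        the 0.02 threshold, Hc = median{.01,.05,.06,.04,.05,.01} = .045."""
        lookup = build_match_lookup(small_vocab, 1)
        segs = []
        for gc in (0.40, 0.41, 0.45, 0.46):
            seq = _exact_gc_segment(gc, 2000, rng)
            segs += segment_sequence(seq, 2000, vocab=small_vocab, r=1,
                                     lookup=lookup, source_id=f"gc{gc}")
        sc = intra_heterogeneity(segs, delta_gc_max=0.02)
        assert sc.n_pairs_total == 6
        assert sc.n_pairs_gc == 2
        assert sc.pair_fraction == pytest.approx(1 / 3)
        assert sc.Hc == pytest.approx(0.045)

    def test_needs_two_segments(self, small_vocab):
        segs = segment_sequence("ACGT" * 1000, 4000, vocab=small_vocab, r=1)
        with pytest.raises(ParameterError):
            intra_heterogeneity(segs)

    def test_ho_undefined_flag(self, small_vocab, rng):
        lookup = build_match_lookup(small_vocab, 1)
        segs = []
        for gc in (0.30, 0.60):
            segs += segment_sequence(_exact_gc_segment(gc, 2000, rng), 2000,
                                     vocab=small_vocab, r=1, lookup=lookup)
        sc = intra_heterogeneity(segs, delta_gc_max=0.01)
        assert not sc.ho_defined
        assert np.isnan(sc.Ho)

    def test_reorder_invariance(self, std_vocab, std_lookup, rng):
        segs = []
        for _ in range(8):
            seq = random_sequence(4000, gc=0.45, bias=0.2, rng=rng)
            segs += segment_sequence(seq, 4000, vocab=std_vocab, r=3,
                                     lookup=std_lookup)
        a = intra_heterogeneity(segs, 0.02)
        perm = [segs[i] for i in rng.permutation(len(segs))]
        b = intra_heterogeneity(perm, 0.02)
        assert (a.Hc, a.Ho, a.Ht) == pytest.approx((b.Hc, b.Ho, b.Ht))

    def test_sampled_median_close_to_exact(self, std_vocab, std_lookup, rng):
        segs = []
        for _ in range(50):
            seq = random_sequence(5000, gc=0.45, bias=0.2, rng=rng)
            segs += segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                     lookup=std_lookup)
        exact = intra_heterogeneity(segs, 0.02)
        samp = intra_heterogeneity(
            segs, 0.02, PairSampling(threshold=100, sample_size=600, rng_seed=0))
        assert samp.sampled and not exact.sampled
        assert samp.median_deviation is not None and samp.median_deviation > 0
        assert abs(samp.Ht - exact.Ht) < 3 * samp.median_deviation + 1e-9


class TestInterHeterogeneity:
    def test_single_segment_lists(self, std_vocab, std_lookup, rng):
        a = segment_sequence(random_sequence(5000, 0.45, 0.2, rng), 5000,
                             vocab=std_vocab, r=3, lookup=std_lookup)
        b = segment_sequence(random_sequence(5000, 0.45, 0.2, rng), 5000,
                             vocab=std_vocab, r=3, lookup=std_lookup)
        sc = inter_sequence_heterogeneity(a, b, 1.0)
        assert sc.n_pairs_total == 1
        pair_d = min(
            oriented_distance(a[0].spectrum, b[0].spectrum),
            oriented_distance(a[0].spectrum, b[0].spectrum_rc),
            oriented_distance(a[0].spectrum_rc, b[0].spectrum),
            oriented_distance(a[0].spectrum_rc, b[0].spectrum_rc))
        assert sc.Ht == pytest.approx(pair_d)
        assert sc.Hc == pytest.approx(abs(a[0].gc - b[0].gc))

    def test_self_cross_bounded_by_intra(self, std_vocab, std_lookup, rng):
        segs = []
        for _ in range(6):
            seq = random_sequence(5000, gc=0.45, bias=0.2, rng=rng)
            segs += segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                     lookup=std_lookup)
        # cross pairs of A with itself include the zero-distance self pairs
        cross = inter_sequence_heterogeneity(segs, segs, 1.0)
        intra = intra_heterogeneity(segs, 1.0)
        assert cross.Ht <= intra.Ht + 1e-12

    def test_same_vs_different_generator(self, std_vocab, std_lookup, rng):
        def group(gc, bias, n):
            out = []
            for _ in range(n):
                seq = random_sequence(5000, gc=gc, bias=bias, rng=rng)
                out += segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                        lookup=std_lookup)
            return out

        a = group(0.45, 0.3, 6)
        b_same = group(0.45, 0.3, 6)
        b_diff = group(0.52, 0.05, 6)
        same = inter_sequence_heterogeneity(a, b_same, 1.0)
        diff = inter_sequence_heterogeneity(a, b_diff, 1.0)
        assert same.Ht < diff.Ht


class TestGenomeVsChromosomes:
    def _segs(self, seq, vocab, lookup, name, window=5000):
        return segment_sequence(seq, window, source_id=name, vocab=vocab,
                                r=3, lookup=lookup)

    def test_identical_chromosomes(self, std_vocab, std_lookup, rng):
        seq = "".join(random_sequence(5000, 0.45, 0.2, rng) for _ in range(4))
        by = {c: self._segs(seq, std_vocab, std_lookup, c)
              for c in ("chr1", "chr2")}
        tab = genome_vs_chromosomes(by, 0.02)
        ht = tab.set_index("scope")["Ht"]
        assert ht["whole-genome"] == pytest.approx(
            ht["inter-chromosomal-median"], abs=0.02)

    def test_matches_brute_force(self, std_vocab, std_lookup, rng):
        by = {}
        for c in ("c1", "c2", "c3"):
            seq = "".join(random_sequence(4000, 0.45, 0.25, rng)
                          for _ in range(3))
            by[c] = segment_sequence(seq, 4000, source_id=c, vocab=std_vocab,
                                     r=3, lookup=std_lookup)
        tab = genome_vs_chromosomes(by, 0.02).set_index("scope")

        def pair_d(x, y):
            return min(oriented_distance(x.spectrum, y.spectrum),
                       oriented_distance(x.spectrum, y.spectrum_rc),
                       oriented_distance(x.spectrum_rc, y.spectrum),
                       oriented_distance(x.spectrum_rc, y.spectrum_rc))

        pooled = [s for segs in by.values() for s in segs]
        all_d = [pair_d(a, b) for a, b in combinations(pooled, 2)]
        assert tab.loc["whole-genome", "Ht"] == pytest.approx(np.median(all_d))

        pair_medians = []
        for a, b in combinations(by, 2):
            ds = [pair_d(x, y) for x in by[a] for y in by[b]]
            pair_medians.append(np.median(ds))
        assert tab.loc["inter-chromosomal-median", "Ht"] == \
            pytest.approx(np.median(pair_medians))

    def test_confined_state_raises_inter(self, std_vocab, std_lookup, rng):
        """A generator confined to one chromosome makes inter-chromosomal
        Ht exceed whole-genome Ht (disproportional state distribution)."""
        def chrom(gc, bias, blocks=5):
            seq = "".join(random_sequence(5000, gc, bias, rng)
                          for _ in range(blocks))
            return segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                    lookup=std_lookup)

        by = {"chr1": chrom(0.42, 0.15), "chr2": chrom(0.42, 0.15),
              "chr3": chrom(0.50, 0.35)}
        tab = genome_vs_chromosomes(by, 0.02).set_index("scope")
        assert tab.loc["inter-chromosomal-median", "Ht"] > \
            tab.loc["whole-genome", "Ht"]


class TestGcBins:
    def test_single_bin_equals_group_ht(self, std_vocab, std_lookup, rng):
        segs = []
        for _ in range(6):
            seq = _exact_gc_segment(0.455, 5000, rng)
            segs += segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                     lookup=std_lookup)
        df = gc_bin_ho(segs, bin_width=0.01, min_bin_size=3)
        assert len(df) == 1
        sc = intra_heterogeneity(segs, delta_gc_max=1.0)
        assert df.iloc[0]["ho"] == pytest.approx(sc.Ht)

    def test_half_open_boundary(self):
        # a segment with GC exactly 0.50 belongs to [0.50, 0.51)
        assert int(np.floor(0.50 / 0.01)) == 50

    def test_bin_counts_match_histogram(self, std_vocab, std_lookup, rng):
        segs = []
        for gc in (0.35, 0.45, 0.55):
            for _ in range(5):
                seq = _exact_gc_segment(gc, 5000, rng)
                segs += segment_sequence(seq, 5000, vocab=std_vocab, r=3,
                                         lookup=std_lookup)
        df = gc_bin_ho(segs, bin_width=0.01, min_bin_size=2)
        hand = {}
        for s in segs:
            hand[int(np.floor(s.gc / 0.01))] = \
                hand.get(int(np.floor(s.gc / 0.01)), 0) + 1
        expected = {b: n for b, n in hand.items() if n >= 2}
        got = {int(round(r.gc_low / 0.01)): r.n_segments
               for r in df.itertuples()}
        assert got == expected


class TestThresholdSensitivity:
    def _fixture(self, std_vocab, std_lookup, rng):
        by = {}
        for c in ("c1", "c2"):
            seq = "".join(random_sequence(4000, gc, 0.2, rng)
                          for gc in (0.42, 0.44, 0.47))
            by[c] = segment_sequence(seq, 4000, source_id=c, vocab=std_vocab,
                                     r=3, lookup=std_lookup)
        return by

    def test_none_threshold_is_ht(self, std_vocab, std_lookup, rng):
        by = self._fixture(std_vocab, std_lookup, rng)
        pairs, summary = threshold_sensitivity(by, ["none", 0.02])
        none_row = pairs[pairs.threshold == "none"].iloc[0]
        ht = inter_sequence_heterogeneity(by["c1"], by["c2"], 1.0)
        assert none_row.median_d == pytest.approx(ht.Ht)
        assert summary.set_index("threshold").loc["none", "participation"] == 1.0

    def test_participation_monotone(self, std_vocab, std_lookup, rng):
        by = self._fixture(std_vocab, std_lookup, rng)
        _, summary = threshold_sensitivity(by, ["none", 0.05, 0.02, 0.01])
        part = summary["participation"].tolist()
        assert part == sorted(part, reverse=True)

    def test_fraction_matches_hand_count(self, std_vocab, std_lookup, rng):
        by = self._fixture(std_vocab, std_lookup, rng)
        _, summary = threshold_sensitivity(by, [0.02])
        gcs1 = [s.gc for s in by["c1"]]
        gcs2 = [s.gc for s in by["c2"]]
        hand = sum(1 for a in gcs1 for b in gcs2 if abs(a - b) <= 0.02)
        assert summary.iloc[0]["participation"] == \
            pytest.approx(hand / (len(gcs1) * len(gcs2)))


def test_hc_independent_of_vocabulary(std_vocab, std_lookup, std_vocab_alt,
                                      std_lookup_alt, rng):
    """Hc is a pure GC statistic: identical under any probe set."""
    seqs = [random_sequence(8_000, gc=0.44, bias=0.25, rng=rng)
            for _ in range(8)]

    def scores(vocab, lookup):
        segs = []
        for i, s in enumerate(seqs):
            segs += segment_sequence(s, 8_000, source_id=str(i), vocab=vocab,
                                     r=3, lookup=lookup)
        return intra_heterogeneity(segs, 0.02)

    a = scores(std_vocab, std_lookup)
    b = scores(std_vocab_alt, std_lookup_alt)
    assert a.Hc == pytest.approx(b.Hc)
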