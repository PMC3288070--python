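"""Synthetic genomes with controlled composition and organization.

Real vertebrate genomes are mosaics of regions ("CS-genomic states")
sharing both nucleotide composition and sequence organization.  The
generator emulates this with a small set of states, each defined by a
target GC content and a stickiness parameter `bias` of a first-order
(copying) Markov chain: with probability `bias` a position copies its
predecessor, otherwise it is drawn iid from the state's letter
distribution (A and T at (1−GC)/2 each, C and G at GC/2 each, i.e.
within-strand parity).  bias = 0 gives an iid sequence; bias > 0 gives
correlated letter runs — an "organized" state whose segments share a
spectral signature that reshuffling destroys.

Chromosomes are laid out as sequences of fixed-length state blocks; an
optional annotation plan emits synthetic gene and repeat intervals so
the fraction-partitioning machinery can be exercised end to end.  All
randomness flows through one seeded generator, so output is
deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encoding import ALPHABET
from .vocabulary import ParameterError

__all__ = ["StateSpec", "AnnotationPlan", "GeneratorSpec", "SyntheticGenome",
           "generate_synthetic_genome", "random_sequence",
           "exact_composition_sequence"]


@dataclass
class StateSpec:
    """One CS-state: a GC target plus first-order copy bias."""

    gc: float
    bias: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.gc < 1.0):
            raise ParameterError(f"GC target must be in (0,1), got {self.gc}")
        if not (0.0 <= self.bias < 1.0):
            raise ParameterError(f"bias must be in [0,1), got {self.bias}")

    @property
    def letter_probs(self) -> np.ndarray:
        at = (1.0 - self.gc) / 2.0
        cg = self.gc / 2.0
        return np.array([at, cg, cg, at])  # A C G T


@dataclass
class AnnotationPlan:
    """Synthetic gene/repeat intervals, placed periodically in each block.

    Within every block, `gene_frac` of the length is emitted as gene
    features and `repeat_frac` as repeat features, alternating in fixed
    phase; feature length is `feature_len`.
    """

    gene_frac: float = 0.3
    repeat_frac: float = 0.2
    feature_len: int = 2000

    def __post_init__(self):
        if self.gene_frac + self.repeat_frac > 1.0:
            raise ParameterError("gene_frac + repeat_frac must be <= 1")


@dataclass
class GeneratorSpec:
    states: dict[str, StateSpec]
    block_length: int
    layout: dict[str, list[str]]          # chromosome -> state labels
    annotation_plan: AnnotationPlan | None = None
    rng_seed: int = 0

    def __post_init__(self):
        for chrom, labels in self.layout.items():
            for lab in labels:
                if lab not in self.states:
                    raise ParameterError(
                        f"layout of {chrom!r} references undefined state {lab!r}")
        if self.block_length < 1:
            raise ParameterError("block_length must be positive")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame                    # chrom, start, end (BED-like)
    repeats: pd.DataFrame
    truth: pd.DataFrame                    # chrom, start, end, state

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def random_sequence(length: int, gc: float = 0.5, bias: float = 0.0,
                    rng=None) -> str:
    """One sequence from a single state (see module docstring)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = StateSpec(gc=gc, bias=bias).letter_probs
    iid = rng.choice(4, size=length, p=probs)
    if bias > 0.0:
        copy = rng.random(length) < bias
        copy[0] = False
        # index of the most recent non-copy position
        src = np.maximum.accumulate(np.where(~copy, np.arange(length), -1))
        iid = iid[src]
    table = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return table[iid].tobytes().decode("ascii")


def exact_composition_sequence(counts: dict[str, int], rng=None) -> str:
    """Uniform random permutation of an exact letter multiset.

    `counts` maps letters to abundances, e.g. {"A": 25000, "C": 25000,
    "G": 25000, "T": 25000} for a 100-kb segment of strictly equal
    composition.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    letters = np.concatenate([
        np.full(n, ord(c), dtype=np.uint8) for c, n in counts.items()])
    return letters[rng.permutation(len(letters))].tobytes().decode("ascii")


def _block_annotations(start: int, end: int, plan: AnnotationPlan):
    """Periodic gene/repeat features inside [start, end)."""
    genes, repeats = [], []
    period = plan.feature_len
    n_slots = (end - start) // period
    # walk fixed-length slots, assigning gene/repeat by running deficit
    g_def = r_def = 0.0
    pos = start
    for _ in range(n_slots):
        g_def += plan.gene_frac
        r_def += plan.repeat_frac
        if g_def >= 1.0:
            genes.append((pos, min(pos + period, end)))
            g_def -= 1.0
        elif r_def >= 1.0:
            repeats.append((pos, min(pos + period, end)))
            r_def -= 1.0
        pos += period
    return genes, repeats


def generate_synthetic_genome(spec: GeneratorSpec) -> SyntheticGenome:
    """Generate FASTA-ready sequences, BED-like annotations and a truth
    table mapping every block to its generating state."""
    rng = np.random.default_rng(spec.rng_seed)
    sequences: dict[str, str] = {}
    truth_rows, gene_rows, repeat_rows = [], [], []
    for chrom, labels in spec.layout.items():
        parts = []
        pos = 0
        for lab in labels:
            st = spec.states[lab]
            parts.append(random_sequence(spec.block_length, gc=st.gc,
                                         bias=st.bias, rng=rng))
            end = pos + spec.block_length
            truth_rows.append({"chrom": chrom, "start": pos, "end": end,
                               "state": lab})
            if spec.annotation_plan is not None:
                g, rp = _block_annotations(pos, end, spec.annotation_plan)
                gene_rows.extend({"chrom": chrom, "start": s, "end": e}
                                 for s, e in g)
                repeat_rows.extend({"chrom": chrom, "start": s, "end": e}
                                   for s, e in rp)
            pos = end
        sequences[chrom] = "".join(parts)
    cols = ["chrom", "start", "end"]
    return SyntheticGenome(
        sequences=sequences,
        genes=pd.DataFrame(gene_rows, columns=cols),
        repeats=pd.DataFrame(repeat_rows, columns=cols),
        truth=pd.DataFrame(truth_rows, columns=cols + ["state"]))
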