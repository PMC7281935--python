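"""Biophysical TF-binding affinity (TRAP) and wt-vs-mutant delta ranking.

The model converts a position frequency matrix into a mismatch-energy
matrix and scores a sequence by its expected occupancy summed over every
offset on both strands:

    E(b, j) = (1/lambda) * ln(p_max,j / p_b,j)          (consensus base: 0)
    E_i     = sum_j E(s[i+j], j)
    A(seq)  = sum_i  R0 * exp(-E_i) / (1 + R0 * exp(-E_i))   (both strands)

with lambda = 0.7 and ln R0 = 0.584*W - 5.66 by default. Variant impact is
the affinity difference between a mutant and a wild-type window (41 bp,
variant-centered by convention), ranked across a PFM set by |delta|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_LAMBDA = 0.7


def default_r0(width: int) -> float:
    return math.exp(0.584 * width - 5.66)


class PFMModel:
    """A position frequency matrix with its derived TRAP energy matrix.

    ``counts`` is a 4 x W array (rows A, C, G, T of non-negative counts).
    """

    def __init__(self, tf_name: str, counts, pseudocount: float = 1.0,
                 lambda_param: float = DEFAULT_LAMBDA, r0: float | None = None):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W array (rows A,C,G,T)")
        if counts.shape[1] < 4:
            raise ValueError("matrix width must be >= 4")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero PFM column")
        self.tf_name = tf_name
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.lambda_param = float(lambda_param)
        self.r0 = default_r0(counts.shape[1]) if r0 is None else float(r0)
        self.energy = pfm_to_energy(counts, pseudocount, lambda_param)
        # column-mean energy stands in for an N base
        self._energy_n = self.energy.mean(axis=0)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        depth = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount) / (depth + 4 * self.pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def pfm_to_energy(counts, pseudocount: float = 1.0, lambda_param: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Mismatch energies: 0 for each column's most frequent base, >= 0 otherwise."""
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero PFM column")
    depth = counts.sum(axis=0)
    p = (counts + pseudocount) / (depth + 4 * pseudocount)
    return np.log(p.max(axis=0) / p) / lambda_param


def _site_energies(seq: str, pfm: PFMModel) -> np.ndarray:
    w = pfm.width
    n_offsets = len(seq) - w + 1
    energies = np.zeros(n_offsets)
    for i in range(n_offsets):
        e = 0.0
        for j in range(w):
            b = seq[i + j]
            e += pfm._energy_n[j] if b == "N" else pfm.energy[_IDX[b], j]
        energies[i] = e
    return energies


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trap_affinity(sequence: str, pfm: PFMModel) -> float:
    """Expected occupancy summed over all offsets on both strands."""
    sequence = sequence.upper()
    if len(sequence) < pfm.width:
        raise ValueError(f"sequence shorter than matrix width {pfm.width}")
    total = 0.0
    for strand_seq in (sequence, reverse_complement(sequence)):
        x = pfm.r0 * np.exp(-_site_energies(strand_seq, pfm))
        total += float((x / (1.0 + x)).sum())
    return total


@dataclass
class AffinityDelta:
    tf_name: str
    affinity_wt: float
    affinity_mut: float
    delta: float
    rank: int = 0


def affinity_delta(wt_window: str, mut_window: str, pfm_set, top: int | None = None) -> list[AffinityDelta]:
    """Per-TF affinity change for a mutant vs wild-type window, ranked by |delta|.

    Identical windows are legal and yield all-zero deltas. SPM windows must
    be equal length; indel windows may differ in length.
    """
    results = []
    for pfm in pfm_set:
        wt = trap_affinity(wt_window, pfm)
        mut = trap_affinity(mut_window, pfm)
        results.append(AffinityDelta(pfm.tf_name, wt, mut, mut - wt))
    results.sort(key=lambda d: (-abs(d.delta), d.tf_name))
    for i, d in enumerate(results, start=1):
        d.rank = i
    return results[:top] if top is not None else results


def matrix_position_conservation(pfm: PFMModel, column_index: int) -> float:
    """Information content of one matrix column, in bits (pseudocounted)."""
    if not 0 <= column_index < pfm.width:
        raise IndexError(f"column {column_index} out of range for width {pfm.width}")
    p = pfm.probabilities[:, column_index]
    return float(2.0 + (p * np.log2(p)).sum())


# ----------------------------------------------------------- JASPAR I/O


def write_jaspar(pfms, path) -> None:
    from Bio.motifs import jaspar

    ms = []
    for i, p in enumerate(pfms, start=1):
        counts = {b: [float(c) for c in p.counts[_IDX[b]]] for b in BASES}
        ms.append(jaspar.Motif(matrix_id=f"MA{i:04d}.1", name=p.tf_name, counts=counts))
    with open(path, "w") as fh:
        fh.write(jaspar.write(ms, "jaspar"))


def read_jaspar(path, pseudocount: float = 1.0, lambda_param: float = DEFAULT_LAMBDA) -> list[PFMModel]:
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out.append(PFMModel(m.name, counts, pseudocount=pseudocount, lambda_param=lambda_param))
    return out


def variant_windows(sequences, variant, window: int = 41) -> tuple[str, str]:
    """41-bp (default) windows with the wild-type or mutant allele centered.

    For indels, the anchor base is centered and the mutant window carries the
    alternate allele spliced in at the anchor.
    """
    if window % 2 == 0:
        raise ValueError("window length must be odd")
    half = window // 2
    seq = sequences[variant.chrom]
    if not isinstance(seq, str):
        seq = str(seq[:])
    p0 = variant.pos0
    left = seq[max(0, p0 - half):p0]
    wt = left + seq[p0:p0 + half + 1]
    right = seq[p0 + len(variant.ref):p0 + len(variant.ref) + half]
    mut = left + variant.alt + right[: max(0, half + 1 - len(variant.alt))]
    return wt, mut
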