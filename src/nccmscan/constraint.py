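"""Per-base evolutionary-constraint track (GERP-RS-like scores).

Backed by one float32 array per chromosome so point lookups and
constrained-fraction queries over arbitrary interval sets are O(1)/O(bases).
Bases absent from a loaded bedGraph score as the fill value (unconstrained).
"""

from __future__ import annotations

import numpy as np

from .intervals import Interval

UNSCORED = 0.0  # neutral; below any sensible constraint threshold


class ConstraintTrack:
    def __init__(self, scores: dict[str, np.ndarray]):
        self.scores = {c: np.asarray(a, dtype=np.float32) for c, a in scores.items()}

    @classmethod
    def from_bedgraph(cls, path, chrom_lengths: dict[str, int]) -> "ConstraintTrack":
        arrays = {c: np.full(n, UNSCORED, dtype=np.float32) for c, n in chrom_lengths.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                if chrom in arrays:
                    arrays[chrom][int(start):int(end)] = float(value)
        return cls(arrays)

    def to_bedgraph(self, path) -> None:
        """Run-length-encoded bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="constraint_rs"\n')
            for chrom in sorted(self.scores):
                a = self.scores[chrom]
                if a.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(a)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [a.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{a[s]:g}\n")

    def score(self, chrom: str, pos0: int) -> float:
        a = self.scores.get(chrom)
        if a is None or not (0 <= pos0 < a.size):
            return UNSCORED
        return float(a[pos0])

    def constrained_mask(self, chrom: str, threshold: float = 2.0) -> np.ndarray:
        return self.scores[chrom] >= threshold

    def constrained_bases(self, chrom: str, ivs: list[Interval], threshold: float = 2.0) -> int:
        a = self.scores.get(chrom)
        n = 0
        for s, e in ivs:
            if a is None:
                continue
            s, e = max(s, 0), min(e, a.size)
            if e > s:
                n += int(np.count_nonzero(a[s:e] >= threshold))
        return n

    def constrained_fraction_genome(self, threshold: float = 2.0) -> float:
        tot = sum(a.size for a in self.scores.values())
        hit = sum(int(np.count_nonzero(a >= threshold)) for a in self.scores.values())
        return hit / tot if tot else 0.0
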