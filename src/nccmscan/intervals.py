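"""Half-open interval arithmetic on (start, end) integer pairs.

All coordinates in this package are 0-based half-open internally; VCF
positions are converted at the I/O boundary.
"""

from __future__ import annotations

from bisect import bisect_right

Interval = tuple[int, int]


def validate(ivs: list[Interval]) -> None:
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")


def merge(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent intervals."""
    if not ivs:
        return []
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: list[Interval], cut: list[Interval]) -> list[Interval]:
    """Set difference base \\ cut, both merged first."""
    base = merge(base)
    cut = merge(cut)
    out: list[Interval] = []
    ci = 0
    for s, e in base:
        cur = s
        while ci < len(cut) and cut[ci][1] <= cur:
            ci += 1
        j = ci
        while j < len(cut) and cut[j][0] < e:
            cs, ce = cut[j]
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if ce >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(ivs: list[Interval], lo: int, hi: int) -> list[Interval]:
    out = []
    for s, e in ivs:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def total_length(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def contains(ivs: list[Interval], pos: int) -> bool:
    """Point membership; `ivs` must be merged/sorted."""
    i = bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out
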