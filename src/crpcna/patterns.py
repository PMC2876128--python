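"""Enumeration of copy-number dependency run patterns.

With a minimum aberration run length of ``m`` markers, the local
evidence at a locus considers the 2m-1 surrounding markers.  Every
hypothesis about which of those markers share the center's copy number
is a contiguous run of length at least m that contains the center, and
there are exactly m(m+1)/2 of them: m runs of length m, m-1 of length
m+1, ..., down to one run spanning the full window.
"""

from __future__ import annotations

from .model import PatternSet

__all__ = ["enumerate_patterns"]


def enumerate_patterns(m: int) -> PatternSet:
    """All contiguous center-containing runs of length >= m in a 2m-1 window.

    Offsets are relative to the center locus, so the window is
    [-(m-1), ..., +(m-1)] and every pattern contains offset 0.  For
    m=4 this yields the ten classic patterns over seven loci, ordered
    by run length then by left edge: {-3..0}, {-2..+1}, {-1..+2},
    {0..+3}, {-3..+1}, {-2..+2}, {-1..+3}, {-3..+2}, {-2..+3}, {-3..+3}.

    Parameters
    ----------
    m : int
        Minimum believable aberration run length, in markers.  Must be
        a positive integer.
    """
    if isinstance(m, bool) or int(m) != m or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    m = int(m)
    half = m - 1
    patterns: list[tuple[int, ...]] = []
    for length in range(m, 2 * m):
        for start in range(-half, half - length + 2):
            if start <= 0 <= start + length - 1:
                patterns.append(tuple(range(start, start + length)))
    return PatternSet(m=m, patterns=tuple(patterns))
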