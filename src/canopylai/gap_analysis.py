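"""Sub-image gap analysis and cover fractions.

A binary canopy mask is tiled into ``subdivision²`` rectangular sub-images.
Within each sub-image the sky pixels S and leaf pixels L are counted; when
S/L exceeds the big-gap ratio (or the sub-image holds no foliage at all) the
sub-image's sky pixels are counted as *large gaps* — sky between crowns
rather than within them.  From the pooled tallies:

    foliage cover  f_f = 1 − g_T / T_P
    crown cover    f_c = 1 − g_L / T_P

where g_T is the total gap pixel count, g_L the large-gap pixel count and
T_P the total pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .imaging import BinaryCanopyMask

__all__ = [
    "GapCounts",
    "CoverMetrics",
    "subdivide",
    "analyze_gaps",
    "cover_fractions",
    "pool_counts",
    "DEFAULT_SUBDIVISION",
    "DEFAULT_BIG_GAP_RATIO",
]

DEFAULT_SUBDIVISION = 7
DEFAULT_BIG_GAP_RATIO = 0.75


@dataclass(frozen=True)
class GapCounts:
    """Pixel tallies from sub-image gap analysis of one or more images."""

    g_T: int  # total gap (sky) pixels
    g_L: int  # large-gap pixels
    T_P: int  # total pixels
    subdivision: int = DEFAULT_SUBDIVISION
    big_gap_ratio: float = DEFAULT_BIG_GAP_RATIO

    def __post_init__(self) -> None:
        if self.T_P <= 0:
            raise ValueError("total pixel count must be positive")
        if not 0 <= self.g_L <= self.g_T <= self.T_P:
            raise ValueError(
                f"require 0 <= g_L <= g_T <= T_P, got "
                f"g_L={self.g_L}, g_T={self.g_T}, T_P={self.T_P}"
            )


@dataclass(frozen=True)
class CoverMetrics:
    """Foliage and crown cover fractions of an image or tree."""

    f_f: float
    f_c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_f <= self.f_c <= 1.0:
            raise ValueError(
                f"require 0 <= f_f <= f_c <= 1, got f_f={self.f_f}, f_c={self.f_c}"
            )


def subdivide(
    mask: BinaryCanopyMask | np.ndarray, subdivision: int
) -> list[np.ndarray]:
    """Tile a mask into ``subdivision²`` near-equal rectangular sub-masks.

    Every pixel lands in exactly one sub-mask; within each axis the block
    sizes differ by at most one pixel (sizes that do not divide evenly put
    the larger blocks first).  Returned row-major: left-to-right within each
    band of rows, top band first.
    """
    grid = mask.is_foliage if isinstance(mask, BinaryCanopyMask) else np.asarray(mask)
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    h, w = grid.shape
    if subdivision > h or subdivision > w:
        raise ValueError(
            f"subdivision {subdivision} exceeds image dimensions {h}x{w}"
        )
    blocks: list[np.ndarray] = []
    for row_band in np.array_split(grid, subdivision, axis=0):
        blocks.extend(np.array_split(row_band, subdivision, axis=1))
    return blocks


def analyze_gaps(
    mask: BinaryCanopyMask,
    subdivision: int = DEFAULT_SUBDIVISION,
    big_gap_ratio: float = DEFAULT_BIG_GAP_RATIO,
) -> GapCounts:
    """Count gap and large-gap pixels by the per-sub-image S/L ratio rule.

    A sub-image's sky count S joins the large-gap tally when it contains no
    foliage (L = 0: a pure between-crown region) or when S/L is *strictly*
    greater than ``big_gap_ratio``; at exactly the ratio the sub-image is
    not a large gap.
    """
    if big_gap_ratio <= 0:
        raise ValueError("big_gap_ratio must be positive")
    g_T = 0
    g_L = 0
    for block in subdivide(mask, subdivision):
        n = block.size
        leaves = int(block.sum())
        sky = n - leaves
        g_T += sky
        # S/L > ratio compared in exact integer arithmetic: S > ratio*L
        if leaves == 0 or sky > big_gap_ratio * leaves:
            g_L += sky
    return GapCounts(
        g_T=g_T,
        g_L=g_L,
        T_P=mask.is_foliage.size,
        subdivision=subdivision,
        big_gap_ratio=big_gap_ratio,
    )


def cover_fractions(counts: GapCounts) -> CoverMetrics:
    """f_f = 1 − g_T/T_P and f_c = 1 − g_L/T_P."""
    return CoverMetrics(
        f_f=1.0 - counts.g_T / counts.T_P,
        f_c=1.0 - counts.g_L / counts.T_P,
    )


def pool_counts(counts_per_image: Sequence[GapCounts] | Iterable[GapCounts]) -> GapCounts:
    """Pool per-image tallies into one per-tree tally (component-wise sums).

    All inputs must share the same subdivision and big-gap ratio.
    """
    items = list(counts_per_image)
    if not items:
        raise ValueError("cannot pool an empty collection of GapCounts")
    first = items[0]
    for c in items[1:]:
        if c.subdivision != first.subdivision or c.big_gap_ratio != first.big_gap_ratio:
            raise ValueError(
                "cannot pool GapCounts with mixed subdivision or big_gap_ratio"
            )
    return GapCounts(
        g_T=sum(c.g_T for c in items),
        g_L=sum(c.g_L for c in items),
        T_P=sum(c.T_P for c in items),
        subdivision=first.subdivision,
        big_gap_ratio=first.big_gap_ratio,
    )
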