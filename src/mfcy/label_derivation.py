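"""Derive cavity and whole-structure labels from an annular wall annotation.

In a 2D cross-section the thoracic wall is a closed ring (annulus).  Given
only the wall mask, the thoracic cavity is the region it encloses, and the
whole thorax is the union of wall and cavity — equivalently the hole-filled
wall.  The three labels satisfy, pixel for pixel:

    cavity ∩ wall = ∅,   thorax = wall ∪ cavity,   wall = thorax − cavity.

Enclosure uses a 4-connected background flood fill from the image border,
so an 8-connected wall (diagonally touching pixels) still counts as closed;
this is the standard connectivity duality that prevents leaks through wall
corners.  A wall that encloses nothing (empty, or broken by a gap the fill
escapes through) yields an empty cavity with a ``degenerate`` flag rather
than an error, so batch label generation over imperfect annotations runs to
completion and reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask_core import as_binary_mask

__all__ = ["LabelTriple", "derive_cavity", "derive_whole_thorax", "make_label_triple"]

# 4-connected structuring element for the background fill.
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class LabelTriple:
    """Wall (tw), cavity (tc) and whole-structure (wt) masks for one frame."""

    tw: np.ndarray
    tc: np.ndarray
    wt: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        tw = as_binary_mask(self.tw)
        tc = as_binary_mask(self.tc)
        wt = as_binary_mask(self.wt)
        if not (tw.shape == tc.shape == wt.shape):
            raise ValueError("tw, tc, wt must share one shape")
        if np.any(tw & tc):
            raise ValueError("wall and cavity must be disjoint")
        if not np.array_equal(wt, tw | tc):
            raise ValueError("whole structure must equal the union of wall and cavity")
        object.__setattr__(self, "tw", tw)
        object.__setattr__(self, "tc", tc)
        object.__setattr__(self, "wt", wt)


def derive_cavity(tw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cavity enclosed by the wall: background pixels unreachable from the border.

    Returns ``(cavity, degenerate)`` where ``degenerate`` is True when the
    wall encloses no pixel at all (empty or non-closed annotation).
    The cavity is disjoint from the wall by construction.
    """
    wall = as_binary_mask(tw).astype(bool)
    filled = ndimage.binary_fill_holes(wall, structure=_CROSS)
    cavity = (filled & ~wall).astype(np.uint8)
    return cavity, not cavity.any()


def derive_whole_thorax(tw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Whole structure = wall ∪ cavity, i.e. the hole-filled wall."""
    wall = as_binary_mask(tw)
    cavity, degenerate = derive_cavity(wall)
    return (wall | cavity).astype(np.uint8), degenerate


def make_label_triple(tw: np.ndarray) -> LabelTriple:
    """Build the full label triple from a wall annotation.

    Constructed as cavity-then-union so the disjointness and union
    identities hold bit-exactly by construction; in particular
    ``wt - tc == tw`` element-wise.
    """
    wall = as_binary_mask(tw)
    cavity, degenerate = derive_cavity(wall)
    wt = (wall | cavity).astype(np.uint8)
    return LabelTriple(tw=wall, tc=cavity, wt=wt, degenerate=degenerate)
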