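"""Programmatic test-input generation: letter/shape images and focus sets.

Everything here is reproducible from a recipe plus a seed; letters are
rasterised from a built-in 5x7 dot-matrix font so rendering is bit-exact
on every platform (no font files, no text engine).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .holography import TargetPattern
from .multifocus import FocusSet

__all__ = [
    "PatternRecipe",
    "FONT_5X7",
    "render_pattern",
    "reference_focus_sets",
]

# Classic 5x7 dot-matrix glyphs; '#' marks an on pixel.
FONT_5X7: dict[str, tuple[str, ...]] = {
    " ": (".....",) * 7,
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "B": ("####.", "#...#", "#...#", "####.", "#...#", "#...#", "####."),
    "C": (".###.", "#...#", "#....", "#....", "#....", "#...#", ".###."),
    "D": ("####.", "#...#", "#...#", "#...#", "#...#", "#...#", "####."),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "G": (".###.", "#...#", "#....", "#.###", "#...#", "#...#", ".###."),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "I": (".###.", "..#..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "J": ("..###", "...#.", "...#.", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "#.#..", "##...", "#.#..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#.#.#", "#...#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "Q": (".###.", "#...#", "#...#", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "#...#", "####.", "#.#..", "#..#.", "#...#"),
    "S": (".###.", "#...#", "#....", ".###.", "....#", "#...#", ".###."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", "#...#", ".#.#.", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#...#", "#.#.#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", "#...#", ".#.#.", "..#..", ".#.#.", "#...#", "#...#"),
    "Y": ("#...#", "#...#", ".#.#.", "..#..", "..#..", "..#..", "..#.."),
    "Z": ("#####", "....#", "...#.", "..#..", ".#...", "#....", "#####"),
}

_GLYPH_W, _GLYPH_H, _GLYPH_GAP = 5, 7, 1


class UnsupportedGlyphError(ValueError):
    """Text contains characters outside the built-in font."""


@dataclass(frozen=True)
class PatternRecipe:
    """Deterministic description of a synthetic target image.

    kinds and their parameters:

    - ``letters``: ``text`` (A-Z and space);
    - ``points``: ``points`` = list of (row, col) pixel indices, default a
      single centred pixel;
    - ``disks``: ``disks`` = list of (row, col, radius_px), default three
      spread disks;
    - ``checkerboard``: ``cells`` = cell count per side (default 8).
    """

    kind: str
    size_px: int = 256
    pixel_pitch: float = 0.035  # mm
    depth: float = 7.0          # mm
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("letters", "points", "disks", "checkerboard"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.size_px < 16:
            raise ValueError("size_px must be >= 16")


def _rasterize_text(text: str, size: int) -> np.ndarray:
    missing = sorted({c for c in text.upper() if c not in FONT_5X7})
    if missing:
        raise UnsupportedGlyphError(f"unsupported glyphs: {missing}")
    text = text.upper()
    n = len(text)
    cell_w = n * _GLYPH_W + (n - 1) * _GLYPH_GAP
    scale = max(1, min(size // cell_w, size // _GLYPH_H))
    img = np.zeros((size, size), dtype=float)
    total_w = cell_w * scale
    total_h = _GLYPH_H * scale
    r0 = (size - total_h) // 2
    c0 = (size - total_w) // 2
    for gi, ch in enumerate(text):
        rows = FONT_5X7[ch]
        gc = c0 + gi * (_GLYPH_W + _GLYPH_GAP) * scale
        for r, row in enumerate(rows):
            for c, px in enumerate(row):
                if px == "#":
                    rr = r0 + r * scale
                    cc = gc + c * scale
                    img[rr : rr + scale, cc : cc + scale] = 1.0
    return img


def render_pattern(recipe: PatternRecipe) -> TargetPattern:
    """Rasterise a recipe into a TargetPattern; bit-identical per recipe."""
    size = recipe.size_px
    img = np.zeros((size, size), dtype=float)
    if recipe.kind == "letters":
        img = _rasterize_text(recipe.params.get("text", "USC"), size)
    elif recipe.kind == "points":
        pts = recipe.params.get("points", [(size // 2, size // 2)])
        for r, c in pts:
            img[int(r), int(c)] = 1.0
    elif recipe.kind == "disks":
        default = [
            (size // 4, size // 4, size // 16),
            (size // 4, 3 * size // 4, size // 16),
            (3 * size // 4, size // 2, size // 16),
        ]
        rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        for r, c, rad in recipe.params.get("disks", default):
            img[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = 1.0
    elif recipe.kind == "checkerboard":
        cells = recipe.params.get("cells", 8)
        cell = size // cells
        rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        img = (((rr // cell) + (cc // cell)) % 2).astype(float)
    return TargetPattern(
        amplitude=img, pixel_pitch=recipe.pixel_pitch, depth=recipe.depth
    )


def reference_focus_sets(depth: float) -> dict[str, FocusSet]:
    """Canonical focus suites at a given stimulation depth (mm).

    ``single``: one on-axis focus; ``pair``: two foci at x = +/-0.3 mm;
    ``grid3x3``: a 3x3 lateral grid spanning 1 mm.  All targets have unit
    amplitude and zero phase.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    single = FocusSet(points=[[0.0, 0.0, depth]], target_pressures=[1.0])
    pair = FocusSet(
        points=[[-0.3, 0.0, depth], [0.3, 0.0, depth]],
        target_pressures=[1.0, 1.0],
    )
    offsets = np.linspace(-0.5, 0.5, 3)
    pts = [[x, y, depth] for y in offsets for x in offsets]
    grid = FocusSet(points=pts, target_pressures=np.ones(9))
    return {"single": single, "pair": pair, "grid3x3": grid}
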