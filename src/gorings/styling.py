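"""Colour assignment: distinct parent palettes, child gradients, GO tags.

Each parent group receives a perceptually distinct base colour from a fixed
curated 20-entry palette (in the spirit of Colorgorical-generated palettes,
embedded so output is reproducible offline).  Its children are coloured by a
dark-to-light gradient of that base colour: the darkest shade marks the most
significant term, and the per-parent overflow slice — always last — ends up
lightest.  Every parent also gets a "GO j" tag tying its wedge to the
legend, which keeps the plot readable for colour-impaired readers.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

from .hierarchy import TwoLevelHierarchy

RGB = tuple[float, float, float]

#: Curated qualitative palette (hex), pairwise RGB distance >= 0.1.
_PALETTE_HEX = (
    "#1f77b4",  # blue
    "#ff7f0e",  # orange
    "#2ca02c",  # green
    "#d62728",  # red
    "#9467bd",  # purple
    "#8c564b",  # brown
    "#e377c2",  # pink
    "#7f7f7f",  # grey
    "#bcbd22",  # olive
    "#17becf",  # cyan
    "#393b79",  # navy
    "#637939",  # moss
    "#8c6d31",  # ochre
    "#843c39",  # maroon
    "#7b4173",  # plum
    "#3caea3",  # teal
    "#f6d55c",  # gold
    "#ed553b",  # coral
    "#20639b",  # steel
    "#a0d568",  # lime
)

#: Fraction of the distance toward white covered by a gradient's endpoint.
GRADIENT_WHITE_BLEND = 0.75

#: Lightness subtracted per palette cycle when more than 20 groups exist.
CYCLE_LIGHTNESS_OFFSET = 0.15


def _hex_to_rgb(code: str) -> RGB:
    code = code.lstrip("#")
    return tuple(int(code[i : i + 2], 16) / 255.0 for i in (0, 2, 4))


BASE_PALETTE: tuple[RGB, ...] = tuple(_hex_to_rgb(c) for c in _PALETTE_HEX)


def luma(color: RGB) -> float:
    """Perceptual lightness approximation (Rec. 601 luma)."""
    r, g, b = color
    return 0.299 * r + 0.587 * g + 0.114 * b


@dataclass(frozen=True)
class StyleMap:
    """Resolved colours and tags for one hierarchy, in display order.

    All three mappings are insertion-ordered by group display order (and,
    for ``child_colors``, child display order within each group), so their
    values can be consumed positionally by the renderer.
    """

    parent_colors: dict[str, RGB]
    child_colors: dict[tuple[str, int], RGB]
    go_tags: dict[str, str]


def _darken(color: RGB, offset: float) -> RGB:
    if offset == 0.0:  # avoid HLS round-trip noise on the first cycle
        return color
    h, l, s = colorsys.rgb_to_hls(*color)
    return colorsys.hls_to_rgb(h, max(0.0, l - offset), s)


def make_parent_palette(k: int) -> list[RGB]:
    """Deterministic list of k base colours for the parent wedges.

    Beyond 20 groups the palette cycles, each cycle darkened by a fixed
    lightness offset so repeated hues remain tellable apart.
    """
    if k < 1:
        raise ValueError(f"palette size must be >= 1, got {k}")
    colors: list[RGB] = []
    for i in range(k):
        cycle, idx = divmod(i, len(BASE_PALETTE))
        colors.append(_darken(BASE_PALETTE[idx], CYCLE_LIGHTNESS_OFFSET * cycle))
    return colors


def make_gradient(base: RGB, steps: int) -> list[RGB]:
    """Interpolate from ``base`` toward a light endpoint over ``steps``.

    The endpoint is the base blended three-quarters of the way to white;
    the first colour is the base itself, and lightness increases strictly
    along the sequence.  ``steps=1`` returns just the base.
    """
    if steps < 1:
        raise ValueError(f"gradient length must be >= 1, got {steps}")
    if steps == 1:
        return [base]
    end = tuple(c + GRADIENT_WHITE_BLEND * (1.0 - c) for c in base)
    out: list[RGB] = []
    for i in range(steps):
        t = i / (steps - 1)
        out.append(tuple((1.0 - t) * b + t * e for b, e in zip(base, end)))
    return out


def build_style(h: TwoLevelHierarchy) -> StyleMap:
    """Assign palette colours, per-child gradients and GO tags to ``h``."""
    palette = make_parent_palette(len(h.groups))
    parent_colors: dict[str, RGB] = {}
    child_colors: dict[tuple[str, int], RGB] = {}
    go_tags: dict[str, str] = {}
    for i, group in enumerate(h.groups):
        parent_colors[group.parent_label] = palette[i]
        go_tags[group.parent_label] = f"GO {i + 1}"
        gradient = make_gradient(palette[i], len(group.children))
        for j, color in enumerate(gradient):
            child_colors[(group.parent_label, j)] = color
    return StyleMap(parent_colors, child_colors, go_tags)
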