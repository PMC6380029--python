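"""Geometry and rendering of the two-ring circular plot.

Angles are measured in degrees clockwise from 12 o'clock, matching the
pie-chart convention readers expect: the most significant group starts at
the top and slices proceed clockwise in decreasing significance.  A child
slice's angular span is proportional to its |log10 p| weight; each inner
(parent) wedge spans exactly the union of its children's outer wedges.

Every child label is drawn — none is ever omitted for space — at the same
font size, rotated to the local radial direction, with labels on the left
half of the circle flipped 180 degrees so the text still reads outward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Patch, Wedge
import matplotlib

from .errors import ValidationError
from .hierarchy import MAX_CATEGORIES, DEFAULT_CATEGORIES, TwoLevelHierarchy, group_proportions
from .styling import StyleMap, build_style, luma

_ANGLE_TOL = 1e-6

#: Default ring radii (r0, r1, r2, r3) as fractions of the figure half-size:
#: inner ring [r0, r1], outer ring [r1, r2], labels anchored at r3.
DEFAULT_RADII = (0.35, 0.60, 0.85, 0.90)

#: Labels longer than this many characters wrap onto two lines.
LABEL_WRAP_CHARS = 35

_FORMATS = ("svg", "png", "pdf")


@dataclass(frozen=True)
class RingLayout:
    """Resolved angular geometry for both rings.

    ``inner_arcs[i]`` spans group i; ``outer_arcs[j]`` spans child j in
    display order; all angles in degrees clockwise from 12 o'clock.
    """

    inner_arcs: tuple[tuple[float, float], ...]
    outer_arcs: tuple[tuple[float, float], ...]
    radii: tuple[float, float, float, float] = DEFAULT_RADII

    def validate(self) -> None:
        r0, r1, r2, r3 = self.radii
        if not (0 < r0 < r1 < r2 < r3 <= 1):
            raise ValidationError(f"radii must satisfy 0<r0<r1<r2<r3<=1: {self.radii}")
        span = math.fsum(e - s for s, e in self.outer_arcs)
        if abs(span - 360.0) > _ANGLE_TOL:
            raise ValidationError(f"outer arcs span {span!r} deg, expected 360")
        cursor = 0.0
        for s, e in self.outer_arcs:
            if abs(s - cursor) > _ANGLE_TOL or e < s:
                raise ValidationError("outer arcs not contiguous from 0 deg")
            cursor = e


@dataclass(frozen=True)
class LegendSpec:
    """Ordered legend entries: (GO tag, parent label, percentage)."""

    entries: tuple[tuple[str, str, float], ...]
    title: str = "GO terms"

    def formatted(self) -> list[str]:
        return [
            f"{tag}: {label} ({pct:.2f}%)" for tag, label, pct in self.entries
        ]


@dataclass(frozen=True)
class LabelPlacement:
    """One text element: a child label or a parent's GO tag."""

    text: str
    kind: str  # "child" or "tag"
    angle: float  # mid-angle, degrees clockwise from 12 o'clock
    radius: float
    rotation: float  # matplotlib text rotation, degrees counterclockwise
    ha: str
    flipped: bool
    font_size: float


@dataclass(frozen=True)
class RenderConfig:
    """User-facing plotting parameters."""

    m: int = DEFAULT_CATEGORIES
    font_size: float = 7.0
    legend_title: str = "GO terms"
    output_format: str = "svg"
    dpi: int = 300
    figure_size: tuple[float, float] = (10.0, 8.0)
    radii: tuple[float, float, float, float] = DEFAULT_RADII

    def __post_init__(self) -> None:
        if not 1 <= self.m <= MAX_CATEGORIES:
            raise ValidationError(
                f"number of categories must be in [1, {MAX_CATEGORIES}], got {self.m}"
            )
        if self.font_size <= 0:
            raise ValidationError(f"font size must be positive, got {self.font_size}")
        if self.dpi < 72:
            raise ValidationError(f"dpi must be >= 72, got {self.dpi}")
        if self.output_format not in _FORMATS:
            raise ValidationError(
                f"unknown output format {self.output_format!r}; "
                f"choose one of {_FORMATS}"
            )


def compute_angles(
    h: TwoLevelHierarchy,
    radii: tuple[float, float, float, float] = DEFAULT_RADII,
) -> RingLayout:
    """Lay both rings out clockwise from 12 o'clock, spans ~ value/total."""
    outer: list[tuple[float, float]] = []
    inner: list[tuple[float, float]] = []
    cumulative = 0.0
    start = 0.0
    for group in h.groups:
        group_start = start
        for child in group.children:
            cumulative += child.value
            end = 360.0 * cumulative / h.total
            outer.append((start, end))
            start = end
        inner.append((group_start, start))
    # Snap the closing edge onto 360 (floating summation residue only).
    if outer and abs(outer[-1][1] - 360.0) <= _ANGLE_TOL:
        outer[-1] = (outer[-1][0], 360.0)
        inner[-1] = (inner[-1][0], 360.0)
    layout = RingLayout(tuple(inner), tuple(outer), radii)
    layout.validate()
    return layout


def _wrap_label(text: str) -> str:
    """Wrap overlong labels onto two lines at the space nearest the middle."""
    if len(text) <= LABEL_WRAP_CHARS or " " not in text:
        return text
    middle = len(text) / 2
    split = min(
        (i for i, ch in enumerate(text) if ch == " "),
        key=lambda i: abs(i - middle),
    )
    return text[:split] + "\n" + text[split + 1 :]


def _radial_rotation(mid_angle: float) -> tuple[float, str, bool]:
    """Rotation (ccw degrees), alignment and flip flag for a radial label."""
    rotation = 90.0 - mid_angle
    flipped = 180.0 < mid_angle % 360.0 < 360.0
    if flipped:
        rotation += 180.0
        ha = "right"
    else:
        ha = "left"
    return rotation, ha, flipped


def place_labels(
    layout: RingLayout, h: TwoLevelHierarchy, cfg: RenderConfig
) -> list[LabelPlacement]:
    """Place every child label and every GO tag; nothing is omitted.

    Child labels anchor at their arc's angular midpoint at the label radius
    and run along the radial direction; GO tags sit at the inner-arc
    midpoints.  All text uses the single configured font size.
    """
    placements: list[LabelPlacement] = []
    r0, r1, _, r3 = layout.radii
    flat = h.flatten()
    for (parent, child), (s, e) in zip(flat, layout.outer_arcs):
        mid = (s + e) / 2.0
        rotation, ha, flipped = _radial_rotation(mid)
        placements.append(
            LabelPlacement(
                text=_wrap_label(child.label),
                kind="child",
                angle=mid,
                radius=r3,
                rotation=rotation,
                ha=ha,
                flipped=flipped,
                font_size=cfg.font_size,
            )
        )
    for i, (s, e) in enumerate(layout.inner_arcs):
        mid = (s + e) / 2.0
        placements.append(
            LabelPlacement(
                text=f"GO {i + 1}",
                kind="tag",
                angle=mid,
                radius=(r0 + r1) / 2.0,
                rotation=0.0,
                ha="center",
                flipped=False,
                font_size=cfg.font_size,
            )
        )
    return placements


def build_legend(
    h: TwoLevelHierarchy, style: StyleMap, title: str = "GO terms"
) -> LegendSpec:
    """One legend entry per group: GO tag, parent label, weight share."""
    proportions = group_proportions(h)
    entries = tuple(
        (style.go_tags[g.parent_label], g.parent_label, proportions[g.parent_label])
        for g in h.groups
    )
    return LegendSpec(entries=entries, title=title)


def _to_xy(angle_cw_from_top: float, radius: float) -> tuple[float, float]:
    phi = math.radians(90.0 - angle_cw_from_top)
    return radius * math.cos(phi), radius * math.sin(phi)


def _mpl_angles(start: float, end: float) -> tuple[float, float]:
    """Clockwise-from-12 arc to matplotlib's counterclockwise-from-east."""
    return 90.0 - end, 90.0 - start


def render(
    layout: RingLayout,
    style: StyleMap,
    legend: LegendSpec,
    cfg: RenderConfig,
    out_path: str | Path,
    labels: Sequence[LabelPlacement] = (),
) -> None:
    """Draw the two-ring plot and write it to ``out_path``.

    SVG output is deterministic: identical inputs produce byte-identical
    files (fixed hash salt, no timestamp metadata, fonts referenced by
    family name rather than embedded).  Raster determinism is best-effort.
    """
    out_path = Path(out_path)
    inner_colors = list(style.parent_colors.values())
    outer_colors = list(style.child_colors.values())
    if len(inner_colors) != len(layout.inner_arcs):
        raise ValidationError("style and layout disagree on group count")
    if len(outer_colors) != len(layout.outer_arcs):
        raise ValidationError("style and layout disagree on child count")

    r0, r1, r2, _ = layout.radii
    with matplotlib.rc_context(
        {
            "svg.hashsalt": "gorings",
            "svg.fonttype": "none",
            "font.family": "DejaVu Sans",
        }
    ):
        fig = Figure(figsize=cfg.figure_size)
        FigureCanvasAgg(fig)
        ax = fig.add_axes((0.01, 0.03, 0.60, 0.94))
        ax.set_aspect("equal")
        ax.set_axis_off()
        ax.set_xlim(-1.45, 1.45)
        ax.set_ylim(-1.45, 1.45)

        for i, (s, e) in enumerate(layout.inner_arcs):
            t1, t2 = _mpl_angles(s, e)
            ax.add_patch(
                Wedge(
                    (0, 0), r1, t1, t2, width=r1 - r0,
                    facecolor=inner_colors[i], edgecolor="white",
                    linewidth=0.5, gid=f"inner-wedge-{i}",
                )
            )
        for j, (s, e) in enumerate(layout.outer_arcs):
            t1, t2 = _mpl_angles(s, e)
            ax.add_patch(
                Wedge(
                    (0, 0), r2, t1, t2, width=r2 - r1,
                    facecolor=outer_colors[j], edgecolor="white",
                    linewidth=0.5, gid=f"outer-wedge-{j}",
                )
            )

        tag_index = 0
        for k, lab in enumerate(labels):
            x, y = _to_xy(lab.angle, lab.radius)
            color = "black"
            if lab.kind == "tag":
                # Tags sit on the parent wedge; pick contrasting text.
                base = inner_colors[min(tag_index, len(inner_colors) - 1)]
                color = "white" if luma(base) < 0.5 else "black"
                tag_index += 1
            ax.text(
                x, y, lab.text,
                rotation=lab.rotation, rotation_mode="anchor",
                ha=lab.ha, va="center", fontsize=lab.font_size,
                color=color, gid=f"label-{k}",
            )

        handles = [
            Patch(facecolor=c, edgecolor="white", linewidth=0.5)
            for c in inner_colors
        ]
        fig.legend(
            handles,
            legend.formatted(),
            loc="center right",
            bbox_to_anchor=(0.99, 0.5),
            title=legend.title,
            fontsize=cfg.font_size,
            title_fontsize=cfg.font_size + 1,
            frameon=False,
        )

        save_kwargs: dict = {"format": cfg.output_format, "dpi": cfg.dpi}
        if cfg.output_format == "svg":
            save_kwargs["metadata"] = {"Date": None}
        elif cfg.output_format == "pdf":
            save_kwargs["metadata"] = {"CreationDate": None}
        try:
            fig.savefig(out_path, **save_kwargs)
        except OSError:
            raise
        finally:
            fig.clear()


def render_hierarchy(
    h: TwoLevelHierarchy, cfg: RenderConfig, out_path: str | Path
) -> tuple[RingLayout, StyleMap, LegendSpec]:
    """Convenience pipeline: style, lay out, label, legend, render."""
    style = build_style(h)
    layout = compute_angles(h, cfg.radii)
    labels = place_labels(layout, h, cfg)
    legend = build_legend(h, style, cfg.legend_title)
    render(layout, style, legend, cfg, out_path, labels=labels)
    return layout, style, legend
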