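"""Assembly of the two-level parent/child hierarchy that drives the plot.

The pipeline here is: sort all records by significance, keep the top *m*
child categories, collapse everything beyond the cut into one aggregate
"additional categories" slice per parent, and order parent groups from most
to least significant.  Total |log10 p| mass is conserved exactly: every
parsed input value ends up either as a named child slice, inside a parent's
aggregate slice, or in the trailing orphan pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io_formats import GOTermRecord

#: Label of every overflow slice and of the orphan-pool group.
AGGREGATE_LABEL = "additional categories"

#: Hard upper bound on the number of displayed child categories.
MAX_CATEGORIES = 60

#: Default number of displayed child categories.
DEFAULT_CATEGORIES = 40

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ChildSlice:
    """One outer-ring slice: a real term or a per-parent aggregate."""

    label: str
    value: float
    is_aggregate: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(
                f"child slice value must be positive, got {self.value!r}"
            )
        if self.is_aggregate and self.label != AGGREGATE_LABEL:
            raise ValidationError(
                f"aggregate slices must be labelled {AGGREGATE_LABEL!r}"
            )


@dataclass(frozen=True)
class ParentGroup:
    """An inner-ring wedge: a parent term and its ordered child slices."""

    parent_label: str
    children: tuple[ChildSlice, ...]
    group_total: float

    def validate(self) -> None:
        if not self.children:
            raise ValidationError(f"group {self.parent_label!r} has no children")
        total = math.fsum(c.value for c in self.children)
        if not math.isclose(total, self.group_total, rel_tol=_REL_TOL):
            raise ValidationError(
                f"group {self.parent_label!r}: total {self.group_total!r} "
                f"!= child sum {total!r}"
            )
        aggregates = [i for i, c in enumerate(self.children) if c.is_aggregate]
        if len(aggregates) > 1:
            raise ValidationError(
                f"group {self.parent_label!r} has multiple aggregate slices"
            )
        if aggregates and aggregates[0] != len(self.children) - 1:
            raise ValidationError(
                f"group {self.parent_label!r}: aggregate slice must be last"
            )
        regular = [c.value for c in self.children if not c.is_aggregate]
        if any(b > a for a, b in zip(regular, regular[1:])):
            raise ValidationError(
                f"group {self.parent_label!r}: children not in "
                "non-increasing value order"
            )


@dataclass(frozen=True)
class TwoLevelHierarchy:
    """Ordered parent groups plus the bookkeeping counts n and m."""

    groups: tuple[ParentGroup, ...]
    total: float
    n_input_rows: int
    m_requested: int

    def validate(self) -> None:
        if not self.groups:
            raise ValidationError("hierarchy has no groups")
        for g in self.groups:
            g.validate()
        total = math.fsum(g.group_total for g in self.groups)
        if not math.isclose(total, self.total, rel_tol=_REL_TOL):
            raise ValidationError(
                f"hierarchy total {self.total!r} != group sum {total!r}"
            )
        # The orphan pool (if any) is exempt from the total-ordering rule.
        comparable = [
            g.group_total
            for g in self.groups
            if g.parent_label != AGGREGATE_LABEL
        ]
        if any(b > a for a, b in zip(comparable, comparable[1:])):
            raise ValidationError("groups not in non-increasing total order")
        n_regular = sum(
            1 for g in self.groups for c in g.children if not c.is_aggregate
        )
        if n_regular != min(self.m_requested, self.n_input_rows):
            raise ValidationError(
                f"expected {min(self.m_requested, self.n_input_rows)} "
                f"regular child slices, found {n_regular}"
            )

    @property
    def n_outer_slices(self) -> int:
        return sum(len(g.children) for g in self.groups)

    def flatten(self) -> list[tuple[str, ChildSlice]]:
        """Child slices in display order, tagged with their parent label."""
        return [(g.parent_label, c) for g in self.groups for c in g.children]


def sort_records(records: Sequence[GOTermRecord]) -> list[GOTermRecord]:
    """Sort by significance: non-increasing value, ties alphabetically.

    The sort is stable, so records equal in both value and description keep
    their input order.
    """
    if not records:
        raise ValidationError("cannot sort an empty record list")
    return sorted(records, key=lambda r: (-r.value, r.description))


def select_top(
    sorted_records: Sequence[GOTermRecord], m: int
) -> tuple[list[GOTermRecord], list[GOTermRecord]]:
    """Split sorted records into the m most significant and the remainder."""
    if not 1 <= m <= MAX_CATEGORIES:
        raise ValidationError(
            f"number of categories must be in [1, {MAX_CATEGORIES}], got {m}"
        )
    kept = list(sorted_records[:m])
    omitted = list(sorted_records[m:])
    return kept, omitted


def aggregate_overflow(
    omitted: Sequence[GOTermRecord], kept_parents: Iterable[str]
) -> tuple[dict[str, ChildSlice], ParentGroup | None]:
    """Collapse beyond-top-m records into per-parent aggregate slices.

    Omitted records whose representative is among the kept parents sum into
    that parent's "additional categories" slice.  Records whose parent has
    no kept children cannot attach to any inner wedge; they are pooled into
    a single trailing group (also labelled "additional categories") so that
    no input mass is dropped.
    """
    kept_parents = set(kept_parents)
    per_parent: dict[str, list[float]] = {}
    orphan_values: list[float] = []
    for r in omitted:
        if r.representative in kept_parents:
            per_parent.setdefault(r.representative, []).append(r.value)
        else:
            orphan_values.append(r.value)

    aggregates = {
        parent: ChildSlice(AGGREGATE_LABEL, math.fsum(values), is_aggregate=True)
        for parent, values in per_parent.items()
    }
    orphan_pool = None
    if orphan_values:
        total = math.fsum(orphan_values)
        orphan_pool = ParentGroup(
            parent_label=AGGREGATE_LABEL,
            children=(ChildSlice(AGGREGATE_LABEL, total, is_aggregate=True),),
            group_total=total,
        )
    return aggregates, orphan_pool


def build_hierarchy(
    kept: Sequence[GOTermRecord],
    aggregates: Mapping[str, ChildSlice],
    orphan_pool: ParentGroup | None,
    m: int,
    n: int,
) -> TwoLevelHierarchy:
    """Group the kept records under their parents and order everything.

    Within a group the real children stay in non-increasing value order and
    the aggregate slice, when present, always comes last — even when its
    summed value exceeds a sibling's — because it stands for the least
    significant terms.  Groups are ordered by non-increasing total weight,
    ties broken by first appearance of the parent in the kept records; the
    orphan pool, if any, is placed last regardless of size.
    """
    if not kept:
        raise ValidationError("cannot build a hierarchy from zero kept records")

    order: list[str] = []
    members: dict[str, list[ChildSlice]] = {}
    for r in kept:
        if r.representative not in members:
            members[r.representative] = []
            order.append(r.representative)
        members[r.representative].append(ChildSlice(r.description, r.value))

    groups: list[ParentGroup] = []
    for parent in order:
        children = sorted(
            members[parent], key=lambda c: (-c.value, c.label)
        )
        if parent in aggregates:
            children.append(aggregates[parent])
        groups.append(
            ParentGroup(
                parent_label=parent,
                children=tuple(children),
                group_total=math.fsum(c.value for c in children),
            )
        )

    first_seen = {parent: i for i, parent in enumerate(order)}
    groups.sort(key=lambda g: (-g.group_total, first_seen[g.parent_label]))
    if orphan_pool is not None:
        groups.append(orphan_pool)

    hierarchy = TwoLevelHierarchy(
        groups=tuple(groups),
        total=math.fsum(g.group_total for g in groups),
        n_input_rows=n,
        m_requested=m,
    )
    hierarchy.validate()
    return hierarchy


def summarise_records(
    records: Sequence[GOTermRecord], m: int = DEFAULT_CATEGORIES
) -> TwoLevelHierarchy:
    """Run the full values-calculation step: sort, subset, aggregate, build."""
    ordered = sort_records(records)
    kept, omitted = select_top(ordered, m)
    aggregates, orphan_pool = aggregate_overflow(
        omitted, {r.representative for r in kept}
    )
    return build_hierarchy(kept, aggregates, orphan_pool, m, len(ordered))


def group_proportions(h: TwoLevelHierarchy) -> dict[str, float]:
    """Per-group share of total weight, as percentages rounded to 2 dp."""
    return {
        g.parent_label: round(100.0 * g.group_total / h.total, 2)
        for g in h.groups
    }
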