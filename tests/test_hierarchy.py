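"""The values-calculation step: sort, subset, overflow aggregation, assembly."""

import math

import pytest
from hypothesis import given, strategies as st

from gorings import (
    AGGREGATE_LABEL,
    ChildSlice,
    GOTermRecord,
    ValidationError,
    aggregate_overflow,
    build_hierarchy,
    group_proportions,
    select_top,
    sort_records,
    summarise_records,
    toy_T1,
)
from gorings.fixtures import FixtureSpec, generate_revigo_table


class TestSortRecords:
    def test_descending_by_value(self):
        records = [GOTermRecord(d, "p", v) for d, v in [("x", 3), ("y", 5), ("z", 1)]]
        assert [r.value for r in sort_records(records)] == [5, 3, 1]

    def test_ties_break_alphabetically(self):
        records = [GOTermRecord("b", "p", 2.0), GOTermRecord("a", "p", 2.0)]
        assert [r.description for r in sort_records(records)] == ["a", "b"]

    def test_idempotent_on_sorted_input(self, t1_records):
        once = sort_records(t1_records)
        assert sort_records(once) == once

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sort_records([])


class TestSelectTop:
    def test_toy_split(self, t1_records):
        kept, omitted = select_top(sort_records(t1_records), 3)
        assert [r.description for r in kept] == ["a1", "b1", "a2"]
        assert [r.description for r in omitted] == ["b2", "a3"]
        assert sorted(kept + omitted, key=lambda r: r.description) == sorted(
            t1_records, key=lambda r: r.description
        )

    def test_m_at_least_n_leaves_nothing_out(self, t1_records):
        kept, omitted = select_top(sort_records(t1_records), 60)
        assert len(kept) == 5 and omitted == []

    @pytest.mark.parametrize("m", [0, -1, 61, 1000])
    def test_out_of_range_m_rejected(self, t1_records, m):
        with pytest.raises(ValidationError):
            select_top(sort_records(t1_records), m)


class TestAggregateOverflow:
    def test_toy_per_parent_sums(self, t1_records):
        _, omitted = select_top(sort_records(t1_records), 3)
        aggregates, orphan = aggregate_overflow(omitted, {"A", "B"})
        assert orphan is None
        assert aggregates["A"].value == 1.0
        assert aggregates["B"].value == 2.0
        assert all(c.is_aggregate and c.label == AGGREGATE_LABEL
                   for c in aggregates.values())

    def test_empty_omitted(self):
        aggregates, orphan = aggregate_overflow([], {"A"})
        assert aggregates == {} and orphan is None

    def test_orphans_pooled_not_dropped(self):
        aggregates, orphan = aggregate_overflow(
            [GOTermRecord("c1", "C", 2.0)], {"A", "B"}
        )
        assert aggregates == {}
        assert orphan.parent_label == AGGREGATE_LABEL
        assert orphan.group_total == 2.0
        assert orphan.children[0].is_aggregate


class TestBuildHierarchy:
    def test_toy_worked_example(self, t1_hierarchy):
        h = t1_hierarchy
        assert [g.parent_label for g in h.groups] == ["A", "B"]
        a, b = h.groups
        assert [(c.label, c.value) for c in a.children] == [
            ("a1", 5.0), ("a2", 3.0), (AGGREGATE_LABEL, 1.0)
        ]
        assert [(c.label, c.value) for c in b.children] == [
            ("b1", 4.0), (AGGREGATE_LABEL, 2.0)
        ]
        assert (a.group_total, b.group_total) == (9.0, 6.0)
        assert h.total == 15.0
        assert h.n_outer_slices == 5  # m=3 kept + 2 aggregate slices

    def test_single_record(self):
        h = summarise_records([GOTermRecord("x", "X", 7.0)], m=1)
        assert len(h.groups) == 1
        assert h.groups[0].children[0].label == "x"
        assert h.total == 7.0

    def test_no_overflow_when_m_covers_all(self, t1_records):
        h = summarise_records(t1_records, m=60)
        assert h.n_outer_slices == 5
        assert not any(c.is_aggregate for g in h.groups for c in g.children)

    def test_empty_kept_rejected(self):
        with pytest.raises(ValidationError):
            build_hierarchy([], {}, None, 3, 0)

    def test_aggregate_last_even_when_largest(self):
        # Overflow sum (4+4=8) exceeds every kept sibling of parent A.
        records = [GOTermRecord(d, "A", v) for d, v in
                   [("a1", 5), ("a2", 4.5), ("o1", 4), ("o2", 4)]]
        h = summarise_records(records, m=2)
        children = h.groups[0].children
        assert children[-1].is_aggregate and children[-1].value == 8.0
        assert [c.value for c in children] == [5.0, 4.5, 8.0]

    def test_orphan_pool_placed_last_regardless_of_size(self):
        # Parent C's only child is omitted; its pooled mass (6) exceeds B's total.
        records = [
            GOTermRecord("a1", "A", 9.0),
            GOTermRecord("b1", "B", 8.0),
            GOTermRecord("c1", "C", 6.0),
        ]
        h = summarise_records(records, m=2)
        assert [g.parent_label for g in h.groups] == ["A", "B", AGGREGATE_LABEL]
        assert h.groups[-1].group_total == 6.0


class TestGroupProportions:
    def test_toy_percentages(self, t1_hierarchy):
        assert group_proportions(t1_hierarchy) == {"A": 60.0, "B": 40.0}

    def test_single_group_is_100(self):
        h = summarise_records([GOTermRecord("x", "X", 7.0)], m=1)
        assert group_proportions(h) == {"X": 100.0}

    def test_three_equal_groups_round_to_33_33(self):
        records = [GOTermRecord(f"t{i}", f"P{i}", 2.0) for i in range(3)]
        h = summarise_records(records, m=3)
        assert set(group_proportions(h).values()) == {33.33}

    def test_unrounded_values_sum_to_100(self, t1_hierarchy):
        raw = [100 * g.group_total / t1_hierarchy.total for g in t1_hierarchy.groups]
        assert math.isclose(math.fsum(raw), 100.0, rel_tol=1e-12)


def _slice_count_oracle(records, m):
    """Hand-executed slice-count law, independent of the hierarchy code."""
    ordered = sorted(records, key=lambda r: (-r.value, r.description))
    kept, omitted = ordered[:m], ordered[m:]
    kept_parents = {r.representative for r in kept}
    overflow_parents = {r.representative for r in omitted} & kept_parents
    orphans = any(r.representative not in kept_parents for r in omitted)
    return min(m, len(records)) + len(overflow_parents) + (1 if orphans else 0)


@given(seed=st.integers(0, 2**20), m=st.integers(1, 60), data=st.data())
def test_hierarchy_properties_on_random_tables(tmp_path, seed, m, data):
    """Conservation, slice-count law and ordering hold for random inputs."""
    spec = FixtureSpec(
        n_parents=data.draw(st.integers(1, 8)),
        children_per_parent=(1, data.draw(st.integers(1, 6))),
        seed=seed,
    )
    records = generate_revigo_table(spec, tmp_path / f"{seed}.csv")
    h = summarise_records(records, m=m)
    h.validate()
    # conservation vs brute-force summation oracle
    assert math.isclose(h.total, math.fsum(r.value for r in records), rel_tol=1e-9)
    # slice-count law
    assert h.n_outer_slices == _slice_count_oracle(records, m)
    # ordering: groups non-increasing (orphan pool exempt), aggregates last
    totals = [g.group_total for g in h.groups if g.parent_label != AGGREGATE_LABEL]
    assert all(a >= b for a, b in zip(totals, totals[1:]))
    for g in h.groups:
        regular = [c.value for c in g.children if not c.is_aggregate]
        assert all(a >= b for a, b in zip(regular, regular[1:]))
        assert not any(c.is_aggregate for c in g.children[:-1])


@given(seed=st.integers(0, 2**20))
def test_rebuilding_from_flattened_output_reproduces_structure(tmp_path, seed):
    """Feeding a hierarchy's own slices back in reproduces its groups."""
    spec = FixtureSpec(n_parents=4, children_per_parent=(1, 4), seed=seed)
    records = generate_revigo_table(spec, tmp_path / f"{seed}.csv")
    h = summarise_records(records, m=10)
    # Aggregate slices re-enter as ordinary terms; (label, parent) pairs stay unique.
    flat = [GOTermRecord(c.label, parent, c.value) for parent, c in h.flatten()]
    h2 = summarise_records(flat, m=min(60, len(flat)))
    assert math.isclose(h2.total, h.total, rel_tol=1e-9)
    groups1 = {g.parent_label: sorted(c.value for c in g.children) for g in h.groups}
    groups2 = {g.parent_label: sorted(c.value for c in g.children) for g in h2.groups}
    assert groups1 == groups2
    assert sorted(round(g.group_total, 9) for g in h.groups) == sorted(
        round(g.group_total, 9) for g in h2.groups
    )
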