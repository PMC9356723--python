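"""Clinical outcomes: normalization, subdomain aggregation, mapping, MoCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keycog.clinical import (
    DEFAULT_MAPPING,
    MOCA_SECTIONS,
    SUBDOMAINS,
    ConfigurationError,
    MappingSchemaError,
    MissingValueError,
    ScaleItemValue,
    load_mapping,
    moca_total,
    normalize_item,
    score_subject,
    subdomain_score,
)


def brute_force_scores(items, mapping):
    """Independent literal re-evaluation of the normalization and mean.

    Kept deliberately naive (per-item loops, no shared helpers) so it can
    serve as an oracle for score_subject.
    """
    out = {}
    for sd in SUBDOMAINS:
        vals = []
        for it in items:
            if it.missing:
                continue
            found = [
                d for d in mapping.items
                if d.scale == it.scale and d.item == it.item and sd in d.subdomains
            ]
            if not found:
                continue
            frac = it.raw / it.max
            vals.append(frac if it.direction == "higher_worse" else 1.0 - frac)
        out[sd] = (math.fsum(vals) / len(vals) if vals else math.nan, len(vals))
    return out


def random_item_set(rng):
    items = []
    for d in DEFAULT_MAPPING.items:
        missing = rng.random() < 0.15
        raw = float(rng.integers(0, int(d.max) + 1))
        items.append(
            ScaleItemValue(d.scale, d.item, raw, d.max, d.direction, missing)
        )
    return items


@pytest.mark.parametrize(
    "raw, mx, direction, expected",
    [
        (0, 5, "higher_worse", 0.0),
        (5, 5, "higher_worse", 1.0),
        (3, 4, "higher_better", 0.25),
        (4, 4, "higher_better", 0.0),
        (0, 4, "higher_better", 1.0),
    ],
)
def test_normalize_item_anchors(raw, mx, direction, expected):
    item = ScaleItemValue("MoCA", "Memory", raw, mx, direction)
    assert normalize_item(item) == pytest.approx(expected)


def test_normalize_item_errors():
    with pytest.raises(MissingValueError):
        normalize_item(ScaleItemValue("MoCA", "Memory", 1, 5, "higher_worse", True))
    with pytest.raises(ConfigurationError):
        normalize_item(ScaleItemValue("MoCA", "Memory", 0, 0, "higher_worse"))


def test_subdomain_score_is_mean_of_valid_items():
    # three ADLQ-style higher_worse items mapped to executive function
    items = [
        ScaleItemValue("ADLQ", "Self-Care", 1.5, 3, "higher_worse"),   # 0.5
        ScaleItemValue("FAB", "Similarities", 2.25, 3, "higher_better"),  # 0.25
        ScaleItemValue("DRS2", "Construction", 1.5, 6, "higher_better"),  # 0.75
    ]
    score, m = subdomain_score(items, DEFAULT_MAPPING, "executive_function")
    assert (score, m) == (pytest.approx(0.5), 3)


def test_subdomain_score_skips_missing_items():
    items = [
        ScaleItemValue("ADLQ", "Self-Care", 0.6, 3, "higher_worse"),       # 0.2
        ScaleItemValue("FAB", "Similarities", 1.8, 3, "higher_better"),    # 0.4
        ScaleItemValue("DRS2", "Construction", 2.4, 6, "higher_better"),   # 0.6
        ScaleItemValue("MoCA", "Abstraction", 1, 2, "higher_better", True),
    ]
    score, m = subdomain_score(items, DEFAULT_MAPPING, "executive_function")
    assert m == 3
    assert score == pytest.approx(0.4)


def test_all_items_missing_gives_nan_and_zero_count():
    items = [ScaleItemValue("MoCA", "Memory", 3, 5, "higher_better", True)]
    score, m = subdomain_score(items, DEFAULT_MAPPING, "verbal_memory")
    assert math.isnan(score) and m == 0


def test_unknown_subdomain_rejected():
    with pytest.raises(ConfigurationError):
        subdomain_score([], DEFAULT_MAPPING, "memory_x")


def test_moca_memory_feeds_both_memory_subdomains():
    items = [ScaleItemValue("MoCA", "Memory", 0, 5, "higher_better")]  # fully impaired
    scores = score_subject(items, DEFAULT_MAPPING)
    assert scores["verbal_memory"] == pytest.approx(1.0)
    assert scores["non_verbal_memory"] == pytest.approx(1.0)
    assert math.isnan(scores["perception"])


def test_unimpaired_subject_scores_zero_everywhere():
    items = [
        ScaleItemValue(
            d.scale, d.item,
            0.0 if d.direction == "higher_worse" else d.max,
            d.max, d.direction,
        )
        for d in DEFAULT_MAPPING.items
    ]
    scores = score_subject(items, DEFAULT_MAPPING)
    assert all(scores[sd] == pytest.approx(0.0) for sd in SUBDOMAINS)


def test_score_subject_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        items = random_item_set(rng)
        got = score_subject(items, DEFAULT_MAPPING)
        want = brute_force_scores(items, DEFAULT_MAPPING)
        for sd in SUBDOMAINS:
            w, wm = want[sd]
            assert got.counts[sd] == wm
            if math.isnan(w):
                assert math.isnan(got[sd])
            else:
                assert got[sd] == w  # bitwise for rational inputs


def test_unmapped_item_warns_and_is_ignored():
    items = [ScaleItemValue("MoCA", "NotAnItem", 1, 5, "higher_better")]
    with pytest.warns(UserWarning, match="not in the subdomain mapping"):
        scores = score_subject(items, DEFAULT_MAPPING)
    assert all(math.isnan(scores[sd]) for sd in SUBDOMAINS)


class TestMocaTotal:
    def _sections(self, values):
        return [
            ScaleItemValue("MoCA", name, v, mx, "higher_better")
            for (name, mx), v in zip(MOCA_SECTIONS.items(), values)
        ]

    def test_full_score_sums_to_30(self):
        assert moca_total(self._sections([5, 3, 6, 3, 2, 5, 6])) == 30

    def test_all_zero(self):
        assert moca_total(self._sections([0] * 7)) == 0

    def test_missing_section_yields_nan(self):
        items = self._sections([5, 3, 6, 3, 2, 5, 6])[:-1]
        assert math.isnan(moca_total(items))

    def test_partial_sum_opt_in(self):
        items = self._sections([5, 3, 6, 3, 2, 5, 6])[:-1]
        with pytest.warns(UserWarning, match="6/7"):
            assert moca_total(items, allow_partial=True) == 24


class TestDefaultMapping:
    def test_moca_memory_maps_to_both_memories(self):
        d = DEFAULT_MAPPING.lookup("MoCA", "Memory")
        assert set(d.subdomains) == {"verbal_memory", "non_verbal_memory"}

    def test_mental_tracking_is_moca_attention_only(self):
        items = DEFAULT_MAPPING.items_for("mental_tracking_monitoring")
        assert [(d.scale, d.item) for d in items] == [("MoCA", "Attention")]

    def test_executive_function_has_largest_item_set(self):
        sizes = {sd: len(DEFAULT_MAPPING.items_for(sd)) for sd in SUBDOMAINS}
        assert sizes["executive_function"] == 12
        assert sizes["executive_function"] == max(sizes.values())
        assert all(n > 0 for n in sizes.values())

    def test_every_subdomain_is_canonical_and_covered(self):
        covered = {sd for d in DEFAULT_MAPPING.items for sd in d.subdomains}
        assert covered == set(SUBDOMAINS)


class TestLoadMapping:
    def test_default_returns_shipped_mapping(self):
        assert load_mapping("default") is DEFAULT_MAPPING

    def test_custom_yaml_round_trip(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text(
            "scales:\n"
            "  MoCA:\n"
            "    Memory:\n"
            "      max: 5\n"
            "      direction: higher_better\n"
            "      subdomains: [verbal_memory, non_verbal_memory]\n"
        )
        spec = load_mapping(path)
        assert len(spec.items) == 1
        assert spec.lookup("MoCA", "Memory").max == 5

    def test_non_canonical_subdomain_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "scales:\n  MoCA:\n    Memory:\n      max: 5\n"
            "      direction: higher_better\n      subdomains: [memory_x]\n"
        )
        with pytest.raises(MappingSchemaError, match="memory_x"):
            load_mapping(path)

    def test_empty_subdomain_set_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "scales:\n  MoCA:\n    Memory:\n      max: 5\n"
            "      direction: higher_better\n      subdomains: []\n"
        )
        with pytest.raises(MappingSchemaError, match="empty"):
            load_mapping(path)


item_st = st.sampled_from(DEFAULT_MAPPING.items).flatmap(
    lambda d: st.floats(0, float(d.max), allow_nan=False).map(
        lambda raw: ScaleItemValue(d.scale, d.item, raw, d.max, d.direction)
    )
)


@settings(max_examples=100, deadline=None)
@given(st.lists(item_st, max_size=25))
def test_all_scores_stay_in_unit_interval(items):
    scores = score_subject(items, DEFAULT_MAPPING)
    for sd in SUBDOMAINS:
        v = scores[sd]
        assert math.isnan(v) or 0.0 <= v <= 1.0


@settings(max_examples=50, deadline=None)
@given(st.lists(item_st, min_size=1, max_size=25), st.randoms())
def test_item_order_never_changes_scores(items, rnd):
    a = score_subject(list(items), DEFAULT_MAPPING)
    shuffled = list(items)
    rnd.shuffle(shuffled)
    b = score_subject(shuffled, DEFAULT_MAPPING)
    for sd in SUBDOMAINS:
        va, vb = a[sd], b[sd]
        assert (math.isnan(va) and math.isnan(vb)) or va == vb


def test_raising_higher_worse_item_never_lowers_mapped_scores():
    rng = np.random.default_rng(7)
    for _ in range(50):
        items = random_item_set(rng)
        idx = next(
            (i for i, it in enumerate(items)
             if it.direction == "higher_worse" and not it.missing and it.raw < it.max),
            None,
        )
        if idx is None:
            continue
        bumped = list(items)
        it = items[idx]
        bumped[idx] = ScaleItemValue(it.scale, it.item, it.raw + 1, it.max, it.direction)
        before = score_subject(items, DEFAULT_MAPPING)
        after = score_subject(bumped, DEFAULT_MAPPING)
        mapped = DEFAULT_MAPPING.lookup(it.scale, it.item).subdomains
        for sd in mapped:
            assert after[sd] >= before[sd]
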