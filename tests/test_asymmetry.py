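"""Tests for ratio computation, the asymmetry statistic and peak ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bsamap import (Gene, asymmetry_profile, asymmetry_value, build_segments,
                    compute_ratios, merge_mating_types, rank_peaks)
from bsamap.segments import SegmentCountMatrix


def _matrix(segment_ids, libs, values, totals):
    columns = pd.MultiIndex.from_product([libs, ["A", "B"]],
                                         names=["library", "genome"])
    df = pd.DataFrame(values, index=pd.Index(segment_ids, name="segment"),
                      columns=columns)
    return SegmentCountMatrix(df, totals)


def test_merge_sums_counts_and_totals():
    libs = ["NS_a", "NS_alpha", "SW_a", "SW_alpha", "parent_A", "parent_B"]
    values = np.arange(2 * 12).reshape(2, 12)
    totals = {(lib, g): 100 + i for i, (lib, g) in
              enumerate((l, g) for l in libs for g in "AB")}
    merged = merge_mating_types(_matrix(["s0", "s1"], libs, values, totals))
    assert (merged.counts[("SW", "A")] ==
            values[:, libs.index("SW_a") * 2] +
            values[:, libs.index("SW_alpha") * 2]).all()
    assert merged.totals[("NS", "B")] == \
        totals[("NS_a", "B")] + totals[("NS_alpha", "B")]
    # zero pool: merged equals the other mating type
    values2 = values.copy()
    values2[:, libs.index("SW_a") * 2:libs.index("SW_a") * 2 + 2] = 0
    m2 = merge_mating_types(_matrix(["s0", "s1"], libs, values2, totals))
    assert (m2.counts[("SW", "A")] ==
            values2[:, libs.index("SW_alpha") * 2]).all()


def test_merge_requires_all_four_pools():
    libs = ["SW_a", "parent_A", "parent_B"]
    with pytest.raises(KeyError, match="missing"):
        merge_mating_types(_matrix(["s0"], libs, np.ones((1, 6)),
                                   {(l, g): 1 for l in libs for g in "AB"}))


def test_ratio_arithmetic_from_definition():
    """counts 20/1000 over parent 10/1000 -> ratio exactly 2."""
    libs = ["SW", "NS", "parent_A", "parent_B"]
    values = np.array([[20, 0, 10, 0, 10, 0, 0, 10]])
    totals = {("SW", "A"): 1000, ("SW", "B"): 1000,
              ("NS", "A"): 1000, ("NS", "B"): 1000,
              ("parent_A", "A"): 1000, ("parent_A", "B"): 1,
              ("parent_B", "A"): 1, ("parent_B", "B"): 1000}
    ratios = compute_ratios(_matrix(["s0"], libs, values, totals))
    assert ratios.loc["s0", "SW_A"] == pytest.approx(2.0)
    assert ratios.loc["s0", "NS_A"] == pytest.approx(1.0)


def test_proportional_counts_give_unit_ratios():
    libs = ["SW", "NS", "parent_A", "parent_B"]
    rng = np.random.default_rng(0)
    base = rng.integers(10, 50, size=5)
    values = np.column_stack([base * 2, base, base * 3, base * 2,
                              base * 5, np.zeros(5, int),
                              np.zeros(5, int), base * 4])
    totals = {("SW", "A"): int(base.sum() * 2), ("SW", "B"): int(base.sum()),
              ("NS", "A"): int(base.sum() * 3), ("NS", "B"): int(base.sum() * 2),
              ("parent_A", "A"): int(base.sum() * 5), ("parent_A", "B"): 1,
              ("parent_B", "A"): 1, ("parent_B", "B"): int(base.sum() * 4)}
    ratios = compute_ratios(_matrix([f"s{i}" for i in range(5)], libs,
                                    values, totals))
    for col in ("SW_A", "NS_A", "SW_B", "NS_B"):
        assert np.allclose(ratios[col], 1.0)
    assert (asymmetry_profile(ratios) == 0).all()


def test_zero_parent_count_invalidates_ratio_and_zeroes_asymmetry():
    libs = ["SW", "NS", "parent_A", "parent_B"]
    values = np.array([[50, 1, 1, 50, 0, 0, 0, 20]])  # parent_A count 0
    totals = {(l, g): 100 for l in libs for g in "AB"}
    ratios = compute_ratios(_matrix(["s0"], libs, values, totals))
    assert not ratios.loc["s0", "SW_A_valid"]
    assert np.isnan(ratios.loc["s0", "SW_A"])
    assert asymmetry_profile(ratios).loc["s0"] == 0.0


def test_zero_library_total_is_an_error():
    libs = ["SW", "NS", "parent_A", "parent_B"]
    totals = {(l, g): 100 for l in libs for g in "AB"}
    totals[("SW", "A")] = 0
    with pytest.raises(ValueError, match="zero reads"):
        compute_ratios(_matrix(["s0"], libs, np.ones((1, 8)), totals))


@pytest.mark.parametrize("ratios,expected", [
    ((1.0, 1.0, 1.0, 1.0), 0.0),
    ((2.0, 0.5, 0.5, 2.0), 0.25),
    ((2.0, 1.5, 0.5, 2.0), 0.0),     # NS_A clamp kills it
    ((2.0, 0.0, 0.0, 0.5), 0.0),     # NS_B clamp kills it
    ((2.0, 0.0, 0.0, 2.0), 1.0),
    ((0.9, 0.5, 0.5, 2.0), 0.0),     # SW_A clamp
])
def test_asymmetry_value_is_the_clamped_product(ratios, expected):
    sw_a, ns_a, sw_b, ns_b = ratios
    assert asymmetry_value(sw_a, ns_a, sw_b, ns_b) == pytest.approx(expected)


def test_asymmetry_rejects_negative_and_zeroes_nan():
    with pytest.raises(ValueError):
        asymmetry_value(-0.1, 1, 1, 1)
    assert asymmetry_value(float("nan"), 2.0, 0.5, 2.0) == 0.0


@given(st.tuples(*[st.floats(0, 10) for _ in range(4)]))
def test_asymmetry_nonnegative_and_zero_unless_four_criteria(vals):
    sw_a, ns_a, sw_b, ns_b = vals
    v = asymmetry_value(sw_a, ns_a, sw_b, ns_b)
    assert v >= 0
    four = sw_a > 1 and ns_a < 1 and ns_b > 1 and sw_b < 1
    assert (v > 0) == four


@given(st.tuples(*[st.floats(0, 10) for _ in range(4)]))
def test_asymmetry_symmetric_under_joint_label_swap(vals):
    sw_a, ns_a, sw_b, ns_b = vals
    direct = asymmetry_value(sw_a, ns_a, sw_b, ns_b)
    # exchange genomes A<->B together with pool roles SW<->NS
    swapped = asymmetry_value(ns_b, sw_b, ns_a, sw_a)
    assert direct == pytest.approx(swapped)


def _toy_map(values):
    genes = {}
    orthologs = []
    pos = 10
    for i in range(len(values) // 2):
        gid = f"c1g{i + 1:02d}"
        genes[gid] = Gene(gid, "chr1", pos, pos + 10, "+")
        orthologs.append((gid, gid))
        pos += 20
    smap = build_segments(orthologs, genes, dict(genes),
                          {"chr1": pos}, {"chr1": pos})
    profile = pd.Series(values[:len(smap)],
                        index=[s.segment_id for s in smap.segments])
    return smap, profile


def test_peak_ranking_enumerates_runs_in_order():
    smap, profile = _toy_map([0, 0.1, 0.4, 0, 0, 0.1, 0.05, 0, 0])
    peaks = rank_peaks(profile, smap)
    assert len(peaks) == 2
    assert peaks[0].apex_value == pytest.approx(0.4)
    assert peaks[0].segment_ids == (smap.segments[1].segment_id,
                                    smap.segments[2].segment_id)
    assert peaks[1].apex_value == pytest.approx(0.1)
    assert peaks[0].rank == 1 and peaks[1].rank == 2


def test_single_positive_segment_is_its_own_peak():
    smap, profile = _toy_map([0, 0, 0.3, 0, 0, 0, 0, 0, 0])
    peaks = rank_peaks(profile, smap)
    assert len(peaks) == 1
    assert peaks[0].apex_segment == smap.segments[2].segment_id


def test_all_zero_profile_has_no_peaks():
    smap, profile = _toy_map([0.0] * 9)
    assert rank_peaks(profile, smap) == []


def test_min_value_threshold_filters_runs():
    smap, profile = _toy_map([0, 0.1, 0.4, 0, 0, 0.1, 0.05, 0, 0])
    peaks = rank_peaks(profile, smap, min_value=0.2)
    assert len(peaks) == 1 and peaks[0].apex_value == pytest.approx(0.4)
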