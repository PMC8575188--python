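"""Derived developmental metrics against direct-formula and table oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from acinostereo import devmetrics, volio
from acinostereo.devmetrics import (
    AcinusRecord,
    alveolar_volume_and_diameter,
    cv_of_day,
    day_weighted_mean,
    estimate_n_acini,
    linear_scale_factor,
    normalize_volumes,
    quintile_ratio,
    records_frame,
    sphere_equivalent_diameter_um,
    summarize_by_animal,
    total_alveoli,
)


@pytest.fixture(scope="module")
def synthetic_records():
    rng = np.random.default_rng(7)
    records = []
    for day, animals in [(4, 3), (60, 3)]:
        for a in range(animals):
            for k in range(rng.integers(5, 12)):
                vol = float(rng.lognormal(-3 if day == 4 else 0, 0.8))
                records.append(
                    AcinusRecord(
                        animal_id=f"{day:02d}{chr(65 + a)}",
                        day=day,
                        acinus_id=f"{day}-{a}-{k}",
                        volume_mm3=vol,
                        n_alveoli=int(rng.integers(5, 50)),
                    )
                )
    return records


class TestSummaries:
    def test_per_animal_moments_match_direct_formulas(self, synthetic_records):
        table = summarize_by_animal(synthetic_records, "volume_mm3")
        frame = records_frame(synthetic_records)
        for _, row in table.frame.iterrows():
            vals = frame.loc[frame["animal_id"] == row["animal_id"], "volume_mm3"]
            assert row["assessed_acini"] == len(vals)
            assert row["average"] == pytest.approx(vals.mean())
            assert row["sd"] == pytest.approx(vals.std(ddof=1))
            assert row["minimum"] == vals.min() and row["maximum"] == vals.max()

    def test_input_order_invariance(self, synthetic_records):
        shuffled = list(synthetic_records)
        np.random.default_rng(0).shuffle(shuffled)
        a = summarize_by_animal(synthetic_records, "counts").frame
        b = summarize_by_animal(shuffled, "counts").frame
        pd.testing.assert_frame_equal(a, b)

    def test_single_record_sd_zero_with_flag(self):
        rec = [AcinusRecord("01A", 4, "x", 0.02, 10)]
        table = summarize_by_animal(rec, "volume_mm3")
        assert table.frame.iloc[0]["sd"] == 0.0
        assert table.undefined_sd == ["01A"]

    def test_density_consistent_with_parents(self, synthetic_records):
        frame = records_frame(synthetic_records)
        assert np.allclose(
            frame["density_per_mm3"] * frame["volume_mm3"], frame["n_alveoli"]
        )


class TestDayAggregates:
    def test_counts_day60_rounds_to_702(self):
        table = volio.load_packaged_table("counts")
        assert round(day_weighted_mean(table, 60)) == 702

    def test_volume_day10_rounds_to_004(self):
        table = volio.load_packaged_table("volume_mm3")
        assert round(day_weighted_mean(table, 10), 2) == 0.04

    def test_single_animal_day_returns_its_mean(self):
        frame = pd.DataFrame(
            [{"animal_id": "X", "day": 4, "assessed_acini": 7, "average": 3.5,
              "sd": 1.0, "minimum": 2.0, "maximum": 5.0}]
        )
        table = volio.CountingTable("counts", frame)
        assert day_weighted_mean(table, 4) == 3.5

    def test_unknown_day_is_error(self):
        table = volio.load_packaged_table("counts")
        with pytest.raises(ValueError):
            day_weighted_mean(table, 42)

    def test_weighted_mean_equals_pooled_mean(self, synthetic_records):
        """Weighted per-animal means reproduce the pooled per-acinus mean exactly."""
        table = summarize_by_animal(synthetic_records, "volume_mm3")
        frame = records_frame(synthetic_records)
        pooled = frame.loc[frame["day"] == 60, "volume_mm3"].mean()
        assert day_weighted_mean(table, 60) == pytest.approx(pooled, rel=1e-12)


class TestCV:
    def test_two_point_closed_form(self):
        recs = [AcinusRecord("A", 4, "1", 1.0, 1), AcinusRecord("A", 4, "2", 3.0, 1)]
        assert cv_of_day(recs, 4) == pytest.approx(math.sqrt(2) / 2, rel=1e-12)

    def test_constant_records_zero(self):
        recs = [AcinusRecord("A", 4, str(i), 0.5, 1) for i in range(4)]
        assert cv_of_day(recs, 4) == 0.0

    def test_table_reconstruction_matches_pooled_records(self, synthetic_records):
        """Pooled variance rebuilt from per-animal moments equals the direct CV."""
        table = summarize_by_animal(synthetic_records, "volume_mm3")
        direct = cv_of_day(synthetic_records, 60)
        assert cv_of_day(table, 60) == pytest.approx(direct, rel=1e-10)

    @pytest.mark.parametrize("day,published,tol", [(4, 1.26, 0.03), (60, 0.49, 0.03)])
    def test_volume_cv_from_rounded_table_rows(self, day, published, tol):
        """Rounded per-animal rows reproduce the published CVs within 0.03."""
        table = volio.load_packaged_table("volume_mm3")
        assert abs(cv_of_day(table, day) - published) <= tol


class TestDispersion:
    def test_quintile_ratio_bruteforce_oracle(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 0.3]
        ratio, lo, hi, n = quintile_ratio(vals)
        s = sorted(vals)
        assert n == 2
        assert lo == pytest.approx(np.mean(s[:2])) and hi == pytest.approx(np.mean(s[-2:]))
        assert ratio == pytest.approx(np.mean(s[-2:]) / np.mean(s[:2]))

    def test_constant_volumes_give_unity(self):
        assert quintile_ratio([2.0] * 10)[0] == 1.0

    @pytest.mark.parametrize("n,expected_tail", [(125, 25), (58, 12), (42, 8), (43, 9)])
    def test_tail_sizes_match_published_counts(self, n, expected_tail):
        ratio, _, _, tail = quintile_ratio(np.arange(1.0, n + 1.0))
        assert tail == expected_tail

    def test_too_few_acini_is_error(self):
        with pytest.raises(ValueError):
            quintile_ratio([1.0, 2.0])

    def test_normalization_max_one_and_order(self):
        vals = np.array([0.4, 0.1, 0.8, 0.2])
        normed, median = normalize_volumes(vals)
        assert normed.max() == 1.0
        assert np.array_equal(np.argsort(normed), np.argsort(vals))
        assert median == pytest.approx(np.median(vals / 0.8))

    def test_single_acinus_normalizes_to_one(self):
        normed, median = normalize_volumes([0.3])
        assert normed.tolist() == [1.0] and median == 1.0


class TestLungMetrics:
    def test_simple_quotient(self):
        assert estimate_n_acini(1.0, 0.1) == pytest.approx(10.0)

    def test_algebraic_round_trip(self):
        n = estimate_n_acini(123.4, 0.037)
        assert total_alveoli(n, 50.0) * 1e6 / 50.0 * 0.037 == pytest.approx(123.4)

    def test_total_alveoli_day60_from_published_inputs(self):
        assert total_alveoli(4277, 702) == pytest.approx(3.01, rel=0.01)

    def test_sphere_identity(self):
        assert sphere_equivalent_diameter_um(math.pi / 6.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("v_um3,d_um", [(8.12e5, 116), (4.98e5, 98)])
    def test_published_alveolar_diameters(self, v_um3, d_um):
        assert round(sphere_equivalent_diameter_um(v_um3)) == d_um

    def test_ductal_fraction_multiplies_quotient(self):
        v, d = alveolar_volume_and_diameter(0.74, 702.0, 0.77)
        assert v == pytest.approx(0.77 * 0.74e9 / 702.0)
        assert d == pytest.approx(sphere_equivalent_diameter_um(v))

    def test_zero_count_is_error(self):
        with pytest.raises(ValueError):
            alveolar_volume_and_diameter(0.5, 0.0, 0.8)


class TestScaleFactor:
    def test_ratio_of_sums_cross_study_totals(self):
        hist = [0.823, 3.538, 14.303, 19.297]
        own = [0.64, 1.23, 2.65, 3.01]
        assert linear_scale_factor(hist, own, "ratio_of_sums") == pytest.approx(5.04, abs=0.005)

    def test_mean_of_ratios_alveolar_volumes(self):
        own = [4.98e5, 3.34e5, 3.07e5, 8.12e5]
        hist = [5.91e5, 2.49e5, 1.34e5, 2.93e5]
        assert linear_scale_factor(own, hist, "mean_of_ratios") == pytest.approx(1.81, abs=0.005)

    def test_identical_series_unity_both_modes(self):
        s = [1.0, 2.0, 3.0]
        for mode in ("ratio_of_sums", "mean_of_ratios"):
            assert linear_scale_factor(s, s, mode) == 1.0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            linear_scale_factor([1.0, 2.0], [1.0], "ratio_of_sums")
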