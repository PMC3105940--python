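from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readqa.filters import FilterConfig
from readqa.io import QualityRead
from readqa.stats import (
    CoverageParams,
    accumulate,
    base_quality_histogram,
    coverage_table,
    estimate_coverage,
    per_base_mean_series,
    read_mean,
    read_median,
    retention_percentage,
    truncate2,
)


def reads_from(vectors):
    return [QualityRead(f"r{i}", tuple(v)) for i, v in enumerate(vectors)]


class TestReadMean:
    def test_constant_vector(self):
        assert read_mean([20, 20, 20]) == 20

    def test_forced_arithmetic(self):
        assert read_mean([5, 10, 30]) == 15

    def test_divergent_mean_median_read(self):
        # 13 values of 23 and 12 of 15: sum 479 over 25 -> 19.16 exactly
        qvs = [23] * 13 + [15] * 12
        assert read_mean(qvs) == Fraction(479, 25)
        assert float(read_mean(qvs)) == 19.16

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            read_mean([])


class TestReadMedian:
    def test_odd(self):
        assert read_median([10, 20, 30]) == 20

    def test_even_averages_middles(self):
        assert read_median([10, 20, 20, 30]) == 20
        assert read_median([10, 20, 21, 30]) == Fraction(41, 2)

    def test_robust_to_outlier(self):
        assert read_median([1, 1, 50]) == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            read_median([])

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_side_preserving_perturbation_invariance(self, data):
        qvs = data.draw(
            st.lists(st.integers(min_value=0, max_value=93), min_size=3, max_size=21)
        )
        if len(qvs) % 2 == 0:  # the invariance holds when the median is an element
            qvs = qvs[:-1]
        med = read_median(qvs)
        perturbed = []
        for q in qvs:
            if q > med:
                perturbed.append(data.draw(st.integers(min_value=int(med) + 1, max_value=94)))
            elif q < med:
                lo = -1
                hi = int(med) - (0 if med != int(med) else 1)
                perturbed.append(data.draw(st.integers(min_value=lo, max_value=hi)))
            else:
                perturbed.append(q)
        assert read_median(perturbed) == med


class TestAccumulate:
    def test_two_reads_position_freq(self):
        agg = accumulate(reads_from([[10, 20], [30, 40]]), 2)
        assert base_quality_histogram(agg, 1) == {10: 1, 30: 1}
        assert base_quality_histogram(agg, 2) == {20: 1, 40: 1}
        assert per_base_mean_series(agg) == [20, 30]
        agg.check_invariants()

    def test_wrong_length_read_raises(self):
        with pytest.raises(ValueError):
            accumulate(reads_from([[1, 2, 3]]), 2)

    def test_matches_dense_matrix_oracle(self, random_reads):
        reads = random_reads(1000, 30)
        agg = accumulate(reads, 30)
        matrix = np.array([r.qvs for r in reads])
        for p in range(30):
            expected = Counter(matrix[:, p].tolist())
            assert base_quality_histogram(agg, p + 1) == dict(expected)
        means = per_base_mean_series(agg)
        for p in range(30):
            assert means[p] == Fraction(int(matrix[:, p].sum()), 1000)
        # read-level distributions against brute force
        assert agg.read_mean_freq == Counter(read_mean(r.qvs) for r in reads)
        assert agg.read_median_freq == Counter(read_median(r.qvs) for r in reads)
        agg.check_invariants()

    def test_empty_aggregate_mean_series_raises(self):
        agg = accumulate([], 5)
        with pytest.raises(ValueError):
            per_base_mean_series(agg)

    def test_histogram_position_out_of_range(self):
        agg = accumulate(reads_from([[5, 5]]), 2)
        with pytest.raises(ValueError):
            base_quality_histogram(agg, 3)

    def test_single_read_mean_series_is_the_read(self):
        agg = accumulate(reads_from([[7, 8, 9]]), 3)
        assert per_base_mean_series(agg) == [7, 8, 9]

    def test_histogram_examples(self):
        agg = accumulate(reads_from([[5, 5], [5, 10]]), 2)
        assert base_quality_histogram(agg, 1) == {5: 2}
        assert base_quality_histogram(agg, 2) == {5: 1, 10: 1}


class TestEstimateCoverage:
    def test_mean_qv20_cell(self):
        assert estimate_coverage(CoverageParams(11_349_208, 35, 2_300_000)) == 172

    def test_truncates_not_rounds(self):
        # 13,140,825 * 35 / 2,300,000 = 199.97... -> 199
        assert estimate_coverage(CoverageParams(13_140_825, 35, 2_300_000)) == 199

    def test_zero_reads(self):
        assert estimate_coverage(CoverageParams(0, 35, 2_300_000)) == 0

    def test_invalid_genome_size(self):
        with pytest.raises(ValueError):
            CoverageParams(1, 35, 0)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(min_value=0, max_value=10**8),
        delta=st.integers(min_value=0, max_value=10**6),
        L=st.integers(min_value=1, max_value=100),
        S=st.integers(min_value=1, max_value=10**7),
        dS=st.integers(min_value=0, max_value=10**6),
    )
    def test_monotonicity(self, n, delta, L, S, dS):
        base = estimate_coverage(CoverageParams(n, L, S))
        assert estimate_coverage(CoverageParams(n + delta, L, S)) >= base
        assert estimate_coverage(CoverageParams(n, L, S + dS)) <= base


class TestCoverageTable:
    def test_mean_threshold_20_keeps_one(self):
        # two reads with means 19.16 and 23 (brute-forced)
        r1 = [23] * 13 + [15] * 12
        r2 = [23] * 25
        agg = accumulate(reads_from([r1, r2]), 25)
        table = coverage_table(agg, [20], 25, 1000)
        assert table[("mean", 20)][0] == 1
        assert table[("median", 20)][0] == 2

    def test_threshold_zero_keeps_all(self):
        agg = accumulate(reads_from([[1, 2, 3], [4, 5, 6], [7, 8, 9]]), 3)
        table = coverage_table(agg, [0], 3, 10)
        assert table[("mean", 0)][0] == 3
        assert table[("median", 0)][0] == 3

    def test_equals_refiltering_raw_reads(self, random_reads):
        reads = random_reads(500, 20)
        agg = accumulate(reads, 20)
        for t in (0, 15, 19.5, 20, 25, 41):
            table = coverage_table(agg, [t], 20, 5000)
            for stat in ("mean", "median"):
                cfg = FilterConfig(statistic=stat, threshold=t)
                brute = sum(1 for r in reads if cfg.keeps(r.qvs))
                assert table[(stat, t)][0] == brute
                assert table[(stat, t)][1] == estimate_coverage(
                    CoverageParams(brute, 20, 5000)
                )

    def test_empty_thresholds_raise(self):
        agg = accumulate(reads_from([[1, 2]]), 2)
        with pytest.raises(ValueError):
            coverage_table(agg, [], 2, 10)


class TestRetentionPercentage:
    def test_table_cell_cp162_mean(self):
        assert retention_percentage(11_349_208, 21_102_241) == 53.78

    def test_half(self):
        assert retention_percentage(5, 10) == 50.00

    def test_truncation_not_rounding(self):
        # 33,765,330 / 45,024,226 = 74.994% -> 74.99
        assert retention_percentage(33_765_330, 45_024_226) == 74.99

    def test_zero_raw_raises(self):
        with pytest.raises(ValueError):
            retention_percentage(0, 0)

    def test_kept_above_raw_raises(self):
        with pytest.raises(ValueError):
            retention_percentage(2, 1)


def test_truncate2():
    assert truncate2(Fraction(5646, 100) / 1) == 56.46
    assert truncate2(19.999) == 19.99
    assert truncate2(Fraction(479, 25)) == 19.16
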