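"""Method-comparison statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import vitecal as v


def make_sample(a, b, label="x"):
    a = np.asarray(a, dtype=float)
    return v.PairedSample(
        respondent_ids=tuple(f"r{i}" for i in range(len(a))),
        values_a=a,
        values_b=np.asarray(b, dtype=float),
        label=label,
    )


def sample_with_bias_sd(mean, sd, n=2):
    """Two-point sample whose differences have exactly the given mean and SD."""
    assert n == 2
    x = sd / np.sqrt(2.0)
    return make_sample([mean - x, mean + x], [0.0, 0.0])


class TestBlandAltman:
    def test_loa_construction_identity(self):
        rng = np.random.default_rng(3)
        d = rng.normal(1.0, 2.0, size=50)
        res = v.bland_altman(make_sample(d, np.zeros_like(d)))
        assert res.mean_diff == pytest.approx(np.mean(d))
        assert res.sd_diff == pytest.approx(np.std(d, ddof=1))
        assert res.lower_loa == pytest.approx(res.mean_diff - 1.96 * res.sd_diff)
        assert res.upper_loa == pytest.approx(res.mean_diff + 1.96 * res.sd_diff)

    def test_one_of_twenty_outside_gives_five_percent(self):
        # 19 tightly clustered differences and one extreme outlier
        d = np.concatenate([np.linspace(-1, 1, 19), [50.0]])
        res = v.bland_altman(make_sample(d, np.zeros_like(d)))
        assert res.n_outside == 1
        assert res.ba_index_pct == pytest.approx(5.0)
        assert res.good_agreement

    def test_outside_count_matches_scalar_recount(self, small_cohort):
        _, ffq_table, record = small_cohort
        for var in v.AGREEMENT_VARIABLES:
            sample = v.PairedSample.from_tables(ffq_table, record, var)
            res = v.bland_altman(sample)
            d = sample.values_a - sample.values_b
            recount = sum(1 for x in d if x < res.lower_loa or x > res.upper_loa)
            assert res.n_outside == recount
            assert res.ba_index_pct == pytest.approx(100 * recount / len(d))

    def test_boundary_points_count_as_inside(self):
        res0 = v.bland_altman(make_sample([0.0, 2.0, 1.0, 1.0], [0, 0, 0, 0]))
        d_edge = np.array([res0.lower_loa, res0.upper_loa])  # exactly on the limits
        # recompute with points landing on the old limits appended
        assert res0.n_outside == sum(
            1 for x in [0.0, 2.0, 1.0, 1.0] if x < res0.lower_loa or x > res0.upper_loa
        )
        assert np.all((d_edge >= res0.lower_loa) & (d_edge <= res0.upper_loa))

    def test_swap_reflects_bias_and_loa(self, small_cohort):
        _, ffq_table, record = small_cohort
        s = v.PairedSample.from_tables(ffq_table, record, "alpha_t")
        fwd = v.bland_altman(s)
        rev = v.bland_altman(make_sample(s.values_b, s.values_a))
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.lower_loa == pytest.approx(-fwd.upper_loa)
        assert rev.upper_loa == pytest.approx(-fwd.lower_loa)
        assert rev.ba_index_pct == pytest.approx(fwd.ba_index_pct)

    def test_reported_alpha_te_limits(self):
        # bias 1.57 with the implied SD reproduces the reported interval
        res = v.bland_altman(sample_with_bias_sd(1.57, (24.25 - 1.57) / 1.96))
        assert res.upper_loa == pytest.approx(24.25, abs=0.005)
        assert res.lower_loa == pytest.approx(-21.11, abs=0.005)

    def test_zero_variance_index_zero(self):
        res = v.bland_altman(make_sample([1.0, 1.0, 1.0], [0, 0, 0]))
        assert res.sd_diff == 0.0
        assert res.ba_index_pct == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(v.DomainError):
            make_sample([1.0], [0.0])

    def test_index_from_counts(self):
        assert v.ba_index_from_counts(447, n_within=420) == pytest.approx(100 * 27 / 447)
        assert v.ba_index_from_counts(20, n_outside=1) == pytest.approx(5.0)
        with pytest.raises(v.DomainError):
            v.ba_index_from_counts(10, n_within=4, n_outside=6)

    def test_normal_differences_index_near_five_percent(self):
        rng = np.random.default_rng(12345)
        d = rng.normal(0.0, 1.0, size=10_000)
        res = v.bland_altman(make_sample(d, np.zeros_like(d)))
        assert 4.0 <= res.ba_index_pct <= 6.0  # 2*Phi(-1.96) ~ 5%


class TestSpearman:
    def test_perfect_monotone(self):
        s = make_sample([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert v.spearman(s).rho == pytest.approx(1.0)
        s_rev = make_sample([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert v.spearman(s_rev).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0]
        b = [2.0, 1.0, 4.0, 4.0, 4.0, 7.0, 6.0, 9.0]
        ra, rb = stats.rankdata(a), stats.rankdata(b)  # midranks
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert v.spearman(make_sample(a, b)).rho == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_increasing_transform(self, small_cohort):
        _, ffq_table, record = small_cohort
        s = v.PairedSample.from_tables(ffq_table, record, "gamma_t")
        base = v.spearman(s).rho
        warped = make_sample(np.exp(s.values_a / 10.0), s.values_b ** 3)
        assert v.spearman(warped).rho == pytest.approx(base, rel=1e-12)

    def test_constant_series_flagged_undefined(self):
        res = v.spearman(make_sample([1, 1, 1, 1], [1, 2, 3, 4]))
        assert np.isnan(res.rho) and np.isnan(res.p_value)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(v.DomainError):
            v.spearman(make_sample([1, 2], [1, 2]))


class TestMannWhitney:
    @staticmethod
    def brute_force_u(a, b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )

    def test_identical_samples_half_product(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = v.mann_whitney(a, a)
        assert res.u_statistic == pytest.approx(len(a) * len(a) / 2)

    def test_complete_separation_extremes(self):
        assert v.mann_whitney([1, 2, 3], [10, 11, 12]).u_statistic == 0.0
        assert v.mann_whitney([10, 11, 12], [1, 2, 3]).u_statistic == 9.0

    def test_matches_exhaustive_pair_count_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            assert v.mann_whitney(a, b).u_statistic == pytest.approx(self.brute_force_u(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(v.DomainError):
            v.mann_whitney([], [1.0])


class TestNormalityGate:
    def test_uniform_data_routes_nonparametric(self):
        rng = np.random.default_rng(8)
        res = v.normality_gate(rng.uniform(0, 1, size=447))
        assert not res.normal  # strongly non-normal at this n

    def test_normal_data_passes(self):
        rng = np.random.default_rng(8)
        res = v.normality_gate(rng.normal(0, 1, size=100))
        assert res.normal

    def test_minimum_sample_size(self):
        with pytest.raises(v.DomainError):
            v.normality_gate([1.0, 2.0])


class TestPlotDataAndReport:
    def test_plot_data_shape_and_reference_lines(self):
        s = make_sample([1.0, 2.0, 4.0], [0.5, 2.5, 3.0])
        res = v.bland_altman(s)
        df = v.ba_plot_data(s, res)
        assert len(df) == 3
        assert df["mean"].tolist() == pytest.approx(((s.values_a + s.values_b) / 2).tolist())
        assert set(df["bias"]) == {res.mean_diff}
        assert set(df["lower_loa"]) == {res.lower_loa}
        assert set(df["upper_loa"]) == {res.upper_loa}

    def test_plot_data_round_trip(self, tmp_path):
        s = make_sample([1.0, 2.0, 4.0], [0.5, 2.5, 3.0])
        df = v.ba_plot_data(s, v.bland_altman(s))
        from vitecal.agreement import read_ba_plot_data, write_ba_plot_data

        path = write_ba_plot_data(df, tmp_path / "ba.csv")
        reloaded = read_ba_plot_data(path)
        assert reloaded["diff"].tolist() == pytest.approx(df["diff"].tolist())
        assert reloaded["respondent_id"].tolist() == df["respondent_id"].tolist()

    def test_agreement_report_covers_all_variables(self, small_cohort):
        _, ffq_table, record = small_cohort
        report = v.agreement_report(ffq_table, record)
        assert list(report["variable"]) == list(v.AGREEMENT_VARIABLES)
        for _, row in report.iterrows():
            assert row["n_within"] == f"{row['n'] - round(row['n'] * row['ba_index_pct'] / 100)} out of {row['n']}"
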