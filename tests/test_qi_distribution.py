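"""Lognormal fits, KS tests, empirical limits, detection and group tests."""
import numpy as np
import pandas as pd
import pytest

from snpqc.errors import InputError
from snpqc.qi_distribution import (
    QiReference,
    build_qi_reference,
    compare_groups,
    detect_poor_arrays,
    fit_lognormal,
    ks_lognormal,
)
from snpqc.quality_index import ArrayQiTable


def qi_table_from_values(values, array_label="Nsp", samples=None, scope="GENOME"):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = [f"s{i}" for i in range(len(values))]
    return ArrayQiTable(
        table=pd.DataFrame(
            {
                "sample_id": samples,
                "array_label": array_label,
                "scope": scope,
                "index_kind": "nearest_mean",
                "summary_kind": "winsorized_mean",
                "rho": 0.95,
                "qi_value": values,
                "n_snps_used": 1000,
            }
        )
    )


class TestFitLognormal:
    def test_meanlog_is_mean_of_logs(self):
        values = np.exp([1.0] * 9 + [3.0] * 3) * 1.0  # n = 12 >= 10
        fit = fit_lognormal(values)
        assert fit.meanlog == pytest.approx(np.log(values).mean())
        assert fit.n == 12

    def test_three_value_arithmetic(self):
        # {e^1, e^1, e^3} has mean of logs 5/3; padded copies keep it exact
        values = np.array([np.e, np.e, np.exp(3.0)] * 4)
        fit = fit_lognormal(values)
        assert fit.meanlog == pytest.approx(5 / 3)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(2024)
        x = rng.lognormal(mean=0.2, sigma=0.1, size=10_000)
        fit = fit_lognormal(x)
        assert fit.meanlog == pytest.approx(0.2, abs=0.004)  # 4 * 0.1/sqrt(n)
        assert fit.sdlog == pytest.approx(0.1, abs=0.003)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(InputError):
            fit_lognormal(np.array([1.0] * 9 + [0.0]))

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(InputError, match="degenerate"):
            fit_lognormal(np.full(20, 2.5))


class TestKsLognormal:
    @staticmethod
    def brute_force_ks(logs, meanlog, sdlog):
        from scipy.stats import norm

        x = np.sort(logs)
        n = len(x)
        cdf = norm.cdf(x, meanlog, sdlog)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        return max(d_plus, d_minus)

    def test_statistic_matches_cdf_difference_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = rng.integers(10, 60)
            x = rng.lognormal(0.1, 0.3, size=n)
            stat, _ = ks_lognormal(x, meanlog=0.1, sdlog=0.3)
            expected = self.brute_force_ks(np.log(x), 0.1, 0.3)
            assert stat == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_model_quantile_construction_has_tiny_statistic(self):
        from scipy.stats import norm

        n = 99
        probs = np.arange(1, n + 1) / (n + 1)
        x = np.exp(norm.ppf(probs, 0.0, 1.0))
        stat, _ = ks_lognormal(x, meanlog=0.0, sdlog=1.0)
        assert stat <= 1 / (n + 1) + 1e-12

    def test_rejection_rate_conservative_with_estimated_parameters(self):
        rng = np.random.default_rng(555)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.lognormal(0.2, 0.15, size=100)
            fit = fit_lognormal(x)
            if fit.ks_pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.05


class TestQiReferenceLimits:
    def test_empirical_quantile_matches_sort_oracle(self):
        values = np.arange(1.0, 101.0)
        table = qi_table_from_values(values)
        ref = build_qi_reference(table, levels=(0.95,), source="empirical")
        # type-7 on 1..100 at p=0.95: h = 99*0.95 = 94.05 -> 95 + 0.05*1
        assert ref.table["limit"].iloc[0] == pytest.approx(95.05)

    def test_lognormal_limit_closed_form(self):
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(0.0, 1.0, size=400))
        table = qi_table_from_values(x)
        ref = build_qi_reference(table, levels=(0.975,), source="lognormal")
        fit = fit_lognormal(x)
        expected = np.exp(fit.meanlog + 1.959963985 * fit.sdlog)
        assert ref.table["limit"].iloc[0] == pytest.approx(expected, rel=1e-9)
        # with meanlog ~ 0, sdlog ~ 1 this sits near exp(1.96) ~ 7.1
        assert 5.0 < ref.table["limit"].iloc[0] < 10.0

    def test_limits_nondecreasing_in_level(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0.0, 0.4, size=200)
        ref = build_qi_reference(qi_table_from_values(x))
        limits = ref.table.sort_values("level")["limit"].to_numpy()
        assert (np.diff(limits) >= 0).all()

    def test_small_stratum_skipped_for_empirical_source(self):
        table = qi_table_from_values(np.linspace(1, 2, 5))
        with pytest.raises(InputError):
            build_qi_reference(table, source="empirical")

    def test_empirical_and_lognormal_limits_agree_on_large_lognormal_sample(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(0.2, 0.1, size=5000)
        table = qi_table_from_values(x)
        emp = build_qi_reference(table, source="empirical")
        logn = build_qi_reference(table, source="lognormal")
        rel = np.abs(
            emp.table.sort_values("level")["limit"].to_numpy()
            / logn.table.sort_values("level")["limit"].to_numpy()
            - 1
        )
        assert (rel < 0.05).all()


def reference_population_limits():
    """Published upper confidence limits for a Han Chinese reference cohort
    on the Nsp/Sty 500K platform (synthetic packaging of printed constants
    for fixture use; mu/sigma placeholders are not used by detection)."""
    rows = []
    limits = {
        "Nsp": (1.144, 1.246, 1.385),
        "Sty": (1.133, 1.233, 1.367),
        "Merge": (1.056, 1.129, 1.224),
    }
    for label, (l95, l975, l99) in limits.items():
        for level, limit in zip((0.95, 0.975, 0.99), (l95, l975, l99)):
            rows.append(
                {
                    "population_label": "TWN",
                    "array_label": label,
                    "scope": "GENOME",
                    "index_kind": "nearest_mean",
                    "summary_kind": "winsorized_mean",
                    "rho": 0.95,
                    "level": level,
                    "limit": limit,
                    "mu_qi": 0.8,
                    "sigma_qi": 0.1,
                    "source": "empirical",
                }
            )
    return QiReference(table=pd.DataFrame(rows))


class TestDetection:
    def _qi_table(self, nsp, sty, merge, sample="sample"):
        frames = []
        for label, value in (("Nsp", nsp), ("Sty", sty), ("Merge", merge)):
            frames.append(qi_table_from_values([value], array_label=label, samples=[sample]))
        return ArrayQiTable(table=pd.concat([f.table for f in frames], ignore_index=True))

    def test_flags_a_poor_array(self):
        ref = reference_population_limits()
        report = detect_poor_arrays(self._qi_table(1.521, 1.001, 1.259), ref, level=0.95)
        by_label = report.set_index("array_label")["flag"]
        assert bool(by_label["Nsp"]) is True  # 1.521 > 1.144
        assert bool(by_label["Sty"]) is False  # 1.001 < 1.133
        assert bool(by_label["Merge"]) is True

    def test_good_array_not_flagged(self):
        ref = reference_population_limits()
        report = detect_poor_arrays(self._qi_table(0.733, 0.776, 0.753), ref, level=0.95)
        assert not report["flag"].any()

    def test_boundary_equality_is_not_flagged(self):
        ref = reference_population_limits()
        report = detect_poor_arrays(self._qi_table(1.144, 1.133, 1.056), ref, level=0.95)
        assert not report["flag"].any()

    def test_missing_stratum_error_names_it(self):
        ref = reference_population_limits()
        table = qi_table_from_values([1.0], array_label="Xba", samples=["s"])
        with pytest.raises(InputError, match="Xba"):
            detect_poor_arrays(table, ref, level=0.95)

    def test_false_flag_rate_matches_level_under_the_null(self):
        rng = np.random.default_rng(123)
        reference = rng.lognormal(0.0, 0.2, size=4000)
        ref = build_qi_reference(qi_table_from_values(reference), levels=(0.95,))
        test_values = rng.lognormal(0.0, 0.2, size=4000)
        report = detect_poor_arrays(qi_table_from_values(test_values), ref, level=0.95)
        rate = report["flag"].mean()
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(rate - 0.05) < 5 * se


class TestCompareGroups:
    def test_identical_groups_give_unit_pvalues(self):
        x = np.exp(np.linspace(-0.5, 0.5, 30))
        result = compare_groups(x, x.copy())
        assert result.p_mean == pytest.approx(1.0)
        assert result.p_ks == pytest.approx(1.0)

    def test_separated_means_detected(self):
        rng = np.random.default_rng(31)
        a = np.exp(rng.normal(0.0, 0.1, size=50))
        b = np.exp(rng.normal(1.0, 0.1, size=50))
        result = compare_groups(a, b)
        assert result.p_mean < 1e-6

    def test_type_one_error_close_to_nominal(self):
        rng = np.random.default_rng(99)
        n_rep = 1000
        rejections = np.zeros(3)
        for _ in range(n_rep):
            a = np.exp(rng.normal(0.0, 0.3, size=50))
            b = np.exp(rng.normal(0.0, 0.3, size=50))
            res = compare_groups(a, b)
            rejections += [res.p_mean < 0.05, res.p_var < 0.05, res.p_ks < 0.05]
        rates = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        # Z and F tests track alpha; two-sample KS is discrete/conservative
        assert abs(rates[0] - 0.05) < 5 * se
        assert abs(rates[1] - 0.05) < 5 * se
        assert rates[2] < 0.05 + 5 * se
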