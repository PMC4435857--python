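"""ICC(2,1), SEMs, Romberg quotients and table assembly."""

import numpy as np
import pandas as pd
import pytest

from stabilometry.reliability import (
    ReliabilityError,
    anova_mean_squares,
    icc_2_1,
    reliability_table,
    romberg_quotient,
    romberg_table,
    se_of_mean,
    sem_measurement,
)


def brute_force_icc_2_1(y):
    """ICC(2,1) from first-principles sums of squares (independent oracle)."""
    y = np.asarray(y, float)
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc21:
    def test_perfect_agreement(self):
        s1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, lo, hi = icc_2_1(np.column_stack([s1, s1]))
        assert icc == pytest.approx(1.0)
        assert hi == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            y = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
            icc, _, _ = icc_2_1(y)
            assert icc == pytest.approx(brute_force_icc_2_1(y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            y = rng.normal(size=(10, 2)) + 2 * rng.normal(size=(10, 1))
            icc, lo, hi = icc_2_1(y)
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(10), 2),
                    "rater": np.tile([1, 2], 10),
                    "y": y.ravel(),
                }
            )
            res = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            row = res[res["Type"] == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin rounds its CI to 2 decimals
            assert lo == pytest.approx(row["CI95"][0], abs=0.01)
            assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_variance_components_simulation(self):
        # y_ij = u_i + e_ij with var ratio 0.8: estimator mean and CI coverage
        rng = np.random.default_rng(99)
        target = 0.8
        su, se = np.sqrt(target), np.sqrt(1 - target)
        ests, covered = [], 0
        for _ in range(500):
            y = rng.normal(0, su, (30, 1)) + rng.normal(0, se, (30, 2))
            icc, lo, hi = icc_2_1(y)
            ests.append(icc)
            covered += lo <= target <= hi
        assert np.mean(ests) == pytest.approx(target, abs=0.05)
        assert 0.92 <= covered / 500 <= 0.98

    def test_ci_coverage_grid(self):
        # nominal 95% CI at the two cohort sizes and a range of true ICCs
        for target in (0.5, 0.8, 0.95):
            for n in (15, 26):
                rng = np.random.default_rng(1000 + n)
                su, se = np.sqrt(target), np.sqrt(1 - target)
                covered = sum(
                    (lambda r: r[1] <= target <= r[2])(
                        icc_2_1(rng.normal(0, su, (n, 1)) + rng.normal(0, se, (n, 2)))
                    )
                    for _ in range(1000)
                )
                assert 0.93 <= covered / 1000 <= 0.97, (target, n)

    def test_affine_invariance(self, rng):
        y = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        icc0, _, _ = icc_2_1(y)
        icc1, _, _ = icc_2_1(3.7 * y - 11.0)
        assert icc1 == pytest.approx(icc0, abs=1e-12)

    def test_between_subject_spread_raises_icc(self):
        # raising sigma_u at fixed sigma_e never decreases the estimate
        rng = np.random.default_rng(5)
        u = rng.normal(size=(40, 1))
        e = rng.normal(size=(40, 2))
        iccs = [icc_2_1(su * u + e)[0] for su in (0.5, 1.0, 2.0, 4.0)]
        assert iccs == sorted(iccs)

    def test_ci_bounds_always_finite_and_ordered(self, rng):
        # small noisy cohorts can give strongly negative ICC estimates,
        # where the F-based interval degenerates; bounds must stay finite
        for _ in range(2000):
            n = int(rng.integers(3, 8))
            icc, lo, hi = icc_2_1(rng.normal(size=(n, 2)))
            assert np.isfinite(lo) and np.isfinite(hi)
            assert lo <= icc <= hi <= 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ReliabilityError):
            icc_2_1(np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ReliabilityError):
            icc_2_1(np.ones((5, 2)))

    def test_anova_decomposition_additivity(self, rng):
        y = rng.normal(size=(7, 2))
        msr, msc, mse = anova_mean_squares(y)
        n, k = y.shape
        ss = (n - 1) * msr + (k - 1) * msc + (n - 1) * (k - 1) * mse
        assert ss == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-12)


class TestSems:
    def test_sem_measurement_endpoints(self):
        assert sem_measurement(10.0, 1.0) == 0.0
        assert sem_measurement(10.0, 0.0) == 10.0
        assert sem_measurement(10.0, 0.75) == pytest.approx(5.0)

    def test_sem_measurement_negative_icc_allowed(self):
        assert sem_measurement(1.0, -0.5) == pytest.approx(np.sqrt(1.5))

    @pytest.mark.parametrize(
        "sd,n,printed",
        [(0.1, 26, 0.02), (17.55, 15, 4.53), (0.0, 10, 0.0)],
    )
    def test_se_of_mean_reproduces_printed_values(self, sd, n, printed):
        assert round(se_of_mean(sd, n), 2) == printed


class TestRombergQuotient:
    def test_equal_conditions_unit_ratio(self):
        res = romberg_quotient([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert res.mean_rq == 1.0
        assert res.sd_rq == 0.0

    def test_two_subject_arithmetic(self):
        res = romberg_quotient([100.0, 50.0], [150.0, 100.0])
        assert res.mean_rq == pytest.approx(1.75)
        assert res.sd_rq == pytest.approx(np.sqrt(2) / 4, abs=1e-10)

    def test_zero_eo_names_subject(self):
        with pytest.raises(ReliabilityError, match="B"):
            romberg_quotient([1.0, 0.0], [1.0, 1.0], subject_ids=["A", "B"])

    def test_noisy_cohort_recovers_true_ratio(self, rng):
        n, true_ratio = 200, 1.5
        eo = rng.uniform(50, 150, n)
        ec = eo * true_ratio * (1 + rng.normal(0, 0.1, n))
        res = romberg_quotient(eo, ec)
        se = res.sd_rq / np.sqrt(n)
        assert abs(res.mean_rq - true_ratio) < 3 * se


def simulated_metrics(n_subjects, icc_target, rng, conditions=("FO", "FC")):
    """Long metrics table whose log-variable has a designed true ICC."""
    su = np.sqrt(icc_target)
    se = np.sqrt(1 - icc_target)
    rows = []
    for j in range(n_subjects):
        u = rng.normal(0, su)
        for session in (1, 2):
            v = rng.normal(0, se)
            for cond in conditions:
                rows.append(
                    {
                        "subject_id": f"S{j:03d}",
                        "group": "young",
                        "condition": cond,
                        "session": session,
                        "score": np.exp(u + v),
                    }
                )
    return pd.DataFrame(rows)


class TestReliabilityTable:
    def test_designed_icc_recovered(self):
        rng = np.random.default_rng(31)
        metrics = simulated_metrics(50, 0.9, rng)
        metrics["log_score"] = np.log(metrics["score"])
        table = reliability_table(metrics, variables=["log_score"])
        for _, row in table.iterrows():
            assert row["icc"] == pytest.approx(0.9, abs=0.1)

    def test_two_subjects_rejected(self):
        rng = np.random.default_rng(1)
        metrics = simulated_metrics(2, 0.8, rng)
        with pytest.raises(ReliabilityError):
            reliability_table(metrics, variables=["score"])

    def test_duplicated_sessions_give_unit_icc(self):
        rng = np.random.default_rng(2)
        metrics = simulated_metrics(10, 0.5, rng)
        s1 = metrics[metrics["session"] == 1]
        s2 = s1.assign(session=2)
        table = reliability_table(pd.concat([s1, s2]), variables=["score"])
        np.testing.assert_allclose(table["icc"].to_numpy(), 1.0, atol=1e-12)

    def test_incomplete_pairs_excluded_and_reported(self):
        rng = np.random.default_rng(3)
        metrics = simulated_metrics(8, 0.8, rng)
        drop = (metrics["subject_id"] == "S000") & (
            metrics["condition"] == "FC"
        ) & (metrics["session"] == 2)
        table = reliability_table(metrics[~drop], variables=["score"])
        assert ("S000", "FC") in table.attrs["excluded"]
        n_by_cond = table.set_index("condition")["n"]
        assert n_by_cond["FC"] == 7
        assert n_by_cond["FO"] == 8

    def test_row_identities(self):
        rng = np.random.default_rng(4)
        metrics = simulated_metrics(12, 0.7, rng)
        table = reliability_table(metrics, variables=["score"])
        for _, row in table.iterrows():
            assert row["ci_low"] <= row["icc"] <= row["ci_high"]
            assert row["se1"] == pytest.approx(row["sd1"] / np.sqrt(row["n"]), abs=1e-12)
            assert row["se2"] == pytest.approx(row["sd2"] / np.sqrt(row["n"]), abs=1e-12)
            pooled = np.sqrt((row["sd1"] ** 2 + row["sd2"] ** 2) / 2)
            assert row["sem_measurement"] == pytest.approx(
                pooled * np.sqrt(1 - row["icc"])
            )


class TestRombergTable:
    def test_firm_surface_pairing(self):
        rng = np.random.default_rng(6)
        rows = []
        for j in range(10):
            eo = rng.uniform(50, 150)
            for cond, score in (("FO", eo), ("FC", 1.5 * eo)):
                rows.append(
                    {
                        "subject_id": f"S{j}",
                        "group": "young",
                        "condition": cond,
                        "session": 1,
                        "score": score,
                    }
                )
        table = romberg_table(pd.DataFrame(rows), variables=("score",), pair=("FO", "FC"))
        row = table.iloc[0]
        assert row["mean_rq"] == pytest.approx(1.5)
        assert row["sd_rq"] == pytest.approx(0.0, abs=1e-12)
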