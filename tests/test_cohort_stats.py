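import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fetquant import (
    ContingencyTable,
    PatientRecord,
    chi_square,
    cohens_kappa,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    read_records,
    summarize,
    write_records,
)
from fetquant.cohort_stats import format_count_pct


def table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts,
        tuple(f"r{i}" for i in range(counts.shape[0])),
        tuple(f"c{j}" for j in range(counts.shape[1])),
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def fisher_p_enumeration(t):
    """Two-sided Fisher p by brute-force enumeration at fixed margins."""
    a, b = t[0]
    c, d = t[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mwu_p_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    m = nx * (len(y))
    u_values = []
    for combo in itertools.combinations(range(n), nx):
        r = ranks[list(combo)].sum()
        u_values.append(r - nx * (nx + 1) / 2)
    u_values = np.asarray(u_values)
    r_obs = ranks[:nx].sum()
    u_obs = r_obs - nx * (nx + 1) / 2
    u_low = min(u_obs, m - u_obs)
    return np.mean((u_values <= u_low + 1e-9) | (u_values >= m - u_low - 1e-9))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


class TestChiSquare:
    def test_homogeneous_table_gives_zero(self):
        res = chi_square(table([[10, 10], [10, 10]]))
        assert res.statistic_value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_closed_form_2x2_identity(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, 4)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            res = chi_square(table([[a, b], [c, d]]))
            assert res.statistic_value == pytest.approx(closed, rel=1e-12)

    def test_invariant_to_row_and_column_permutation(self):
        t = np.array([[12, 5, 3], [7, 9, 11]])
        base = chi_square(table(t)).statistic_value
        assert chi_square(table(t[::-1])).statistic_value == pytest.approx(base)
        assert chi_square(table(t[:, ::-1])).statistic_value == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square(table([[0, 0], [5, 5]]))

    def test_low_expected_count_flagged(self):
        res = chi_square(table([[1, 9], [2, 8]]))
        assert res.extra["low_expected"] is True


class TestFisherExact:
    def test_perfect_separation_5x5(self):
        res = fisher_exact(table([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / 252)

    def test_uniform_table_gives_one(self):
        assert fisher_exact(table([[1, 1], [1, 1]])).p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(40):
            t = rng.integers(0, 8, (2, 2))
            if t.sum() == 0 or np.any(t.sum(0) == 0) or np.any(t.sum(1) == 0):
                continue
            res = fisher_exact(table(t))
            assert res.p_value == pytest.approx(fisher_p_enumeration(t), rel=1e-9)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact(table([[1, 2, 3], [4, 5, 6]]))


class TestMannWhitneyU:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert res.statistic_value == 0.0

    def test_identical_multisets_give_half_product(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic_value == pytest.approx(8.0)  # 4*4/2

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            nx = int(rng.integers(3, 7))
            ny = int(rng.integers(3, 13 - nx))
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            res = mann_whitney_u(x, y)
            assert res.extra["method"] == "exact"
            assert res.p_value == pytest.approx(mwu_p_enumeration(x, y), rel=1e-9)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.3, 1, 25)
        res = mann_whitney_u(x, y)
        assert res.extra["method"] == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1, 2])


class TestKruskalWallis:
    def test_identical_constant_groups_give_zero(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_two_group_h_equals_mwu_z_squared(self, rng):
        # algebraic identity: for 2 groups (no ties), H = z^2 of the U statistic
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 10)
        h = kruskal_wallis([x, y]).statistic_value
        nx, ny = len(x), len(y)
        u = mann_whitney_u(x, y).extra["u_x"]
        mu, sigma = nx * ny / 2, np.sqrt(nx * ny * (nx + ny + 1) / 12)
        z = (u - mu) / sigma
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_null_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestCohensKappa:
    def test_perfect_agreement(self):
        res = cohens_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"])
        assert res.statistic_value == pytest.approx(1.0)

    def test_kappa_arithmetic(self):
        # observed agreement 0.9, expected 0.5 -> kappa 0.8
        a = ["x"] * 50 + ["y"] * 50
        b = a.copy()
        for i in list(range(0, 10)):
            b[i] = "y" if a[i] == "x" else "x"
        res = cohens_kappa(a, b)
        assert res.extra["observed_agreement"] == pytest.approx(0.9)
        assert res.extra["expected_agreement"] == pytest.approx(0.5)
        assert res.statistic_value == pytest.approx(0.8)

    def test_independent_raters_give_near_zero_kappa(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["p", "q", "r"], 10_000)
        b = rng.choice(["p", "q", "r"], 10_000)
        res = cohens_kappa(a, b)
        assert abs(res.statistic_value) <= 0.03

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            a = rng.choice(["p", "q", "r"], 60)
            b = np.where(rng.uniform(size=60) < 0.6, a, rng.choice(["p", "q", "r"], 60))
            ours = cohens_kappa(a, b).statistic_value
            assert ours == pytest.approx(cohen_kappa_score(a, b), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohens_kappa(["a"], ["a", "b"])


class TestRecordsAndSummaries:
    def _records(self):
        return [
            PatientRecord("p1", "astrocytoma", 2, False, True, tbr_max=1.0),
            PatientRecord("p2", "astrocytoma", 2, False, True, tbr_max=2.0),
            PatientRecord("p3", "astrocytoma", 2, True, False, tbr_max=3.0),
            PatientRecord("p4", "oligodendroglioma", 3, True, True, tbr_max=2.5,
                          curve_class="increasing", ttp_min=35.0),
        ]

    def test_median_range_summary(self):
        out = summarize(self._records(), "tbr_max", strata=("histology",))
        row = out[out.histology == "astrocytoma"].iloc[0]
        assert row["median"] == 2.0
        assert row["summary"] == "2.00 (1.00–3.00)"

    def test_count_percent_formatting(self):
        assert format_count_pct(62, 68) == "62 (91.2%)"

    def test_grade4_requires_astrocytoma(self):
        with pytest.raises(ValueError, match="grade 4"):
            PatientRecord("x", "oligodendroglioma", 4, False, False)

    def test_tbr_below_one_rejected(self):
        with pytest.raises(ValueError, match="tbr_max"):
            PatientRecord("x", "astrocytoma", 2, False, False, tbr_max=0.8)

    def test_csv_round_trip(self, tmp_path):
        recs = self._records()
        path = tmp_path / "cohort.csv"
        write_records(recs, path)
        back = read_records(path)
        assert back == recs

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            summarize(self._records(), "nope")
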