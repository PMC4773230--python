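import numpy as np
import pandas as pd
import pytest

from fibroscore.stats import (
    CollinearityError,
    bland_altman,
    compare_groups,
    describe,
    fit_multivariate,
    icc_absolute_agreement,
    pearson,
)


def _frame(**cols):
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _percentile_oracle(values, q):
    """Sort-based percentile with linear interpolation."""
    v = sorted(values)
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def _pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def _ols_oracle(X, y):
    """Normal equations with explicit matrix solve; returns beta, se, r2adj."""
    n, k = X.shape
    D = np.column_stack([np.ones(n), X])
    XtX = D.T @ D
    beta = np.linalg.solve(XtX, D.T @ y)
    resid = y - D @ beta
    df = n - k - 1
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df
    return beta, se, r2_adj


def _icc_oracle(x):
    """Two-way ANOVA table built from explicit sums of squares."""
    n, k = x.shape
    grand = x.mean()
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestDescribe:
    def test_simple_values(self):
        d = describe(_frame(v=[1, 2, 3, 4, 5]), "v")
        assert d["mean"] == pytest.approx(3)
        assert d["median"] == pytest.approx(3)

    def test_constant_vector_sd_zero(self):
        assert describe(_frame(v=[7.0] * 5), "v")["sd"] == 0

    def test_sample_sd_uses_n_minus_1(self):
        d = describe(_frame(v=[1.0, 3.0]), "v")
        assert d["sd"] == pytest.approx(np.sqrt(2.0))

    def test_iqr_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(size=rng.integers(5, 40)).tolist()
            d = describe(_frame(v=v), "v")
            assert d["iqr_low"] == pytest.approx(_percentile_oracle(v, 25), abs=1e-12)
            assert d["iqr_high"] == pytest.approx(_percentile_oracle(v, 75), abs=1e-12)
            assert d["median"] == pytest.approx(_percentile_oracle(v, 50), abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            describe(_frame(v=[1.0]), "v")


class TestCompareGroups:
    def test_identical_groups_t0_p1(self):
        frame = _frame(v=[1, 2, 3, 1, 2, 3], g=["a"] * 3 + ["b"] * 3)
        out = compare_groups(frame, "v", group="g")
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_identical_proportions_chi2_zero(self):
        frame = _frame(v=["y", "n"] * 4, g=["a"] * 4 + ["b"] * 4)
        out = compare_groups(frame, "v", group="g")
        assert out["kind"] == "chi2"
        assert out["statistic"] == pytest.approx(0.0)

    def test_chi2_matches_hand_formula(self):
        # constructed 2x2 table: group a 30 pos / 20 neg, group b 10 pos / 40 neg
        rows = [("a", "pos")] * 30 + [("a", "neg")] * 20 + [("b", "pos")] * 10 + [("b", "neg")] * 40
        frame = pd.DataFrame(rows, columns=["g", "v"])
        out = compare_groups(frame, "v", group="g")
        observed = np.array([[20.0, 30.0], [40.0, 10.0]])  # rows a,b; cols neg,pos
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert out["statistic"] == pytest.approx(chi2, abs=1e-10)

    def test_zero_variance_both_groups_rejected(self):
        frame = _frame(v=[1.0, 1.0, 2.0, 2.0], g=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="zero variance"):
            compare_groups(frame, "v", group="g")


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson(_frame(x=x, y=2 * x + 1), "x", "y").r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(_frame(x=x, y=-x), "x", "y").r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = pearson(_frame(x=x, y=y), "x", "y")
            assert res.r == pytest.approx(_pearson_oracle(x, y), abs=1e-12)
            assert res.n == n

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = pearson(_frame(x=x, y=y), "x", "y").r
        r2 = pearson(_frame(x=5 * x - 2, y=0.1 * y + 7), "x", "y").r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(_frame(x=[1.0, 1.0, 1.0], y=[1.0, 2.0, 3.0]), "x", "y")


class TestRegression:
    def test_noiseless_recovery_exact(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        y = 3.0 + 2.0 * x1 - x2
        res = fit_multivariate(_frame(y=y, x1=x1, x2=x2), "y", ["x1", "x2"])
        assert res.table.loc["x1", "coefficient"] == pytest.approx(2.0, abs=1e-10)
        assert res.table.loc["x2", "coefficient"] == pytest.approx(-1.0, abs=1e-10)
        assert res.intercept == pytest.approx(3.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_covariate_partial_equals_pearson(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        res = fit_multivariate(_frame(y=y, x=x), "y", ["x"])
        r = pearson(_frame(y=y, x=x), "x", "y").r
        assert res.table.loc["x", "r_partial"] == pytest.approx(r, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(15, 60))
            k = int(rng.integers(1, 5))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n) + X @ rng.normal(size=k)
            cols = {f"x{j}": X[:, j] for j in range(k)}
            res = fit_multivariate(_frame(y=y, **cols), "y", list(cols))
            beta, se, r2_adj = _ols_oracle(X, y)
            assert res.intercept == pytest.approx(beta[0], abs=1e-10)
            np.testing.assert_allclose(res.table["coefficient"], beta[1:], atol=1e-10)
            np.testing.assert_allclose(res.table["std_error"], se[1:], atol=1e-10)
            assert res.r2_adjusted == pytest.approx(r2_adj, abs=1e-10)

    def test_partial_r_sign_matches_t(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -1.0, 0.2]) + rng.normal(size=60)
        res = fit_multivariate(_frame(y=y, a=X[:, 0], b=X[:, 1], c=X[:, 2]), "y", ["a", "b", "c"])
        assert (np.sign(res.table["r_partial"]) == np.sign(res.table["t"])).all()

    def test_collinearity_error_names_columns(self):
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=30)
        frame = _frame(y=rng.normal(size=30), borg=x1, vas=10.0 * x1)
        with pytest.raises(CollinearityError) as exc:
            fit_multivariate(frame, "y", ["borg", "vas"])
        assert any(c in ("borg", "vas") for c in exc.value.columns)

    def test_affine_rescaling_leaves_r_partial_unchanged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 2))
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=50)
        frame1 = _frame(y=y, a=X[:, 0], b=X[:, 1])
        frame2 = _frame(y=y, a=3.0 * X[:, 0] - 1.0, b=X[:, 1] / 7.0 + 2.0)
        r1 = fit_multivariate(frame1, "y", ["a", "b"]).table["r_partial"]
        r2 = fit_multivariate(frame2, "y", ["a", "b"]).table["r_partial"]
        np.testing.assert_allclose(r1, r2, atol=1e-10)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_absolute_agreement(x).icc == pytest.approx(1.0)

    def test_identical_raters_any_subject_variance(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            col = rng.normal(scale=rng.uniform(0.1, 50), size=12)
            x = np.column_stack([col, col, col])
            assert icc_absolute_agreement(x).icc == pytest.approx(1.0)

    def test_huge_independent_noise_drives_icc_to_zero(self):
        rng = np.random.default_rng(12)
        subj = rng.normal(size=500)
        x = np.column_stack([subj, subj + rng.normal(scale=50, size=500)])
        assert abs(icc_absolute_agreement(x).icc) < 0.1

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc_absolute_agreement(x).icc == pytest.approx(_icc_oracle(x), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.set_index("Type").loc["ICC(A,1)", "ICC"])  # absolute agreement, single
        assert icc_absolute_agreement(x).icc == pytest.approx(icc2, abs=1e-9)

    def test_constant_grid_rejected(self):
        with pytest.raises(ValueError, match="no between-subject variance"):
            icc_absolute_agreement(np.full((5, 3), 2.0))


class TestBlandAltman:
    def test_identical_pairs_loa_zero(self):
        a = np.arange(10.0)
        out = bland_altman(a, a)
        assert out.mean_diff == 0
        assert out.loa_low == 0
        assert out.loa_high == 0

    def test_constant_difference(self):
        a = np.arange(10.0)
        out = bland_altman(a + 3.0, a)
        assert out.loa_low == pytest.approx(3.0)
        assert out.loa_high == pytest.approx(3.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            out = bland_altman(a, b)
            d = a - b
            sd = np.sqrt(np.sum((d - d.mean()) ** 2) / (n - 1))
            assert out.mean_diff == pytest.approx(d.mean(), abs=1e-12)
            assert out.loa_low == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
            assert out.loa_high == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)

    def test_pairs_array_form(self):
        pairs = np.array([[1.0, 0.5], [2.0, 1.5], [3.0, 2.5]])
        assert bland_altman(pairs).mean_diff == pytest.approx(0.5)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
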