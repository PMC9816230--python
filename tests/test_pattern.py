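"""Correlation screen, sampling adequacy, PCA/varimax and expression scores."""

import numpy as np
import pandas as pd
import pytest

from tauperf.pattern import (
    PatternModel, bartlett_sphericity, combine_scores, component_scores,
    correlation_filter, fit_pattern_model, kmo_measure, score_subjects,
    varimax,
)


def exact_corr_pair(n, r):
    """Two mean-zero columns with sample correlation exactly r."""
    e1 = np.zeros(n)
    e1[: n // 2] = 1.0
    e1[n // 2:] = -1.0
    e2 = np.zeros(n)
    e2[0::2] = 1.0
    e2[1::2] = -1.0
    e1 -= e1.mean()
    e2 -= e2.mean()
    e2 -= e1 * (e1 @ e2) / (e1 @ e1)  # orthogonalize
    e1 /= np.linalg.norm(e1)
    e2 /= np.linalg.norm(e2)
    x = e1
    y = r * e1 + np.sqrt(1 - r ** 2) * e2
    return np.column_stack([x, y])


def partial_corr_residual_oracle(X, i, j):
    """Partial correlation of columns i, j given all others, by explicit
    regression residuals (independent of the inverse-matrix route)."""
    others = [k for k in range(X.shape[1]) if k not in (i, j)]
    design = np.column_stack([np.ones(len(X))] + [X[:, k] for k in others])

    def resid(v):
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ri, rj = resid(X[:, i]), resid(X[:, j])
    return (ri @ rj) / np.sqrt((ri @ ri) * (rj @ rj))


def kmo_residual_oracle(X):
    r = np.corrcoef(X, rowvar=False)
    p = r.shape[0]
    r2 = q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += r[i, j] ** 2
            q2 += partial_corr_residual_oracle(X, i, j) ** 2
    return r2 / (r2 + q2)


class TestCorrelationFilter:
    def test_noise_region_discarded(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        X = pd.DataFrame({
            "a": base, "b": base + rng.normal(0, 0.1, 200),
            "noise": rng.normal(size=200),
        })
        assert correlation_filter(X) == ["a", "b"]

    def test_all_mutually_correlated_all_retained(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=300)
        X = pd.DataFrame({f"r{i}": f + rng.normal(0, 0.3, 300) for i in range(4)})
        assert correlation_filter(X) == list(X.columns)

    def test_matches_bruteforce_rule_on_handset_correlations(self):
        """Five regions with correlations straddling 0.3: retained set equals
        literal max-|r| enumeration."""
        rng = np.random.default_rng(2)
        cov = np.eye(5)
        cov[0, 1] = cov[1, 0] = 0.6
        cov[2, 3] = cov[3, 2] = 0.25
        cov[0, 4] = cov[4, 0] = 0.32
        X = pd.DataFrame(
            rng.multivariate_normal(np.zeros(5), cov, size=400),
            columns=list("abcde"),
        )
        result = correlation_filter(X)
        r = np.corrcoef(X.to_numpy(), rowvar=False)
        expected = []
        for i, lab in enumerate(X.columns):
            best = max(abs(r[i, j]) for j in range(5) if j != i)
            if best >= 0.3:
                expected.append(lab)
        assert result == expected

    def test_zero_variance_region_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=100)
        X = pd.DataFrame({"a": base, "b": base * 2, "flat": np.ones(100)})
        with pytest.warns(UserWarning, match="flat"):
            retained = correlation_filter(X)
        assert retained == ["a", "b"]

    def test_mean_abs_rule_differs_when_configured(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=500)
        # "a" correlates strongly with one partner but weakly on average
        X = pd.DataFrame({
            "a": f + rng.normal(0, 0.5, 500),
            "b": f + rng.normal(0, 0.5, 500),
            "n1": rng.normal(size=500), "n2": rng.normal(size=500),
            "n3": rng.normal(size=500),
        })
        assert "a" in correlation_filter(X, rule="max_abs")
        assert "a" not in correlation_filter(X, rule="mean_abs")


class TestSamplingAdequacy:
    def test_two_variable_kmo_is_half(self):
        for r in (0.2, 0.5, -0.8):
            X = exact_corr_pair(40, r)
            assert kmo_measure(X) == pytest.approx(0.5, abs=1e-12)

    def test_kmo_matches_residual_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = rng.integers(4, 9)
            n = 60
            f = rng.normal(size=(n, 2))
            load = rng.uniform(-0.8, 0.8, (2, p))
            X = f @ load + rng.normal(0, 0.6, (n, p))
            assert kmo_measure(X) == pytest.approx(kmo_residual_oracle(X), abs=1e-8)

    def test_near_identity_kmo_small(self):
        """Uncorrelated variables: sampling noise makes anti-image partial
        correlations dominate the raw ones, pushing KMO well below 0.5."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 30))
        assert kmo_measure(X) < 0.45

    def test_singular_correlation_matrix_errors(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x, rng.normal(size=50)])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            kmo_measure(X)

    def test_bartlett_direct_formula(self):
        """p = 2, sample r exactly 0.6, n = 50: chi2 = -(49 - 9/6) ln(0.64)."""
        X = exact_corr_pair(50, 0.6)
        res = bartlett_sphericity(X)
        assert res["chi2"] == pytest.approx(-(49 - 9 / 6) * np.log(1 - 0.36), abs=1e-9)
        assert res["df"] == 1

    def test_bartlett_identity_correlation_chi2_zero(self):
        X = exact_corr_pair(30, 0.0)
        res = bartlett_sphericity(X)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0, abs=1e-6)

    def test_bartlett_monotone_in_correlation(self):
        chis = [bartlett_sphericity(exact_corr_pair(50, r))["chi2"]
                for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(chis, chis[1:]))


class TestVarimax:
    def test_single_component_identity(self):
        L = np.array([[0.8], [0.6], [0.4]])
        rotated, R = varimax(L)
        assert np.allclose(rotated, L)
        assert np.allclose(R, [[1.0]])

    def test_orthogonality_and_communality_preserved(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            L = rng.normal(size=(12, 4))
            rotated, R = varimax(L)
            assert np.allclose(R.T @ R, np.eye(4), atol=1e-8)
            assert np.allclose(
                (rotated ** 2).sum(axis=1), (L ** 2).sum(axis=1), atol=1e-8
            )
            assert np.allclose(L @ R, rotated, atol=1e-8)

    def test_criterion_does_not_decrease(self):
        from tauperf.pattern import _varimax_criterion
        rng = np.random.default_rng(9)
        L = rng.normal(size=(15, 3))
        rotated, _ = varimax(L, kaiser_normalize=False)
        assert _varimax_criterion(rotated) >= _varimax_criterion(L) - 1e-10


class TestFitPatternModel:
    @staticmethod
    def _labels(n):
        rng = np.random.default_rng(0)
        y = np.zeros(n)
        y[: n // 2] = 1
        rng.shuffle(y)
        return y

    def test_two_region_eigenvalues_one_plus_minus_r(self):
        X = pd.DataFrame(exact_corr_pair(60, 0.5) + 5.0, columns=["a", "b"])
        model = fit_pattern_model(X, self._labels(60))
        assert np.allclose(sorted(model.eigenvalues), [0.5, 1.5])
        assert model.n_components == 1  # only 1 + r > 1

    def test_total_variance_equals_region_count(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=(80, 2))
        X = pd.DataFrame(
            f @ rng.uniform(-1, 1, (2, 6)) + rng.normal(0, 0.5, (80, 6)),
            columns=list("abcdef"),
        )
        model = fit_pattern_model(X, self._labels(80))
        assert model.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_planted_block_structure_recovered(self):
        """Two disjoint 3-region factor blocks: varimax loadings assign each
        region's dominant component to its block, communalities preserved."""
        rng = np.random.default_rng(11)
        n = 500
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for i in range(3):
            cols[f"p{i}"] = 0.85 * f1 + rng.normal(0, 0.5, n)
        for i in range(3):
            cols[f"q{i}"] = 0.85 * f2 + rng.normal(0, 0.5, n)
        X = pd.DataFrame(cols)
        model = fit_pattern_model(X, self._labels(n))
        assert model.n_components == 2
        dominant = np.abs(model.rotated_loadings).argmax(axis=1)
        assert len(set(dominant[:3])) == 1
        assert len(set(dominant[3:])) == 1
        assert dominant[0] != dominant[3]
        # communality conservation against unrotated eigen-loadings
        lam = model.eigenvalues[model.eigenvalues > 1.0]
        assert np.allclose(
            (model.rotated_loadings ** 2).sum(axis=1).sum(), lam.sum(), atol=1e-8
        )

    def test_no_components_retained_errors(self):
        X = pd.DataFrame(exact_corr_pair(40, 0.0) + 2.0, columns=["a", "b"])
        with pytest.raises(ValueError, match="no components"):
            fit_pattern_model(X, self._labels(40))

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame(exact_corr_pair(40, 0.5) + 2.0, columns=["a", "b"])
        with pytest.raises(ValueError, match="both classes"):
            fit_pattern_model(X, np.ones(40))

    def test_unrotated_component_scores_uncorrelated(self):
        """Regression-method scores of the retained components are exactly
        uncorrelated with unit variance before rotation."""
        rng = np.random.default_rng(12)
        f = rng.normal(size=(120, 3))
        X = f @ rng.uniform(-1, 1, (3, 8)) + rng.normal(0, 0.4, (120, 8))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        R = (Z.T @ Z) / (len(X) - 1)
        lam, V = np.linalg.eigh(R)
        order = np.argsort(lam)[::-1]
        lam, V = lam[order], V[:, order]
        keep = lam > 1.0
        loadings = V[:, keep] * np.sqrt(lam[keep])
        scores = Z @ np.linalg.pinv(R) @ loadings
        cov = (scores.T @ scores) / (len(X) - 1)
        assert np.allclose(cov, np.eye(keep.sum()), atol=1e-8)


class TestScoring:
    @pytest.fixture
    def trained(self):
        rng = np.random.default_rng(13)
        n = 150
        y = np.zeros(n)
        y[:70] = 1
        f = rng.normal(size=n) + 1.2 * y
        X = pd.DataFrame({
            f"r{i}": f * w + rng.normal(0, 0.7, n)
            for i, w in enumerate((0.9, 0.8, 0.7, 0.6, 0.5))
        }, index=[f"S{i}" for i in range(n)])
        return X, y, fit_pattern_model(X, y)

    def test_self_projection_reproduces_training_scores(self, trained):
        X, y, model = trained
        s1 = score_subjects(X, model)
        s2 = score_subjects(X.copy(), model)
        assert np.allclose(s1, s2)
        # training-mean subject scores exactly zero
        mean_subject = pd.DataFrame([model.mean], columns=model.retained_labels)
        assert score_subjects(mean_subject, model).iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_score_orientation_separates_classes(self, trained):
        X, y, model = trained
        s = score_subjects(X, model)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_affine_rescaling_of_region_absorbed(self, trained):
        """Rescaling one input region (and refitting) leaves scores invariant:
        standardization removes affine units."""
        X, y, model = trained
        X2 = X.copy()
        X2["r0"] = X2["r0"] * 12.5 + 3.0
        model2 = fit_pattern_model(X2, y)
        assert np.allclose(score_subjects(X, model), score_subjects(X2, model2), atol=1e-8)

    def test_missing_retained_region_rejected(self, trained):
        X, _, model = trained
        with pytest.raises(ValueError, match="r4"):
            score_subjects(X.drop(columns=["r4"]), model)

    def test_json_round_trip(self, trained, tmp_path):
        X, _, model = trained
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PatternModel.from_json(path)
        assert back.retained_labels == model.retained_labels
        assert np.allclose(back.score_coefficients, model.score_coefficients)
        assert np.allclose(score_subjects(X, back), score_subjects(X, model))

    def test_linear_regression_option(self, trained):
        X, y, _ = trained
        model = fit_pattern_model(X, y, regression="linear")
        s = score_subjects(X, model)
        assert s[y == 1].mean() > s[y == 0].mean()


class TestCombineScores:
    def test_sum_examples(self):
        assert combine_scores(0.4, 0.6) == pytest.approx(1.0)
        assert combine_scores(2.5, 0.0) == pytest.approx(2.5)

    def test_series_sum_is_exact(self):
        a = pd.Series([0.1, -0.5, 2.0])
        b = pd.Series([1.0, 0.5, -2.0])
        assert np.allclose(combine_scores(a, b), a + b)
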