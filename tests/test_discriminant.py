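"""LDA, LOOCV confusion matrices, exact binomial CIs and two-group
discriminant-function construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numobat import discriminant as da


def two_gaussians(rng, n=40, delta=6.0, d=3):
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(delta / np.sqrt(d), 1, (n, d))])
    y = np.array(["A"] * n + ["B"] * n)
    return pd.DataFrame(X, columns=[f"t{i}" for i in range(d)]), pd.Series(y)


class TestFitLDA:
    def test_separated_classes_high_training_accuracy(self, rng):
        X, y = two_gaussians(rng, n=100)
        model = da.fit_lda(X, y)
        acc = (model.predict(X) == y.to_numpy()).mean()
        assert acc >= 0.99

    def test_class_mean_classifies_to_its_class(self, rng):
        X, y = two_gaussians(rng)
        model = da.fit_lda(X, y)
        for c in model.classes:
            assert model.predict(model.means.loc[c].to_numpy())[0] == c

    def test_equal_prior_prediction_equals_brute_force_mahalanobis(self, rng):
        """Oracle equivalence on 50 random points: the LDA rule must agree
        with nearest-class pooled Mahalanobis distance exactly."""
        X, y = two_gaussians(rng, n=30)
        model = da.fit_lda(X, y)
        cov_inv = np.linalg.inv(model.pooled_cov.to_numpy())
        pts = rng.normal(1.0, 2.0, (50, X.shape[1]))
        pred = model.predict(pts)
        for i, p in enumerate(pts):
            d2 = {
                c: (p - model.means.loc[c]) @ cov_inv @ (p - model.means.loc[c])
                for c in model.classes
            }
            assert pred[i] == min(d2, key=d2.get)

    def test_matches_sklearn_lda(self, rng):
        """Independent cross-check against the reference implementation."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = two_gaussians(rng, n=50, delta=2.0)
        ours = da.fit_lda(X, y).predict(X)
        theirs = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
        assert (ours == theirs).mean() == 1.0

    def test_singular_covariance_raises(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = pd.Series(["A"] * 15 + ["B"] * 15)
        with pytest.raises(ValueError, match="singular|ridge"):
            da.fit_lda(X, y)

    def test_class_size_guard(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            da.fit_lda(X, pd.Series(["A", "A", "B"]))


class TestLOOCV:
    def test_perfect_separation_gives_diagonal_table(self, rng):
        X, y = two_gaussians(rng, n=20, delta=12.0)
        cm = da.loocv_confusion(X, y)
        off = cm.counts.to_numpy() - np.diag(np.diag(cm.counts.to_numpy()))
        assert off.sum() == 0
        assert cm.accuracy == 1.0

    def test_accuracy_equals_trace_over_total(self, rng):
        X, y = two_gaussians(rng, n=15, delta=1.0)
        cm = da.loocv_confusion(X, y)
        assert cm.accuracy == pytest.approx(cm.correct / cm.total)

    def test_invariant_to_row_permutation_and_affine_scaling(self, rng):
        X, y = two_gaussians(rng, n=12, delta=2.0)
        base = da.loocv_confusion(X, y).accuracy
        perm = rng.permutation(len(X))
        assert da.loocv_confusion(X.iloc[perm], y.iloc[perm]).accuracy == base
        assert da.loocv_confusion(X * 3.7 + 11.0, y).accuracy == base

    def test_small_class_guard(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 1.5]})
        y = pd.Series(["A", "A", "B", "B", "A"])
        with pytest.raises(ValueError):
            da.loocv_confusion(X, y)


class TestAccuracyCI:
    def test_boundaries(self):
        acc, lo, hi = da.accuracy_ci(10, 10)
        assert acc == 1.0 and hi == 1.0
        acc, lo, hi = da.accuracy_ci(0, 5)
        assert acc == 0.0 and lo == 0.0

    def test_clopper_pearson_matches_beta_quantile_oracle(self):
        # 369 correct of 380: lower = Beta(0.025; x, n-x+1), upper = Beta(0.975; x+1, n-x)
        x, n = 369, 380
        acc, lo, hi = da.accuracy_ci(x, n)
        assert acc == pytest.approx(x / n)
        assert lo == pytest.approx(stats.beta.ppf(0.025, x, n - x + 1), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, x + 1, n - x), abs=1e-12)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            da.accuracy_ci(1, 0)


class TestBuildTwoGroup:
    def test_group_score_means_are_opposite(self, rng):
        X, y = two_gaussians(rng, n=30, delta=3.0)
        fn = da.build_two_group(X, y)
        means = [fn.group_stats[c]["mean"] for c in ("A", "B")]
        assert means[0] + means[1] == pytest.approx(0.0, abs=1e-10)
        assert means[0] > 0  # first-named class takes the positive side

    def test_group_means_approximate_half_mahalanobis_distance(self, rng):
        """Closed-form oracle: with unit within-group score SD the two
        group score means sit at ±Δ/2, Δ the pooled Mahalanobis distance."""
        n, d = 4000, 3
        delta = 3.0
        mu = np.zeros(d)
        mu2 = np.array([delta, 0, 0])  # identity covariance → Δ = 3
        X = np.vstack([rng.normal(mu, 1, (n, d)), rng.normal(mu2, 1, (n, d))])
        y = pd.Series(["A"] * n + ["B"] * n)
        fn = da.build_two_group(pd.DataFrame(X, columns=list("abc")), y)
        assert abs(fn.group_stats["A"]["mean"]) == pytest.approx(delta / 2, rel=0.05)

    def test_unit_pooled_score_sd(self, rng):
        X, y = two_gaussians(rng, n=60, delta=2.0)
        fn = da.build_two_group(X, y)
        scores = fn.score(X)
        pooled_var = sum(
            ((scores[(y == c).to_numpy()] - fn.group_stats[c]["mean"]) ** 2).sum()
            for c in ("A", "B")
        ) / (len(X) - 2)
        assert pooled_var == pytest.approx(1.0, abs=1e-10)

    def test_classification_by_sign(self, rng):
        X, y = two_gaussians(rng, n=50, delta=8.0)
        fn = da.build_two_group(X, y)
        assert (fn.classify(X) == y.to_numpy()).mean() >= 0.99

    def test_needs_exactly_two_classes(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = pd.Series(["A", "B", "C"] * 10)
        with pytest.raises(ValueError):
            da.build_two_group(X, y)


class TestForwardSelect:
    def test_single_informative_trait_selected_first(self, rng):
        n = 30
        sig = np.concatenate([rng.normal(0, 1, n), rng.normal(8, 1, n)])
        X = pd.DataFrame(
            {"noise1": rng.normal(size=2 * n), "signal": sig, "noise2": rng.normal(size=2 * n)}
        )
        y = pd.Series(["A"] * n + ["B"] * n)
        selected, _ = da.forward_select(X, y, max_traits=1)
        assert selected == ["signal"]

    def test_best_so_far_success_is_monotone(self, rng):
        n = 25
        sig = np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)])
        X = pd.DataFrame(
            {"signal": sig, "noise": rng.normal(size=2 * n), "noise2": rng.normal(size=2 * n)}
        )
        y = pd.Series(["A"] * n + ["B"] * n)
        _, trajectory = da.forward_select(X, y, max_traits=3)
        best = trajectory["success"].cummax()
        assert (trajectory["success"] == best).all() or (
            trajectory["success"].diff().dropna() >= -1e-12
        ).any()
        # the best-so-far column never decreases
        assert (best.diff().dropna() >= 0).all()

    def test_zero_traits_reports_baseline(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        y = pd.Series(["A"] * 6 + ["B"] * 4)
        selected, trajectory = da.forward_select(X, y, max_traits=0)
        assert selected == []
        assert trajectory["success"].iloc[0] == pytest.approx(0.6)

    def test_max_traits_clipped_with_warning(self, rng):
        n = 20
        sig = np.concatenate([rng.normal(0, 1, n), rng.normal(6, 1, n)])
        X = pd.DataFrame({"s": sig})
        y = pd.Series(["A"] * n + ["B"] * n)
        with pytest.warns(UserWarning, match="clipped"):
            selected, _ = da.forward_select(X, y, max_traits=5)
        assert selected == ["s"]
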