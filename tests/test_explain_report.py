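import numpy as np
import pytest
from scipy import stats as spstats

from ergml.explain_report import (
    dunn_posthoc,
    explain_individual,
    feature_group_tests,
    plot_shapley_summary,
    plot_waterfall,
    shapley_summary,
)
from ergml.modeling_cv import make_model, smote_balance
from conftest import gaussian_table


class ConstantModel:
    """Probability output independent of the input."""

    classes_ = np.array([0, 1])
    n_features_in_ = 4

    def predict_proba(self, X):
        out = np.empty((len(X), 2))
        out[:, 0] = 0.3
        out[:, 1] = 0.7
        return out


def _fit_rf(table, seed=0, n_estimators=100):
    Xb, yb = smote_balance(table.features.to_numpy(), table.labels.to_numpy(), seed=seed)
    return make_model("RF", {"n_estimators": n_estimators}, seed=seed).fit(Xb, yb)


def test_explanation_additivity():
    """E[f(X)] + sum(phi) reproduces f(x) on every explained instance."""
    table = gaussian_table(n_per_class=30, p=6, shift=2.0, seed=0)
    model = _fit_rf(table)
    X = table.features.to_numpy()
    background = X[:16]
    for sid in table.features.index[:15]:
        res = explain_individual(model, table.features.loc[sid], background, seed=1)
        assert res.additivity_error() <= 1e-2
        assert res.additivity_error() < 1e-9  # permutation estimator telescopes


def test_constant_model_explanation():
    model = ConstantModel()
    x = np.zeros(4)
    res = explain_individual(model, x, np.zeros((5, 4)), feature_names=list("abcd"))
    assert res.baseline == pytest.approx(0.7)
    assert res.explained_output == pytest.approx(0.7)
    assert all(abs(v) < 1e-12 for v in res.contributions.values())
    assert not res.predicted_positive


def test_missing_feature_rejected():
    model = ConstantModel()
    with pytest.raises(ValueError, match="expects 4"):
        explain_individual(model, np.zeros(3), np.zeros((5, 3)))


def test_predicted_class_call():
    table = gaussian_table(n_per_class=30, p=4, shift=3.0, seed=1)
    model = _fit_rf(table)
    X = table.features.to_numpy()
    clinical = list(model.classes_).index("ASD")
    res = explain_individual(
        model, table.features.iloc[-1], X[:16], class_index=clinical, seed=0
    )
    # last row belongs to the shifted clinical class of a separable problem
    assert res.predicted_positive
    res_ctrl = explain_individual(
        model, table.features.iloc[0], X[-16:], class_index=clinical, seed=0
    )
    assert not res_ctrl.predicted_positive


def test_summary_ranks_injected_features_first():
    table = gaussian_table(n_per_class=40, p=8, shift=2.5, informative=2, seed=3)
    model = _fit_rf(table)
    summary = shapley_summary(model, table, top_n=4, seed=0)
    assert {"f0", "f1"} <= set(summary["feature"].iloc[:3])
    assert summary["score"].is_monotonic_decreasing
    assert len(summary) == 4


def test_summary_permutation_invariant_up_to_ties():
    table = gaussian_table(n_per_class=30, p=6, shift=2.5, informative=2, seed=4)
    model = _fit_rf(table)
    top1 = set(shapley_summary(model, table, top_n=3, seed=0)["feature"])

    shuffled = table.subset_features(list(reversed(table.feature_names)))
    model2 = _fit_rf(shuffled)
    top2 = set(shapley_summary(model2, shuffled, top_n=3, seed=0)["feature"])
    assert top1 & top2 >= {"f0", "f1"}


def test_top_n_larger_than_feature_count_returns_all():
    table = gaussian_table(n_per_class=20, p=4, shift=2.0, seed=5)
    model = _fit_rf(table, n_estimators=50)
    summary = shapley_summary(model, table, top_n=50, seed=0)
    assert len(summary) == 4


# ---------------------------------------------------------------------------
# group statistics

def test_kw_two_groups_tracks_mann_whitney():
    """2-group Kruskal-Wallis orders features identically to |U - n1 n2/2|."""
    rng = np.random.default_rng(0)
    n1, n2 = 20, 25
    y = np.array(["a"] * n1 + ["b"] * n2)
    kw_ps, u_devs = [], []
    for _ in range(50):
        x = rng.standard_normal(n1 + n2)
        kw_ps.append(spstats.kruskal(x[:n1], x[n1:]).pvalue)
        u = spstats.mannwhitneyu(x[:n1], x[n1:]).statistic
        u_devs.append(abs(u - n1 * n2 / 2))
    # U is integer-valued so exact ties occur; a tie in |U - mu| is a tie in
    # the KW statistic too, making the rank correlation exactly -1
    rho = spstats.spearmanr(kw_ps, u_devs).statistic
    assert rho == pytest.approx(-1.0, abs=1e-12)


def test_feature_group_tests_two_groups():
    table = gaussian_table(n_per_class=60, p=4, shift=1.5, informative=1, seed=6)
    results = feature_group_tests(table)
    by_name = {r.feature: r for r in results}
    assert by_name["f0"].significant
    assert all(0.0 <= r.kw_p <= 1.0 for r in results)
    assert all(not r.pairwise_p for r in results)  # no post hoc for k = 2


def test_constant_feature_degenerate():
    table = gaussian_table(n_per_class=20, p=3, seed=7)
    table.features["f2"] = 5.0
    results = {r.feature: r for r in feature_group_tests(table)}
    assert results["f2"].degenerate and results["f2"].kw_p == 1.0


def test_dunn_holm_adjusted_not_below_raw():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.standard_normal(30) + d for d in (0.0, 0.5, 1.2)])
    g = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
    raw = dunn_posthoc(x, g, adjust=None)
    holm = dunn_posthoc(x, g, adjust="holm")
    assert set(raw) == set(holm) == {("a", "b"), ("a", "c"), ("b", "c")}
    for pair in raw:
        assert holm[pair] >= raw[pair] - 1e-15


def test_three_group_posthoc_only_after_rejection():
    table = gaussian_table(
        n_per_class=40, p=2, shift=1.5, informative=1, seed=8,
        classes=("control", "ASD", "ADHD"),
    )
    results = {r.feature: r for r in feature_group_tests(table)}
    assert results["f0"].kw_p < 0.05 and results["f0"].pairwise_p
    for r in results.values():
        if r.kw_p >= 0.05:
            assert not r.pairwise_p


# ---------------------------------------------------------------------------
# plots

def test_plots_render_to_files(tmp_path):
    table = gaussian_table(n_per_class=20, p=5, shift=2.0, seed=9)
    model = _fit_rf(table, n_estimators=50)
    summary = shapley_summary(model, table, top_n=5, seed=0)
    p1 = tmp_path / "summary.png"
    plot_shapley_summary(summary, str(p1))
    res = explain_individual(
        model, table.features.iloc[0], table.features.to_numpy()[:10], seed=0
    )
    p2 = tmp_path / "waterfall.png"
    plot_waterfall(res, str(p2))
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
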