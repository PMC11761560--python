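"""Shapley explanation summaries, per-individual decompositions, and
non-parametric group-difference statistics.

Per-instance explanations are additive: the explained output f(x) equals
the baseline E[f(X)] plus the sum of per-feature contributions, and the
predicted-class call for an individual is f(x) > E[f(X)].  Group-level
screening uses the Kruskal-Wallis H test per feature (tie-corrected, chi-
square approximation) with Dunn's pairwise z-tests under Holm-Bonferroni
adjustment when more than two groups are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from ergml.fusion_selection import FeatureTable, shapley_scores
from ergml.shapley import model_shapley

__all__ = [
    "ExplainResult",
    "FeatureSignificance",
    "shapley_summary",
    "explain_individual",
    "feature_group_tests",
    "dunn_posthoc",
    "plot_shapley_summary",
    "plot_waterfall",
]


@dataclass
class ExplainResult:
    """Additive Shapley decomposition of one model output."""

    instance_id: str
    baseline: float  # E[f(X)]
    contributions: dict[str, float]
    explained_output: float  # f(x)

    @property
    def predicted_positive(self) -> bool:
        """Class call: instance belongs to the clinical class when the
        explained output exceeds the expected output."""
        return self.explained_output > self.baseline

    def additivity_error(self) -> float:
        return abs(self.explained_output - (self.baseline + sum(self.contributions.values())))


@dataclass
class FeatureSignificance:
    feature: str
    kw_p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.kw_p < 0.05


def dunn_posthoc(
    values: np.ndarray, groups: np.ndarray, adjust: str | None = "holm"
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise rank-sum z-tests after a Kruskal-Wallis rejection.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, multiplicity-adjusted (Holm by default).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = spstats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    labels = sorted(set(groups.tolist()))
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    ns = {g: int(np.sum(groups == g)) for g in labels}

    pairs, raw = [], []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / ns[gi] + 1.0 / ns[gj]))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / se
                p = 2.0 * spstats.norm.sf(abs(z))
            pairs.append((gi, gj))
            raw.append(p)
    if not pairs:
        return {}
    adj = raw if adjust is None else multipletests(raw, method=adjust)[1]
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def feature_group_tests(
    table: FeatureTable | pd.DataFrame, labels: pd.Series | np.ndarray | None = None
) -> list[FeatureSignificance]:
    """Kruskal-Wallis screen per feature, with Dunn post hoc for k > 2.

    Constant features are degenerate and reported with p = 1.  Pairwise
    Dunn tests (Holm-adjusted) are computed only when more than two groups
    are present and the omnibus test rejects at 0.05.
    """
    if isinstance(table, FeatureTable):
        features, y = table.features, table.labels.to_numpy()
    else:
        features, y = table, np.asarray(labels)
    group_names = sorted(set(y.tolist()))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    if min(np.sum(y == g) for g in group_names) < 2:
        raise ValueError("need at least two observations per group")

    out = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            out.append(FeatureSignificance(feature=name, kw_p=1.0, degenerate=True))
            continue
        samples = [x[y == g] for g in group_names]
        kw_p = float(spstats.kruskal(*samples).pvalue)
        pairwise = {}
        if len(group_names) > 2 and kw_p < 0.05:
            pairwise = dunn_posthoc(x, y)
        out.append(FeatureSignificance(feature=name, kw_p=kw_p, pairwise_p=pairwise))
    return out


def shapley_summary(
    model,
    table: FeatureTable,
    top_n: int = 10,
    seed: int = 0,
    max_background: int = 32,
    n_permutations: int = 8,
) -> pd.DataFrame:
    """Rank features by mean |Shapley| (averaged over classes).

    Returns the ``top_n`` features with their scores, per-instance Shapley
    value clouds (for the positive / last class), and Kruskal-Wallis
    significance flags.  Ranking ties are broken by column order, so the
    result is permutation-invariant up to ties.
    """
    scores = shapley_scores(
        model, table, seed=seed, max_background=max_background,
        n_permutations=n_permutations,
    )
    names = table.feature_names
    order = sorted(range(len(names)), key=lambda i: (-scores[names[i]], i))
    top = [names[i] for i in order[: min(top_n, len(names))]]

    X = table.features.to_numpy()
    rng = np.random.default_rng(seed)
    bg = X[rng.choice(len(X), size=min(max_background, len(X)), replace=False)]
    phi, _ = model_shapley(
        model, X, bg, method="permutation", n_permutations=n_permutations,
        seed=seed + len(model.classes_),
    )
    sig = {s.feature: s.significant for s in feature_group_tests(table)}

    col = {n: i for i, n in enumerate(names)}
    return pd.DataFrame(
        {
            "feature": top,
            "score": [scores[n] for n in top],
            "significant": [sig[n] for n in top],
            "instance_values": [phi[:, col[n]].tolist() for n in top],
        }
    )


def explain_individual(
    model,
    instance: pd.Series | np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
    instance_id: str = "",
    class_index: int | None = None,
    seed: int = 0,
    **kwargs,
) -> ExplainResult:
    """Additive Shapley decomposition of one instance's model output.

    ``background`` supplies the reference distribution defining E[f(X)].
    The decomposition satisfies f(x) = E[f(X)] + sum(contributions) up to
    floating-point error (permutation estimator) or exactly (exact
    enumeration for small feature counts).
    """
    if isinstance(instance, pd.Series):
        feature_names = list(instance.index)
        instance_id = instance_id or str(instance.name)
        x = instance.to_numpy(dtype=float)
    else:
        x = np.asarray(instance, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(x.size)]
    expected = getattr(model, "n_features_in_", None)
    if expected is None and hasattr(model, "_model"):
        expected = getattr(model._model, "n_features_in_", None)
    if expected is not None and x.size != expected:
        missing = expected - x.size
        raise ValueError(
            f"instance has {x.size} features but the model expects {expected} "
            f"({missing:+d})"
        )

    phi, base = model_shapley(
        model, x[None, :], background, class_index=class_index, seed=seed, **kwargs
    )
    ci = len(model.classes_) - 1 if class_index is None else class_index
    fx = float(model.predict_proba(x[None, :])[0, ci])
    return ExplainResult(
        instance_id=instance_id,
        baseline=base,
        contributions=dict(zip(feature_names, phi[0].tolist())),
        explained_output=fx,
    )


# ---------------------------------------------------------------------------
# plotting (layout only; not a numeric contract)

def plot_shapley_summary(summary: pd.DataFrame, path: str | None = None):
    """Beeswarm-style summary: one jittered value cloud per top feature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(summary) + 1.5))
    rng = np.random.default_rng(0)
    for i, row in summary.iloc[::-1].reset_index(drop=True).iterrows():
        vals = np.asarray(row["instance_values"])
        jitter = rng.normal(0, 0.08, size=vals.size)
        ax.scatter(vals, np.full(vals.size, i) + jitter, s=8, alpha=0.5)
        label = row["feature"] + ("" if row["significant"] else " *")
        ax.text(-0.02, i, label, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks([])
    ax.set_xlabel("Shapley value (impact on model output)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_waterfall(result: ExplainResult, path: str | None = None, top_n: int = 10):
    """Waterfall of the largest contributions from E[f(X)] to f(x)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(result.contributions.items(), key=lambda kv: -abs(kv[1]))
    shown = items[:top_n]
    rest = sum(v for _, v in items[top_n:])
    if items[top_n:]:
        shown.append((f"sum of {len(items) - top_n} others", rest))

    fig, ax = plt.subplots(figsize=(7, 0.45 * len(shown) + 1.5))
    level = result.baseline
    for i, (name, contrib) in enumerate(reversed(shown)):
        ax.barh(i, contrib, left=level, color="#d62728" if contrib >= 0 else "#1f77b4")
        ax.text(-0.02, i, name, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=8)
        level += contrib
    ax.axvline(result.baseline, color="grey", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel(
        f"model output: E[f(X)]={result.baseline:.3f} -> f(x)={result.explained_output:.3f}"
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
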