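"""Modelling correctness against identity and consensus scores.

Two complementary models predict whether an assignment is correct from
its identity and consensus scores.  A binomial GLM (logit link, with
interaction) captures smooth trends; a Gini classification tree,
pruned with the one-standard-error rule on the cross-validated error,
finds the discontinuities that suggest discard thresholds.  Both are
trained only on assigned rows — unassigned targets carry no scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, export_text

FEATURES = ("identity", "consensus")


def _training_frame(rows: pd.DataFrame, rank: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "identity": rows[f"{rank}_identity"],
            "consensus": rows[f"{rank}_consensus"],
            "correct": rows[f"{rank}_correct"].astype(int),
        }
    ).dropna(subset=["identity", "consensus"])
    if df.empty:
        raise ValueError("no assigned rows with scores to train on")
    return df


# ---------------------------------------------------------------------------
# Binomial GLM

@dataclass(frozen=True)
class GlmFit:
    """Binomial GLM of correctness on identity, consensus (+ interaction)."""

    rank: str
    label: str
    params: pd.Series
    bse: pd.Series
    converged: bool
    separation: bool
    monotone_identity: bool
    monotone_consensus: bool
    n: int
    result: object = field(repr=False, compare=False, default=None)

    def predict(self, identity: np.ndarray, consensus: np.ndarray) -> np.ndarray:
        X = _design(np.asarray(identity, float), np.asarray(consensus, float),
                    interaction="identity:consensus" in self.params.index)
        return self.result.predict(X)


def _design(identity: np.ndarray, consensus: np.ndarray, interaction: bool) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "identity": identity, "consensus": consensus})
    if interaction:
        X["identity:consensus"] = identity * consensus
    return X


def fit_correctness_glm(
    rows: pd.DataFrame, rank: str, label: str = "", interaction: bool = True
) -> GlmFit:
    """Maximum-likelihood logit fit of correct ~ identity * consensus.

    Degenerate designs (a constant predictor) raise; an all-one-class
    response or detected perfect separation sets the ``separation``
    flag while still returning whatever the IRLS fitter produced.
    Monotonicity of the predicted probability in each score over its
    observed range (the other held at its median) is checked and
    reported, not enforced.
    """
    df = _training_frame(rows, rank)
    for feat in FEATURES:
        if df[feat].nunique() < 2:
            raise ValueError(f"predictor {feat!r} is constant: degenerate design")
    y = df["correct"].to_numpy()
    separation = bool(y.min() == y.max())
    X = _design(df["identity"].to_numpy(), df["consensus"].to_numpy(), interaction)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    converged = False
    try:
        with np.errstate(all="ignore"):
            result = model.fit(maxiter=100, tol=1e-8)
        converged = bool(result.converged)
        if not converged or np.any(np.abs(result.params) > 1e3):
            separation = separation or not converged
    except Exception:  # perfect separation can abort IRLS outright
        return GlmFit(rank, label, pd.Series(dtype=float), pd.Series(dtype=float),
                      False, True, False, False, len(df), None)

    fit = GlmFit(rank, label, result.params, result.bse, converged, separation,
                 False, False, len(df), result)
    mono_i = _is_monotone(fit, df, "identity")
    mono_c = _is_monotone(fit, df, "consensus")
    return GlmFit(rank, label, result.params, result.bse, converged, separation,
                  mono_i, mono_c, len(df), result)


def _is_monotone(fit: GlmFit, df: pd.DataFrame, feature: str) -> bool:
    grid = np.linspace(df[feature].min(), df[feature].max(), 50)
    other = [f for f in FEATURES if f != feature][0]
    med = np.full_like(grid, df[other].median())
    if feature == "identity":
        probs = fit.predict(grid, med)
    else:
        probs = fit.predict(med, grid)
    return bool(np.all(np.diff(probs) >= -1e-9))


# ---------------------------------------------------------------------------
# Gini classification tree with 1-SE cost-complexity pruning

@dataclass(frozen=True)
class TreeParams:
    """Growth limits and pruning-CV settings for the threshold tree."""

    max_depth: int | None = 6
    min_samples_split: int = 40
    min_samples_leaf: int = 20
    min_impurity_decrease: float = 0.0
    cv_folds: int = 10
    seed: int = 0


@dataclass(frozen=True)
class TreeFit:
    """Pruned Gini tree over (identity, consensus) with its pruning record."""

    rank: str
    label: str
    tree: DecisionTreeClassifier = field(repr=False, compare=False)
    pruning: pd.DataFrame
    chosen_alpha: float
    n: int

    def splits(self) -> list[tuple[str, float]]:
        """(variable, threshold) of every internal node, preorder."""
        t = self.tree.tree_
        return [
            (FEATURES[t.feature[i]], float(t.threshold[i]))
            for i in range(t.node_count)
            if t.children_left[i] != -1
        ]

    def n_leaves(self) -> int:
        return int(self.tree.get_n_leaves())

    def predict(self, identity: np.ndarray, consensus: np.ndarray) -> np.ndarray:
        X = np.column_stack([identity, consensus])
        return self.tree.predict(X)

    def to_text(self) -> str:
        return export_text(self.tree, feature_names=list(FEATURES))


def fit_threshold_tree(
    rows: pd.DataFrame, rank: str, params: TreeParams | None = None, label: str = ""
) -> TreeFit:
    """Grow a Gini tree, compute its cost-complexity path, and keep the
    smallest subtree within one standard error of the minimal
    cross-validated error.

    The CV error of each complexity value is the mean 0/1 loss over the
    held-out observations of a seeded stratified k-fold; its standard
    error is the standard error of those per-observation losses.  Ties
    in "smallest subtree" resolve toward fewer leaves (larger alpha).
    An all-one-class response yields a valid single-leaf tree.
    """
    params = params or TreeParams()
    df = _training_frame(rows, rank)
    X = df[list(FEATURES)].to_numpy()
    y = df["correct"].to_numpy()

    grow = dict(
        criterion="gini",
        max_depth=params.max_depth,
        min_samples_split=params.min_samples_split,
        min_samples_leaf=params.min_samples_leaf,
        min_impurity_decrease=params.min_impurity_decrease,
        random_state=params.seed,
    )
    base = DecisionTreeClassifier(**grow).fit(X, y)
    alphas = np.unique(base.cost_complexity_pruning_path(X, y).ccp_alphas)
    alphas = np.clip(alphas, 0.0, None)

    if len(np.unique(y)) < 2 or len(alphas) == 1:
        pruning = pd.DataFrame(
            {"alpha": alphas, "n_leaves": [base.get_n_leaves()] * len(alphas),
             "cv_error": np.nan, "se": np.nan}
        )
        return TreeFit(rank, label, base, pruning, float(alphas[0]), len(df))

    n_folds = min(params.cv_folds, int(np.bincount(y).min()), len(y))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=params.seed)
    losses = np.zeros((len(alphas), len(y)))
    for train, test in skf.split(X, y):
        for ai, alpha in enumerate(alphas):
            clf = DecisionTreeClassifier(ccp_alpha=alpha, **grow)
            clf.fit(X[train], y[train])
            losses[ai, test] = clf.predict(X[test]) != y[test]

    cv_error = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(len(y))
    best = int(np.argmin(cv_error))
    threshold = cv_error[best] + se[best]
    # largest alpha (fewest leaves) still within one SE of the minimum
    chosen = float(alphas[np.nonzero(cv_error <= threshold)[0].max()])

    final = DecisionTreeClassifier(ccp_alpha=chosen, **grow).fit(X, y)
    n_leaves = [
        DecisionTreeClassifier(ccp_alpha=a, **grow).fit(X, y).get_n_leaves()
        for a in alphas
    ]
    pruning = pd.DataFrame(
        {"alpha": alphas, "n_leaves": n_leaves, "cv_error": cv_error, "se": se}
    )
    return TreeFit(rank, label, final, pruning, chosen, len(df))
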