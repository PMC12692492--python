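"""Metastasis risk modeling on bulk cohorts.

Feature genes are those chosen by at least ``min_selectors`` of several
feature selectors (L1-penalized logistic path at the CV-optimal penalty,
null-calibrated held-out permutation importance of a tree ensemble,
univariate rank-AUC filter). Candidate learners are
evaluated by cross-validated and held-out AUC and ranked by the Model
Score

    ModelScore = (CV + Test) / 2 - lambda * |CV - Test|,   lambda = 0.8,

which penalizes CV/test divergence (overfitting) alongside rewarding
accuracy. The best model is linearized with a plain logistic fit whose
coefficients define the metastasis prediction score (MPS per cancer,
GMPS when trained on pooled cancers): the linear predictor
``beta_0 + sum_i beta_i x_i``. Samples are stratified High/Low at the
median MPS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

__all__ = [
    "ScoreModel",
    "ModelEval",
    "split_cohort",
    "select_features",
    "model_score",
    "rank_models",
    "evaluate_models",
    "fit_score_model",
    "compute_score",
    "stratify_risk",
    "auc",
    "default_learners",
]

LAMBDA_DEFAULT = 0.8


@dataclass
class ScoreModel:
    """Logistic coefficients defining an MPS/GMPS risk score."""

    genes: list[str]
    coef: np.ndarray
    intercept: float
    scope: str = "cancer"  # 'cancer' (MPS) or 'global' (GMPS)


@dataclass
class ModelEval:
    model_id: str
    cv_auc: float
    test_auc: float
    score: float = field(init=False)
    lam: float = LAMBDA_DEFAULT

    def __post_init__(self) -> None:
        self.score = model_score(self.cv_auc, self.test_auc, self.lam)


def _encode(labels: pd.Series) -> np.ndarray:
    y = np.asarray(labels)
    if set(pd.unique(y)) <= {"NM", "M"}:
        return (y == "M").astype(int)
    return y.astype(int)


def split_cohort(expr: pd.DataFrame, labels: pd.Series, train_frac: float = 0.8,
                 seed: int = 0) -> pd.Series:
    """Stratified train/test split labels (``'train'``/``'test'`` per sample)."""
    if len(expr) < 10:
        raise ValueError("cohort needs at least 10 samples")
    y = _encode(labels.reindex(expr.index))
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single class")
    idx_train, idx_test = train_test_split(
        np.arange(len(expr)), train_size=train_frac, stratify=y,
        random_state=seed)
    split = pd.Series("test", index=expr.index, name="split")
    split.iloc[idx_train] = "train"
    return split


# ---------------------------------------------------------------------------
# feature selection


def _select_l1(X: np.ndarray, y: np.ndarray, genes: list[str],
               seed: int) -> set[str]:
    # The path is scored by held-out log-loss (deviance), as in glmnet: on
    # uninformative data deviance strictly worsens as noise genes enter, so
    # the CV optimum is the null model, whereas rank metrics sit flat at
    # chance and pick a penalty at random. The one-standard-error rule then
    # takes the strongest penalty within one fold-SE of the optimum.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegressionCV(
            Cs=10, penalty="l1", solver="liblinear", cv=5,
            scoring="neg_log_loss", random_state=seed, max_iter=2000)
        clf.fit(X, y)
        scores = next(iter(clf.scores_.values()))  # (n_folds, n_Cs)
        mean = scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean))
        # Cs_ is ascending, so the smallest eligible C is the sparsest fit.
        eligible = np.nonzero(mean >= mean[best] - se[best])[0]
        c_1se = float(clf.Cs_[eligible[0]])
        refit = LogisticRegression(penalty="l1", solver="liblinear", C=c_1se,
                                   random_state=seed, max_iter=2000).fit(X, y)
    keep = np.abs(refit.coef_[0]) > 1e-8
    return {g for g, k in zip(genes, keep) if k}


def _heldout_perm_importance(X: np.ndarray, y: np.ndarray, seed: int,
                             n_repeats: int = 5) -> np.ndarray:
    """Mean held-out AUC drop per feature when it is permuted.

    The ensemble is fit on an internal 70/30 split and importances are
    measured on the held-out part; features the ensemble never splits on
    have importance exactly zero and are skipped.
    """
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), train_size=0.7, stratify=y, random_state=seed)
    est = GradientBoostingClassifier(random_state=seed).fit(X[idx_tr],
                                                            y[idx_tr])
    used = np.nonzero(est.feature_importances_ > 0)[0]
    Xv, yv = X[idx_va].copy(), y[idx_va]
    base = auc(est.predict_proba(Xv)[:, 1], yv)
    rng = np.random.default_rng(seed)
    mean = np.zeros(X.shape[1])
    for j in used:
        col = Xv[:, j].copy()
        drops = []
        for _ in range(n_repeats):
            Xv[:, j] = rng.permutation(col)
            drops.append(base - auc(est.predict_proba(Xv)[:, 1], yv))
        Xv[:, j] = col
        mean[j] = float(np.mean(drops))
    return mean


def _select_tree(X: np.ndarray, y: np.ndarray, genes: list[str],
                 seed: int, top_n: int = 35, n_null: int = 3) -> set[str]:
    # Permutation importances are calibrated against a label-permutation
    # null (Altmann-style): a feature is kept only when its held-out
    # importance exceeds the largest importance any feature attains after
    # the labels are shuffled. Without this, finite-sample chance
    # correlations make the top of the importance ranking agree with the
    # univariate filter even on pure noise.
    imp = _heldout_perm_importance(X, y, seed)
    rng = np.random.default_rng(seed + 1)
    null_max = max(
        _heldout_perm_importance(X, rng.permutation(y), seed + 1 + b).max()
        for b in range(n_null))
    order = np.argsort(-imp, kind="stable")[:top_n]
    return {genes[i] for i in order if imp[i] > null_max}


def _select_univariate(X: np.ndarray, y: np.ndarray, genes: list[str],
                       seed: int, top_n: int = 35) -> set[str]:
    scores = np.array([abs(auc(X[:, i], y) - 0.5) for i in range(X.shape[1])])
    order = np.argsort(-scores, kind="stable")[:top_n]
    return {genes[i] for i in order}


BUILTIN_SELECTORS = {
    "l1_logistic": _select_l1,
    "tree_importance": _select_tree,
    "univariate_auc": _select_univariate,
}


def select_features(expr: pd.DataFrame, labels: pd.Series,
                    candidates: list[str], selectors: dict | None = None,
                    min_selectors: int = 2, seed: int = 0) -> list[str]:
    """Genes chosen by >= ``min_selectors`` of the registered selectors."""
    if not candidates:
        raise ValueError("empty candidate gene list")
    selectors = selectors or BUILTIN_SELECTORS
    if len(selectors) < 2:
        raise ValueError("need at least 2 selectors")
    genes = [g for g in candidates if g in expr.columns]
    X = expr[genes].to_numpy(dtype=float)
    y = _encode(labels.reindex(expr.index))
    votes: dict[str, int] = {g: 0 for g in genes}
    for fn in selectors.values():
        for g in fn(X, y, genes, seed):
            votes[g] += 1
    return [g for g in genes if votes[g] >= min_selectors]


# ---------------------------------------------------------------------------
# model scoring and ranking


def model_score(cv_auc: float, test_auc: float, lam: float = LAMBDA_DEFAULT) -> float:
    """(CV + Test)/2 - lam * |CV - Test|."""
    for name, v in (("cv_auc", cv_auc), ("test_auc", test_auc)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} out of [0, 1]: {v}")
    return (cv_auc + test_auc) / 2.0 - lam * abs(cv_auc - test_auc)


def rank_models(evals: list[ModelEval]) -> list[ModelEval]:
    """Sort by descending Model Score, ties by Test AUC then model id."""
    if not evals:
        raise ValueError("no evaluations to rank")
    return sorted(evals, key=lambda e: (-e.score, -e.test_auc, e.model_id))


def default_learners(seed: int = 0) -> dict:
    return {
        "logistic": LogisticRegression(max_iter=2000),
        "l2_logistic": LogisticRegression(C=0.5, max_iter=2000),
        "gboost": GradientBoostingClassifier(random_state=seed),
    }


def evaluate_models(expr: pd.DataFrame, labels: pd.Series, genes: list[str],
                    split: pd.Series, learners: dict | None = None,
                    lam: float = LAMBDA_DEFAULT, cv_folds: int = 5,
                    seed: int = 0) -> list[ModelEval]:
    """Fit each learner on the training split; score CV and test AUC."""
    learners = learners or default_learners(seed)
    tr = split == "train"
    Xtr = expr.loc[tr, genes].to_numpy(dtype=float)
    ytr = _encode(labels.reindex(expr.index)[tr])
    Xte = expr.loc[~tr, genes].to_numpy(dtype=float)
    yte = _encode(labels.reindex(expr.index)[~tr])
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    evals = []
    for name, est in learners.items():
        cv_auc = float(np.mean(cross_val_score(est, Xtr, ytr, cv=cv,
                                               scoring="roc_auc")))
        est.fit(Xtr, ytr)
        prob = est.predict_proba(Xte)[:, 1]
        evals.append(ModelEval(model_id=name, cv_auc=cv_auc,
                               test_auc=auc(prob, yte), lam=lam))
    return rank_models(evals)


# ---------------------------------------------------------------------------
# MPS / GMPS


def fit_score_model(expr: pd.DataFrame, labels: pd.Series, genes: list[str],
                    scope: str = "cancer") -> ScoreModel:
    """Maximum-likelihood logistic fit on the selected genes.

    Falls back to a lightly ridge-penalized fit when the unpenalized fit
    does not produce finite, stable coefficients (complete separation).
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise ValueError(f"genes absent from cohort: {missing[:5]}")
    X = expr[genes].to_numpy(dtype=float)
    y = _encode(labels.reindex(expr.index))
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, max_iter=5000).fit(X, y)
    coef = clf.coef_[0]
    if not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > 1e3:
        warnings.warn("separation detected; refitting with tiny ridge penalty",
                      stacklevel=2)
        clf = LogisticRegression(C=100.0, max_iter=5000).fit(X, y)
        coef = clf.coef_[0]
    if not np.all(np.isfinite(coef)):
        raise RuntimeError("logistic fit failed to produce finite coefficients")
    return ScoreModel(genes=list(genes), coef=coef.copy(),
                      intercept=float(clf.intercept_[0]), scope=scope)


def compute_score(model: ScoreModel, expr: pd.DataFrame) -> pd.Series:
    """MPS/GMPS linear predictor per sample; absent genes imputed at cohort mean."""
    cols = []
    for g in model.genes:
        if g in expr.columns:
            cols.append(expr[g].to_numpy(dtype=float))
        else:
            warnings.warn(f"gene {g!r} absent; imputing cohort mean",
                          stacklevel=2)
            cols.append(np.full(len(expr), np.nanmean(expr.to_numpy())))
    X = np.column_stack(cols)
    name = "GMPS" if model.scope == "global" else "MPS"
    return pd.Series(model.intercept + X @ model.coef, index=expr.index,
                     name=name)


def stratify_risk(scores: pd.Series) -> pd.Series:
    """High/Low split at the median (scores <= median are Low)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    med = float(np.median(scores.to_numpy(dtype=float)))
    return pd.Series(np.where(scores > med, "High", "Low"),
                     index=scores.index, name="risk_group")


def auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> float:
    """Rank-based AUC (Mann-Whitney U with tie correction)."""
    s = np.asarray(scores, dtype=float)
    y = _encode(pd.Series(np.asarray(labels)))
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
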