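"""Cohort modeling: PCA on per-ROI features, PC1 testing, logistic
regression of chronic rejection on PC1, and the marker correlation network.

PCA centers (and by default unit-variance scales) the ROI x variable
matrix and eigen-decomposes its covariance; scaling is the default because
heavy-metal tags differ widely in raw signal yield, which would otherwise
let a few bright markers dominate the components. Scores and loadings use
a deterministic sign convention (the largest-magnitude loading of each
component is positive). The leading component feeds a univariate logistic
regression P(CR) = 1 / (1 + exp(-(a + b * PC1))); when the two cohorts are
perfectly separable along PC1 the unpenalized MLE diverges, so the model
falls back to a ridge penalty (strength 1.0) and flags it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .quantify import rank_sum_test

logger = logging.getLogger(__name__)

_SLOPE_DIVERGENCE = 30.0  # |coef| beyond this on scaled scores ~ separation


@dataclass
class PcaModel:
    """Fitted PCA: loadings, explained variance (%), per-variable
    contributions (%), per-ROI scores."""

    loadings: pd.DataFrame          # variables x components
    explained_pct: np.ndarray       # per component, sums to 100
    contributions_pct: pd.DataFrame  # variables x components, columns sum to 100
    scores: pd.DataFrame            # ROIs x components
    scaled: bool


def pca_fit(features: pd.DataFrame, scale: bool = True) -> PcaModel:
    """PCA of an ROI x variable feature matrix.

    Columns are centered and, when ``scale``, divided by their population
    SD; a zero-variance column with scaling requested is an error naming
    the column, as is any missing value (error names the ROI).
    """
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValueError("PCA requires >= 2 ROIs and >= 2 variables")
    if features.isna().any().any():
        bad = features.index[features.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing feature values for ROI(s) {bad}")
    X = features.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    Xp = X - mu
    if scale:
        sd = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [features.columns[i] for i in zero]
            raise ValueError(f"zero-variance column(s) with scale=True: {names}")
        Xp = Xp / sd
    u, s, vt = np.linalg.svd(Xp, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for kcomp in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[kcomp])))
        if vt[kcomp, j] < 0:
            vt[kcomp] *= -1
            u[:, kcomp] *= -1
    var = s**2
    explained = 100.0 * var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=features.columns, columns=comps)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    scores = pd.DataFrame(u * s, index=features.index, columns=comps)
    return PcaModel(
        loadings=loadings,
        explained_pct=explained,
        contributions_pct=contributions,
        scores=scores,
        scaled=scale,
    )


def pc1_test(pca: PcaModel, cohorts: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of PC1 scores, NR vs CR."""
    cohorts = cohorts.reindex(pca.scores.index)
    x = pca.scores.loc[cohorts == "NR", "PC1"].to_numpy()
    y = pca.scores.loc[cohorts == "CR", "PC1"].to_numpy()
    return rank_sum_test(x, y)


@dataclass
class Lr1Model:
    """Univariate logistic regression of chronic rejection on PC1."""

    intercept: float
    slope: float
    ridge: float
    separation_flag: bool
    probabilities: pd.Series        # per-ROI P(CR)
    n_high_confidence: int          # correct-class probability >= 0.75
    n_outliers: int                 # correct-class probability < 0.5

    def predict_proba(self, pc1: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * np.asarray(pc1))))


def logistic_pc1(
    pca: PcaModel, cohorts: pd.Series, ridge: float = 0.0
) -> Lr1Model:
    """Fit P(CR | PC1); falls back to ridge 1.0 on complete separation.

    Reports per-ROI P(CR), the number of ROIs whose correct-class
    probability reaches 0.75, and the number of outliers (correct-class
    probability below 0.5).
    """
    cohorts = cohorts.reindex(pca.scores.index)
    y = (cohorts == "CR").to_numpy(dtype=int)
    if y.all() or not y.any():
        raise ValueError("both cohorts must be present to fit the model")
    x = pca.scores["PC1"].to_numpy()

    separation = False
    if ridge > 0:
        intercept, slope = _fit_ridge(x, y, ridge)
    else:
        fitted = _fit_mle(x, y)
        if fitted is None:
            separation = True
            logger.warning(
                "complete separation along PC1; refitting with ridge penalty 1.0"
            )
            ridge = 1.0
            intercept, slope = _fit_ridge(x, y, ridge)
        else:
            intercept, slope = fitted

    prob = 1.0 / (1.0 + np.exp(-(intercept + slope * x)))
    correct = np.where(y == 1, prob, 1.0 - prob)
    return Lr1Model(
        intercept=float(intercept),
        slope=float(slope),
        ridge=float(ridge),
        separation_flag=separation,
        probabilities=pd.Series(prob, index=pca.scores.index, name="p_cr"),
        n_high_confidence=int(np.sum(correct >= 0.75)),
        n_outliers=int(np.sum(correct < 0.5)),
    )


def _fit_mle(x: np.ndarray, y: np.ndarray):
    """Unpenalized logit MLE; ``None`` signals (quasi-)separation."""
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None
        if not res.mle_retvals.get("converged", False):
            return None
        params = np.asarray(res.params)
    scale = max(np.std(x), 1e-12)
    if abs(params[1]) * scale > _SLOPE_DIVERGENCE:
        return None
    return float(params[0]), float(params[1])


def _fit_ridge(x: np.ndarray, y: np.ndarray, ridge: float):
    # sklearn's C = 1 / lambda; the intercept is unpenalized
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
    clf.fit(x.reshape(-1, 1), y)
    return float(clf.intercept_[0]), float(clf.coef_[0, 0])


def correlation_network(
    features: pd.DataFrame,
    method: str = "spearman",
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise marker correlation edges with |r| >= threshold.

    Returns (edge list, constant columns whose correlations are undefined
    and recorded as missing). Spearman is the default; Pearson available.
    """
    if len(features) < 3:
        raise ValueError("correlation network requires >= 3 ROIs")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be spearman or pearson")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        logger.warning("constant column(s) %s: correlations recorded as missing",
                       constant)
    usable = [c for c in features.columns if c not in constant]
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            if method == "spearman":
                r = stats.spearmanr(features[a], features[b]).statistic
            else:
                r = stats.pearsonr(features[a], features[b]).statistic
            if np.isfinite(r) and abs(r) >= threshold:
                rows.append({"marker_a": a, "marker_b": b, "r": float(r)})
    edges = pd.DataFrame(rows, columns=["marker_a", "marker_b", "r"])
    return edges, constant
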