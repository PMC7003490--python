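"""Gene-expression learning: feature-matrix assembly, preprocessing,
elastic-net regression under nested Monte-Carlo cross-validation, and
OLS-based feature significance.

The regression solves

    beta_hat = argmin ||y - X beta||^2 + lambda [ alpha ||beta||_2^2
                                                  + (1 - alpha) ||beta||_1 ]

i.e. the user-facing mixing parameter ``alpha`` weights the *ridge* term and
``1 - alpha`` the lasso term.  Most implementations (glmnet, scikit-learn)
use the opposite convention, so internally ``l1_ratio = 1 - alpha`` is
passed to scikit-learn; the mapping is confined to this module.

Model selection is a ten-fold outer Monte-Carlo cross-validation (10
independent 80/20 train/test splits); within each training split a six-fold
inner CV picks ``alpha`` over a grid (0.0 .. 1.0, step 0.01 by default) and
``lambda`` over an automatic geometric path by minimum mean inner MSE.
Performance is the Spearman correlation on the held-out 20%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

__all__ = [
    "FEATURE_SETUPS",
    "default_alpha_grid",
    "build_feature_matrix",
    "preprocess",
    "FoldResult",
    "CVResult",
    "fit_elastic_net",
    "fit_elastic_net_cv",
    "evaluate",
    "ols_feature_pvalues",
]

FEATURE_SETUPS = (
    "Promoter:Peaks",
    "Promoter+Loops:Peaks",
    "Promoter+Loops:CPeaks",
    "Promoter:Peaks+TFs",
    "ExtendedFeatureSpace",
)

# l1_ratio=0 (pure ridge) has no automatic lambda path; the ridge end of the
# grid is represented by this floor instead.
_MIN_L1_RATIO = 0.01


def default_alpha_grid(step: float = 0.01) -> np.ndarray:
    """Ridge-weight grid 0.0 .. 1.0 inclusive (101 points at step 0.01)."""
    n = int(round(1.0 / step)) + 1
    return np.linspace(0.0, 1.0, n)


def _to_l1_ratio(alpha: np.ndarray | float) -> np.ndarray:
    """Map the ridge-weight convention to scikit-learn's l1_ratio."""
    return np.maximum(1.0 - np.asarray(alpha, dtype=float), _MIN_L1_RATIO)


def build_feature_matrix(
    setup: str,
    peak_features: pd.DataFrame,
    tf_scores: pd.DataFrame | None = None,
    tf_loop_scores: pd.DataFrame | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the design matrix for one feature setup.

    ``peak_features`` must carry columns pl, pc, ps, pl_star, pc_star,
    ps_star indexed by gene; TF score tables are genes x TFs.  Genes without
    loop links contribute zeros in loop columns.  Setups:

    * ``Promoter:Peaks`` — pl, pc, ps
    * ``Promoter+Loops:Peaks`` — pl, pc, ps, pl*, pc*, ps*
    * ``Promoter+Loops:CPeaks`` — columnwise sums pl+pl*, pc+pc*, ps+ps*
    * ``Promoter:Peaks+TFs`` — pl, pc, ps plus one column per promoter TF score
    * ``ExtendedFeatureSpace`` — all six peak columns plus promoter *and*
      loop TF-score columns per TF (suffixes ``:promoter`` / ``:loop``)
    """
    if setup not in FEATURE_SETUPS:
        raise ValueError(f"unknown feature setup {setup!r}; choose from {FEATURE_SETUPS}")
    idx = pd.Index(genes) if genes is not None else peak_features.index
    pf = peak_features.reindex(idx).fillna(0.0)

    if setup == "Promoter:Peaks":
        return pf[["pl", "pc", "ps"]].copy()
    if setup == "Promoter+Loops:Peaks":
        return pf[["pl", "pc", "ps", "pl_star", "pc_star", "ps_star"]].copy()
    if setup == "Promoter+Loops:CPeaks":
        out = pd.DataFrame(index=idx)
        out["pl"] = pf["pl"] + pf["pl_star"]
        out["pc"] = pf["pc"] + pf["pc_star"]
        out["ps"] = pf["ps"] + pf["ps_star"]
        return out
    if tf_scores is None:
        raise ValueError(f"setup {setup!r} requires TF-gene scores")
    prom = tf_scores.reindex(idx).fillna(0.0)
    if setup == "Promoter:Peaks+TFs":
        return pd.concat([pf[["pl", "pc", "ps"]], prom], axis=1)
    # ExtendedFeatureSpace
    if tf_loop_scores is None:
        raise ValueError("ExtendedFeatureSpace requires loop TF-gene scores")
    loop = tf_loop_scores.reindex(idx).fillna(0.0)
    prom = prom.rename(columns=lambda c: f"{c}:promoter")
    loop = loop.rename(columns=lambda c: f"{c}:loop")
    return pd.concat(
        [pf[["pl", "pc", "ps", "pl_star", "pc_star", "ps_star"]], prom, loop], axis=1
    )


def preprocess(
    X: pd.DataFrame, y: pd.Series
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """log(v + 1) on X and y, then centre to mean 0 / scale to unit variance.

    Zero-variance columns cannot be scaled and are dropped (their names are
    returned).  Negative entries are rejected.
    """
    if (X.to_numpy() < 0).any() or (y.to_numpy() < 0).any():
        raise ValueError("preprocess expects non-negative features and expression")
    Xl = np.log1p(X)
    yl = np.log1p(y)
    sd = Xl.std(axis=0, ddof=1)
    constant = Xl.nunique(axis=0) == 1  # sd of a constant column is only ~0 in floats
    dropped = list(Xl.columns[constant | (sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s): {dropped[:5]}...")
        Xl = Xl.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    Xp = (Xl - Xl.mean(axis=0)) / sd
    y_sd = yl.std(ddof=1)
    if y_sd == 0:
        raise ValueError("expression vector is constant after log transform")
    yp = (yl - yl.mean()) / y_sd
    return Xp, yp, dropped


@dataclass
class FoldResult:
    alpha: float  # ridge-weight convention
    lam: float  # scikit-learn penalty scale
    coef: pd.Series
    test_spearman: float
    test_mse: float
    per_gene_se: pd.Series
    train_index: np.ndarray
    test_index: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    seed: int
    feature_names: list[str]

    def coef_matrix(self) -> pd.DataFrame:
        """folds x features matrix of fitted coefficients."""
        return pd.DataFrame(
            [f.coef for f in self.folds], index=range(len(self.folds))
        ).fillna(0.0)

    @property
    def test_spearmans(self) -> np.ndarray:
        return np.array([f.test_spearman for f in self.folds])


def fit_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float
) -> np.ndarray:
    """Single elastic-net fit at fixed (alpha, lambda); lam=0 is exact OLS."""
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    model = ElasticNet(
        alpha=lam,
        l1_ratio=float(_to_l1_ratio(alpha)),
        fit_intercept=False,
        max_iter=50000,
        tol=1e-8,
    )
    model.fit(X, y)
    return model.coef_


def fit_elastic_net_cv(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_outer: int = 10,
    train_fraction: float = 0.8,
    n_inner: int = 6,
    alpha_grid: np.ndarray | None = None,
    n_lambda: int = 100,
) -> CVResult:
    """Nested Monte-Carlo cross-validated elastic net.

    Ten (by default) independent 80/20 splits; per split an inner six-fold
    CV selects (alpha, lambda) minimizing mean inner MSE, the model is refit
    on the full training split, and held-out predictions are scored.
    Deterministic in ``seed``.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = Xv.shape[0]
    if n <= n_inner:
        raise ValueError("need more samples than inner folds")
    l1_grid = sorted(set(float(v) for v in _to_l1_ratio(alpha_grid)))
    rng = np.random.default_rng(seed)
    folds: list[FoldResult] = []
    n_train = int(round(train_fraction * n))
    for k in range(n_outer):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        X_tr, y_tr = Xv[train_idx], yv[train_idx]
        X_te, y_te = Xv[test_idx], yv[test_idx]
        inner_cv = KFold(n_splits=n_inner, shuffle=True, random_state=int(seed * 1009 + k) % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = ElasticNetCV(
                l1_ratio=l1_grid,
                alphas=n_lambda,
                cv=inner_cv,
                fit_intercept=False,
                n_jobs=None,
                max_iter=5000,
            )
            cv.fit(X_tr, y_tr)
        alpha_paper = float(np.clip(1.0 - cv.l1_ratio_, 0.0, 1.0))
        coef = pd.Series(cv.coef_, index=X.columns)
        pred = X_te @ cv.coef_
        sp, mse, per_se = evaluate(pred, y_te)
        folds.append(
            FoldResult(
                alpha=alpha_paper,
                lam=float(cv.alpha_),
                coef=coef,
                test_spearman=sp,
                test_mse=mse,
                per_gene_se=pd.Series(per_se, index=X.index[test_idx]),
                train_index=train_idx,
                test_index=test_idx,
            )
        )
    return CVResult(folds=folds, seed=seed, feature_names=list(X.columns))


def evaluate(
    predictions: np.ndarray, truth: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """(Spearman, MSE, per-gene squared error) for held-out predictions.

    A constant prediction vector has no rank correlation; Spearman is
    returned as NaN in that case.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if predictions.size < 2:
        raise ValueError("need at least two observations to evaluate")
    se = (predictions - truth) ** 2
    mse = float(np.mean(se))
    if np.all(predictions == predictions[0]) or np.all(truth == truth[0]):
        warnings.warn("constant vector: Spearman undefined, reported as NaN")
        return float("nan"), mse, se
    rho = scipy.stats.spearmanr(predictions, truth).statistic
    return float(rho), mse, se


def ols_feature_pvalues(
    X: pd.DataFrame, y: pd.Series, nonzero_features: Sequence[str]
) -> pd.Series:
    """Per-feature partial F-test (1 df; squared-t) p-values from an OLS fit
    restricted to the features the elastic net kept.

    Rank-deficient selections are repaired by greedily dropping aliased
    columns (with a warning).
    """
    sel = [f for f in nonzero_features if f in X.columns]
    if not sel:
        return pd.Series(dtype=float)
    if len(sel) >= len(y):
        raise ValueError("more selected features than observations")
    Xs = X[sel].to_numpy(dtype=float)
    # drop aliased columns so the F-test is well defined
    keep: list[int] = []
    for j in range(Xs.shape[1]):
        cand = Xs[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < len(sel):
        warnings.warn(f"dropped {len(sel) - len(keep)} aliased column(s) from the OLS design")
    names = [sel[j] for j in keep]
    design = sm.add_constant(X[names].to_numpy(dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    return pd.Series(fit.pvalues[1:], index=names)
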