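"""Probabilistic classification, cross-validation and age regression.

Classification uses the SupCP marginal likelihood: for a held-out
participant each candidate class is substituted into the supervision row
(covariates kept at their observed values), Bayes' rule combines the
class-conditional likelihoods with training-fold priors, and the class
with the highest posterior is predicted.  Generalizability is assessed
with stratified k-fold cross-validation (k shrinks to the minority-class
size when that is below k); AUROC and Brier score are computed from the
pooled held-out posteriors.  Age regression feeds retained latent
factors to a suite of standard regressors with cross-validated
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn import ensemble, linear_model, neighbors, svm
from sklearn.metrics import brier_score_loss, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict

from tensoreeg.supcp import extract_factor_report, fit_supcp, marginal_log_likelihood
from tensoreeg.tensor import FeatureTensor, SupervisionMatrix


def posterior_class_probs(log_likelihoods: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Posterior class probabilities from per-class log-likelihoods.

    softmax(loglik + log prior), numerically stabilized.  Accepts a single
    row or an (n, k) array.  Ties in the resulting posteriors are broken
    toward the first class in canonical order by downstream argmax.
    """
    ll = np.atleast_2d(np.asarray(log_likelihoods, dtype=float))
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    if np.all(np.isneginf(ll)):
        raise ValueError("all class log-likelihoods are -inf")
    post = special.softmax(ll + np.log(priors)[None, :], axis=1)
    return post[0] if np.ndim(log_likelihoods) == 1 else post


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(random positive outranks random negative).

    Ties count one half.  Raises on single-class labels.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def brier(probs: np.ndarray, labels: np.ndarray) -> float:
    """Brier score: mean squared error of the positive-class probability."""
    return float(brier_score_loss(np.asarray(labels, dtype=int), np.asarray(probs, dtype=float)))


@dataclass
class CrossValResult:
    """Pooled held-out posteriors plus aggregate discrimination metrics."""

    table: pd.DataFrame  # participant, fold, label, posterior_pos, predicted
    auroc: float
    brier: float
    fold_sizes: list[int]
    per_fold_auroc: list[float]
    classes: tuple[str, str]  # (reference, positive)

    def recompute_metrics(self) -> tuple[float, float]:
        """AUROC / Brier recomputed from the serialized posterior table."""
        return (
            auroc(self.table["posterior_pos"], self.table["label"]),
            brier(self.table["posterior_pos"], self.table["label"]),
        )


def _n_splits(labels: np.ndarray, k: int) -> int:
    counts = np.bincount(labels.astype(int))
    minority = int(counts[counts > 0].min())
    return min(k, minority)


def crossval_classify(
    X: FeatureTensor,
    Y: SupervisionMatrix,
    rank: int = 30,
    k: int = 5,
    seed: int = 0,
    priors: str = "empirical",
    tol: float = 1e-5,
    max_iter: int = 200,
    average_folds: bool = False,
) -> CrossValResult:
    """Stratified cross-validated probabilistic classification.

    Parameters
    ----------
    X : unstandardized feature tensor (standardization constants are
        computed per training fold and applied to the held-out slices)
    Y : supervision matrix whose first column is the 0/1 class contrast;
        remaining columns are covariates, which stay fixed at observed
        values when candidate classes are scored
    rank : SupCP rank fitted within each fold
    k : requested folds; reduced to the minority-class size when smaller
    priors : 'empirical' (training-fold class proportions) or 'uniform'
    average_folds : additionally average per-fold AUROCs (the pooled
        estimate remains the headline number)
    """
    labels = Y.Y[:, 0].astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("classification requires exactly two classes in Y[:, 0]")
    n_splits = _n_splits(labels, k)
    if n_splits < 2:
        raise ValueError("each class needs at least 2 members for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    rows = []
    per_fold_auroc: list[float] = []
    fold_sizes: list[int] = []
    for fold, (train, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        x_train = X.subset(train)
        mean, sd = x_train.array.mean(axis=0), x_train.array.std(axis=0, ddof=0)
        x_train_std = x_train.standardized_with(mean, sd)
        model = fit_supcp(
            x_train_std, Y.subset(train), R=rank, tol=tol, max_iter=max_iter, seed=seed
        )
        if priors == "empirical":
            p1 = labels[train].mean()
        elif priors == "uniform":
            p1 = 0.5
        else:
            raise ValueError(f"unknown priors {priors!r}")
        prior_vec = np.array([1 - p1, p1])

        x_test_std = X.subset(test).standardized_with(mean, sd)
        for row_i, i in enumerate(test):
            y_i = Y.Y[i].copy()
            lls = []
            for cls in (0, 1):
                y_i[0] = cls
                lls.append(
                    marginal_log_likelihood(model, x_test_std.array[row_i], y_i)
                )
            post = posterior_class_probs(np.asarray(lls), prior_vec)
            rows.append(
                {
                    "participant": X.participants[i],
                    "fold": fold,
                    "label": int(labels[i]),
                    "posterior_pos": float(post[1]),
                    "predicted": int(np.argmax(post)),
                }
            )
        fold_sizes.append(len(test))
        fold_rows = [r for r in rows if r["fold"] == fold]
        fl = np.array([r["label"] for r in fold_rows])
        if average_folds and len(np.unique(fl)) == 2:
            per_fold_auroc.append(
                auroc(np.array([r["posterior_pos"] for r in fold_rows]), fl)
            )

    table = pd.DataFrame(rows)
    return CrossValResult(
        table=table,
        auroc=auroc(table["posterior_pos"].to_numpy(), table["label"].to_numpy()),
        brier=brier(table["posterior_pos"].to_numpy(), table["label"].to_numpy()),
        fold_sizes=fold_sizes,
        per_fold_auroc=per_fold_auroc,
        classes=("reference", Y.column_names[0]),
    )


#: default regression suite mirroring a standard scikit-learn benchmark set
def _default_regressors(seed: int) -> dict:
    return {
        "KNN": neighbors.KNeighborsRegressor(n_neighbors=5),
        "Linear regression": linear_model.LinearRegression(),
        "Random Forest": ensemble.RandomForestRegressor(
            n_estimators=200, random_state=seed
        ),
        "Gradient Boost": ensemble.GradientBoostingRegressor(random_state=seed),
        "SVM rbf": svm.SVR(kernel="rbf"),
        "SVM linear": svm.SVR(kernel="linear"),
    }


def age_regression(
    latent_features: np.ndarray,
    ages: np.ndarray,
    k: int = 5,
    seed: int = 0,
    regressors: dict | None = None,
) -> pd.DataFrame:
    """Cross-validated age prediction from retained latent factors.

    Returns one row per regressor with the cross-validated correlation
    ``r``, coefficient of determination ``r2`` (squared correlation of
    predicted vs true, matching the convention of reporting paired
    r / r^2), and mean absolute error in the age unit supplied.

    Raises on degenerate inputs (no features, constant features/ages).
    """
    z = np.asarray(latent_features, dtype=float)
    ages = np.asarray(ages, dtype=float).ravel()
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] == 0:
        raise ValueError("no retained latent factors; nothing to regress on")
    if np.allclose(z.std(axis=0), 0):
        raise ValueError("latent features are constant; regression undefined")
    if np.std(ages) == 0:
        raise ValueError("outcome ages are constant")
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for name, reg in (regressors or _default_regressors(seed)).items():
        pred = cross_val_predict(reg, z, ages, cv=cv)
        if np.std(pred) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(pred, ages)
        rows.append(
            {
                "regressor": name,
                "r": float(r),
                "r2": float(r**2),
                "p": float(p),
                "mae": float(np.mean(np.abs(pred - ages))),
            }
        )
    return pd.DataFrame(rows)


def latent_age_features(X: FeatureTensor, ages: np.ndarray, rank: int = 30,
                        threshold: float = 0.2, seed: int = 0,
                        tol: float = 1e-5, max_iter: int = 200):
    """Fit SupCP supervised by age alone and return the retained factors.

    Convenience wrapper for the age-validation analysis: the supervision
    matrix is the (centered) age vector, factors are ranked by |r| with
    age and those above the threshold are returned as features.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    y = np.column_stack([np.ones_like(ages), ages - ages.mean()])
    model = fit_supcp(X, y, R=rank, tol=tol, max_iter=max_iter, seed=seed)
    report = extract_factor_report(model, ages, threshold=threshold)
    if not report.retained.any():
        raise ValueError(
            "no latent factor exceeds the |r| threshold; lower the threshold "
            "or increase the rank"
        )
    return report.retained_weights, report
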