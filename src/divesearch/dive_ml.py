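"""Supervised dive prediction from track metrics.

A gradient-boosted tree classifier (logistic loss, shallow trees) predicts
whether a fix carries at least one dive from step length, speed, |turning
angle|, local solar hour and tortuosity. Dives are rare, so no resampling
or reweighting is applied; instead the operating point is the ROC threshold
maximizing Youden's J on bootstrap held-out predictions. Evaluation is a
2x2 confusion matrix at that threshold, Cohen's kappa and dive recall, on a
stratified 25% hold-out (or on another colony's data for cross-colony
transfer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

FEATURES = ("step_len", "speed", "abs_turn", "hour", "tortuosity")

DEFAULT_GRID = (
    {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
    {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.05},
)


def build_feature_table(traj: pd.DataFrame, matched_dives: pd.DataFrame) -> pd.DataFrame:
    """Per-fix features and dive labels over valid, fully-defined fixes.

    Rows with any undefined metric are dropped (count retained in
    ``attrs['n_dropped']``); a fix is labeled 1 if at least one matched dive
    points at it. Hour of day is local solar hour (UTC + lon/15), 0-23.
    """
    ok = traj["valid"].to_numpy(bool) if "valid" in traj.columns else np.ones(len(traj), bool)
    hour = (
        np.floor(
            (traj["t"].to_numpy(float) / 3600.0 + traj["lon"].to_numpy(float) / 15.0)
        ).astype(int)
        % 24
    )
    tbl = pd.DataFrame(
        {
            "step_len": traj["step_len"].to_numpy(float),
            "speed": traj["speed"].to_numpy(float),
            "abs_turn": np.abs(traj["turn"].to_numpy(float)),
            "hour": hour,
            "tortuosity": traj["tortuosity"].to_numpy(float),
        }
    )
    label = np.zeros(len(traj), dtype=int)
    fi = matched_dives.loc[matched_dives["matched"], "fix_index"].to_numpy(int)
    label[fi] = 1
    tbl["dive"] = label
    defined = ok & np.isfinite(tbl[list(FEATURES)].to_numpy(float)).all(axis=1)
    out = tbl[defined].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~defined).sum())
    return out


def split_train_test(tbl: pd.DataFrame, frac: float = 0.75, random_state: int = 0):
    """Stratified-by-class random split into (train, test)."""
    classes = tbl["dive"].unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    train, test = train_test_split(
        tbl, train_size=frac, stratify=tbl["dive"], random_state=random_state
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


class DiveClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted dive classifier with bootstrap-tuned hyperparameters.

    ``fit`` scores each candidate configuration by mean out-of-bag AUROC
    over ``n_resamples`` bootstrap resamples, refits the winner on the full
    training set, and fixes the decision threshold at the Youden-J optimum
    of the pooled out-of-bag predictions. Fitted attributes: ``model_``,
    ``best_params_``, ``threshold_``, ``cv_auroc_``.
    """

    def __init__(self, n_resamples: int = 500, grid=DEFAULT_GRID, random_state: int = 0):
        self.n_resamples = n_resamples
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame) and "dive" in X.columns:
            y = X["dive"].to_numpy(int)
            X = X[list(FEATURES)].to_numpy(float)
        else:
            X = np.asarray(X, float)
            y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data has a single class")
        rng = np.random.default_rng(self.random_state)
        n = len(y)

        scores = []
        oob_pred_best = None
        for ci, params in enumerate(self.grid):
            aurocs = []
            oob_scores = np.full(n, np.nan)
            oob_counts = np.zeros(n)
            oob_sums = np.zeros(n)
            for b in range(self.n_resamples):
                idx = rng.integers(0, n, size=n)
                oob = np.setdiff1d(np.arange(n), idx)
                if len(np.unique(y[idx])) < 2 or len(np.unique(y[oob])) < 2:
                    continue
                clf = GradientBoostingClassifier(
                    random_state=int(rng.integers(2**31)), **params
                )
                clf.fit(X[idx], y[idx])
                p = clf.predict_proba(X[oob])[:, 1]
                aurocs.append(roc_auc_score(y[oob], p))
                oob_sums[oob] += p
                oob_counts[oob] += 1
            covered = oob_counts > 0
            oob_scores[covered] = oob_sums[covered] / oob_counts[covered]
            scores.append(np.mean(aurocs) if aurocs else -np.inf)
            if ci == int(np.argmax(scores)):
                oob_pred_best = oob_scores
        best = int(np.argmax(scores))
        self.cv_auroc_ = float(scores[best])
        self.best_params_ = dict(self.grid[best])

        self.model_ = GradientBoostingClassifier(
            random_state=self.random_state, **self.best_params_
        )
        self.model_.fit(X, y)

        covered = np.isfinite(oob_pred_best)
        if covered.sum() > 1 and len(np.unique(y[covered])) == 2:
            fpr, tpr, thr = roc_curve(y[covered], oob_pred_best[covered])
            self.threshold_ = float(thr[np.argmax(tpr - fpr)])
        else:
            self.threshold_ = 0.5
        self.threshold_ = float(np.clip(self.threshold_, 1e-6, 1 - 1e-6))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURES)].to_numpy(float)
        return self.model_.predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold_).astype(int)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def kappa_from_confusion(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from 2x2 counts (chance agreement from the marginals)."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pred_pos = (cm.tp + cm.fp) / n
    act_pos = (cm.tp + cm.fn) / n
    pe = pred_pos * act_pos + (1 - pred_pos) * (1 - act_pos)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def recall_from_confusion(cm: ConfusionMatrix) -> float:
    """Dive-class recall as a percentage."""
    denom = cm.tp + cm.fn
    return 100.0 * cm.tp / denom if denom else np.nan


def evaluate_dive_model(model: DiveClassifier, test: pd.DataFrame):
    """Confusion matrix at the fitted threshold, kappa and dive recall (%).

    ``test`` may come from the training colony's hold-out or from another
    colony entirely (cross-colony transfer).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test["dive"].to_numpy(int)
    pred = model.predict(test)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )
    return cm, kappa_from_confusion(cm), recall_from_confusion(cm)
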