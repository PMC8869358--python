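"""Classification QSAR: under-sampling ensembles, metrics and consensus.

Models predict the active-antagonist vs inactive outcome from the
selected descriptors. Because the screen is heavily imbalanced, each
model is an ensemble of five sub-models: the training inactives are
partitioned into five folds, each topped up by seeded sampling to a 75%
inactive / 25% active ratio against the full training-active set, so the
union of the sub-model inactive sets covers every training inactive.
Hyperparameters maximize 10-fold cross-validated Matthews correlation
(MCC); performance is reported as mean +/- SD over the five sub-models
for cross-validation, fitting (resubstitution) and the held-out test
split. The ensemble probability is the mean sub-model probability; a
consensus model averages the RF and DNN ensemble probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import QSARError

ALGORITHMS = ("CART", "NN", "DNN", "SVM_linear", "SVM_radial", "SVM_sigmoid", "RF", "LDA")


@dataclass
class Metrics:
    TP: int
    TN: int
    FP: int
    FN: int
    SE: float
    SP: float
    Q: float
    Qb: float
    MCC: float

    def as_dict(self) -> dict[str, float]:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
                "SE": self.SE, "SP": self.SP, "Q": self.Q, "Qb": self.Qb, "MCC": self.MCC}


def compute_metrics(y_true, y_pred) -> Metrics:
    """Confusion-matrix metric suite.

    SE = TP/(TP+FN), SP = TN/(TN+FP), Q = (TP+TN)/n, Qb = (SE+SP)/2 and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC
    defined as 0 when any denominator factor vanishes. SE/SP are 0 when
    their class is absent.
    """
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.size == 0:
        raise QSARError("empty prediction vector")
    if y_true.shape != y_pred.shape:
        raise QSARError("y_true and y_pred length mismatch")
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    q = (tp + tn) / (tp + tn + fp + fn)
    qb = (se + sp) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return Metrics(tp, tn, fp, fn, se, sp, q, qb, float(mcc))


def _mcc_score(y_true, y_pred) -> float:
    return compute_metrics(y_true, y_pred).MCC


MCC_SCORER = make_scorer(_mcc_score)


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    inactive_subsets: list[list[str]]
    seed: int

    @property
    def n_submodels(self) -> int:
        return len(self.inactive_subsets)


def make_split(labels: pd.Series, test_frac: float = 0.15, n_subsets: int = 5,
               active_ratio: float = 0.25, seed: int = 0) -> SplitPlan:
    """Stratified train/test split plus the under-sampling plan.

    Per class, round((1-test_frac) * n) chemicals go to training (549
    actives at 15% held out -> 467 training actives). Training inactives
    are partitioned into ``n_subsets`` folds — so their union covers the
    full training set — and each fold is topped up by seeded sampling
    from its complement until it holds (1-active_ratio)/active_ratio
    times the training-active count.
    """
    labels = labels.astype(bool)
    rng = np.random.default_rng(seed)
    n_act, n_inact = int(labels.sum()), int((~labels).sum())
    if min(n_act, n_inact) < 5:
        raise QSARError("each class needs at least 5 chemicals")

    train_ids, test_ids = [], []
    for cls in (True, False):
        ids = np.asarray(labels.index[labels == cls])
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round((1.0 - test_frac) * len(ids)))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])

    train_lab = labels.loc[train_ids]
    train_act = train_lab.index[train_lab].tolist()
    train_inact = np.asarray(train_lab.index[~train_lab])
    target = int(round(len(train_act) * (1.0 - active_ratio) / active_ratio))

    shuffled = train_inact[rng.permutation(len(train_inact))]
    folds = np.array_split(shuffled, n_subsets)
    subsets = []
    for fold in folds:
        fold = list(fold)
        complement = np.asarray([i for i in shuffled if i not in set(fold)])
        need = target - len(fold)
        if need > 0 and len(complement):
            extra = complement[rng.choice(len(complement),
                                          size=min(need, len(complement)), replace=False)]
            fold = fold + list(extra)
        subsets.append(fold)
    return SplitPlan(list(train_ids), list(test_ids), subsets, seed)


def default_grid(algorithm: str) -> tuple:
    """(estimator factory, hyperparameter grid) per algorithm name."""
    grids = {
        "CART": (lambda seed: DecisionTreeClassifier(random_state=seed),
                 {"ccp_alpha": [0.001, 0.01]}),
        "NN": (lambda seed: MLPClassifier(random_state=seed, max_iter=500),
               {"hidden_layer_sizes": [(8,), (32,)]}),
        "DNN": (lambda seed: MLPClassifier(hidden_layer_sizes=(64, 32), random_state=seed,
                                           early_stopping=True, max_iter=300),
                {"alpha": [1e-4, 1e-3]}),
        "SVM_linear": (lambda seed: SVC(kernel="linear", probability=True, random_state=seed),
                       {"C": [0.1, 1, 10]}),
        "SVM_radial": (lambda seed: SVC(kernel="rbf", probability=True, random_state=seed),
                       {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]}),
        "SVM_sigmoid": (lambda seed: SVC(kernel="sigmoid", probability=True, random_state=seed),
                        {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]}),
        "RF": (lambda seed: RandomForestClassifier(random_state=seed),
               {"n_estimators": [100, 500], "max_features": ["sqrt", 0.33]}),
        "LDA": (lambda seed: LinearDiscriminantAnalysis(), {}),
    }
    if algorithm not in grids:
        raise QSARError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return grids[algorithm]


@dataclass
class QSARBundle:
    algorithm: str
    models: list                     # fitted estimators, one per sub-model
    scaler: StandardScaler
    feature_names: list[str]
    decision_threshold: float
    metrics: dict[str, pd.DataFrame] = field(default_factory=dict)
    best_params: list[dict] = field(default_factory=list)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise QSARError("descriptor manifest mismatch")
        return self.scaler.transform(X.to_numpy(dtype=float))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Ensemble probability of the active class (mean over sub-models)."""
        Z = self._check(X)
        probs = [m.predict_proba(Z)[:, list(m.classes_).index(True)] for m in self.models]
        return np.mean(probs, axis=0)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X) >= self.decision_threshold

    def metric_summary(self) -> pd.DataFrame:
        """mean +/- SD of each criterion over sub-models, per evaluation split."""
        rows = {}
        for split, df in self.metrics.items():
            rows[split] = {c: f"{df[c].mean():.3f} (+/-{df[c].std(ddof=0):.3f})"
                           for c in ("Q", "Qb", "SP", "SE", "MCC")}
        return pd.DataFrame(rows).T


def train_bundle(X: pd.DataFrame, labels: pd.Series, algorithm: str,
                 plan: SplitPlan, cv_folds: int = 10, grid: dict | None = None,
                 undersample: bool = True, seed: int = 0,
                 decision_threshold: float = 0.5) -> QSARBundle:
    """Train the under-sampling ensemble for one algorithm.

    Descriptors are z-scored with training-set statistics only. For each
    sub-model, a grid search maximizing ``cv_folds``-fold CV MCC selects
    hyperparameters; CV, fitting and test metrics are recorded per
    sub-model. With ``undersample=False`` a single model is trained on
    the full training split (the protocol used when the active fraction
    is already high).
    """
    labels = labels.astype(bool)
    X = X.loc[:, :]
    if X.isna().any().any():
        raise QSARError("descriptor matrix contains NaN")
    if (X.std(ddof=0) == 0).any():
        raise QSARError("degenerate (constant) descriptor column")

    factory, default = default_grid(algorithm)
    grid = default if grid is None else grid
    scaler = StandardScaler().fit(X.loc[plan.train_ids].to_numpy(dtype=float))

    def transform(ids):
        return scaler.transform(X.loc[ids].to_numpy(dtype=float))

    train_act = [i for i in plan.train_ids if labels[i]]
    sub_sets = ([train_act + list(s) for s in plan.inactive_subsets]
                if undersample else [list(plan.train_ids)])
    seeds = np.random.SeedSequence(seed).generate_state(len(sub_sets)) % (2 ** 31)

    models, best_params = [], []
    cv_rows, fit_rows, test_rows = [], [], []
    Zte, yte = transform(plan.test_ids), labels.loc[plan.test_ids].to_numpy()
    for sub_ids, sub_seed in zip(sub_sets, seeds):
        Ztr = transform(sub_ids)
        ytr = labels.loc[sub_ids].to_numpy()
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(sub_seed))
        est = factory(int(sub_seed))
        if grid:
            search = GridSearchCV(est, grid, scoring=MCC_SCORER, cv=cv, n_jobs=1)
            search.fit(Ztr, ytr)
            best = search.best_estimator_
            best_params.append(search.best_params_)
        else:
            best = est.fit(Ztr, ytr)
            best_params.append({})
        y_cv = cross_val_predict(best, Ztr, ytr, cv=cv)
        cv_rows.append(compute_metrics(ytr, y_cv).as_dict())
        fit_rows.append(compute_metrics(ytr, best.predict(Ztr)).as_dict())
        test_rows.append(compute_metrics(yte, best.predict(Zte)).as_dict())
        models.append(best)

    metrics = {"cv": pd.DataFrame(cv_rows), "fit": pd.DataFrame(fit_rows),
               "test": pd.DataFrame(test_rows)}
    return QSARBundle(algorithm, models, scaler, list(X.columns),
                      decision_threshold, metrics, best_params)


def consensus_predict(bundles: dict[str, QSARBundle], X: pd.DataFrame,
                      threshold: float = 0.5) -> pd.DataFrame:
    """Average the ensemble probabilities of two bundles (e.g. RF and DNN).

    A probability at or above the threshold is called active (ties go to
    the active call). Bundles must share one descriptor manifest.
    """
    if len(bundles) < 2:
        raise QSARError("consensus requires at least two bundles")
    manifests = {tuple(b.feature_names) for b in bundles.values()}
    if len(manifests) != 1:
        raise QSARError("descriptor manifest mismatch between bundles")
    probs = {name: b.predict_proba(X) for name, b in bundles.items()}
    consensus = np.mean(list(probs.values()), axis=0)
    out = pd.DataFrame(probs, index=X.index)
    out["consensus_prob"] = consensus
    out["call"] = consensus >= threshold
    return out
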