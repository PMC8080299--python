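"""Feature assembly, kNN imputation, and the 18-model classification grid.

Three algorithms (random forest, logistic regression, gradient boosting)
x three feature sets (activity bouts only, sociodemographic only,
combined) x two training sets (T2D vs Norm-0, T2D vs Norm-2) = 18 models.
Headline metric: stratified 10-fold cross-validated AUC (mean over folds,
normal-approximation 95% CI); a stratified 80:20 holdout evaluation is
run alongside and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .bouts import FEATURE_NAMES
from .synth import CATEGORICAL_LEVELS, NUMERIC_DEMO_COLS

ALGORITHMS: tuple[str, ...] = ("random_forest", "logistic_regression", "gradient_boosting")
FEATURE_SETS: tuple[str, ...] = ("activity_only", "socio_only", "combined")


def make_model(algorithm: str, seed: int = 0):
    """Library-default classifiers with fixed seeds; logistic regression is
    wrapped with a standardiser fitted on the training folds only."""
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        )
    if algorithm == "gradient_boosting":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def impute_knn(table: pd.DataFrame, k: int = 5, id_col: str = "participant_id") -> pd.DataFrame:
    """k-nearest-neighbour imputation of the demographics table.

    Numeric cells: mean of the k nearest rows (NaN-aware Euclidean distance
    on z-scored numeric columns, missing dimensions skipped pairwise with
    rescaling). Categorical cells: mode among the k nearest rows that have
    the value, ties broken lexicographically. Observed cells are unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.copy()
    num_cols = [c for c in out.columns if c != id_col and pd.api.types.is_numeric_dtype(out[c])]
    cat_cols = [c for c in out.columns if c not in num_cols and c != id_col]

    num = out[num_cols].to_numpy(dtype=float)
    if np.isnan(num).all(axis=0).any():
        bad = [c for c, allna in zip(num_cols, np.isnan(num).all(axis=0)) if allna]
        raise ValueError(f"column(s) entirely missing: {bad}")
    mu = np.nanmean(num, axis=0)
    sd = np.nanstd(num, axis=0)
    sd[sd == 0] = 1.0
    z = (num - mu) / sd
    zf = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(z)
    out[num_cols] = zf * sd + mu

    if cat_cols and out[cat_cols].isna().to_numpy().any():
        dist = nan_euclidean_distances(z, z)
        np.fill_diagonal(dist, np.inf)
        for col in cat_cols:
            vals = out[col]
            missing = np.flatnonzero(vals.isna().to_numpy())
            observed = ~vals.isna().to_numpy()
            for i in missing:
                order = np.argsort(dist[i], kind="stable")
                donors = [j for j in order if observed[j] and np.isfinite(dist[i, j])][:k]
                # a row with no usable distances falls back to the global
                # mode, mirroring the column-mean fallback on the numeric side
                donor_vals = vals.iloc[donors] if donors else vals.dropna()
                counts = donor_vals.value_counts()
                best = sorted(counts.index[counts == counts.max()])[0]
                out.iat[i, out.columns.get_loc(col)] = best
    return out


def encode_demographics(demo: pd.DataFrame, id_col: str = "participant_id") -> pd.DataFrame:
    """Numeric design matrix for the sociodemographic variables: numeric
    columns as-is plus one-hot indicators with fixed, documented levels."""
    df = demo.set_index(id_col) if id_col in demo.columns else demo.copy()
    parts = [df[list(NUMERIC_DEMO_COLS)].astype(float)]
    for col, levels in CATEGORICAL_LEVELS.items():
        for lev in levels:
            parts.append((df[col] == lev).astype(float).rename(f"{col}_{lev}"))
    return pd.concat(parts, axis=1)


def assemble_features(
    activity: pd.DataFrame,
    demo: pd.DataFrame,
    feature_set: str,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Model matrix for one feature-set specification, id-aligned."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    demo_x = encode_demographics(demo)
    act = activity if activity.index.name == "participant_id" else activity.set_index(
        "participant_id"
    )
    if ids is None:
        ids = sorted(set(act.index) & set(demo_x.index))
    missing_act = set(ids) - set(act.index)
    missing_demo = set(ids) - set(demo_x.index)
    if feature_set in ("activity_only", "combined") and missing_act:
        raise KeyError(f"participants without activity features: {sorted(missing_act)[:5]}")
    if feature_set in ("socio_only", "combined") and missing_demo:
        raise KeyError(f"participants without demographics: {sorted(missing_demo)[:5]}")
    if feature_set == "activity_only":
        return act.loc[ids, FEATURE_NAMES]
    if feature_set == "socio_only":
        return demo_x.loc[ids]
    return pd.concat([act.loc[ids, FEATURE_NAMES], demo_x.loc[ids]], axis=1)


@dataclass
class EvalResult:
    """Cross-validated and holdout metrics for one grid cell."""

    algorithm: str
    training_set: str
    feature_set: str
    n: int
    seed: int
    auc_mean: float
    auc_ci: tuple[float, float]
    fold_aucs: np.ndarray = field(repr=False)
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    roc: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    mode: str = "cv"

    @property
    def auc_se(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1) / np.sqrt(len(self.fold_aucs)))

    def to_row(self) -> dict:
        return {
            "training_set": self.training_set,
            "feature_set": self.feature_set,
            "algorithm": self.algorithm,
            "mode": self.mode,
            "n": self.n,
            "auc": self.auc_mean,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "precision_pos": self.precision.get("positive", np.nan),
            "precision_neg": self.precision.get("negative", np.nan),
            "recall_pos": self.recall.get("positive", np.nan),
            "recall_neg": self.recall.get("negative", np.nan),
            "f1_pos": self.f1.get("positive", np.nan),
            "f1_neg": self.f1.get("negative", np.nan),
        }


def _fold_metrics(y_true, prob):
    pred = (prob >= 0.5).astype(int)
    auc = roc_auc_score(y_true, prob)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, pred, labels=[1, 0], zero_division=0
    )
    return auc, prec, rec, f1


def crossval_eval(
    X, y, algorithm: str, folds: int = 10, seed: int = 0, tags: dict | None = None
) -> EvalResult:
    """Stratified k-fold evaluation; per-fold AUC/precision/recall/F1 on the
    held-out fold, with the mean and a normal-approximation 95% CI over
    folds; ROC points pooled from out-of-fold probabilities."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, precs, recs, f1s = [], [], [], []
    oof_prob = np.empty(len(yv))
    for tr, te in skf.split(Xv, yv):
        model = make_model(algorithm, seed)
        model.fit(Xv[tr], yv[tr])
        prob = model.predict_proba(Xv[te])[:, 1]
        oof_prob[te] = prob
        auc, prec, rec, f1 = _fold_metrics(yv[te], prob)
        aucs.append(auc)
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    aucs = np.array(aucs)
    se = np.std(aucs, ddof=1) / np.sqrt(folds)
    mean = float(aucs.mean())
    prec_m, rec_m, f1_m = (np.mean(a, axis=0) for a in (precs, recs, f1s))
    fpr, tpr, _ = roc_curve(yv, oof_prob)
    tags = tags or {}
    return EvalResult(
        algorithm=algorithm,
        training_set=tags.get("training_set", ""),
        feature_set=tags.get("feature_set", ""),
        n=len(yv),
        seed=seed,
        auc_mean=mean,
        auc_ci=(mean - 1.96 * se, mean + 1.96 * se),
        fold_aucs=aucs,
        precision={"positive": prec_m[0], "negative": prec_m[1]},
        recall={"positive": rec_m[0], "negative": rec_m[1]},
        f1={"positive": f1_m[0], "negative": f1_m[1]},
        roc=(fpr, tpr),
        mode="cv",
    )


def holdout_eval(
    X, y, algorithm: str, train_fraction: float = 0.8, seed: int = 0, tags: dict | None = None
) -> EvalResult:
    """Single stratified train/test split (default 80:20)."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=int)
    Xtr, Xte, ytr, yte = train_test_split(
        Xv, yv, train_size=train_fraction, stratify=yv, random_state=seed
    )
    model = make_model(algorithm, seed)
    model.fit(Xtr, ytr)
    prob = model.predict_proba(Xte)[:, 1]
    auc, prec, rec, f1 = _fold_metrics(yte, prob)
    fpr, tpr, _ = roc_curve(yte, prob)
    tags = tags or {}
    return EvalResult(
        algorithm=algorithm,
        training_set=tags.get("training_set", ""),
        feature_set=tags.get("feature_set", ""),
        n=len(yv),
        seed=seed,
        auc_mean=float(auc),
        auc_ci=(np.nan, np.nan),
        fold_aucs=np.array([auc]),
        precision={"positive": prec[0], "negative": prec[1]},
        recall={"positive": rec[0], "negative": rec[1]},
        f1={"positive": f1[0], "negative": f1[1]},
        roc=(fpr, tpr),
        mode="holdout",
    )


def run_grid(
    training_sets,
    activity: pd.DataFrame,
    demo: pd.DataFrame,
    algorithms: tuple[str, ...] = ALGORITHMS,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    folds: int = 10,
    seed: int = 0,
    holdout: bool = False,
    train_fraction: float = 0.8,
) -> list[EvalResult]:
    """The full classification grid in fixed order: training set (TS1, TS2)
    -> feature set -> algorithm. With both training sets, three feature
    sets and three algorithms this emits exactly 18 cross-validated
    results (plus 18 holdout results when ``holdout=True``)."""
    results: list[EvalResult] = []
    for ts in training_sets:
        ids = ts.ids
        y = ts.y
        for fs in feature_sets:
            try:
                X = assemble_features(activity, demo, fs, ids=ids)
            except KeyError as exc:
                raise RuntimeError(f"grid cell ({ts.tag}, {fs}) failed: {exc}") from exc
            for algo in algorithms:
                tags = {"training_set": ts.tag, "feature_set": fs}
                try:
                    results.append(crossval_eval(X, y, algo, folds=folds, seed=seed, tags=tags))
                    if holdout:
                        results.append(
                            holdout_eval(
                                X, y, algo, train_fraction=train_fraction, seed=seed, tags=tags
                            )
                        )
                except Exception as exc:
                    raise RuntimeError(
                        f"grid cell ({ts.tag}, {fs}, {algo}) failed: {exc}"
                    ) from exc
    return results


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def auc_pivot(results: list[EvalResult], mode: str = "cv") -> pd.DataFrame:
    """AUC summary with algorithms as rows and (feature set, training set)
    as columns."""
    df = results_table([r for r in results if r.mode == mode])
    return df.pivot_table(
        index="algorithm", columns=["feature_set", "training_set"], values="auc"
    )
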