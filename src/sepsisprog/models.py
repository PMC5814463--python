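"""Re-trainable parametrized mortality predictors.

The two parametrized model families used alongside the difference-of-
means scores: elastic-net penalized logistic regression and a random
forest.  Both follow the study's two-phase design — a feature-selection
phase combining per-cohort differential-expression statistics across all
discovery cohorts, then a model-construction phase — and an ensemble
combiner that averages within-cohort rank-normalized model outputs.

The originally published fitted weights are not reproduced here (they
were never printed); the architectures are re-trainable on any
discovery collection with recorded hyperparameters and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import ExpressionMatrix, SampleTable
from .scoring import ScoreVector

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelection",
    "TrainedModel",
    "select_features",
    "fit_model",
    "predict",
    "ensemble_predict",
    "save_model",
    "load_model",
]


@dataclass
class FeatureSelection:
    """Genes passing the cross-cohort differential-expression screen."""

    combined_z: pd.Series          # per-gene Stouffer-combined z
    selected: list[str]
    z_threshold: float
    cohorts_used: list[str]
    cohorts_excluded: list[str] = field(default_factory=list)


def _welch_z(values: np.ndarray, dead: np.ndarray) -> np.ndarray:
    """Per-gene Welch t (non-survivor minus survivor) as a normal z-score."""
    x1 = values[:, dead == 1]
    x0 = values[:, dead == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    t = np.where(np.isfinite(t), t, 0.0)
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    # map through the t tail to the standard-normal quantile with the
    # same upper-tail probability; sign restored afterwards
    sf = stats.t.sf(np.abs(t), df)
    z_mag = stats.norm.isf(sf)
    z_mag = np.where(np.isfinite(z_mag), z_mag, 38.0)  # tail underflow
    return np.sign(t) * z_mag


def select_features(cohorts: list[tuple[ExpressionMatrix, SampleTable]],
                    z_threshold: float = 4.0) -> FeatureSelection:
    """Cross-cohort differential-expression feature screen.

    Per cohort each gene gets a Welch t-statistic (non-survivors minus
    survivors) converted to a z-score; cohort z-scores are combined by
    Stouffer's method weighted by the square root of cohort size, and
    genes with ``|combined z| >= z_threshold`` are selected.  Cohorts
    with a single outcome class are excluded with a warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need >=2 cohorts for feature selection")
    per_cohort: list[pd.Series] = []
    weights: list[float] = []
    used: list[str] = []
    excluded: list[str] = []
    for i, (em, st) in enumerate(cohorts):
        label = em.cohort_id or f"cohort_{i}"
        outcome = st.outcome().reindex(em.sample_ids)
        keep = outcome.notna()
        y = outcome[keep].to_numpy().astype(int)
        if keep.sum() == 0 or y.min() == y.max():
            logger.warning("select_features: cohort %s has a single outcome "
                           "class; excluded", label)
            excluded.append(label)
            continue
        values = em.data.loc[:, keep.to_numpy()].to_numpy(dtype=float)
        z = _welch_z(values, y)
        per_cohort.append(pd.Series(z, index=em.data.index))
        weights.append(np.sqrt(len(y)))
        used.append(label)
    if not per_cohort:
        raise ValueError("all cohorts excluded (single outcome class)")
    zmat = pd.concat(per_cohort, axis=1)
    if zmat.isna().any().any():
        raise ValueError("cohorts must share a common gene universe")
    w = np.asarray(weights)
    combined = (zmat.to_numpy() * w).sum(axis=1) / np.sqrt((w ** 2).sum())
    combined = pd.Series(combined, index=zmat.index, name="combined_z")
    selected = sorted(combined.index[np.abs(combined) >= z_threshold])
    return FeatureSelection(combined_z=combined, selected=selected,
                            z_threshold=z_threshold, cohorts_used=used,
                            cohorts_excluded=excluded)


@dataclass
class TrainedModel:
    """A fitted predictor plus everything needed to reproduce it."""

    kind: str                      # "penalized_lr" | "random_forest"
    feature_genes: list[str]
    estimator: object
    seed: int
    training_meta: dict = field(default_factory=dict)
    training_scores: pd.Series | None = None


DEFAULT_HYPER = {
    "penalized_lr": {"l1_ratio": 0.5, "cv_folds": 5, "n_Cs": 20},
    "random_forest": {"n_estimators": 1000, "max_features": "sqrt"},
}


def _select_penalty(X: np.ndarray, y: np.ndarray, hp: dict, seed: int) -> tuple[float, np.ndarray]:
    """Pick the elastic-net penalty by stratified CV maximizing AUROC.

    Among penalties whose mean CV AUROC is within one standard error of
    the best, the strongest (smallest C) is chosen — the usual
    one-standard-error rule, which favours sparse models.
    """
    from sklearn.metrics import roc_auc_score

    Cs = np.logspace(-3, 2, hp["n_Cs"])
    n_folds = max(2, min(hp["cv_folds"], int(np.bincount(y).min())))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.full((n_folds, len(Cs)), np.nan)
    for f, (tr, te) in enumerate(cv.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Ztr, Zte = scaler.transform(X[tr]), scaler.transform(X[te])
        if y[te].min() == y[te].max():
            continue
        for j, C in enumerate(Cs):
            lr = LogisticRegression(C=C, l1_ratio=hp["l1_ratio"],
                                    solver="saga", class_weight="balanced",
                                    max_iter=5000, random_state=seed)
            lr.fit(Ztr, y[tr])
            scores[f, j] = roc_auc_score(y[te], lr.predict_proba(Zte)[:, 1])
    mean = np.nanmean(scores, axis=0)
    n_eff = np.sum(~np.isnan(scores), axis=0)
    se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    best = int(np.nanargmax(mean))
    threshold = mean[best] - se[best]
    chosen = next(j for j in range(len(Cs)) if mean[j] >= threshold)
    return float(Cs[chosen]), mean


def fit_model(kind: str, m: ExpressionMatrix, t: SampleTable,
              features: list[str], hyper: dict | None = None,
              seed: int = 0) -> TrainedModel:
    """Fit a penalized LR or random forest on log2 expression of ``features``.

    ``penalized_lr`` standardizes features and fits an elastic-net
    logistic regression whose penalty strength is chosen by stratified
    5-fold cross-validation maximizing AUROC (one-standard-error rule,
    favouring the sparser model); ``random_forest`` uses 1000 trees with
    sqrt(p) features per split.  Class imbalance is handled by class
    weighting.  Fully reproducible given the seed.
    """
    if kind not in DEFAULT_HYPER:
        raise ValueError(f"unknown model kind {kind!r}")
    hp = {**DEFAULT_HYPER[kind], **(hyper or {})}
    missing = [g for g in features if g not in m.data.index]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:10]}")
    outcome = t.outcome().reindex(m.sample_ids)
    keep = outcome.notna().to_numpy()
    y = outcome[keep].to_numpy().astype(int)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError("training outcome has a single class")
    X = m.data.loc[features].to_numpy(dtype=float).T[keep]

    if kind == "penalized_lr":
        C_sel, _ = _select_penalty(X, y, hp, seed)
        hp = {**hp, "C": C_sel}
        est = Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(C=C_sel, l1_ratio=hp["l1_ratio"],
                                      solver="saga", class_weight="balanced",
                                      max_iter=10_000, random_state=seed)),
        ])
    else:
        est = RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_features=hp["max_features"],
            class_weight="balanced", random_state=seed, n_jobs=1,
        )
    est.fit(X, y)
    model = TrainedModel(
        kind=kind, feature_genes=list(features), estimator=est, seed=seed,
        training_meta={
            "hyperparameters": hp,
            "n_samples": int(len(y)),
            "n_events": int(y.sum()),
            "cohorts": sorted(t.table["cohort_id"].dropna().unique().tolist()),
        },
    )
    sample_ids = np.asarray(m.sample_ids)[keep]
    model.training_scores = pd.Series(
        est.predict_proba(X)[:, 1], index=sample_ids)
    return model


def predict(model: TrainedModel, m: ExpressionMatrix) -> ScoreVector:
    """Per-sample risk in [0, 1]: predicted probability (LR) or vote fraction (RF)."""
    missing = [g for g in model.feature_genes if g not in m.data.index]
    if missing:
        raise ValueError(f"model features absent from matrix: {missing[:10]}")
    X = m.data.loc[model.feature_genes].to_numpy(dtype=float).T
    prob = model.estimator.predict_proba(X)[:, 1]
    return ScoreVector(
        scores=pd.Series(prob, index=m.data.columns),
        signature_name=model.kind,
        cohort_ids=(pd.Series(m.cohort_id, index=m.data.columns)
                    if m.cohort_id is not None else None),
    )


def ensemble_predict(per_model_scores: list[ScoreVector],
                     name: str = "ensemble") -> ScoreVector:
    """Average of within-cohort rank-normalized model scores.

    Every model's scores are converted to mid-ranks within cohort,
    normalized as rank/(n+1), and averaged across models, making the
    ensemble invariant to any strictly monotone rescaling of the inputs.
    """
    if len(per_model_scores) < 2:
        raise ValueError("ensemble needs >=2 models")
    index = per_model_scores[0].scores.index
    for sv in per_model_scores[1:]:
        if not index.sort_values().equals(sv.scores.index.sort_values()):
            raise ValueError("models were scored on different sample sets")
    cohorts = None
    for sv in per_model_scores:
        if sv.cohort_ids is not None:
            cohorts = sv.cohort_ids.reindex(index)
            break
    if cohorts is None:
        cohorts = pd.Series("pooled", index=index)
    n_per = cohorts.map(cohorts.value_counts())
    normed = []
    for sv in per_model_scores:
        s = sv.scores.reindex(index)
        normed.append(s.groupby(cohorts).rank(method="average") / (n_per + 1.0))
    mean = pd.concat(normed, axis=1).mean(axis=1)
    return ScoreVector(scores=mean, signature_name=name,
                       cohort_ids=cohorts if (cohorts != "pooled").any() else None)


# ---------------------------------------------------------------------------
# Serialization: versioned JSON sidecar + joblib parameter bundle

BUNDLE_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write ``<path>.json`` (metadata) and ``<path>.joblib`` (fitted state)."""
    path = Path(path)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "kind": model.kind,
        "feature_genes": model.feature_genes,
        "seed": model.seed,
        "training_meta": model.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model.estimator, path.with_suffix(".joblib"))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version: "
                         f"{meta.get('bundle_version')}")
    estimator = joblib.load(path.with_suffix(".joblib"))
    return TrainedModel(kind=meta["kind"], feature_genes=meta["feature_genes"],
                        estimator=estimator, seed=meta["seed"],
                        training_meta=meta["training_meta"])
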