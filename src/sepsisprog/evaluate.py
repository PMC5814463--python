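"""Discrimination and reclassification statistics for mortality predictors.

Everything downstream of a per-sample risk score lives here: empirical
ROC curves and trapezoidal AUROC/AUPRC, the Kester–Buntinx summary ROC
pooled over cohorts, operating-threshold selection and 2x2 test
characteristics, joint logistic models against clinical severity scores,
continuous net reclassification improvement (cNRI), paired AUROC tests,
inter-model rank correlation, four-model consensus classification, and a
longitudinal slope comparison.

Convention throughout: higher score means higher predicted mortality
risk, and the positive class is 30-day death.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "AurocResult",
    "SummaryROC",
    "NRIResult",
    "EvalReport",
    "roc_curve_points",
    "auroc",
    "auroc_point",
    "auprc",
    "summary_roc",
    "threshold_at_sensitivity",
    "test_characteristics",
    "joint_severity_model",
    "cnri",
    "paired_auroc_test",
    "model_rank_correlation",
    "consensus_classification",
    "longitudinal_slope_test",
    "evaluate_scores",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    return labels.astype(int)


# ---------------------------------------------------------------------------
# ROC / AUROC / AUPRC


@dataclass
class ROCCurve:
    """Empirical ROC operating points, ordered by rising threshold.

    The trivial endpoints — everything called positive (sens 1, spec 0)
    and everything called negative (sens 0, spec 1) — are always present.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def roc_curve_points(scores, labels) -> ROCCurve:
    """All achievable operating points of ``score >= threshold`` rules."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    # cut only between distinct score values
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    sens = np.r_[0.0, tp / n_pos][::-1]
    spec = np.r_[1.0, 1.0 - fp / n_neg][::-1]
    thr = np.r_[np.inf, s[distinct]][::-1]
    return ROCCurve(thresholds=thr, sensitivity=sens, specificity=spec,
                    n_pos=n_pos, n_neg=n_neg)


def auroc_point(scores, labels) -> float:
    """Trapezoidal AUROC; equals pairwise concordance with ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class AurocResult:
    auroc: float
    ci_95: tuple[float, float]
    n_pos: int
    n_neg: int
    n_boot: int


def auroc(scores, labels, n_boot: int = 2000, seed: int = 0) -> AurocResult:
    """AUROC with a stratified-bootstrap 95% CI.

    Positives and negatives are resampled separately (class sizes are
    preserved), ``n_boot`` times, and the CI is the 2.5/97.5 percentile
    of the bootstrap AUROCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    point = auroc_point(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    y = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots[b] = auroc_point(np.r_[bp, bn], y)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AurocResult(auroc=point, ci_95=(float(lo), float(hi)),
                       n_pos=len(pos), n_neg=len(neg), n_boot=n_boot)


def auprc(scores, labels) -> float:
    """Trapezoidal area under the precision–recall operating points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    predicted_pos = distinct + 1
    precision = tp / predicted_pos
    recall = tp / n_pos
    # anchor at recall 0 with the first achievable precision
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return float(np.trapezoid(precision, recall))


# ---------------------------------------------------------------------------
# Summary ROC (Kester & Buntinx logit-linear family)


@dataclass
class SummaryROC:
    """Cross-cohort summary ROC in the two-parameter logit-linear family.

    Operating points are mapped to S = logit(TPR) + logit(FPR) and
    D = logit(TPR) - logit(FPR); a size-weighted linear fit D = a + bS
    defines the family member, which is back-transformed on an FPR grid
    and integrated by the trapezoidal rule.
    """

    intercept: float
    slope: float
    auroc: float
    ci_95: tuple[float, float]
    fpr_grid: np.ndarray = field(repr=False)
    tpr_grid: np.ndarray = field(repr=False)
    n_cohorts: int = 0


def _correct(p: np.ndarray, n: int) -> np.ndarray:
    """Continuity-correct proportions at 0 or 1 by half a count."""
    p = p.copy()
    eps = 0.5 / n
    p[p <= 0.0] = eps
    p[p >= 1.0] = 1.0 - eps
    return p


def _srocc_points(curves: list[ROCCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    S, D, W = [], [], []
    for c in curves:
        interior = (c.sensitivity > 0) & (c.sensitivity < 1) & \
                   (c.specificity > 0) & (c.specificity < 1)
        tpr = c.tpr.copy()
        fpr = c.fpr.copy()
        # keep degenerate points too, after continuity correction, but
        # drop the two trivial all-or-nothing endpoints
        nontrivial = ~(((tpr == 0) & (fpr == 0)) | ((tpr == 1) & (fpr == 1)))
        tpr = _correct(tpr[nontrivial], c.n_pos)
        fpr = _correct(fpr[nontrivial], c.n_neg)
        u, v = logit(tpr), logit(fpr)
        S.append(u + v)
        D.append(u - v)
        W.append(np.full(len(u), c.n_pos + c.n_neg, dtype=float))
        del interior
    return np.concatenate(S), np.concatenate(D), np.concatenate(W)


def _fit_sroc(curves: list[ROCCurve], grid_size: int) -> tuple[float, float, np.ndarray, np.ndarray, float]:
    S, D, W = _srocc_points(curves)
    X = sm.add_constant(S)
    fit = sm.WLS(D, X, weights=W).fit()
    a, b = float(fit.params[0]), float(fit.params[1])
    if abs(1.0 - b) < 1e-8:
        raise ValueError("degenerate summary-ROC fit (slope ~ 1)")
    fpr = np.linspace(1e-4, 1 - 1e-4, grid_size)
    v = logit(fpr)
    tpr = expit((a + (1.0 + b) * v) / (1.0 - b))
    fgrid = np.r_[0.0, fpr, 1.0]
    tgrid = np.r_[0.0, tpr, 1.0]
    area = float(np.trapezoid(tgrid, fgrid))
    return a, b, fgrid, tgrid, area


def summary_roc(cohort_curves: list[ROCCurve], n_boot: int = 1000,
                seed: int = 0, grid_size: int = 512) -> SummaryROC:
    """Fit a summary ROC over per-cohort empirical curves.

    The 95% CI on the summary AUROC comes from bootstrapping cohorts
    (resampling whole cohorts with replacement ``n_boot`` times).
    """
    if not cohort_curves:
        raise ValueError("no cohort ROC curves supplied")
    a, b, fgrid, tgrid, area = _fit_sroc(cohort_curves, grid_size)
    rng = np.random.default_rng(seed)
    k = len(cohort_curves)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, k, size=k)
        try:
            boots.append(_fit_sroc([cohort_curves[i] for i in pick], 128)[4])
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = area
    return SummaryROC(intercept=a, slope=b, auroc=area,
                      ci_95=(float(lo), float(hi)),
                      fpr_grid=fgrid, tpr_grid=tgrid, n_cohorts=k)


# ---------------------------------------------------------------------------
# Thresholds and test characteristics


def threshold_at_sensitivity(roc: ROCCurve, target: float) -> dict:
    """Operating point at the nearest achievable sensitivity above ``target``.

    Among points with sensitivity strictly greater than ``target`` the
    one with the smallest sensitivity is returned; ties are broken in
    favour of higher specificity.
    """
    if not (0 <= target < 1):
        raise ValueError("target sensitivity must be in [0, 1)")
    mask = roc.sensitivity > target
    if not mask.any():
        raise ValueError(f"no operating point with sensitivity > {target}")
    sens = roc.sensitivity[mask]
    spec = roc.specificity[mask]
    thr = roc.thresholds[mask]
    best = np.lexsort((-spec, sens))[0]
    return {"threshold": float(thr[best]),
            "sensitivity": float(sens[best]),
            "specificity": float(spec[best])}


def test_characteristics(scores, labels, threshold: float) -> dict:
    """2x2 test characteristics of the rule ``score >= threshold`` -> death.

    PPV/NPV with a zero denominator are reported as None, not 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "npv": tn / (tn + fn) if (tn + fn) else None,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


# ---------------------------------------------------------------------------
# Severity-score comparison


@dataclass
class JointModelResult:
    auroc_severity: float
    auroc_gene: float
    auroc_joint: float
    loglik_severity: float
    loglik_gene: float
    loglik_joint: float
    n: int
    n_dropped_no_severity: int
    penalized: bool = False


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """MLE logistic fit; on separation/non-convergence, ridge-penalized refit."""
    Xc = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
            return expit(Xc @ res.params), float(res.llf), False
    except Exception:  # noqa: BLE001 - statsmodels raises several types here
        pass
    logger.warning("logistic fit did not converge cleanly; "
                   "refitting with a small ridge penalty")
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=100.0, max_iter=2000)  # ridge-penalized
    lr.fit(X, y)
    prob = lr.predict_proba(X)[:, 1]
    eps = 1e-12
    llf = float(np.sum(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
    return prob, llf, True


def joint_severity_model(sample_table, gene_scores) -> JointModelResult:
    """Compare clinical severity, gene score, and their joint logistic model.

    Fits three logistic regressions of 30-day mortality — on severity
    alone, on the gene score alone, and on both without interaction —
    and reports the AUROC of each model's fitted probabilities.  Samples
    without a severity value are dropped.
    """
    df = sample_table.table.set_index("sample_id")
    scores = gene_scores.scores
    common = scores.index.intersection(df.index)
    df = df.loc[common]
    scores = scores.loc[common]
    has_sev = df["severity_value"].notna() & df["mortality_30d"].notna()
    n_dropped = int((~has_sev).sum())
    if n_dropped:
        logger.info("joint_severity_model: dropped %d samples without "
                    "severity or outcome", n_dropped)
    df = df[has_sev]
    scores = scores[has_sev]
    y = _check_binary(df["mortality_30d"].to_numpy())
    sev = df["severity_value"].to_numpy(dtype=float)
    gene = scores.to_numpy(dtype=float)

    p_sev, ll_sev, pen1 = _fit_logistic(sev[:, None], y)
    p_gene, ll_gene, pen2 = _fit_logistic(gene[:, None], y)
    p_joint, ll_joint, pen3 = _fit_logistic(np.c_[sev, gene], y)
    return JointModelResult(
        auroc_severity=auroc_point(p_sev, y),
        auroc_gene=auroc_point(p_gene, y),
        auroc_joint=auroc_point(p_joint, y),
        loglik_severity=ll_sev, loglik_gene=ll_gene, loglik_joint=ll_joint,
        n=len(y), n_dropped_no_severity=n_dropped,
        penalized=pen1 or pen2 or pen3,
    )


# ---------------------------------------------------------------------------
# Continuous net reclassification improvement


@dataclass
class NRIResult:
    """Continuous NRI of a new risk model over an old one.

    ``cnri = event_component + nonevent_component``; each component lies
    in [-1, 1] so the total lies in [-2, 2].  2 means every event's risk
    moved up and every non-event's risk moved down.
    """

    event_component: float
    nonevent_component: float
    cnri: float
    ci_95: tuple[float, float]
    p_value: float
    n_events: int
    n_nonevents: int


def cnri(old_risk, new_risk, labels, bootstrap: bool = False,
         n_boot: int = 2000, seed: int = 0) -> NRIResult:
    """Continuous net reclassification improvement, new model vs old.

    event component   = P(new > old | event)    - P(new < old | event)
    nonevent component = P(new < old | nonevent) - P(new > old | nonevent)

    Ties contribute zero.  The default CI/p use the asymptotic normal
    form with component variances estimated from the up/down movement
    proportions; ``bootstrap=True`` replaces the CI with a stratified
    bootstrap percentile interval (p stays asymptotic).
    """
    old = np.asarray(old_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    labels = _check_binary(labels)
    if not (len(old) == len(new) == len(labels)):
        raise ValueError("old_risk, new_risk and labels must align")

    def _components(old, new, labels):
        move = np.sign(new - old)
        ev = move[labels == 1]
        ne = move[labels == 0]
        return float(np.mean(ev)), float(-np.mean(ne))

    def _var(move: np.ndarray) -> float:
        up = float(np.mean(move > 0))
        down = float(np.mean(move < 0))
        return (up + down - (up - down) ** 2) / len(move)

    e_comp, ne_comp = _components(old, new, labels)
    total = e_comp + ne_comp
    move = np.sign(new - old)
    v = _var(move[labels == 1]) + _var(move[labels == 0])
    se = float(np.sqrt(v))
    if se > 0:
        z = total / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if total == 0 else 0.0
    if bootstrap:
        rng = np.random.default_rng(seed)
        idx_e = np.nonzero(labels == 1)[0]
        idx_n = np.nonzero(labels == 0)[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = np.r_[rng.choice(idx_e, len(idx_e)), rng.choice(idx_n, len(idx_n))]
            ec, nc = _components(old[pick], new[pick], labels[pick])
            boots[b] = ec + nc
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo, hi = total - 1.959964 * se, total + 1.959964 * se
    return NRIResult(event_component=e_comp, nonevent_component=ne_comp,
                     cnri=total, ci_95=(float(lo), float(hi)), p_value=p,
                     n_events=int(labels.sum()),
                     n_nonevents=int(len(labels) - labels.sum()))


# ---------------------------------------------------------------------------
# Model comparison across datasets


def paired_auroc_test(aurocs_a, aurocs_b) -> dict:
    """Two-sided paired t-test on per-dataset AUROC differences."""
    a = np.asarray(aurocs_a, dtype=float)
    b = np.asarray(aurocs_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >=2 paired datasets")
    diff = a - b
    mean_diff = float(diff.mean())
    degenerate = bool(np.ptp(diff) == 0)
    if degenerate:
        p = 1.0 if mean_diff == 0 else 0.0
        t = np.inf * np.sign(mean_diff) if mean_diff else 0.0
        logger.warning("paired_auroc_test: zero-variance differences (degenerate)")
    else:
        t, p = stats.ttest_rel(a, b)
        t, p = float(t), float(p)
    return {"mean_difference": mean_diff, "t": t, "p_value": p,
            "n_datasets": len(a), "degenerate": degenerate}


def model_rank_correlation(scores_by_model: list) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-patient model ranks.

    Each model's scores are rank-normalized within cohort (mid-ranks for
    ties, rank/(n+1)), pooled across cohorts, and correlated pairwise.
    """
    if len(scores_by_model) < 2:
        raise ValueError("need >=2 models")
    common = scores_by_model[0].scores.index
    for sv in scores_by_model[1:]:
        common = common.intersection(sv.scores.index)
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    cohorts = None
    for sv in scores_by_model:
        if sv.cohort_ids is not None:
            cohorts = sv.cohort_ids.reindex(common)
            break
    if cohorts is None:
        cohorts = pd.Series("pooled", index=common)
    normed = {}
    for sv in scores_by_model:
        s = sv.scores.loc[common]
        r = s.groupby(cohorts).rank(method="average")
        n = cohorts.map(cohorts.value_counts())
        normed[sv.signature_name] = r / (n + 1.0)
    names = list(normed)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            rho = stats.spearmanr(normed[ni], normed[names[j]]).statistic
            mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat


def consensus_classification(per_model_correct) -> pd.DataFrame:
    """Per-patient agreement category over four models.

    ``per_model_correct`` is an n x 4 binary array/frame: 1 where the
    model classified the patient correctly at its 90%-sensitivity
    threshold.  Categories: 0 correct -> ``always_misclassified``,
    1–2 -> ``no_consensus``, 3–4 -> ``consensus``.  Returns per-patient
    categories plus per-category fractions.
    """
    arr = np.asarray(per_model_correct, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected exactly 4 model-correctness flags per patient")
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("correctness flags must be binary")
    n_correct = arr.sum(axis=1).astype(int)
    category = np.where(n_correct == 0, "always_misclassified",
                        np.where(n_correct <= 2, "no_consensus", "consensus"))
    out = pd.DataFrame({"n_correct": n_correct, "category": category})
    fractions = (out["category"].value_counts(normalize=True)
                 .reindex(["always_misclassified", "no_consensus", "consensus"])
                 .fillna(0.0))
    out.attrs["fractions"] = fractions.to_dict()
    return out


def longitudinal_slope_test(long_scores: pd.DataFrame, labels: pd.Series) -> dict:
    """Compare score trajectories between survivors and non-survivors.

    ``long_scores`` has columns ``patient_id``, ``time_h``, ``score``
    with repeated measures per patient; ``labels`` maps patient_id to
    30-day mortality.  Each patient's ordinary least-squares slope of
    score against time (per day) and mean score are computed; groups are
    compared by two-sided Welch t-tests on slopes (trajectory shape) and
    on mean levels.
    """
    required = {"patient_id", "time_h", "score"}
    if not required <= set(long_scores.columns):
        raise ValueError(f"long_scores needs columns {sorted(required)}")
    slopes, levels, outcome = [], [], []
    excluded = 0
    for pid, grp in long_scores.groupby("patient_id"):
        if grp["time_h"].nunique() < 2:
            excluded += 1
            continue
        if pid not in labels.index or pd.isna(labels.loc[pid]):
            excluded += 1
            continue
        t_days = grp["time_h"].to_numpy(dtype=float) / 24.0
        y = grp["score"].to_numpy(dtype=float)
        slopes.append(np.polyfit(t_days, y, 1)[0])
        levels.append(y.mean())
        outcome.append(int(labels.loc[pid]))
    if excluded:
        logger.warning("longitudinal_slope_test: excluded %d patients "
                       "(single time point or missing outcome)", excluded)
    slopes = np.asarray(slopes)
    levels = np.asarray(levels)
    outcome = np.asarray(outcome)
    if min((outcome == 1).sum(), (outcome == 0).sum()) < 3:
        raise ValueError("need >=3 patients with >=2 time points per group")
    s1, s0 = slopes[outcome == 1], slopes[outcome == 0]
    l1, l0 = levels[outcome == 1], levels[outcome == 0]
    slope_p = float(stats.ttest_ind(s1, s0, equal_var=False).pvalue)
    level_p = float(stats.ttest_ind(l1, l0, equal_var=False).pvalue)
    return {
        "mean_slope_nonsurvivors": float(s1.mean()),
        "mean_slope_survivors": float(s0.mean()),
        "slope_p": slope_p,
        "mean_level_nonsurvivors": float(l1.mean()),
        "mean_level_survivors": float(l0.mean()),
        "level_p": level_p,
        "n_nonsurvivors": int((outcome == 1).sum()),
        "n_survivors": int((outcome == 0).sum()),
        "n_excluded": excluded,
    }


# ---------------------------------------------------------------------------
# Bundled per-cohort report


@dataclass
class EvalReport:
    """Discrimination summary for one score vector on one cohort."""

    auroc: float
    auroc_ci_95: tuple[float, float]
    auprc: float
    roc: ROCCurve
    thresholds: dict = field(default_factory=dict)
    n_pos: int = 0
    n_neg: int = 0

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci_95": list(self.auroc_ci_95),
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "thresholds": self.thresholds,
        }


def evaluate_scores(scores, labels, n_boot: int = 2000, seed: int = 0,
                    sensitivity_targets: tuple[float, ...] = (0.9,)) -> EvalReport:
    """Full single-cohort discrimination report for one score vector."""
    res = auroc(scores, labels, n_boot=n_boot, seed=seed)
    roc = roc_curve_points(scores, labels)
    thresholds = {}
    for target in sensitivity_targets:
        try:
            op = threshold_at_sensitivity(roc, target)
        except ValueError:
            continue
        chars = test_characteristics(scores, labels, op["threshold"])
        thresholds[f"sens>{target:g}"] = {**op, **chars}
    return EvalReport(auroc=res.auroc, auroc_ci_95=res.ci_95,
                      auprc=auprc(scores, labels), roc=roc,
                      thresholds=thresholds, n_pos=res.n_pos, n_neg=res.n_neg)
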