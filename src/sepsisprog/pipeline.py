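"""End-to-end multi-cohort validation pipeline.

Given per-cohort expression matrices and sample annotations, scores
every signature on every cohort, evaluates discrimination per cohort,
and assembles the cross-cohort statistics: a summary ROC per signature,
the rank-combined ensemble, four-model consensus classification at the
90%-sensitivity thresholds, inter-model rank correlations, and the
severity-score comparison (joint models and cNRI) where severity is
available.

The bundle is a pure function of (inputs, config, seed): the same call
always produces the same JSON-serializable dictionary, which carries
the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .models import ensemble_predict
from .preprocess import ExpressionMatrix, SampleTable, filter_samples
from .scoring import ScoreVector, signature_score
from .signatures import SignatureSet, builtin_signatures

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_validation_pipeline", "write_bundle"]


@dataclass
class RunConfig:
    """Options controlling one validation run."""

    n_boot: int = 2000
    seed: int = 0
    sensitivity_target: float = 0.9
    max_time_h: float = 48.0
    require_outcome: bool = True
    consensus_per_cohort: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and cohort."""

    def __init__(self, stage: str, cohort: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on cohort {cohort!r}: {cause}")
        self.stage = stage
        self.cohort = cohort


def run_validation_pipeline(
    cohorts: list[tuple[ExpressionMatrix, SampleTable]],
    signatures: SignatureSet | None = None,
    cfg: RunConfig | None = None,
    extra_scores: dict[str, list[ScoreVector]] | None = None,
) -> dict:
    """Score and evaluate every signature across a cohort collection.

    ``extra_scores`` lets pre-computed per-cohort score vectors (for
    instance from trained models) join the per-signature evaluation.
    Cohorts with a single outcome class are skipped per-statistic, with
    the reason logged in the bundle.
    """
    cfg = cfg or RunConfig()
    signatures = signatures or builtin_signatures()

    # --- per-cohort scoring ------------------------------------------------
    per_sig_scores: dict[str, list[ScoreVector]] = {s.name: [] for s in signatures}
    labels_by_cohort: dict[str, pd.Series] = {}
    severity_tables: dict[str, SampleTable] = {}
    skipped: dict[str, str] = {}
    for em, st in cohorts:
        cid = em.cohort_id or "unnamed"
        try:
            st_f = filter_samples(st, max_time_h=cfg.max_time_h,
                                  require_outcome=cfg.require_outcome)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("filter_samples", cid, exc) from exc
        outcome = st_f.outcome().reindex(em.sample_ids).dropna()
        if outcome.empty or outcome.min() == outcome.max():
            skipped[cid] = "single outcome class (or no labelled samples)"
            logger.warning("cohort %s skipped: %s", cid, skipped[cid])
            continue
        labels_by_cohort[cid] = outcome.astype(int)
        severity_tables[cid] = st_f
        for sig in signatures:
            try:
                sv = signature_score(em, sig)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("signature_score", cid, exc) from exc
            sv.scores = sv.scores.loc[outcome.index]
            if sv.cohort_ids is not None:
                sv.cohort_ids = sv.cohort_ids.loc[outcome.index]
            per_sig_scores[sig.name].append(sv)
    if extra_scores:
        for name, svs in extra_scores.items():
            per_sig_scores[name] = [
                ScoreVector(
                    scores=sv.scores.loc[sv.scores.index.intersection(
                        labels_by_cohort.get(_cohort_of(sv), pd.Series(dtype=float)).index)],
                    signature_name=name,
                    cohort_ids=sv.cohort_ids,
                )
                for sv in svs if _cohort_of(sv) in labels_by_cohort
            ]

    # --- per-cohort, per-signature evaluation ------------------------------
    bundle: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "skipped_cohorts": skipped,
        "per_cohort": {},
        "cross_cohort": {},
    }
    curves: dict[str, list[ev.ROCCurve]] = {}
    for name, svs in per_sig_scores.items():
        curves[name] = []
        for sv in svs:
            cid = _cohort_of(sv)
            y = labels_by_cohort[cid].loc[sv.scores.index]
            try:
                report = ev.evaluate_scores(
                    sv.scores.to_numpy(), y.to_numpy(),
                    n_boot=cfg.n_boot, seed=cfg.seed,
                    sensitivity_targets=(cfg.sensitivity_target,),
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("evaluate", cid, exc) from exc
            bundle["per_cohort"].setdefault(cid, {})[name] = report.to_dict()
            curves[name].append(report.roc)

    # --- cross-cohort: summary ROC per signature ---------------------------
    for name, cc in curves.items():
        if len(cc) >= 2:
            sroc = ev.summary_roc(cc, n_boot=min(cfg.n_boot, 500), seed=cfg.seed)
            bundle["cross_cohort"].setdefault("summary_roc", {})[name] = {
                "auroc": sroc.auroc, "ci_95": list(sroc.ci_95),
                "intercept": sroc.intercept, "slope": sroc.slope,
                "n_cohorts": sroc.n_cohorts,
            }

    # --- pooled analyses ---------------------------------------------------
    pooled: dict[str, ScoreVector] = {}
    for name, svs in per_sig_scores.items():
        if not svs:
            continue
        scores = pd.concat([sv.scores for sv in svs])
        cohort_ids = pd.concat([
            sv.cohort_ids if sv.cohort_ids is not None
            else pd.Series(_cohort_of(sv), index=sv.scores.index)
            for sv in svs
        ])
        pooled[name] = ScoreVector(scores=scores, signature_name=name,
                                   cohort_ids=cohort_ids)
    pooled_labels = pd.concat(labels_by_cohort.values())

    if len(pooled) >= 2:
        ens = ensemble_predict(list(pooled.values()))
        y = pooled_labels.loc[ens.scores.index].to_numpy()
        ens_auroc = ev.auroc(ens.scores.to_numpy(), y,
                             n_boot=cfg.n_boot, seed=cfg.seed)
        bundle["cross_cohort"]["ensemble"] = {
            "auroc": ens_auroc.auroc, "ci_95": list(ens_auroc.ci_95),
            "auprc": ev.auprc(ens.scores.to_numpy(), y),
        }
        rho = ev.model_rank_correlation(list(pooled.values()))
        bundle["cross_cohort"]["rank_correlation"] = rho.to_dict()

    if len(pooled) == 4:
        bundle["cross_cohort"]["consensus"] = _consensus(
            pooled, per_sig_scores, labels_by_cohort, cfg)

    # --- severity comparison ----------------------------------------------
    severity = {}
    for name, svs in per_sig_scores.items():
        per_cohort_nri = {}
        for sv in svs:
            cid = _cohort_of(sv)
            st_f = severity_tables[cid]
            sub = st_f.table
            if sub["severity_value"].notna().sum() < 5:
                continue
            try:
                jm = ev.joint_severity_model(st_f, sv)
            except ValueError:
                continue
            df = sub.set_index("sample_id")
            has = df["severity_value"].notna() & df["mortality_30d"].notna()
            ids = df.index[has].intersection(sv.scores.index)
            y = df.loc[ids, "mortality_30d"].to_numpy().astype(int)
            if y.min() == y.max():
                continue
            sev = df.loc[ids, "severity_value"].to_numpy(dtype=float)
            gene = sv.scores.loc[ids].to_numpy()
            nri = ev.cnri(_risk(sev, y), _risk(np.c_[sev, gene], y), y)
            per_cohort_nri[cid] = {
                "auroc_severity": jm.auroc_severity,
                "auroc_gene": jm.auroc_gene,
                "auroc_joint": jm.auroc_joint,
                "cnri": nri.cnri, "cnri_p": nri.p_value,
            }
        if per_cohort_nri:
            severity[name] = per_cohort_nri
    if severity:
        bundle["cross_cohort"]["severity_comparison"] = severity
    return bundle


def _cohort_of(sv: ScoreVector) -> str:
    if sv.cohort_ids is not None and len(sv.cohort_ids):
        return str(sv.cohort_ids.iloc[0])
    return "unnamed"


def _risk(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted logistic risk for the cNRI old/new comparison."""
    if X.ndim == 1:
        X = X[:, None]
    prob, _, _ = ev._fit_logistic(X, y)
    return prob


def _consensus(pooled, per_sig_scores, labels_by_cohort, cfg) -> dict:
    """Correctness flags at each model's 90%-sensitivity threshold.

    Thresholds are set on the pooled samples by default; with
    ``cfg.consensus_per_cohort`` each cohort gets its own threshold.
    """
    names = list(pooled)
    index = pooled[names[0]].scores.index
    flags = np.zeros((len(index), len(names)), dtype=int)
    y_all = pd.concat(labels_by_cohort.values()).loc[index].to_numpy()
    cohorts = pooled[names[0]].cohort_ids.loc[index].to_numpy()
    for j, name in enumerate(names):
        s = pooled[name].scores.loc[index].to_numpy()
        pred = np.zeros_like(s, dtype=int)
        if cfg.consensus_per_cohort:
            for cid in np.unique(cohorts):
                mask = cohorts == cid
                if y_all[mask].min() == y_all[mask].max():
                    continue
                roc = ev.roc_curve_points(s[mask], y_all[mask])
                thr = ev.threshold_at_sensitivity(
                    roc, cfg.sensitivity_target)["threshold"]
                pred[mask] = (s[mask] >= thr).astype(int)
        else:
            roc = ev.roc_curve_points(s, y_all)
            thr = ev.threshold_at_sensitivity(
                roc, cfg.sensitivity_target)["threshold"]
            pred = (s >= thr).astype(int)
        flags[:, j] = (pred == y_all).astype(int)
    table = ev.consensus_classification(flags)
    return {"fractions": table.attrs["fractions"],
            "n_patients": int(len(index)),
            "per_cohort_thresholds": bool(cfg.consensus_per_cohort)}


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write the JSON bundle plus flat TSVs of the per-cohort statistics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "validation_bundle.json"
    path.write_text(json.dumps(bundle, indent=2, default=_json_default))
    rows = []
    for cid, models in bundle.get("per_cohort", {}).items():
        for name, rep in models.items():
            rows.append({"cohort_id": cid, "signature": name,
                         "auroc": rep["auroc"], "auprc": rep["auprc"],
                         "n_pos": rep["n_pos"], "n_neg": rep["n_neg"]})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "per_cohort_metrics.tsv",
                                  sep="\t", index=False)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
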