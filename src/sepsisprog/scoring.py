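"""Difference-of-geometric-means signature scoring.

The parameter-free score behind the Duke and Stanford mortality
predictors: for each sample, the geometric mean of the signature's
up-genes minus the geometric mean of its down-genes.  On log2-scale
data the geometric mean is exactly the arithmetic mean of log2 values,
so the score is

    S = mean(log2 x, up genes) - mean(log2 x, down genes)

The same formula, evaluated on a sorted-cell reference profile instead
of a patient sample, yields a cell-type enrichment score; significance
there comes from a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "CellTypeProfile",
    "signature_score",
    "to_log2",
    "enrichment_in_profiles",
    "LINEAR_FLOOR",
]

#: floor applied before log2 when transforming linear-scale values
LINEAR_FLOOR = 2.0 ** -10


@dataclass
class ScoreVector:
    """Per-sample signature scores plus bookkeeping.

    ``scores`` is indexed by sample_id.  ``n_up_used``/``n_down_used``
    record how many signature genes were found in the matrix; scores are
    renormalized over the genes present.
    """

    scores: pd.Series
    signature_name: str
    n_up_used: int = 0
    n_down_used: int = 0
    cohort_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in ScoreVector")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.scores.index,
            "cohort_id": (self.cohort_ids.reindex(self.scores.index).to_numpy()
                          if self.cohort_ids is not None else None),
            "signature": self.signature_name,
            "score": self.scores.to_numpy(),
        })
        return df


@dataclass
class CellTypeProfile:
    """Mean expression of one sorted cell type over a gene universe."""

    cell_type: str
    expression: pd.Series  # indexed by gene symbol, log2 scale

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError(f"profile {self.cell_type}: duplicate gene ids")
        if not np.all(np.isfinite(self.expression.to_numpy(dtype=float))):
            raise ValueError(f"profile {self.cell_type}: non-finite values")


def signature_score(m: ExpressionMatrix, sig: GeneSignature) -> ScoreVector:
    """Score every sample of ``m`` with the difference-of-means formula.

    Requires log2-scale input (use :func:`to_log2` for linear data).
    Signature genes absent from the matrix are dropped with a warning;
    at least one up and one down gene must remain.
    """
    if m.scale == "counts":
        raise ValueError("signature_score needs log2 expression, not counts; "
                         "run log2_cpm_weights first")
    if m.scale == "linear":
        raise ValueError("signature_score needs log2 expression; "
                         "log2-transform linear intensities first (see to_log2)")
    index = pd.Index([g.upper() for g in m.data.index])
    up = sorted(sig.up & set(index))
    down = sorted(sig.down & set(index))
    missing = (sig.up | sig.down) - set(index)
    if missing:
        logger.warning("signature %s: %d/%d genes absent from matrix: %s",
                       sig.name, len(missing), len(sig), sorted(missing)[:10])
    if not up:
        raise ValueError(f"signature {sig.name}: no up genes present in matrix")
    if not down:
        raise ValueError(f"signature {sig.name}: no down genes present in matrix")
    data = m.data.set_axis(index, axis=0)
    score = data.loc[up].mean(axis=0) - data.loc[down].mean(axis=0)
    return ScoreVector(
        scores=score,
        signature_name=sig.name,
        n_up_used=len(up),
        n_down_used=len(down),
        cohort_ids=(pd.Series(m.cohort_id, index=score.index)
                    if m.cohort_id is not None else None),
    )


def to_log2(m: ExpressionMatrix, floor: float = LINEAR_FLOOR) -> ExpressionMatrix:
    """log2-transform a linear-scale matrix, flooring values at ``floor``."""
    if m.scale != "linear":
        raise ValueError("to_log2 expects a linear-scale matrix")
    data = np.log2(np.maximum(m.data.to_numpy(dtype=float), floor))
    return ExpressionMatrix(
        pd.DataFrame(data, index=m.data.index, columns=m.data.columns),
        scale="log2", cohort_id=m.cohort_id,
    )


def _profile_score(expr: pd.Series, up: list[str], down: list[str]) -> float:
    return float(expr.loc[up].mean() - expr.loc[down].mean())


def enrichment_in_profiles(
    pooled: GeneSignature,
    profiles: list[CellTypeProfile],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type enrichment of a gene signature in sorted-cell profiles.

    For each profile the signature score (up-gene geometric mean minus
    down-gene geometric mean, in log2 space) measures how strongly that
    cell type's transcriptome expresses the signature.  Significance is
    a two-sided permutation p: ``n_perm`` random same-size up/down draws
    from the profile's gene universe form the null score distribution,
    and p = (1 + #{|null| >= |observed|}) / (n_perm + 1).

    Returns a DataFrame indexed by cell type with ``score`` and
    ``p_value`` columns.
    """
    if not profiles:
        raise ValueError("no cell-type profiles supplied")
    if n_perm < 100:
        logger.warning("enrichment_in_profiles: n_perm=%d is low; "
                       "p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    rows = {}
    for prof in profiles:
        universe = pd.Index([g.upper() for g in prof.expression.index])
        expr = prof.expression.set_axis(universe)
        up = sorted(pooled.up & set(universe))
        down = sorted(pooled.down & set(universe))
        if not up or not down:
            raise ValueError(
                f"profile {prof.cell_type}: signature not covered "
                f"({len(up)} up, {len(down)} down genes present)"
            )
        obs = _profile_score(expr, up, down)
        values = expr.to_numpy(dtype=float)
        n_up, n_down = len(up), len(down)
        null = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(len(values), size=n_up + n_down, replace=False)
            null[i] = values[draw[:n_up]].mean() - values[draw[n_up:]].mean()
        p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
        rows[prof.cell_type] = {"score": obs, "p_value": p}
    return pd.DataFrame.from_dict(rows, orient="index")
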