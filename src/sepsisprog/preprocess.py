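"""Expression-matrix containers and the normalization steps feeding the scores.

Inputs are summarized probe- or gene-level matrices (log2 microarray
intensities) or RNA-seq counts; raw-intensity background correction and
platform-specific summarization are assumed to have happened upstream.
The steps here are: probe-to-gene collapsing by mean, between-array
quantile normalization, a voom-style log2-CPM transform with precision
weights for count data, and sample-inclusion filtering (first 48 h after
admission, known 30-day outcome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "collapse_probes",
    "quantile_normalize",
    "log2_cpm_weights",
    "filter_samples",
]

Scale = Literal["log2", "linear", "counts"]

SEVERITY_TYPES = (
    "APACHE II", "APACHE III", "SOFA", "SAPS II",
    "PRISM", "PELOD", "Denver", "MODS",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with scale metadata.

    ``data`` is a DataFrame indexed by gene (or probe) identifier with
    one column per sample.  ``scale`` records whether values are log2
    intensities, linear intensities, or integer read counts.
    """

    data: pd.DataFrame
    scale: Scale = "log2"
    cohort_id: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if self.scale not in ("log2", "linear", "counts"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "counts":
            if values.size and (np.any(values < 0) or
                                not np.allclose(values, np.round(values))):
                raise ValueError("counts must be non-negative integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_tsv(cls, path: str | Path, scale: Scale = "log2",
                 cohort_id: str | None = None, sep: str = "\t") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, scale=scale, cohort_id=cohort_id)

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="gene_id")


@dataclass
class SampleTable:
    """Per-sample annotations: outcome, cohort, severity, sampling time.

    Columns: ``sample_id``, ``cohort_id``, ``mortality_30d`` (0/1 or
    missing), ``severity_value``, ``severity_type``,
    ``time_from_admission_h``.
    """

    table: pd.DataFrame
    exclusion_log: list[dict] = field(default_factory=list)

    REQUIRED = ("sample_id",)
    OPTIONAL = ("cohort_id", "mortality_30d", "severity_value",
                "severity_type", "time_from_admission_h")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"SampleTable missing column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids")
        mort = df["mortality_30d"].dropna()
        if not mort.isin([0, 1]).all():
            raise ValueError("mortality_30d must be 0/1 or missing")
        bad = df["severity_type"].dropna()
        bad = bad[~bad.isin(SEVERITY_TYPES)]
        if len(bad):
            raise ValueError(f"unknown severity types: {sorted(set(bad))}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def outcome(self) -> pd.Series:
        """mortality_30d indexed by sample_id (may contain NaN)."""
        return self.table.set_index("sample_id")["mortality_30d"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", na_values=["", "NA"])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def collapse_probes(probe_matrix: ExpressionMatrix,
                    mapping: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes by the per-gene probe mean.

    ``mapping`` has two columns, probe identifier then gene symbol.  Each
    retained probe must map to exactly one gene; probes absent from the
    mapping are dropped (count logged).  Gene symbols are upper-cased.
    """
    if probe_matrix.scale not in ("log2", "linear"):
        raise ValueError("collapse_probes expects log2 or linear intensities")
    if mapping.shape[1] < 2 or len(mapping) == 0:
        raise ValueError("probe mapping must be a nonempty two-column table")
    probe_col, gene_col = mapping.columns[:2]
    mp = mapping[[probe_col, gene_col]].dropna()
    multi = mp.groupby(probe_col)[gene_col].nunique()
    ambiguous = multi[multi > 1]
    if len(ambiguous):
        raise ValueError(
            f"probes mapped to multiple genes: {sorted(ambiguous.index[:10])}"
        )
    mp = mp.drop_duplicates(subset=probe_col)
    lookup = dict(zip(mp[probe_col].astype(str), mp[gene_col].astype(str).str.upper()))
    genes = probe_matrix.data.index.map(lambda p: lookup.get(str(p)))
    unmapped = int(pd.isna(genes).sum())
    if unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", unmapped)
    kept = probe_matrix.data.loc[~pd.isna(genes)]
    collapsed = kept.groupby(genes[~pd.isna(genes)]).mean()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed, scale=probe_matrix.scale,
                            cohort_id=probe_matrix.cohort_id)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    After normalization every sample's sorted value vector equals the
    cross-sample mean of sorted vectors; tied values within a sample
    receive the mean of the reference values at their tied ranks.
    """
    if m.scale not in ("log2", "linear"):
        raise ValueError("quantile_normalize expects log2 or linear intensities")
    values = m.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    if np.ptp(values) == 0:
        logger.warning("quantile_normalize: constant matrix returned unchanged")
        return replace(m, data=m.data.copy())
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(n_genes, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(values[:, j], method="average") - 1.0
        # linear interpolation realizes the mean-of-tied-reference rule
        out[:, j] = np.interp(ranks, grid, reference)
    return replace(m, data=pd.DataFrame(out, index=m.data.index,
                                        columns=m.data.columns))


def log2_cpm_weights(
    counts: ExpressionMatrix,
    span: float = 0.5,
    apply_weights: bool = True,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Voom-style log2-CPM with per-observation precision weights.

    ``log2cpm = log2((count + 0.5) / (libsize + 1) * 1e6)``.  A lowess
    trend of the per-gene residual spread (sqrt of the standard
    deviation) against the per-gene mean log2-CPM predicts each
    observation's standard deviation; the precision weight is the inverse
    predicted variance.  When ``apply_weights`` is true (the default
    pipeline behaviour) the returned expression is ``weight * log2cpm``;
    otherwise unweighted log2-CPM is returned and the weights are only
    reported.

    Returns the expression matrix (scale ``log2``) and the genes x
    samples weight table.
    """
    if counts.scale != "counts":
        raise ValueError("log2_cpm_weights expects a counts matrix")
    raw = counts.data.to_numpy(dtype=float)
    if np.any(raw < 0):
        raise ValueError("negative counts")
    if raw.shape[0] < 10:
        raise ValueError("too few genes to fit a mean-variance trend (<10)")
    libsize = raw.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("library sizes must be positive")
    log2cpm = np.log2((raw + 0.5) / (libsize + 1.0) * 1e6)

    gene_mean = log2cpm.mean(axis=1)
    gene_sd = log2cpm.std(axis=1, ddof=1)
    # quarter-root spread vs mean, the usual variance-stabilized trend scale
    sqrt_sd = np.sqrt(np.maximum(gene_sd, 1e-8))
    lo = sm.nonparametric.lowess(sqrt_sd, gene_mean, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-4)
    pred_sqrt_sd = np.interp(log2cpm, lx, ly)
    weights = pred_sqrt_sd ** -4  # inverse predicted variance

    expr = weights * log2cpm if apply_weights else log2cpm
    em = ExpressionMatrix(
        pd.DataFrame(expr, index=counts.data.index, columns=counts.data.columns),
        scale="log2", cohort_id=counts.cohort_id,
    )
    wdf = pd.DataFrame(weights, index=counts.data.index, columns=counts.data.columns)
    return em, wdf


def filter_samples(
    t: SampleTable,
    max_time_h: float = 48.0,
    require_outcome: bool = False,
) -> SampleTable:
    """Apply the study inclusion filters.

    Keeps samples drawn within the first ``max_time_h`` hours after
    admission (closed interval; missing sampling times are kept and
    logged) and, when ``require_outcome`` is set, drops samples with an
    unknown 30-day mortality label.  The returned table carries an
    exclusion log listing each dropped sample and the reason.
    """
    df = t.table
    exclusions: list[dict] = []
    keep = pd.Series(True, index=df.index)

    time = df["time_from_admission_h"]
    late = time.notna() & (time > max_time_h)
    for _, row in df[late].iterrows():
        exclusions.append({
            "sample_id": row["sample_id"],
            "reason": f"sampled at {row['time_from_admission_h']:g} h "
                      f"> {max_time_h:g} h after admission",
        })
    keep &= ~late
    n_missing_time = int(time.isna().sum())
    if n_missing_time:
        logger.info("filter_samples: %d samples with missing sampling time kept",
                    n_missing_time)

    if require_outcome:
        no_outcome = df["mortality_30d"].isna() & keep
        for _, row in df[no_outcome].iterrows():
            exclusions.append({
                "sample_id": row["sample_id"],
                "reason": "missing 30-day mortality outcome",
            })
        keep &= ~no_outcome

    return SampleTable(df[keep].reset_index(drop=True), exclusion_log=exclusions)
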