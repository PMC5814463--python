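"""Gene-set over-representation analysis for the pooled predictor genes.

The workflow mirrors the study's exploratory enrichment: user-supplied
GO/Reactome/KEGG sets (GMT format) are intersected with a background
universe (by default the genes shared by all analyzed cohorts), filtered
by a retention rule (at least 3 predictor genes and at least 10% of the
set overlapping the predictors), tested one-sided by Fisher's exact
(hypergeometric) test, and Benjamini–Hochberg corrected.

No pathway content ships with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_gene_sets",
    "overrepresentation_fet",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    background: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.background = {g.upper() for g in self.background}
        self.sets = {name: {g.upper() for g in genes}
                     for name, genes in self.sets.items()}
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to_background(self) -> "GeneSetCollection":
        """Drop genes absent from the background; remove emptied sets."""
        restricted = {}
        for name, genes in self.sets.items():
            kept = genes & self.background
            if kept:
                restricted[name] = kept
            else:
                logger.info("gene set %s empty after background intersection; "
                            "dropped", name)
        return GeneSetCollection(sets=restricted, background=self.background,
                                 descriptions=self.descriptions)


def read_gmt(path: str | Path, background: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...) into a collection.

    If no background is given, the union of all set members is used.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {i}: expected name, description, >=1 gene")
        name, desc, *genes = fields
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = {g.strip().upper() for g in genes if g.strip()}
        descriptions[name] = desc
    bg = background if background is not None else set().union(*sets.values())
    return GeneSetCollection(sets=sets, background=bg, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in coll.sets.items():
        desc = coll.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def filter_gene_sets(coll: GeneSetCollection, predictors: set[str],
                     min_overlap: int = 3,
                     min_fraction: float = 0.10) -> GeneSetCollection:
    """Retention filter before testing.

    After intersecting every set with the background, keeps sets whose
    overlap with the predictor genes is at least ``min_overlap`` genes
    AND at least ``min_fraction`` of the set's (intersected) size.
    Predictor genes outside the background are dropped with a warning.
    """
    predictors = {g.upper() for g in predictors}
    stray = predictors - coll.background
    if stray:
        logger.warning("filter_gene_sets: %d predictor genes outside the "
                       "background dropped: %s", len(stray), sorted(stray)[:10])
        predictors = predictors & coll.background
    coll = coll.restricted_to_background()
    kept = {}
    for name, genes in coll.sets.items():
        overlap = len(genes & predictors)
        if overlap >= min_overlap and overlap >= min_fraction * len(genes):
            kept[name] = genes
    if not kept:
        logger.warning("filter_gene_sets: no gene sets pass the retention filter")
    return GeneSetCollection(sets=kept, background=coll.background,
                             descriptions=coll.descriptions)


def overrepresentation_fet(coll: GeneSetCollection, predictors: set[str],
                           fdr: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher's exact (hypergeometric) over-representation test.

    For each set, the 2x2 table is (in set / not in set) x (predictor /
    rest of background); the enrichment p is the hypergeometric upper
    tail P(X >= overlap).  q-values are Benjamini–Hochberg; a set is
    called significant at ``q < fdr``.
    """
    predictors = {g.upper() for g in predictors} & coll.background
    N = len(coll.background)
    n_pred = len(predictors)
    rows = []
    for name, genes in coll.sets.items():
        if not genes <= coll.background:
            raise ValueError(f"gene set {name!r} extends beyond the background")
        K = len(genes)
        k = len(genes & predictors)
        p = float(hypergeom.sf(k - 1, N, K, n_pred))
        # sample odds ratio of the 2x2 table (inf when a margin is empty)
        a, b = k, n_pred - k
        c, d = K - k, N - K - (n_pred - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"gene_set": name, "set_size": K, "overlap": k,
                     "odds_ratio": odds, "p_value": p,
                     "overlap_genes": ",".join(sorted(genes & predictors))})
    if not rows:
        return pd.DataFrame(columns=["gene_set", "set_size", "overlap",
                                     "odds_ratio", "p_value", "q_value",
                                     "significant", "overlap_genes"])
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df["q_value"] < fdr
    return df.sort_values("p_value", ignore_index=True)
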