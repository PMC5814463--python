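"""Registry of the 21 analyzed sepsis cohorts and mortality summaries.

The registry transcribes the published per-cohort survivor and
non-survivor counts: 12 discovery cohorts (485 survivors / 157
non-survivors), 5 community-onset validation cohorts (161 / 28), and 4
hospital-acquired-infection cohorts (258 / 24).  Two notes on the
transcription: the GSE13015 study contributes two cohorts (a: 35/13,
b: 8/7), and the two GAinS-array cohorts are merged into the single
record E-MTAB-4421.51 (15/7) — the parse consistent with all three
printed role totals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortRecord", "load_registry", "summarize_mortality",
           "REGISTRY_FILE"]

REGISTRY_FILE = "cohort_registry.tsv"
REGISTRY_SHA256 = (
    "a6aab077fe4a066052ca04b68482aa4e7307733ff00de4b54edfe10f061f5bcd"
)

ROLES = ("discovery", "validation", "hai")


@dataclass(frozen=True)
class CohortRecord:
    """One cohort's registry row."""

    accession: str
    role: str
    n_survived: int
    n_died: int
    description: str = ""
    country: str = ""
    timing: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.accession}: unknown role {self.role!r}")
        if self.n_survived < 0 or self.n_died < 0:
            raise ValueError(f"{self.accession}: negative counts")
        if self.n_survived + self.n_died < 1:
            raise ValueError(f"{self.accession}: empty cohort")

    @property
    def n_total(self) -> int:
        return self.n_survived + self.n_died

    @property
    def mortality_rate(self) -> float:
        return self.n_died / self.n_total


def load_registry(path: str | Path | None = None,
                  verify_checksum: bool = True) -> list[CohortRecord]:
    """Load the cohort registry (the packaged fixture by default).

    The packaged fixture is guarded by a checksum; a mismatch raises.
    """
    if path is None:
        ref = resources.files("sepsisprog.data") / REGISTRY_FILE
        raw = ref.read_bytes()
        if verify_checksum:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != REGISTRY_SHA256:
                raise ValueError(
                    f"cohort registry fixture failed its checksum (got {digest})"
                )
        from io import BytesIO
        df = pd.read_csv(BytesIO(raw), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = [
        CohortRecord(
            accession=row["accession"], role=row["role"],
            n_survived=int(row["n_survived"]), n_died=int(row["n_died"]),
            description=str(row.get("description", "")),
            country=str(row.get("country", "")),
            timing=str(row.get("timing", "")),
        )
        for _, row in df.iterrows()
    ]
    accessions = [r.accession for r in records]
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate accessions in registry")
    return records


def summarize_mortality(records: list[CohortRecord],
                        roles: tuple[str, ...] | None = None) -> dict:
    """Totals and per-cohort mortality rates, optionally filtered by role.

    ``mean_rate`` is the unweighted mean of per-cohort rates and
    ``sd_rate`` the population standard deviation (divisor N), both as
    fractions.
    """
    if roles is not None:
        records = [r for r in records if r.role in roles]
    if not records:
        raise ValueError("no cohorts after role filter")
    rates = np.array([r.mortality_rate for r in records])
    return {
        "n_cohorts": len(records),
        "total_survived": sum(r.n_survived for r in records),
        "total_died": sum(r.n_died for r in records),
        "per_cohort_rates": {r.accession: r.mortality_rate for r in records},
        "mean_rate": float(rates.mean()),
        "sd_rate": float(rates.std(ddof=0)),
    }
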