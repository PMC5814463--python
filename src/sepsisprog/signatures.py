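"""Gene signatures for sepsis mortality prognosis.

A signature is a named pair of gene lists: genes expressed *higher* in
patients who die within 30 days (``up``) and genes expressed *lower*
(``down``).  Four published whole-blood predictors ship as a built-in
fixture (from Duke University, Sage Bionetworks — one penalized logistic
regression and one random forest gene set — and Stanford University);
arbitrary user signatures are loaded from GMT or YAML files.

Gene identity is the official symbol string, upper-cased.  No alias
resolution is attempted: the published predictors are defined on symbols,
and symbol-level matching keeps scoring deterministic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SignatureSet",
    "OverlapReport",
    "load_signatures",
    "builtin_signatures",
    "pooled_union",
    "signature_overlap",
    "BUILTIN_SIGNATURE_FILE",
]

#: packaged fixture carrying the four published mortality predictors
BUILTIN_SIGNATURE_FILE = "mortality_predictors.gmt"

#: sha256 of the packaged fixture; guards against accidental edits
BUILTIN_SIGNATURE_SHA256 = (
    "c18cb249bf519a4ac7e05c38eee014343a7846f1e46d5a02167fc07b33d42e5d"
)


class SignatureError(ValueError):
    """Raised for malformed or inconsistent gene signatures."""


@dataclass(frozen=True)
class GeneSignature:
    """Named up/down gene lists defining a prognostic signature.

    Parameters
    ----------
    name
        Short identifier (e.g. ``"Stanford"``).
    up
        Gene symbols expressed higher in non-survivors.
    down
        Gene symbols expressed lower in non-survivors.
    """

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise SignatureError("signature name must be nonempty")
        up = frozenset(_normalize(self.up, self.name, "up"))
        down = frozenset(_normalize(self.down, self.name, "down"))
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        overlap = up & down
        if overlap:
            raise SignatureError(
                f"signature {self.name!r}: genes in both up and down lists: "
                f"{sorted(overlap)}"
            )
        if not (up | down):
            raise SignatureError(f"signature {self.name!r} has no genes")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def swapped(self) -> "GeneSignature":
        """Return the signature with up and down lists exchanged."""
        return GeneSignature(self.name, up=self.down, down=self.up)


def _normalize(genes: Iterable[str], name: str, side: str) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        if not isinstance(g, str) or not g.strip():
            raise SignatureError(
                f"signature {name!r}: empty/non-string gene symbol in {side} list"
            )
        sym = g.strip().upper()
        if sym in seen:
            logger.warning(
                "signature %s: duplicate %s gene %s dropped", name, side, sym
            )
            continue
        seen.add(sym)
        out.append(sym)
    return out


@dataclass
class SignatureSet:
    """Ordered collection of uniquely named signatures."""

    signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SignatureError(f"duplicate signature names: {dupes}")

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]


def _parse_gmt(lines: Iterable[str]) -> SignatureSet:
    """Parse the GMT dialect: ``<name>_up`` / ``<name>_down`` line pairs."""
    halves: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise SignatureError(
                f"GMT line {i}: expected name, description and >=1 gene"
            )
        label, _desc, *genes = fields
        for side in ("up", "down"):
            if label.lower().endswith(f"_{side}"):
                name = label[: -(len(side) + 1)]
                break
        else:
            raise SignatureError(
                f"GMT line {i}: set name {label!r} must end in _up or _down"
            )
        if name not in halves:
            halves[name] = {}
            order.append(name)
        if side in halves[name]:
            raise SignatureError(f"duplicate GMT record {label!r}")
        halves[name][side] = genes
    sigs = [
        GeneSignature(n, up=frozenset(halves[n].get("up", ())),
                      down=frozenset(halves[n].get("down", ())))
        for n in order
    ]
    return SignatureSet(sigs)


def _parse_yaml(text: str) -> SignatureSet:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "signatures" not in doc:
        raise SignatureError("YAML signature file needs a top-level 'signatures' list")
    sigs = []
    for rec in doc["signatures"]:
        try:
            name = rec["name"]
        except (TypeError, KeyError) as exc:
            raise SignatureError(f"signature record missing 'name': {rec!r}") from exc
        sigs.append(
            GeneSignature(
                name,
                up=frozenset(rec.get("up") or ()),
                down=frozenset(rec.get("down") or ()),
            )
        )
    return SignatureSet(sigs)


def load_signatures(path: str | Path) -> SignatureSet:
    """Load a :class:`SignatureSet` from a GMT or YAML file.

    GMT files carry two lines per signature (``<name>_up``,
    ``<name>_down``); YAML files carry explicit ``up``/``down`` keys per
    record.  Symbols are upper-cased, duplicates within a list dropped
    with a warning, and up/down overlap is a validation error.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _parse_yaml(text)
    return _parse_gmt(text.splitlines())


def builtin_signatures(verify_checksum: bool = True) -> SignatureSet:
    """Return the four published mortality predictors.

    The packaged fixture is checksum-guarded; pass
    ``verify_checksum=False`` to skip the guard.
    """
    ref = resources.files("sepsisprog.data") / BUILTIN_SIGNATURE_FILE
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != BUILTIN_SIGNATURE_SHA256:
            raise SignatureError(
                "built-in signature fixture failed its checksum "
                f"(got {digest})"
            )
    return _parse_gmt(raw.decode().splitlines())


def pooled_union(sigs: SignatureSet | Iterable[GeneSignature],
                 name: str = "pooled") -> GeneSignature:
    """Directional union of several signatures.

    Genes appearing in any up list are pooled into ``up``, likewise for
    ``down``.  A gene listed up in one signature and down in another is
    a directional conflict and raises (none occurs among the four
    built-in predictors, which pool to 58 genes: 31 up, 27 down).
    """
    sig_list = list(sigs)
    if not sig_list:
        raise SignatureError("pooled_union of an empty signature collection")
    up: set[str] = set()
    down: set[str] = set()
    for s in sig_list:
        up |= s.up
        down |= s.down
    conflict = up & down
    if conflict:
        raise SignatureError(
            f"directional conflict between signatures for genes {sorted(conflict)}"
        )
    return GeneSignature(name, up=frozenset(up), down=frozenset(down))


@dataclass(frozen=True)
class OverlapReport:
    """Symmetric overlap between two signatures."""

    shared_up: frozenset[str]
    shared_down: frozenset[str]
    conflicting: frozenset[str]  # up in one, down in the other

    @property
    def n_shared(self) -> int:
        return len(self.shared_up) + len(self.shared_down)


def signature_overlap(a: GeneSignature, b: GeneSignature) -> OverlapReport:
    """Report genes shared (same direction) or conflicting between two signatures."""
    return OverlapReport(
        shared_up=a.up & b.up,
        shared_down=a.down & b.down,
        conflicting=frozenset((a.up & b.down) | (a.down & b.up)),
    )
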