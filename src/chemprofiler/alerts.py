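"""SMARTS-catalog screening: PAINS families, structural alerts (toxicophores)
and a cationic-amphiphilic-drug phospholipidosis flag.

Catalogs are plain-text ``family_name<TAB>SMARTS`` files shipped with the
package (partial but versioned; see the data files). The phospholipidosis
model is a documented composite proxy for SMARTS-fragment classifiers of
cationic amphiphilic drugs: a protonatable basic nitrogen plus at least two
rings plus logP >= 3. It reproduces the input/output contract (boolean
inducer flag + named matched pattern) of published fragment models, not any
specific published fragment list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .curation import CompoundRecord
from .descriptors import DescriptorVector, count_basic_nitrogens

__all__ = [
    "AlertCatalog",
    "AlertReport",
    "load_catalog",
    "available_catalogs",
    "screen",
    "screen_set",
    "phospholipidosis_flag",
]

_SHIPPED = ("pains", "structural_alerts")


@dataclass
class AlertCatalog:
    """A named collection of (family_name, SMARTS) substructure queries."""

    name: str
    entries: list[tuple[str, str]]
    _patterns: dict[str, Chem.Mol] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for family, smarts in self.entries:
            if family in seen:
                raise ValueError(f"duplicate family {family!r} in catalog {self.name!r}")
            seen.add(family)
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(
                    f"catalog {self.name!r}: SMARTS for {family!r} does not compile: {smarts!r}"
                )
            self._patterns[family] = patt

    @property
    def families(self) -> list[str]:
        return [family for family, _ in self.entries]

    def serialize(self, path: str | Path) -> None:
        """Write the catalog back to the plain-text tab-separated format."""
        with Path(path).open("w") as fh:
            fh.write(f"# catalog: {self.name}\n")
            for family, smarts in self.entries:
                fh.write(f"{family}\t{smarts}\n")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "AlertCatalog":
        path = Path(path)
        entries = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            family, smarts = line.split("\t", 1)
            entries.append((family.strip(), smarts.strip()))
        return cls(name=name or path.stem, entries=entries)


@dataclass
class AlertReport:
    """Named catalog matches for one compound.

    ``alert_count`` is the number of distinct structural-alert families
    matched (the quantity consumed by QED); PAINS matches do not count
    toward it.
    """

    compound_id: str
    matches: list[tuple[str, str]]  # (catalog_name, family_name)

    @property
    def alert_count(self) -> int:
        return len({f for c, f in self.matches if c == "structural_alerts"})

    def families(self, catalog: str) -> list[str]:
        return [f for c, f in self.matches if c == catalog]


def available_catalogs() -> tuple[str, ...]:
    return _SHIPPED


def load_catalog(name: str) -> AlertCatalog:
    """Load a shipped catalog by name ('pains' or 'structural_alerts')."""
    if name not in _SHIPPED:
        raise ValueError(
            f"unknown catalog {name!r}; available: {', '.join(_SHIPPED)}"
        )
    text = resources.files("chemprofiler.data").joinpath(f"{name}.smarts").read_text()
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        family, smarts = line.split("\t", 1)
        entries.append((family.strip(), smarts.strip()))
    return AlertCatalog(name=name, entries=entries)


def screen(record: CompoundRecord, catalog: AlertCatalog) -> AlertReport:
    """Match every catalog SMARTS against one compound. Deterministic."""
    matches = [
        (catalog.name, family)
        for family, _ in catalog.entries
        if record.structure.HasSubstructMatch(catalog._patterns[family])
    ]
    return AlertReport(compound_id=record.id, matches=matches)


def screen_set(
    records: list[CompoundRecord], catalogs: list[AlertCatalog]
) -> dict[str, AlertReport]:
    """Screen a compound set against several catalogs, merging per compound."""
    out: dict[str, AlertReport] = {}
    for rec in records:
        merged: list[tuple[str, str]] = []
        for cat in catalogs:
            merged.extend(screen(rec, cat).matches)
        out[rec.id] = AlertReport(compound_id=rec.id, matches=merged)
    return out


def phospholipidosis_flag(
    record: CompoundRecord, dv: DescriptorVector
) -> tuple[bool, str | None]:
    """Cationic-amphiphilic-drug phospholipidosis-inducer flag.

    Inducer iff all three hold: >= 1 basic nitrogen protonatable at pH 7
    (per the descriptor module's ionization rules), >= 2 rings, and
    logP >= 3. The matched-pattern string names the satisfied
    sub-conditions; None when not an inducer.
    """
    basic_n = count_basic_nitrogens(record)
    conds = (
        ("basic_nitrogen", basic_n >= 1),
        ("rings>=2", dv.rings >= 2),
        ("logP>=3", dv.logp >= 3.0),
    )
    if all(ok for _, ok in conds):
        return True, "+".join(name for name, _ in conds)
    return False, None
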