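"""Chemical registry: the substances that define a read-across category.

A registry row describes one chemical by its identity (name, CAS), the
physicochemical descriptors that drive baseline aquatic toxicity
(molecular weight, log Kow, water solubility) and the grouping attributes
used to build a read-across category (mode of action, functional group,
subgroup, Verhaar activity class).  The packaged fixture
``chemicals_table1.csv`` holds 25 organophosphate/carbamate insecticides
that act through acetylcholinesterase (AChE) inhibition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import RegistryError, RowError, SchemaError

#: Mode of action shared by every chemical in the packaged category.
ACHE_INHIBITION = "AChE_inhibition"

#: Functional groups recognised for the AChE-inhibition category.
FUNCTIONAL_GROUPS = frozenset({"ester_phosphate", "carbamate", "thiophosphate"})

_CAS_RE = re.compile(r"^\d+-\d+-\d$")

REQUIRED_COLUMNS = (
    "name",
    "cas",
    "molecular_weight",
    "log_kow",
    "water_solubility_mg_L",
    "moa",
    "functional_group",
    "subgroup",
    "verhaar_class",
)


@dataclass(frozen=True)
class ChemicalRecord:
    """One registered chemical.

    Attributes
    ----------
    molecular_weight : float
        g/mol, strictly positive.
    log_kow : float
        Base-10 log of the octanol-water partition coefficient.
    water_solubility : float
        mg/L, strictly positive.
    moa : str
        Mode of toxic action, e.g. ``"AChE_inhibition"``.
    functional_group : str
        One of :data:`FUNCTIONAL_GROUPS` for AChE inhibitors.
    verhaar_class : int
        Verhaar screening class (1-5); input data, never computed here.
    """

    name: str
    cas: str
    molecular_weight: float
    log_kow: float
    water_solubility: float
    moa: str
    functional_group: str
    subgroup: str | None = None
    verhaar_class: int = 4

    def __post_init__(self) -> None:
        if not _CAS_RE.match(self.cas):
            raise ValueError(f"malformed CAS number: {self.cas!r}")
        if not self.molecular_weight > 0:
            raise ValueError(f"{self.cas}: molecular_weight must be > 0")
        if not self.water_solubility > 0:
            raise ValueError(f"{self.cas}: water_solubility must be > 0")
        if not 1 <= int(self.verhaar_class) <= 5:
            raise ValueError(f"{self.cas}: verhaar_class must be in 1..5")
        if self.moa == ACHE_INHIBITION and self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"{self.cas}: functional_group {self.functional_group!r} not in "
                f"{sorted(FUNCTIONAL_GROUPS)}"
            )

    @property
    def water_solubility_ug_L(self) -> float:
        """Water solubility on the canonical toxicity scale (µg/L)."""
        return self.water_solubility * 1000.0


@dataclass(frozen=True)
class SelectionCriteria:
    """Category-membership rules for read-across grouping.

    The log Kow cutoff is inclusive by default: hydrophobicity-driven
    baseline toxicity dominates up to log Kow ~5-6, and the category is
    meant to stay below that regime.
    """

    max_log_kow: float = 5.0
    inclusive: bool = True
    moa: str = ACHE_INHIBITION
    functional_groups: frozenset[str] = field(default_factory=lambda: FUNCTIONAL_GROUPS)

    def admits(self, rec: ChemicalRecord) -> bool:
        if self.inclusive:
            if rec.log_kow > self.max_log_kow:
                return False
        elif rec.log_kow >= self.max_log_kow:
            return False
        if rec.moa != self.moa:
            return False
        return rec.functional_group in self.functional_groups


@dataclass(frozen=True)
class RegistrySummary:
    n: int
    log_kow_min: float
    log_kow_max: float
    functional_group_counts: dict[str, int]
    verhaar_class_counts: dict[int, int]


def packaged_registry_path() -> Path:
    """Path of the packaged 25-chemical AChE-inhibitor registry."""
    return Path(str(resources.files("toxra").joinpath("data/chemicals_table1.csv")))


def load_chemicals(path: str | Path) -> list[ChemicalRecord]:
    """Read a registry CSV into validated :class:`ChemicalRecord` objects.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RowError
        If any row has an unparseable number or fails validation; the
        error lists every offending row index.
    RegistryError
        If two rows share a CAS number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ChemicalRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            records.append(
                ChemicalRecord(
                    name=row["name"].strip(),
                    cas=row["cas"].strip(),
                    molecular_weight=float(row["molecular_weight"]),
                    log_kow=float(row["log_kow"]),
                    water_solubility=float(row["water_solubility_mg_L"]),
                    moa=row["moa"].strip(),
                    functional_group=row["functional_group"].strip(),
                    subgroup=row["subgroup"].strip() or None,
                    verhaar_class=int(row["verhaar_class"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append((int(i), str(exc)))
    if problems:
        raise RowError(problems)

    seen: dict[str, str] = {}
    for rec in records:
        if rec.cas in seen:
            raise RegistryError(f"duplicate CAS {rec.cas} ({seen[rec.cas]} / {rec.name})")
        seen[rec.cas] = rec.name
    return records


def select_category(
    records: Iterable[ChemicalRecord],
    criteria: SelectionCriteria | None = None,
) -> list[ChemicalRecord]:
    """Filter a registry down to the records satisfying the category rules.

    Pure filter: order is preserved and the operation is idempotent.
    """
    criteria = criteria or SelectionCriteria()
    return [rec for rec in records if criteria.admits(rec)]


def registry_summary(records: Sequence[ChemicalRecord]) -> RegistrySummary:
    """Descriptive summary (count, log Kow range, group tallies)."""
    if not records:
        raise RegistryError("cannot summarise an empty registry")
    kows = [rec.log_kow for rec in records]
    fg_counts: dict[str, int] = {}
    vc_counts: dict[int, int] = {}
    for rec in records:
        fg_counts[rec.functional_group] = fg_counts.get(rec.functional_group, 0) + 1
        vc_counts[rec.verhaar_class] = vc_counts.get(rec.verhaar_class, 0) + 1
    return RegistrySummary(
        n=len(records),
        log_kow_min=min(kows),
        log_kow_max=max(kows),
        functional_group_counts=fg_counts,
        verhaar_class_counts=vc_counts,
    )
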