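"""Acute toxicity records and per-species aggregation.

Raw records are single LC50 determinations in the style of ECOTOX
Knowledgebase extracts: one row per (chemical, species, test).  All values
are converted to µg/L at load time.  Replicate determinations for the same
(chemical, species) are collapsed to a geometric mean, pooling the 24, 48
and 96 h exposure durations as a single acute endpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import RegistryError, RowError, SchemaError
from .registry import ChemicalRecord

log = logging.getLogger(__name__)

TAXA = ("fish", "crustacean", "insect", "amphibian")
DURATIONS_H = (24, 48, 96)
UNIT_TO_UG_L = {"ug_per_L": 1.0, "mg_per_L": 1000.0}

REQUIRED_COLUMNS = ("cas", "species", "taxon", "endpoint", "duration_h", "value", "unit")


@dataclass(frozen=True)
class ToxicityRecord:
    """One acute LC50 determination, value stored in canonical µg/L."""

    cas: str
    species: str
    taxon: str
    duration_h: int
    value_ug_L: float
    endpoint: str = "LC50"

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")
        if self.duration_h not in DURATIONS_H:
            raise ValueError(f"duration_h must be one of {DURATIONS_H}")
        if not self.value_ug_L > 0:
            raise ValueError("LC50 must be > 0")
        if self.endpoint != "LC50":
            raise ValueError(f"unsupported endpoint {self.endpoint!r}")


@dataclass(frozen=True)
class SpeciesToxicity:
    """Aggregated LC50 for one (chemical, species): geometric mean of replicates."""

    cas: str
    species: str
    taxon: str
    lc50_ug_L: float
    n_values: int
    min_ug_L: float
    max_ug_L: float

    def __post_init__(self) -> None:
        if not (self.min_ug_L <= self.lc50_ug_L <= self.max_ug_L):
            raise ValueError("geometric mean must lie within [min, max]")
        if self.n_values < 1:
            raise ValueError("n_values must be >= 1")


def packaged_toxicity_ranges() -> pd.DataFrame:
    """Per-chemical × taxon LC50 summaries (n, min, max in mg/L).

    A published range summary of the ECOTOX extracts behind the packaged
    25-chemical registry; useful for demos and sanity checks, not raw
    records.  Several ranges exceed the registry's water-solubility
    limits, which is why :func:`filter_solubility` is switchable.
    """
    from importlib import resources

    path = resources.files("toxra").joinpath("data/toxicity_ranges_table2.csv")
    return pd.read_csv(str(path))


def load_toxicity(path: str | Path) -> list[ToxicityRecord]:
    """Read a toxicity CSV, converting every value to µg/L.

    Expected header: ``cas,species,taxon,endpoint,duration_h,value,unit``
    with ``unit`` one of ``mg_per_L`` / ``ug_per_L`` per row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ToxicityRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            unit = row["unit"].strip()
            if unit not in UNIT_TO_UG_L:
                raise ValueError(f"unknown unit {unit!r}")
            value = float(row["value"]) * UNIT_TO_UG_L[unit]
            records.append(
                ToxicityRecord(
                    cas=row["cas"].strip(),
                    species=row["species"].strip(),
                    taxon=row["taxon"].strip(),
                    duration_h=int(float(row["duration_h"])),
                    value_ug_L=value,
                    endpoint=row["endpoint"].strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append((int(i), str(exc)))
    if problems:
        raise RowError(problems)
    return records


def filter_solubility(
    records: Iterable[ToxicityRecord],
    registry: Sequence[ChemicalRecord] | Mapping[str, ChemicalRecord],
) -> list[ToxicityRecord]:
    """Keep only records whose LC50 is strictly below the water solubility.

    Concentrations at or above the solubility limit cannot be fully
    dissolved, so the nominal LC50 does not reflect true exposure.  A
    record exactly equal to the limit is dropped (strict ``<``).

    Raises
    ------
    RegistryError
        If a record's CAS is absent from the registry.
    """
    if not isinstance(registry, Mapping):
        registry = {rec.cas: rec for rec in registry}
    kept: list[ToxicityRecord] = []
    dropped: dict[str, int] = {}
    for rec in records:
        chem = registry.get(rec.cas)
        if chem is None:
            raise RegistryError(f"CAS {rec.cas} not present in the chemical registry")
        if rec.value_ug_L < chem.water_solubility_ug_L:
            kept.append(rec)
        else:
            dropped[rec.cas] = dropped.get(rec.cas, 0) + 1
    for cas, n in sorted(dropped.items()):
        log.info("solubility filter dropped %d record(s) for CAS %s", n, cas)
    return kept


def aggregate_species(
    records: Iterable[ToxicityRecord],
    durations: Sequence[int] | None = None,
) -> list[SpeciesToxicity]:
    """Collapse replicates to one geometric-mean LC50 per (chemical, species).

    Durations are pooled by default; pass ``durations`` to restrict the
    aggregation to a subset of (24, 48, 96) h.  The geometric mean is used
    for any replicate count (it reduces to the identity for n = 1).
    """
    groups: dict[tuple[str, str], list[ToxicityRecord]] = {}
    for rec in records:
        if durations is not None and rec.duration_h not in durations:
            continue
        groups.setdefault((rec.cas, rec.species), []).append(rec)

    out: list[SpeciesToxicity] = []
    for (cas, species), recs in groups.items():
        values = [r.value_ug_L for r in recs]
        gmean = math.exp(sum(math.log(v) for v in values) / len(values))
        gmean = min(max(gmean, min(values)), max(values))  # guard rounding at n=1
        out.append(
            SpeciesToxicity(
                cas=cas,
                species=species,
                taxon=recs[0].taxon,
                lc50_ug_L=gmean,
                n_values=len(values),
                min_ug_L=min(values),
                max_ug_L=max(values),
            )
        )
    out.sort(key=lambda s: (s.cas, s.taxon, s.species))
    return out
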