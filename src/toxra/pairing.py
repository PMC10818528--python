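"""Source→target pairing and per-taxon species matching.

Within a read-across category the member with the lower log Kow serves as
the data-rich *source* and the member with the higher log Kow as the
*target* whose toxicity is predicted: baseline aquatic toxicity increases
with hydrophobicity, so the target is expected to be the more toxic of
the two.  Pairing spans the whole category (cross-functional-group pairs
are allowed as long as the mode of action is shared); chemicals with
exactly equal log Kow are never paired in either direction.

For a given pair, each aquatic taxon contributes a :class:`TaxonMatch`
partitioning the species universe into

* ``matched`` — species with LC50s for both chemicals and a species
  sensitivity ratio SSR = LC50(target)/LC50(source) ≤ 1,
* ``excluded`` — species with data for both chemicals but SSR > 1
  (the species is *more* sensitive to the source, contradicting the
  hydrophobicity premise, so it donates no SSR),
* ``source_only`` — species with only source-chemical data (the
  prediction candidates proper), and
* ``target_only`` — species that cannot be predicted for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .registry import ChemicalRecord
from .toxdata import SpeciesToxicity, TAXA

#: Taxa used for prediction by default; amphibians are supported by the
#: data model but opt-in.
DEFAULT_PREDICTION_TAXA = ("fish", "crustacean", "insect")

CASE_I = "case_I"
CASE_II = "case_II"
INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class ChemicalPair:
    """Ordered source→target couple; invariant: log_kow(target) > log_kow(source)."""

    source_cas: str
    target_cas: str
    source_name: str
    target_name: str
    delta_log_kow: float
    functional_group_label: str  # the source chemical's group, for reporting

    def __post_init__(self) -> None:
        if self.source_cas == self.target_cas:
            raise ValueError("source and target must differ")
        if not self.delta_log_kow > 0:
            raise ValueError("delta_log_kow must be > 0")


@dataclass(frozen=True)
class SpeciesMatch:
    species: str
    lc50_source_ug_L: float
    lc50_target_ug_L: float

    @property
    def ssr(self) -> float:
        return self.lc50_target_ug_L / self.lc50_source_ug_L


@dataclass(frozen=True)
class ExcludedSpecies:
    species: str
    lc50_source_ug_L: float
    lc50_target_ug_L: float
    reason: str = "source_more_sensitive"

    @property
    def ssr(self) -> float:
        return self.lc50_target_ug_L / self.lc50_source_ug_L


@dataclass(frozen=True)
class TaxonMatch:
    taxon: str
    matched: tuple[SpeciesMatch, ...] = ()
    excluded: tuple[ExcludedSpecies, ...] = ()
    source_only: tuple[tuple[str, float], ...] = ()  # (species, lc50_source)
    target_only: tuple[str, ...] = ()

    @property
    def prediction_species(self) -> tuple[str, ...]:
        """Species for which a prediction can be issued (have a source value)."""
        return tuple(
            [m.species for m in self.matched]
            + [e.species for e in self.excluded]
            + [s for s, _ in self.source_only]
        )

    def source_lc50(self, species: str) -> float:
        for m in self.matched:
            if m.species == species:
                return m.lc50_source_ug_L
        for e in self.excluded:
            if e.species == species:
                return e.lc50_source_ug_L
        for s, v in self.source_only:
            if s == species:
                return v
        raise KeyError(f"no source-chemical LC50 for species {species!r}")

    def known_lc50(self, species: str) -> float | None:
        for m in self.matched:
            if m.species == species:
                return m.lc50_target_ug_L
        for e in self.excluded:
            if e.species == species:
                return e.lc50_target_ug_L
        return None


def enumerate_pairs(records: Sequence[ChemicalRecord]) -> list[ChemicalPair]:
    """All ordered (source, target) couples with log_kow(source) < log_kow(target).

    Output is sorted by (source CAS, target CAS) for reproducible artifacts.
    """
    pairs: list[ChemicalPair] = []
    for s, t in itertools.permutations(records, 2):
        if s.log_kow < t.log_kow:
            pairs.append(
                ChemicalPair(
                    source_cas=s.cas,
                    target_cas=t.cas,
                    source_name=s.name,
                    target_name=t.name,
                    delta_log_kow=t.log_kow - s.log_kow,
                    functional_group_label=s.functional_group,
                )
            )
    pairs.sort(key=lambda p: (p.source_cas, p.target_cas))
    return pairs


def match_species(
    pair: ChemicalPair,
    profiles: Iterable[SpeciesToxicity],
    taxa: Sequence[str] = TAXA,
    exclude_source_more_sensitive: bool = True,
) -> list[TaxonMatch]:
    """Partition the species universe of a pair, taxon by taxon.

    ``profiles`` must already be aggregated (one value per chemical ×
    species).  With ``exclude_source_more_sensitive`` (the default), a
    shared species whose SSR exceeds 1 is moved to ``excluded`` and
    donates no sensitivity ratio; SSR exactly 1 is retained as neutral
    evidence.
    """
    by_taxon: dict[str, dict[str, dict[str, SpeciesToxicity]]] = {}
    for prof in profiles:
        if prof.cas not in (pair.source_cas, pair.target_cas):
            continue
        side = "source" if prof.cas == pair.source_cas else "target"
        by_taxon.setdefault(prof.taxon, {}).setdefault(side, {})[prof.species] = prof

    out: list[TaxonMatch] = []
    for taxon in taxa:
        src = by_taxon.get(taxon, {}).get("source", {})
        tgt = by_taxon.get(taxon, {}).get("target", {})
        matched: list[SpeciesMatch] = []
        excluded: list[ExcludedSpecies] = []
        for species in sorted(set(src) & set(tgt)):
            m = SpeciesMatch(
                species=species,
                lc50_source_ug_L=src[species].lc50_ug_L,
                lc50_target_ug_L=tgt[species].lc50_ug_L,
            )
            if exclude_source_more_sensitive and m.ssr > 1.0:
                excluded.append(
                    ExcludedSpecies(
                        species=species,
                        lc50_source_ug_L=m.lc50_source_ug_L,
                        lc50_target_ug_L=m.lc50_target_ug_L,
                    )
                )
            else:
                matched.append(m)
        source_only = tuple(
            (s, src[s].lc50_ug_L) for s in sorted(set(src) - set(tgt))
        )
        target_only = tuple(sorted(set(tgt) - set(src)))
        out.append(
            TaxonMatch(
                taxon=taxon,
                matched=tuple(matched),
                excluded=tuple(excluded),
                source_only=source_only,
                target_only=target_only,
            )
        )
    return out


def classify_scenario(
    matches: Sequence[TaxonMatch],
    prediction_taxa: Sequence[str] = DEFAULT_PREDICTION_TAXA,
) -> str:
    """Decide the prediction scenario for a pair.

    * ``case_I`` — at least three taxa carry a matched (SSR-donating)
      species, so every prediction taxon has at least two donor taxa
      (SSR-1 and SSR-2 are both available);
    * ``case_II`` — exactly two taxa qualify (single donor taxon);
    * ``ineligible`` — fewer than two.
    """
    qualified = sum(
        1 for m in matches if m.taxon in prediction_taxa and len(m.matched) > 0
    )
    if qualified >= 3:
        return CASE_I
    if qualified == 2:
        return CASE_II
    return INELIGIBLE
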