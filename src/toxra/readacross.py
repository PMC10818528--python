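"""Species sensitivity factors and read-across LC50 prediction.

The species sensitivity ratio (SSR) of a shared species is the ratio of
the target chemical's LC50 to the source chemical's LC50 for that
species; because the target is the more hydrophobic — and hence usually
the more toxic — member of the pair, an admissible SSR is at most 1.
The species sensitivity factor (SSF) is the geometric mean of a set of
donor SSRs, and the predicted LC50 of a candidate species is

    predicted = SSF × LC50_source(candidate species).

Donor enumeration depends on the scenario:

* Case I (≥3 taxa with matched species): every cross-combination of one
  matched species from each of the *other* prediction taxa contributes an
  SSF, so a candidate species receives ∏(matched counts of other taxa)
  predictions.
* Case II (exactly 2 matched taxa): the single other matched taxon
  donates; by default its matched species are pooled into one SSF
  (geometric mean), and with ``donor_selection="closest"`` only the donor
  whose source-chemical LC50 is nearest the candidate's (log scale) is
  used.

A prediction below the known LC50 *over*states toxicity ("over"), one
above it understates toxicity ("under").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .pairing import (
    CASE_I,
    CASE_II,
    DEFAULT_PREDICTION_TAXA,
    ChemicalPair,
    SpeciesMatch,
    TaxonMatch,
)

log = logging.getLogger(__name__)

#: Relative tolerance for treating predicted and known as exactly equal.
TIE_RTOL = 1e-12

OVER = "over"
UNDER = "under"
TIE = "tie"
UNKNOWN = "unknown"
ND = "nd"


def compute_ssr(lc50_target: float, lc50_source: float) -> float:
    """Species sensitivity ratio: target LC50 over source LC50 (same species)."""
    if not (lc50_target > 0 and lc50_source > 0):
        raise ValueError("LC50 values must be > 0")
    return lc50_target / lc50_source


def compute_ssf(ssrs: Sequence[float]) -> float:
    """Species sensitivity factor: geometric mean of donor SSRs."""
    if len(ssrs) == 0:
        raise ValueError("at least one SSR is required")
    if any(not r > 0 for r in ssrs):
        raise ValueError("SSRs must be > 0")
    return math.exp(sum(math.log(r) for r in ssrs) / len(ssrs))


def classify_prediction(predicted: float, known: float) -> str:
    """``over`` if predicted LC50 < known (toxicity overestimated), else ``under``.

    Exact equality (relative tolerance 1e-12) is a ``tie``.
    """
    if not (predicted > 0 and known > 0):
        raise ValueError("LC50 values must be > 0")
    if math.isclose(predicted, known, rel_tol=TIE_RTOL):
        return TIE
    return OVER if predicted < known else UNDER


@dataclass(frozen=True)
class Prediction:
    """One SSF-based LC50 prediction for a (pair, taxon, candidate species)."""

    pair: ChemicalPair
    taxon: str
    target_species: str
    donor_species: tuple[tuple[str, str], ...]  # (taxon, species) per SSR donor
    ssf: float
    predicted_lc50_ug_L: float
    known_lc50_ug_L: float | None
    classification: str
    beyond_source: bool = False  # predicted above the species' own source LC50

    def __post_init__(self) -> None:
        if not self.ssf > 0:
            raise ValueError("ssf must be > 0")
        if (self.classification == UNKNOWN) != (self.known_lc50_ug_L is None):
            raise ValueError("classification 'unknown' iff the known value is absent")


@dataclass(frozen=True)
class RowDecision:
    """Majority over/under verdict for a collection of classified predictions."""

    pair: ChemicalPair
    taxon: str
    n_over: int
    n_under: int
    n_tie: int
    decision: str

    @property
    def n_predictions(self) -> int:
        return self.n_over + self.n_under + self.n_tie


def _donor_sets(
    matches: Sequence[TaxonMatch],
    taxon: str,
    prediction_taxa: Sequence[str],
) -> list[tuple[str, tuple[SpeciesMatch, ...]]]:
    return [
        (m.taxon, m.matched)
        for m in matches
        if m.taxon != taxon and m.taxon in prediction_taxa and m.matched
    ]


def predict_target(
    pair: ChemicalPair,
    matches: Sequence[TaxonMatch],
    taxon: str,
    scenario: str,
    prediction_taxa: Sequence[str] = DEFAULT_PREDICTION_TAXA,
    donor_selection: str = "all",
) -> list[Prediction]:
    """Predict the target chemical's LC50 for every candidate species of a taxon.

    Candidates are all species with a source-chemical value; the known
    target-chemical value (held-out truth) is attached where one exists.
    Returns an empty list, with a logged reason, when no donor SSRs are
    available.
    """
    taxon_match = next((m for m in matches if m.taxon == taxon), None)
    if taxon_match is None or not taxon_match.prediction_species:
        log.info("%s→%s %s: no candidate species with source data",
                 pair.source_name, pair.target_name, taxon)
        return []
    donors = _donor_sets(matches, taxon, prediction_taxa)
    if not donors:
        log.info("%s→%s %s: no donor taxa with matched species",
                 pair.source_name, pair.target_name, taxon)
        return []

    predictions: list[Prediction] = []
    for species in taxon_match.prediction_species:
        source_lc50 = taxon_match.source_lc50(species)
        known = taxon_match.known_lc50(species)

        if scenario == CASE_I:
            combos: Iterable[tuple[SpeciesMatch, ...]] = product(
                *(matched for _, matched in donors)
            )
            donor_taxa = [t for t, _ in donors]
            for combo in combos:
                ssf = compute_ssf([m.ssr for m in combo])
                predictions.append(
                    _make_prediction(
                        pair, taxon, species,
                        tuple(zip(donor_taxa, (m.species for m in combo))),
                        ssf, source_lc50, known,
                    )
                )
        elif scenario == CASE_II:
            donor_taxon, matched = max(donors, key=lambda d: len(d[1]))
            if donor_selection == "closest":
                pick = min(
                    matched,
                    key=lambda m: abs(
                        math.log(m.lc50_source_ug_L) - math.log(source_lc50)
                    ),
                )
                used = (pick,)
            elif donor_selection == "all":
                used = matched
            else:
                raise ValueError(f"unknown donor_selection {donor_selection!r}")
            ssf = compute_ssf([m.ssr for m in used])
            predictions.append(
                _make_prediction(
                    pair, taxon, species,
                    tuple((donor_taxon, m.species) for m in used),
                    ssf, source_lc50, known,
                )
            )
        else:
            raise ValueError(f"cannot predict under scenario {scenario!r}")
    return predictions


def _make_prediction(
    pair: ChemicalPair,
    taxon: str,
    species: str,
    donor_species: tuple[tuple[str, str], ...],
    ssf: float,
    source_lc50: float,
    known: float | None,
) -> Prediction:
    predicted = ssf * source_lc50
    return Prediction(
        pair=pair,
        taxon=taxon,
        target_species=species,
        donor_species=donor_species,
        ssf=ssf,
        predicted_lc50_ug_L=predicted,
        known_lc50_ug_L=known,
        classification=UNKNOWN if known is None else classify_prediction(predicted, known),
        beyond_source=predicted > source_lc50,
    )


def decide_row(predictions: Sequence[Prediction]) -> RowDecision:
    """Strict-majority verdict over classified predictions of one pair × taxon.

    Ties between the over and under counts — including the all-tie case —
    give ``nd`` (not determined).  Predictions without a known value must
    be filtered out by the caller.
    """
    if not predictions:
        raise ValueError("decide_row requires at least one classified prediction")
    if any(p.classification == UNKNOWN for p in predictions):
        raise ValueError("unclassified (unknown) predictions must be excluded")
    pair, taxon = predictions[0].pair, predictions[0].taxon
    n_over = sum(1 for p in predictions if p.classification == OVER)
    n_under = sum(1 for p in predictions if p.classification == UNDER)
    n_tie = sum(1 for p in predictions if p.classification == TIE)
    if n_over > n_under:
        decision = OVER
    elif n_under > n_over:
        decision = UNDER
    else:
        decision = ND
    return RowDecision(
        pair=pair, taxon=taxon,
        n_over=n_over, n_under=n_under, n_tie=n_tie,
        decision=decision,
    )
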