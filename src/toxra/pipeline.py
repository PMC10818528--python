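"""End-to-end read-across workflow: tables in, prediction artifacts out.

Chains the library stages — registry selection, toxicity aggregation,
pairing, scenario classification, SSF prediction and agreement
evaluation — and writes deterministic CSV artifacts plus a manifest with
input hashes, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import agreement
from .pairing import (
    DEFAULT_PREDICTION_TAXA,
    INELIGIBLE,
    classify_scenario,
    enumerate_pairs,
    match_species,
)
from .readacross import UNKNOWN, Prediction, decide_row, predict_target
from .registry import SelectionCriteria, load_chemicals, select_category
from .toxdata import aggregate_species, filter_solubility, load_toxicity

log = logging.getLogger(__name__)

STATUS_OK = 0
STATUS_INPUT_ERROR = 1
STATUS_NO_PAIRS = 2


@dataclass
class RunConfig:
    chemicals_path: str
    toxicity_path: str
    out_dir: str
    max_log_kow: float = 5.0
    prediction_taxa: tuple[str, ...] = DEFAULT_PREDICTION_TAXA
    donor_selection: str = "all"
    apply_solubility_filter: bool = True
    log_base: int | str = 10
    make_plots: bool = False


@dataclass
class PipelineResult:
    status: int
    n_chemicals: int = 0
    n_pairs: int = 0
    n_predictions: int = 0
    artifacts: dict[str, str] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append(
            {
                "source_cas": p.pair.source_cas,
                "target_cas": p.pair.target_cas,
                "source_name": p.pair.source_name,
                "target_name": p.pair.target_name,
                "functional_group": p.pair.functional_group_label,
                "taxon": p.taxon,
                "target_species": p.target_species,
                "donors": "|".join(f"{t}:{s}" for t, s in p.donor_species),
                "ssf": p.ssf,
                "predicted_ug_L": p.predicted_lc50_ug_L,
                "known_ug_L": p.known_lc50_ug_L,
                "classification": p.classification,
                "beyond_source": p.beyond_source,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["source_cas", "target_cas", "taxon", "target_species", "donors"]
        ).reset_index(drop=True)
    return df


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole workflow; artifacts land in ``config.out_dir``.

    Returns a result whose ``status`` mirrors the CLI exit codes:
    0 success, 2 no eligible pairs.  Input/schema problems raise.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    registry = load_chemicals(config.chemicals_path)
    selected = select_category(
        registry, SelectionCriteria(max_log_kow=config.max_log_kow)
    )
    log.info("selected %d of %d registry chemicals", len(selected), len(registry))

    records = load_toxicity(config.toxicity_path)
    if config.apply_solubility_filter:
        n0 = len(records)
        records = filter_solubility(records, registry)
        log.info("solubility filter kept %d of %d records", len(records), n0)
    profiles = aggregate_species(records)
    log.info("aggregated %d (chemical, species) profiles", len(profiles))

    pairs = enumerate_pairs(selected)
    predictions: list[Prediction] = []
    pair_rows, decision_rows = [], []
    n_eligible = 0
    for pair in pairs:
        matches = match_species(pair, profiles)
        scenario = classify_scenario(matches, config.prediction_taxa)
        pair_rows.append(
            {
                "source_cas": pair.source_cas,
                "target_cas": pair.target_cas,
                "source_name": pair.source_name,
                "target_name": pair.target_name,
                "functional_group": pair.functional_group_label,
                "delta_log_kow": pair.delta_log_kow,
                "scenario": scenario,
                "matched_counts": "/".join(
                    str(len(m.matched))
                    for m in matches
                    if m.taxon in config.prediction_taxa
                ),
            }
        )
        if scenario == INELIGIBLE:
            continue
        n_eligible += 1
        for taxon in config.prediction_taxa:
            preds = predict_target(
                pair, matches, taxon, scenario,
                prediction_taxa=config.prediction_taxa,
                donor_selection=config.donor_selection,
            )
            predictions.extend(preds)
            by_species: dict[str, list[Prediction]] = {}
            for p in preds:
                if p.classification != UNKNOWN:
                    by_species.setdefault(p.target_species, []).append(p)
            for species in sorted(by_species):
                d = decide_row(by_species[species])
                decision_rows.append(
                    {
                        "source_cas": pair.source_cas,
                        "target_cas": pair.target_cas,
                        "taxon": taxon,
                        "target_species": species,
                        "n_over": d.n_over,
                        "n_under": d.n_under,
                        "n_tie": d.n_tie,
                        "decision": d.decision,
                    }
                )

    artifacts: dict[str, str] = {}

    def write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = str(path)

    write(pd.DataFrame(pair_rows), "pairs.csv")
    write(_predictions_frame(predictions), "predictions.csv")
    write(pd.DataFrame(decision_rows), "decisions.csv")

    status = STATUS_OK
    with_known = [p for p in predictions if p.known_lc50_ug_L is not None]
    if n_eligible == 0:
        log.warning("no eligible pairs; writing empty artifacts")
        status = STATUS_NO_PAIRS
    elif with_known:
        frames = []
        for grouping in ("overall", "functional_group"):
            for s in agreement.summarize(
                predictions, grouping=grouping, log_base=config.log_base
            ):
                frames.append({"grouping": grouping, **asdict(s)})
        write(pd.DataFrame(frames), "agreement.csv")
        if config.make_plots:
            rs = agreement.ResidualSet.from_predictions(
                with_known, log_base=config.log_base
            )
            agreement.plot_scatter(rs, out / "scatter.png")
            agreement.plot_bland_altman(
                agreement.bland_altman(rs), out / "bland_altman.png"
            )
            artifacts["scatter.png"] = str(out / "scatter.png")
            artifacts["bland_altman.png"] = str(out / "bland_altman.png")

    manifest = {
        "inputs": {
            "chemicals": _sha256(config.chemicals_path),
            "toxicity": _sha256(config.toxicity_path),
        },
        "config": {
            **{k: v for k, v in asdict(config).items()},
            "prediction_taxa": list(config.prediction_taxa),
        },
        "counts": {
            "chemicals_selected": len(selected),
            "pairs": len(pairs),
            "eligible_pairs": n_eligible,
            "predictions": len(predictions),
            "predictions_with_known": len(with_known),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest.json"] = str(out / "manifest.json")

    return PipelineResult(
        status=status,
        n_chemicals=len(selected),
        n_pairs=len(pairs),
        n_predictions=len(predictions),
        artifacts=artifacts,
    )
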