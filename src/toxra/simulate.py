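"""Synthetic registries and toxicity tables with known ground truth.

The generator emulates the structure of an ECOTOX-style acute-toxicity
extract for a hydrophobicity-driven category: on the log10 scale,

    log10 LC50(c, s, k) = alpha − beta · logKow_c + taxon_offset(taxon(s))
                          + species_effect_s + interaction_{c,s} + noise_k

so toxicity increases (LC50 falls) with log Kow at ``beta`` decades per
Kow unit, taxa differ by fixed offsets, species scatter around their
taxon with SD ``species_sd``, chemical × species idiosyncrasy has SD
``interaction_sd`` and replicate measurement error SD ``replicate_sd``.

Because species and taxon effects are additive in log space they cancel
exactly in a species sensitivity ratio: with zero interaction variance
every pair has the closed-form true factor SSF = 10^(−beta · Δlog Kow),
which makes the full pipeline exactly invertible and is the basis of the
end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairing import ChemicalPair
from .toxdata import TAXA

_DEFAULT_TAXON_OFFSETS = {
    "fish": 0.0,
    "crustacean": -1.0,
    "insect": -0.5,
    "amphibian": 1.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror a 25-chemical AChE-style category.

    ``alpha`` is the log10 LC50 (µg/L) of a hypothetical fish species at
    log Kow 0; ``beta`` the potency gain in decades per log Kow unit.
    """

    n_chemicals: int = 25
    log_kow_range: tuple[float, float] = (-0.85, 4.96)
    taxa: tuple[str, ...] = ("fish", "crustacean", "insect")
    species_per_taxon: int = 8
    replicates_per_species: int = 3
    intercept_alpha: float = 4.0
    potency_slope_beta: float = 0.8
    taxon_offsets: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXON_OFFSETS)
    )
    species_sd: float = 0.6
    interaction_sd: float = 0.2
    replicate_sd: float = 0.3
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 2:
            raise ValueError("need at least two chemicals")
        lo, hi = self.log_kow_range
        if not lo < hi:
            raise ValueError("log_kow_range must be ordered (low, high)")
        if any(t not in TAXA for t in self.taxa):
            raise ValueError(f"taxa must be a subset of {TAXA}")
        if self.species_per_taxon < 1 or self.replicates_per_species < 1:
            raise ValueError("species_per_taxon and replicates_per_species must be >= 1")
        for name in ("species_sd", "interaction_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.potency_slope_beta < 0:
            raise ValueError("potency_slope_beta must be >= 0")


def _chemical_frame(config: SyntheticConfig) -> pd.DataFrame:
    kows = np.linspace(*config.log_kow_range, config.n_chemicals)
    fgs = ["ester_phosphate", "carbamate", "thiophosphate"]
    rows = []
    for i, kow in enumerate(kows):
        rows.append(
            {
                "name": f"SYN-{i + 1:03d}",
                "cas": f"{100000 + i}-00-{i % 10}",
                "molecular_weight": 250.0,
                "log_kow": round(float(kow), 6),
                # generous limit so the solubility filter is inert on
                # synthetic data unless the caller tightens it
                "water_solubility_mg_L": 1e6,
                "moa": "AChE_inhibition",
                "functional_group": fgs[i % 3],
                "subgroup": "",
                "verhaar_class": 4,
            }
        )
    return pd.DataFrame(rows)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (chemical table, toxicity table, truth table).

    The frames use the exact CSV schemas of the registry and toxicity
    loaders.  The truth table carries, per ordered pair and shared
    species, the noise-free species sensitivity ratio and, per pair, the
    model SSF 10^(−beta·ΔlogKow) (exact when ``interaction_sd`` is 0).
    All randomness flows from one generator seeded with ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chem = _chemical_frame(config)

    species = []  # (species_name, taxon, species_effect)
    for taxon in config.taxa:
        effects = rng.normal(0.0, config.species_sd, size=config.species_per_taxon)
        for j, eff in enumerate(effects):
            species.append((f"synthetic_{taxon}_{j + 1}", taxon, float(eff)))

    n_chem, n_spec = len(chem), len(species)
    interaction = rng.normal(0.0, config.interaction_sd, size=(n_chem, n_spec))
    keep = rng.random(size=(n_chem, n_spec)) >= config.dropout_prob

    tox_rows = []
    true_log10 = np.empty((n_chem, n_spec))
    for ci, chem_row in chem.iterrows():
        for si, (sp_name, taxon, sp_eff) in enumerate(species):
            mean_log10 = (
                config.intercept_alpha
                - config.potency_slope_beta * chem_row["log_kow"]
                + config.taxon_offsets.get(taxon, 0.0)
                + sp_eff
                + interaction[ci, si]
            )
            true_log10[ci, si] = mean_log10
            if not keep[ci, si]:
                continue
            noise = rng.normal(0.0, config.replicate_sd, size=config.replicates_per_species)
            for k in range(config.replicates_per_species):
                tox_rows.append(
                    {
                        "cas": chem_row["cas"],
                        "species": sp_name,
                        "taxon": taxon,
                        "endpoint": "LC50",
                        "duration_h": 96,
                        "value": 10.0 ** (mean_log10 + noise[k]),
                        "unit": "ug_per_L",
                    }
                )
    tox = pd.DataFrame(tox_rows)

    truth_rows = []
    for si_idx in range(n_chem):
        for ti_idx in range(n_chem):
            if chem.loc[si_idx, "log_kow"] >= chem.loc[ti_idx, "log_kow"]:
                continue
            delta = chem.loc[ti_idx, "log_kow"] - chem.loc[si_idx, "log_kow"]
            model_ssf = 10.0 ** (-config.potency_slope_beta * delta)
            for sj, (sp_name, taxon, _) in enumerate(species):
                truth_rows.append(
                    {
                        "source_cas": chem.loc[si_idx, "cas"],
                        "target_cas": chem.loc[ti_idx, "cas"],
                        "species": sp_name,
                        "taxon": taxon,
                        "true_ssr": 10.0
                        ** (true_log10[ti_idx, sj] - true_log10[si_idx, sj]),
                        "true_ssf": model_ssf,
                        "true_lc50_ug_L": 10.0 ** true_log10[ti_idx, sj],
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return chem, tox, truth


def true_ssf(config: SyntheticConfig, pair: ChemicalPair | float) -> float:
    """Closed-form SSF 10^(−beta·Δlog Kow) of the generative model.

    Only defined with zero interaction variance; ``pair`` may be a
    :class:`ChemicalPair` or a bare Δlog Kow.
    """
    if config.interaction_sd > 0:
        raise ValueError(
            "true_ssf has no closed form when interaction_sd > 0"
        )
    delta = pair.delta_log_kow if isinstance(pair, ChemicalPair) else float(pair)
    return 10.0 ** (-config.potency_slope_beta * delta)


def write_tables(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and write the three tables as CSVs; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chem, tox, truth = generate(config)
    paths = (
        outdir / "chemicals.csv",
        outdir / "toxicity.csv",
        outdir / "truth.csv",
    )
    chem.to_csv(paths[0], index=False)
    tox.to_csv(paths[1], index=False)
    truth.to_csv(paths[2], index=False)
    return paths
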