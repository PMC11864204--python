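"""Synthetic acute-toxicity databases and target waters with known truth.

The generator emulates the structure of a compiled multi-species acute Ni
database: species drawn from a taxon mix spanning the three model groups
(algae / invertebrates / vertebrates), heterogeneous test-water chemistry
inside the combined applicability window, and multiplicative log-normal
replicate noise at the "2-fold at the 95th percentile" level typical of
repeated acute tests.  Each record's dissolved L(E)C50 is computed exactly
through the forward gBAM + speciation chain before noise is applied, and a
truth table (species -> true Q50, plus the noise-free dissolved L(E)C50 in
the reference water) is emitted alongside, so every pipeline stage can be
tested offline against known ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .chemistry import ReferenceEngine, SpeciationEngine, WaterSample, split_hardness
from .gbam import GBAMModel, load_models, predict_lc50_dissolved
from .toxdb import ToxRecord, assign_model

__all__ = [
    "SyntheticSpec",
    "NOISE_SD_2FOLD_95",
    "generate",
    "make_water",
    "reference_water",
    "make_ecoregion_waters",
]

#: Replicate noise sd (log10) such that the 95th percentile of the
#: multiplicative error is a factor of two: log10(2)/1.645.
NOISE_SD_2FOLD_95 = math.log10(2.0) / 1.645

#: Taxon mix for generated species, cycled deterministically, with the
#: acute endpoint/duration each taxon's screening window accepts.
_TAXON_CYCLE: tuple[tuple[str, str, float], ...] = (
    ("cladoceran", "immobilization", 48.0),
    ("algae", "growth_rate", 72.0),
    ("amphipod", "mortality", 96.0),
    ("fish", "mortality", 96.0),
    ("cladoceran", "immobilization", 48.0),
    ("mollusc", "mortality", 96.0),
    ("insect", "mortality", 96.0),
    ("algae", "growth_rate", 72.0),
    ("annelid", "mortality", 96.0),
    ("anostraca", "mortality", 24.0),
)


def _load_minor_ions() -> dict:
    text = resources.files("nibam").joinpath("data/synthetic_media.json").read_text()
    return json.loads(text)["minor_ions"]


def make_water(
    ph: float,
    doc: float,
    hardness: float,
    water_id: str | None = None,
    temperature: float = 20.0,
) -> WaterSample:
    """Build a complete water from pH/DOC/hardness plus the minor-ion recipe.

    Hardness is split 3:1 (molar) into Ca and Mg; Na, K, Cl, SO4 and
    alkalinity come from the documented reconstituted-water-style defaults.
    """
    minor = _load_minor_ions()
    ca, mg = split_hardness(hardness)
    return WaterSample(
        ph=ph,
        doc=doc,
        ca=ca,
        mg=mg,
        na=minor["na_mol_l"],
        k=minor["k_mol_l"],
        cl=minor["cl_mol_l"],
        so4=minor["so4_fraction_of_ca_plus_mg"] * (ca + mg),
        alkalinity=minor["alkalinity_mg_caco3_per_mg_hardness"] * hardness / 50043.5,
        temperature=temperature,
        water_id=water_id,
    )


def reference_water() -> WaterSample:
    """The fixed reference water used for truth-table normalization."""
    return make_water(ph=7.5, doc=2.0, hardness=100.0, water_id="reference")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic database (seed mandatory)."""

    seed: int
    n_species: int = 40
    records_per_species: int = 3
    q50_mean: float = 5.0  # -log10 mol/L scale
    q50_sd: float = 0.7
    noise_sd_log10: float = NOISE_SD_2FOLD_95
    ph_range: tuple[float, float] = (5.7, 8.7)
    hardness_range: tuple[float, float] = (12.0, 290.0)
    doc_range: tuple[float, float] = (0.0, 20.0)
    artificial_fraction: float = 0.5  # fraction of records in DOC-0 media

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.records_per_species < 1:
            raise ValueError("n_species and records_per_species must be >= 1")
        if self.q50_sd < 0 or self.noise_sd_log10 < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 5.7 <= self.ph_range[0] < self.ph_range[1] <= 8.7:
            raise ValueError("pH range must sit inside the combined window (5.7, 8.7)")
        if not 12.0 <= self.hardness_range[0] < self.hardness_range[1] <= 290.0:
            raise ValueError("hardness range must sit inside the combined window (12, 290)")
        if not 0.0 <= self.doc_range[0] <= self.doc_range[1]:
            raise ValueError("invalid DOC range")


def generate(
    spec: SyntheticSpec,
    models: dict[str, GBAMModel] | None = None,
    engine: SpeciationEngine | None = None,
) -> tuple[list[ToxRecord], pd.DataFrame]:
    """Draw a synthetic database; returns (records, truth table).

    Truth-table columns: species, taxon_group, model_id, true_q50, and
    true_lc50_reference_ug_l (the noise-free dissolved L(E)C50 of the
    species in the reference water).  Deterministic per seed.
    """
    models = models if models is not None else load_models()
    engine = engine if engine is not None else ReferenceEngine()
    rng = np.random.default_rng(spec.seed)
    ref = reference_water()
    records: list[ToxRecord] = []
    truth_rows = []
    for i in range(spec.n_species):
        taxon, endpoint, duration = _TAXON_CYCLE[i % len(_TAXON_CYCLE)]
        species = f"Synthetica {taxon} sp{i:03d}"
        model = models[assign_model(taxon)]
        q50 = float(rng.normal(spec.q50_mean, spec.q50_sd))
        truth_rows.append(
            {
                "species": species,
                "taxon_group": taxon,
                "model_id": model.model_id,
                "true_q50": q50,
                "true_lc50_reference_ug_l": predict_lc50_dissolved(
                    model, q50, ref, engine, allow_outside_range=True
                ),
            }
        )
        for j in range(spec.records_per_species):
            ph = float(rng.uniform(*spec.ph_range))
            hardness = float(
                np.exp(rng.uniform(math.log(spec.hardness_range[0]), math.log(spec.hardness_range[1])))
            )
            artificial = rng.uniform() < spec.artificial_fraction
            doc = 0.0 if artificial else float(rng.uniform(*spec.doc_range))
            water = make_water(ph, doc, hardness, water_id=f"w{i:03d}_{j}")
            true_lc50 = predict_lc50_dissolved(
                model, q50, water, engine, allow_outside_range=True
            )
            noise = 10.0 ** float(rng.normal(0.0, spec.noise_sd_log10)) if spec.noise_sd_log10 else 1.0
            records.append(
                ToxRecord(
                    record_id=f"r{i:03d}_{j}",
                    species=species,
                    taxon_group=taxon,
                    endpoint=endpoint,
                    duration_h=duration,
                    lc50=true_lc50 * noise,
                    basis="total" if artificial else "dissolved",
                    medium="artificial" if artificial else "natural",
                    water=water,
                    source=f"synthetic(seed={spec.seed})",
                )
            )
    return records, pd.DataFrame(truth_rows)


def make_ecoregion_waters() -> list[WaterSample]:
    """The seven European freshwater scenarios (pH / DOC / hardness as
    tabulated), completed with the minor-ion recipe."""
    text = resources.files("nibam").joinpath("data/ecoregions.json").read_text()
    rows = json.loads(text)["waters"]
    return [
        make_water(row["ph"], row["doc"], row["hardness"], water_id=row["water_id"])
        for row in rows
    ]
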