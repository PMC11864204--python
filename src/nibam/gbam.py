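"""Generalized bioavailability models (gBAM) for acute Ni toxicity.

A gBAM predicts the free-ion L(E)C50 of Ni2+ as

    L(E)C50_Ni2+ = 10^-(Q50 + S_pH-term(pH)) * (1 + sum_z K_CatBL,z * {Cat2+_z})

where Q50 is the intrinsic sensitivity (the -log10 free-ion toxicity stripped
of pH and competition effects), the S_pH term is a piecewise-linear,
*cumulative* function of pH (continuous across segment breakpoints), and the
competition sum runs over the cations the model parameterizes (Ca2+ and/or
Mg2+, with biotic-ligand stability constants K_CatBL in L/mol).

Direction 1 infers Q50 from an observed free-ion toxicity and its test-water
chemistry; Direction 2 predicts free-ion toxicity in a target water from Q50.
Both are exact algebraic inverses of each other.

The shipped parameter sets cover the three pre-existing crustacean models
(D. magna, D. pulex, C. dubia), the pH-extended average invertebrate model
derived from them (biotic-ligand constants averaged on the linear K scale,
high-pH slope above pH 8.0), the pH-extended algae model (Mg competition
only) and the fish model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .chemistry import SpeciationEngine, SpeciationResult, WaterSample

__all__ = [
    "GBAMError",
    "ApplicabilityError",
    "PHSegment",
    "GBAMModel",
    "IntrinsicSensitivity",
    "load_models",
    "average_constants",
    "effective_exponent",
    "predict_lc50_free",
    "q50_from_observation",
    "competition_corrected_lc50",
    "combined_applicability",
    "predict_lc50_dissolved",
]


class GBAMError(ValueError):
    """Invalid model input."""


class ApplicabilityError(GBAMError):
    """Chemistry outside a model's validated applicability range."""


@dataclass(frozen=True)
class PHSegment:
    lower: float
    upper: float
    slope: float  # S_pH, unitless, >= 0


@dataclass(frozen=True)
class GBAMModel:
    """One gBAM parameter set (constants, pH segments, applicability window)."""

    model_id: str
    log_k_ca: float | None  # log10 L/mol; None when the model carries no Ca term
    log_k_mg: float | None
    segments: tuple[PHSegment, ...]
    ph_range: tuple[float, float]
    hardness_range: tuple[float, float]  # mg CaCO3/L

    def __post_init__(self) -> None:
        if not self.segments:
            raise GBAMError(f"{self.model_id}: at least one pH segment required")
        for seg in self.segments:
            if seg.slope < 0:
                raise GBAMError(f"{self.model_id}: negative S_pH slope {seg.slope}")
            if not seg.lower < seg.upper:
                raise GBAMError(f"{self.model_id}: empty pH segment {seg}")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if not math.isclose(prev.upper, nxt.lower):
                raise GBAMError(f"{self.model_id}: pH segments not contiguous")
        for lo, hi in (self.ph_range, self.hardness_range):
            if not lo < hi:
                raise GBAMError(f"{self.model_id}: empty applicability range ({lo}, {hi})")
        for name in ("log_k_ca", "log_k_mg"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 10.0:
                raise GBAMError(f"{self.model_id}: {name}={value} outside [0, 10]")

    def ph_in_range(self, ph: float) -> bool:
        return self.ph_range[0] <= ph <= self.ph_range[1]


@dataclass(frozen=True)
class IntrinsicSensitivity:
    """A Q50 value (unitless, -log10 mol/L scale) with its provenance."""

    q50: float
    species: str
    endpoint: str
    duration_h: float
    source_record_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not math.isfinite(self.q50):
            raise GBAMError(f"Q50 must be finite, got {self.q50}")
        if not self.source_record_ids:
            raise GBAMError("an intrinsic sensitivity must trace to >= 1 record")


def load_models(path=None) -> dict[str, GBAMModel]:
    """Load the shipped (or a user-supplied) gBAM parameter-set config."""
    if path is None:
        text = resources.files("nibam").joinpath("data/models.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)["models"]
    models = {}
    for model_id, m in raw.items():
        models[model_id] = GBAMModel(
            model_id=model_id,
            log_k_ca=m["log_k_ca"],
            log_k_mg=m["log_k_mg"],
            segments=tuple(PHSegment(*seg) for seg in m["segments"]),
            ph_range=tuple(m["ph_range"]),
            hardness_range=tuple(m["hardness_range"]),
        )
    return models


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def average_constants(log_k_values: list[float]) -> float:
    """Average biotic-ligand constants on the linear K scale.

    Returns log10 of the arithmetic mean of 10^x over the inputs; this is the
    averaging rule that produces the average invertebrate model's constants
    from the three crustacean models.  Report to 2 decimals.
    """
    if not log_k_values:
        raise GBAMError("cannot average an empty list of constants")
    linear = [10.0 ** x for x in log_k_values]
    return math.log10(sum(linear) / len(linear))


def _ph_term(model: GBAMModel, ph: float) -> float:
    """Cumulative piecewise S_pH contribution: sum of slope x segment overlap."""
    term = 0.0
    for seg in model.segments:
        if ph > seg.lower:
            term += seg.slope * (min(ph, seg.upper) - seg.lower)
    return term


def effective_exponent(
    model: GBAMModel, q50: float, ph: float, *, allow_outside_range: bool = False
) -> float:
    """Q50 plus the cumulative piecewise pH term; continuous in pH."""
    if not allow_outside_range and not model.ph_in_range(ph):
        raise ApplicabilityError(
            f"pH {ph} outside {model.model_id} applicability {model.ph_range}"
        )
    return q50 + _ph_term(model, ph)


def _activities(water_activities) -> tuple[float | None, float | None]:
    if isinstance(water_activities, SpeciationResult):
        return water_activities.activity_ca2, water_activities.activity_mg2
    ca, mg = water_activities
    return ca, mg


def competition_factor(model: GBAMModel, water_activities) -> float:
    """1 + sum over parameterized cations of K_CatBL x activity."""
    a_ca, a_mg = _activities(water_activities)
    factor = 1.0
    for log_k, act, name in ((model.log_k_ca, a_ca, "Ca2+"), (model.log_k_mg, a_mg, "Mg2+")):
        if log_k is None:
            continue
        if act is None:
            raise GBAMError(f"{model.model_id} requires the {name} activity")
        if act < 0:
            raise GBAMError(f"{name} activity must be >= 0, got {act}")
        factor += 10.0 ** log_k * act
    return factor


def predict_lc50_free(
    model: GBAMModel,
    q50: float,
    ph: float,
    water_activities,
    *,
    allow_outside_range: bool = False,
) -> float:
    """Direction 2: predicted free-ion L(E)C50 (mol/L) in the given water.

    ``water_activities`` is a SpeciationResult or a (Ca2+, Mg2+) activity
    pair in mol/L; only cations the model parameterizes enter the sum.
    """
    exponent = effective_exponent(model, q50, ph, allow_outside_range=allow_outside_range)
    return 10.0 ** (-exponent) * competition_factor(model, water_activities)


def q50_from_observation(
    model: GBAMModel,
    observed_lc50_free: float,
    ph: float,
    water_activities,
    *,
    allow_outside_range: bool = False,
) -> float:
    """Direction 1: intrinsic sensitivity from an observed free-ion L(E)C50.

    Exact algebraic inversion of :func:`predict_lc50_free`.
    """
    if observed_lc50_free <= 0:
        raise GBAMError(f"observed free-ion LC50 must be > 0, got {observed_lc50_free}")
    if not allow_outside_range and not model.ph_in_range(ph):
        raise ApplicabilityError(
            f"pH {ph} outside {model.model_id} applicability {model.ph_range}"
        )
    corrected = observed_lc50_free / competition_factor(model, water_activities)
    return -math.log10(corrected) - _ph_term(model, ph)


def competition_corrected_lc50(model: GBAMModel, observed_lc50_free: float, water_activities) -> float:
    """Observed free-ion L(E)C50 divided by the competition factor (>= 1)."""
    if observed_lc50_free <= 0:
        raise GBAMError(f"observed free-ion LC50 must be > 0, got {observed_lc50_free}")
    return observed_lc50_free / competition_factor(model, water_activities)


@dataclass(frozen=True)
class ApplicabilityWindow:
    ph_range: tuple[float, float]
    hardness_range: tuple[float, float]

    @property
    def is_empty(self) -> bool:
        return self.ph_range[0] > self.ph_range[1] or self.hardness_range[0] > self.hardness_range[1]

    def contains(self, ph: float, hardness: float | None) -> bool:
        if self.is_empty:
            return False
        ok_ph = self.ph_range[0] <= ph <= self.ph_range[1]
        ok_h = hardness is None or self.hardness_range[0] <= hardness <= self.hardness_range[1]
        return ok_ph and ok_h


def combined_applicability(models: list[GBAMModel]) -> ApplicabilityWindow:
    """Intersection (narrowest window) of the models' applicability ranges.

    An empty intersection is reported as an empty window, not an exception.
    """
    if not models:
        raise GBAMError("need at least one model")
    ph_lo = max(m.ph_range[0] for m in models)
    ph_hi = min(m.ph_range[1] for m in models)
    h_lo = max(m.hardness_range[0] for m in models)
    h_hi = min(m.hardness_range[1] for m in models)
    return ApplicabilityWindow((ph_lo, ph_hi), (h_lo, h_hi))


def predict_lc50_dissolved(
    model: GBAMModel,
    q50: float,
    water: WaterSample,
    engine: SpeciationEngine,
    *,
    allow_outside_range: bool = False,
    rtol: float = 1e-10,
    max_iter: int = 60,
) -> float:
    """Direction 2 through to dissolved Ni (ug/L) in the given water.

    The gBAM is evaluated with the Ca2+/Mg2+ activities of the water *at the
    predicted Ni level* (self-consistent with Direction 1, which reads the
    activities from the speciation of the observed toxicity level).  The weak
    ionic-strength coupling is resolved by fixed-point iteration; it
    typically converges in 2-4 rounds.
    """
    free = predict_lc50_free(
        model, q50, water.ph, engine.speciate(water, 1.0), allow_outside_range=allow_outside_range
    )
    dissolved = engine.dissolved_from_activity(water, free)
    for _ in range(max_iter):
        res = engine.speciate(water, dissolved)
        free = predict_lc50_free(
            model, q50, water.ph, res, allow_outside_range=allow_outside_range
        )
        new = engine.dissolved_from_activity(water, free)
        if abs(new - dissolved) <= rtol * max(dissolved, new):
            return new
        dissolved = new
    raise GBAMError(
        f"dissolved-level prediction did not converge for {model.model_id} "
        f"(last value {dissolved:.6g} ug/L)"
    )
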