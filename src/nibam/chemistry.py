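"""Water chemistry: sample data model, derived-quantity rules, and speciation.

Speciation (dissolved Ni <-> free Ni2+ activity, plus free Ca2+/Mg2+
activities) is exposed through a pluggable engine interface.  The shipped
:class:`ReferenceEngine` solves the inorganic equilibria (hydroxide,
carbonate, sulfate and chloride complexes of Ni, Ca and Mg) with Davies
activity corrections and an optional single-site DOC binding term.  The
:class:`ExternalActivityEngine` adapter lets externally computed free-ion
activities (for example output of a humic speciation code) flow through the
same pipeline.

Unit conventions
----------------
* pH: unitless; DOC: mg C/L; major ions: mol/L
* alkalinity: eq/L; DIC: mol C/L; hardness: mg CaCO3/L
* dissolved Ni: ug/L; free-ion quantities: activities in mol/L
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Protocol, runtime_checkable

__all__ = [
    "MW_NI",
    "MW_CACO3",
    "ChemistryError",
    "ConvergenceError",
    "WaterSample",
    "SpeciationResult",
    "SpeciationEngine",
    "ReferenceEngine",
    "ExternalActivityEngine",
    "split_hardness",
    "dic_from_alkalinity",
    "davies_gamma",
    "load_stability_constants",
    "mass_balance_error",
    "read_water_csv",
]

MW_NI = 58.6934  # g/mol
MW_CACO3 = 100.087  # g/mol; 1 eq CaCO3 = 50.0435 g


class ChemistryError(ValueError):
    """Invalid chemistry input (negative concentration, pH out of range...)."""


class ConvergenceError(RuntimeError):
    """The equilibrium solver failed to converge; carries a residual report."""


def load_stability_constants() -> dict:
    """Load the shipped, versioned stability-constant table (JSON)."""
    text = resources.files("nibam").joinpath("data/stability_constants.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# Water sample
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterSample:
    """Measured/derived chemistry of one test or target water.

    ``doc``, ``ca`` and ``mg`` use ``None`` for "not reported" so that
    screening can distinguish a missing value from a true zero.  ``na``,
    ``k``, ``so4`` and ``cl`` default to 0 (absent).
    """

    ph: float
    doc: float | None = None  # mg C/L
    ca: float | None = None  # mol/L
    mg: float | None = None  # mol/L
    na: float = 0.0
    k: float = 0.0
    so4: float = 0.0
    cl: float = 0.0
    alkalinity: float | None = None  # eq/L
    dic: float | None = None  # mol C/L
    hardness: float | None = None  # mg CaCO3/L
    temperature: float = 20.0  # degC
    water_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ph < 14.0:
            raise ChemistryError(f"pH must lie in (0, 14), got {self.ph}")
        for name in ("doc", "ca", "mg", "na", "k", "so4", "cl", "alkalinity", "dic", "hardness"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ChemistryError(f"{name} must be >= 0, got {value}")
        if self.ca is not None and self.mg is not None and self.hardness is not None and self.hardness > 0:
            derived = (self.ca + self.mg) * MW_CACO3 * 1000.0
            if abs(derived - self.hardness) > 0.05 * self.hardness:
                raise ChemistryError(
                    f"stored hardness {self.hardness:.3g} mg CaCO3/L disagrees with "
                    f"Ca+Mg-derived hardness {derived:.3g} by more than 5%"
                )

    @property
    def hardness_mg_caco3(self) -> float | None:
        """Hardness in mg CaCO3/L, from Ca+Mg when present, else as stored."""
        if self.ca is not None and self.mg is not None:
            return (self.ca + self.mg) * MW_CACO3 * 1000.0
        return self.hardness


# ---------------------------------------------------------------------------
# Derived-quantity rules
# ---------------------------------------------------------------------------


def split_hardness(hardness: float) -> tuple[float, float]:
    """Split total hardness (mg CaCO3/L) into Ca and Mg (mol/L) at 3:1 molar.

    The total divalent-cation molarity is hardness / 100.087 mmol/L, divided
    3:1 between Ca and Mg on a molar basis.
    """
    if hardness < 0:
        raise ChemistryError(f"hardness must be >= 0, got {hardness}")
    total = hardness * 1e-3 / MW_CACO3  # mol/L
    return 0.75 * total, 0.25 * total


def dic_from_alkalinity(
    ph: float,
    alkalinity: float,
    temperature: float = 25.0,
    pco2_atm: float | None = None,
) -> float:
    """Dissolved inorganic carbon (mol C/L) from pH and alkalinity (eq/L).

    Open-system convention: the charged carbonate species are set by the
    carbonate alkalinity (alkalinity corrected for OH-/H+) at the stated pH,
    while dissolved CO2 is fixed by equilibrium with atmospheric pCO2.  With
    zero alkalinity the result is therefore the atmospheric CO2(aq) alone.
    Constants are 25 degC values; ``temperature`` is accepted for interface
    symmetry (no van 't Hoff correction is applied by default).
    """
    del temperature  # constants held at 25 degC; see module docstring
    if not 2.0 < ph < 12.0:
        raise ChemistryError(f"pH must lie in (2, 12) for DIC derivation, got {ph}")
    if alkalinity < 0:
        raise ChemistryError(f"alkalinity must be >= 0, got {alkalinity}")
    cc = load_stability_constants()["carbonate_system"]
    k2 = 10.0 ** (-cc["pk2_hco3"])
    kw = 10.0 ** (-cc["pkw"])
    kh = 10.0 ** cc["log_kh_co2_mol_per_l_atm"]
    pco2 = cc["pco2_atm"] if pco2_atm is None else pco2_atm
    h = 10.0 ** (-ph)
    oh = kw / h
    alk_carb = max(alkalinity - oh + h, 0.0)
    hco3 = alk_carb / (1.0 + 2.0 * k2 / h)
    co3 = k2 * hco3 / h
    co2 = kh * pco2
    return co2 + hco3 + co3


def davies_gamma(charge: int, ionic_strength: float, a: float = 0.509) -> float:
    """Davies activity coefficient 10^(-A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)).

    ``a`` is the Debye-Hueckel constant (0.509 at 25 degC); neutral species
    and the infinite-dilution limit return 1.
    """
    if ionic_strength < 0:
        raise ChemistryError(f"ionic strength must be >= 0, got {ionic_strength}")
    if charge == 0 or ionic_strength == 0.0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    return 10.0 ** (-a * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength))


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciationResult:
    """Free-ion activities and species concentrations for one water at a
    stated dissolved Ni level."""

    dissolved_ni: float  # ug/L
    activity_ni2: float  # mol/L
    activity_ca2: float  # mol/L
    activity_mg2: float  # mol/L
    ionic_strength: float  # mol/L
    species: dict[str, float] = field(default_factory=dict)  # name -> mol/L
    engine_id: str = "unspecified"


NI_SPECIES = ("Ni2+", "NiOH+", "Ni(OH)2", "NiCO3", "NiHCO3+", "NiSO4", "NiCl+", "Ni-DOC")


def mass_balance_error(result: SpeciationResult) -> float:
    """Relative |sum of Ni species - dissolved Ni| (0 for zero dissolved Ni)."""
    total = result.dissolved_ni * 1e-6 / MW_NI
    if total == 0.0:
        return 0.0
    s = sum(result.species.get(name, 0.0) for name in NI_SPECIES)
    return abs(s - total) / total


@runtime_checkable
class SpeciationEngine(Protocol):
    """Stateless dissolved-Ni <-> free-ion interface used by the pipeline."""

    engine_id: str

    def speciate(self, water: WaterSample, dissolved_ni: float) -> SpeciationResult: ...

    def dissolved_from_activity(self, water: WaterSample, activity_ni2: float) -> float: ...


def _resolve_ca_mg(water: WaterSample) -> tuple[float, float]:
    if water.ca is not None and water.mg is not None:
        return water.ca, water.mg
    if water.hardness is not None:
        return split_hardness(water.hardness)
    if water.ca is not None or water.mg is not None:
        return water.ca or 0.0, water.mg or 0.0
    raise ChemistryError("water needs Ca and Mg, or hardness, for speciation")


class ReferenceEngine:
    """Transparent inorganic equilibrium engine with Davies corrections.

    Solves Ni, Ca and Mg complexation with OH-, CO3--, HCO3-, SO4-- and Cl-
    by damped fixed-point iteration on the mass balances, with the ionic
    strength updated in an outer loop.  Ca/Mg/SO4 ligand depletion is mutual;
    Ni is treated as a trace metal for the ligand pools, while the Ni mass
    balance itself is closed in closed form (exact).  DOC binding is a
    single-site 1:1 Langmuir term against free Ni2+ activity with a
    documented conditional constant (a labelled stand-in, not a humic-ion
    model); DOC = 0 bypasses organic binding entirely.
    """

    engine_id = "reference_davies_v1"

    def __init__(self, constants: dict | None = None, doc_binding: bool = True):
        cfg = constants if constants is not None else load_stability_constants()
        self._cfg = cfg
        cc = cfg["carbonate_system"]
        self._k1 = 10.0 ** (-cc["pk1_h2co3"])
        self._k2 = 10.0 ** (-cc["pk2_hco3"])
        self._kw = 10.0 ** (-cc["pkw"])
        self._kh_pco2 = 10.0 ** cc["log_kh_co2_mol_per_l_atm"] * cc["pco2_atm"]
        k = {name: 10.0 ** r["log_k"] for name, r in cfg["reactions"].items()}
        self._k = k
        doc_cfg = cfg["doc_binding"]
        self._doc_k = 10.0 ** doc_cfg["log_k_conditional"] if doc_binding else 0.0
        self._doc_sites_per_mg = (
            doc_cfg["site_density_mol_per_mg_active"] * doc_cfg["active_fraction"]
        )

    # -- forward ------------------------------------------------------------

    def speciate(self, water: WaterSample, dissolved_ni: float, max_iter: int = 80) -> SpeciationResult:
        if dissolved_ni < 0:
            raise ChemistryError(f"dissolved Ni must be >= 0, got {dissolved_ni}")
        if water.doc is None:
            raise ChemistryError("DOC not reported; derive or set it before speciation")
        ni_tot = dissolved_ni * 1e-6 / MW_NI
        ca_tot, mg_tot = _resolve_ca_mg(water)
        if water.dic is not None:
            dic = water.dic
        else:
            dic = dic_from_alkalinity(water.ph, water.alkalinity or 0.0)
        so4_tot, cl_tot, na, k_ion = water.so4, water.cl, water.na, water.k
        l_doc = water.doc * self._doc_sites_per_mg
        kd = self._doc_k
        k = self._k
        h_act = 10.0 ** (-water.ph)
        oh_act = self._kw / h_act

        ion_strength = 0.5 * (
            4.0 * (ni_tot + ca_tot + mg_tot + so4_tot) + na + k_ion + cl_tot + dic
        )
        a_ni = a_ca = a_mg = 0.0
        species: dict[str, float] = {}
        for _ in range(max_iter):
            g1 = davies_gamma(1, ion_strength)
            g2 = davies_gamma(2, ion_strength)
            # carbonate partition of DIC at fixed pH (concentration basis)
            r1 = self._k1 / (h_act * g1)
            r2 = self._k2 * g1 / (h_act * g2)
            denom = 1.0 + r1 + r1 * r2
            co2_c = dic / denom
            hco3_c = dic * r1 / denom
            co3_c = dic * r1 * r2 / denom
            a_hco3 = g1 * hco3_c
            a_co3 = g2 * co3_c
            a_cl = g1 * cl_tot
            # mutual Ca/Mg/SO4 depletion (Ni is trace for the ligand pools)
            a_ca = g2 * ca_tot
            a_mg = g2 * mg_tot
            a_so4 = g2 * so4_tot
            for _inner in range(200):
                d_ca = 1.0 / g2 + k["CaHCO3+"] * a_hco3 / g1 + k["CaCO3"] * a_co3 + k["CaSO4"] * a_so4
                d_mg = 1.0 / g2 + k["MgHCO3+"] * a_hco3 / g1 + k["MgCO3"] * a_co3 + k["MgSO4"] * a_so4
                new_ca = ca_tot / d_ca
                new_mg = mg_tot / d_mg
                d_so4 = 1.0 / g2 + k["CaSO4"] * new_ca + k["MgSO4"] * new_mg
                new_so4 = so4_tot / d_so4
                moved = max(abs(new_ca - a_ca), abs(new_mg - a_mg), abs(new_so4 - a_so4))
                scale = max(a_ca, a_mg, a_so4, new_ca, new_mg, new_so4, 1e-30)
                a_ca, a_mg, a_so4 = new_ca, new_mg, new_so4
                if moved <= 1e-14 * scale:
                    break
            # Ni side reactions against free Ni2+ activity
            d_ni = (
                1.0 / g2
                + k["NiOH+"] * oh_act / g1
                + k["Ni(OH)2"] * oh_act * oh_act
                + k["NiCO3"] * a_co3
                + k["NiHCO3+"] * a_hco3 / g1
                + k["NiSO4"] * a_so4
                + k["NiCl+"] * a_cl / g1
            )
            if ni_tot == 0.0:
                a_ni = 0.0
                ni_doc = 0.0
            elif kd > 0.0 and l_doc > 0.0:
                # ni_tot = a_ni * d_ni + l_doc * kd*a_ni / (1 + kd*a_ni)
                qa = d_ni * kd
                qb = d_ni + kd * (l_doc - ni_tot)
                a_ni = (-qb + math.sqrt(qb * qb + 4.0 * qa * ni_tot)) / (2.0 * qa)
                ni_doc = l_doc * kd * a_ni / (1.0 + kd * a_ni)
            else:
                a_ni = ni_tot / d_ni
                ni_doc = 0.0
            species = {
                "Ni2+": a_ni / g2,
                "NiOH+": k["NiOH+"] * a_ni * oh_act / g1,
                "Ni(OH)2": k["Ni(OH)2"] * a_ni * oh_act * oh_act,
                "NiCO3": k["NiCO3"] * a_ni * a_co3,
                "NiHCO3+": k["NiHCO3+"] * a_ni * a_hco3 / g1,
                "NiSO4": k["NiSO4"] * a_ni * a_so4,
                "NiCl+": k["NiCl+"] * a_ni * a_cl / g1,
                "Ni-DOC": ni_doc,
                "Ca2+": a_ca / g2,
                "CaHCO3+": k["CaHCO3+"] * a_ca * a_hco3 / g1,
                "CaCO3": k["CaCO3"] * a_ca * a_co3,
                "CaSO4": k["CaSO4"] * a_ca * a_so4,
                "Mg2+": a_mg / g2,
                "MgHCO3+": k["MgHCO3+"] * a_mg * a_hco3 / g1,
                "MgCO3": k["MgCO3"] * a_mg * a_co3,
                "MgSO4": k["MgSO4"] * a_mg * a_so4,
                "HCO3-": hco3_c,
                "CO3-2": co3_c,
                "CO2": co2_c,
                "SO4-2": a_so4 / g2,
                "Cl-": cl_tot,
                "Na+": na,
                "K+": k_ion,
                "H+": h_act / g1,
                "OH-": oh_act / g1,
            }
            new_i = 0.5 * (
                4.0 * species["Ni2+"]
                + species["NiOH+"]
                + species["NiHCO3+"]
                + species["NiCl+"]
                + 4.0 * species["Ca2+"]
                + species["CaHCO3+"]
                + 4.0 * species["Mg2+"]
                + species["MgHCO3+"]
                + 4.0 * species["SO4-2"]
                + species["HCO3-"]
                + 4.0 * species["CO3-2"]
                + species["Cl-"]
                + species["Na+"]
                + species["K+"]
                + species["H+"]
                + species["OH-"]
            )
            if abs(new_i - ion_strength) <= 1e-12 + 1e-9 * ion_strength:
                ion_strength = new_i
                break
            ion_strength = 0.5 * (ion_strength + new_i)
        else:
            raise ConvergenceError(
                f"ionic-strength loop did not converge after {max_iter} iterations "
                f"(last I = {ion_strength:.6g}, change = {abs(new_i - ion_strength):.3g})"
            )
        return SpeciationResult(
            dissolved_ni=dissolved_ni,
            activity_ni2=a_ni,
            activity_ca2=a_ca,
            activity_mg2=a_mg,
            ionic_strength=ion_strength,
            species=species,
            engine_id=self.engine_id,
        )

    # -- inverse ------------------------------------------------------------

    def dissolved_from_activity(self, water: WaterSample, activity_ni2: float) -> float:
        """Dissolved Ni (ug/L) whose speciation gives the target Ni2+ activity.

        Bracketed root-finding (Brent) on dissolved Ni; the forward map is
        strictly increasing, so the round trip holds to ~1e-12 relative.
        """
        if activity_ni2 < 0:
            raise ChemistryError(f"target activity must be >= 0, got {activity_ni2}")
        if activity_ni2 == 0.0:
            return 0.0
        from scipy.optimize import brentq

        trace = self.speciate(water, 1.0)
        if trace.activity_ni2 <= 0.0:
            raise ConvergenceError("trace speciation returned zero free Ni activity")
        guess = activity_ni2 / trace.activity_ni2  # ug/L, exact when linear

        def f(d: float) -> float:
            return self.speciate(water, d).activity_ni2 - activity_ni2

        lo, hi = 0.5 * guess, 1.1 * guess
        f_lo, f_hi = f(lo), f(hi)
        for _ in range(120):
            if f_lo <= 0.0:
                break
            hi, f_hi = lo, f_lo
            lo *= 0.25
            f_lo = f(lo)
        else:
            raise ConvergenceError("could not bracket dissolved Ni from below")
        for _ in range(120):
            if f_hi >= 0.0:
                break
            lo, f_lo = hi, f_hi
            hi *= 4.0
            f_hi = f(hi)
        else:
            raise ConvergenceError("could not bracket dissolved Ni from above")
        return float(brentq(f, lo, hi, rtol=1e-13, maxiter=200))


class ExternalActivityEngine:
    """Adapter for externally computed free-ion activities.

    Accepts a table with columns ``water_id, dissolved_ni_ug_l, activity_ni2,
    activity_ca2, activity_mg2`` (e.g. exported from a humic speciation
    code).  Between tabulated Ni levels, the free-Ni fraction of the nearest
    tabulated level is applied (Ca/Mg activities are Ni-independent).
    Results pass through the pipeline identically to internally computed
    ones.
    """

    engine_id = "external_activity_table"

    REQUIRED = ("water_id", "dissolved_ni_ug_l", "activity_ni2", "activity_ca2", "activity_mg2")

    def __init__(self, table):
        import pandas as pd

        df = pd.DataFrame(table)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ChemistryError(f"activity table is missing columns: {missing}")
        self._table = df

    @classmethod
    def from_csv(cls, path) -> "ExternalActivityEngine":
        import pandas as pd

        return cls(pd.read_csv(path))

    def _rows(self, water: WaterSample):
        if water.water_id is None:
            raise ChemistryError("external-activity lookups need water_id on the WaterSample")
        rows = self._table[self._table["water_id"] == water.water_id]
        if rows.empty:
            raise ChemistryError(f"no external activities for water_id={water.water_id!r}")
        return rows

    def speciate(self, water: WaterSample, dissolved_ni: float) -> SpeciationResult:
        rows = self._rows(water)
        idx = (rows["dissolved_ni_ug_l"] - dissolved_ni).abs().idxmin()
        row = rows.loc[idx]
        ratio = row["activity_ni2"] / row["dissolved_ni_ug_l"]
        return SpeciationResult(
            dissolved_ni=dissolved_ni,
            activity_ni2=ratio * dissolved_ni,
            activity_ca2=float(row["activity_ca2"]),
            activity_mg2=float(row["activity_mg2"]),
            ionic_strength=float("nan"),
            species={},
            engine_id=self.engine_id,
        )

    def dissolved_from_activity(self, water: WaterSample, activity_ni2: float) -> float:
        rows = self._rows(water)
        row = rows.iloc[0]
        ratio = row["activity_ni2"] / row["dissolved_ni_ug_l"]
        return float(activity_ni2 / ratio)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_WATER_COLUMNS = {
    "ph": "ph",
    "doc_mg_l": "doc",
    "ca_mol_l": "ca",
    "mg_mol_l": "mg",
    "na_mol_l": "na",
    "k_mol_l": "k",
    "so4_mol_l": "so4",
    "cl_mol_l": "cl",
    "alkalinity_eq_l": "alkalinity",
    "dic_mol_l": "dic",
    "hardness_mg_caco3_l": "hardness",
    "temp_c": "temperature",
    "water_id": "water_id",
}


def _water_from_row(row) -> WaterSample:
    import pandas as pd

    kwargs = {}
    for col, attr in _WATER_COLUMNS.items():
        if col in row.index and not pd.isna(row[col]):
            kwargs[attr] = row[col]
    for zero_default in ("na", "k", "so4", "cl"):
        kwargs.setdefault(zero_default, 0.0)
    if "ph" not in kwargs:
        raise ChemistryError("water row is missing the required column 'ph'")
    if "ca" not in kwargs and "hardness" not in kwargs:
        raise ChemistryError("water row needs ca_mol_l/mg_mol_l or hardness_mg_caco3_l")
    return WaterSample(**kwargs)


def read_water_csv(path) -> list[WaterSample]:
    """Read target waters from CSV (one row per water; documented dialect)."""
    import pandas as pd

    df = pd.read_csv(path)
    return [_water_from_row(row) for _, row in df.iterrows()]
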