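"""Species aggregation, bioavailability normalization and SSD/HC5 derivation.

Pipeline: Direction-1 intrinsic sensitivities (Q50) per retained record ->
species averaging at the Q50 level (most sensitive endpoint, i.e. highest
mean Q50, with duration multiplicity resolved toward the most sensitive
group and life stages pooled) -> Direction-2 prediction of each species'
free-ion L(E)C50 in the target water -> back-translation to dissolved Ni ->
fit of six candidate distributions (gamma, log-normal, logistic, normal,
Weibull, Gumbel) to the log10 normalized values -> best fit by minimum
Anderson-Darling statistic -> HC5 (5th percentile) with a bootstrap 90%
confidence interval.

The default bootstrap is nonparametric resampling of the species values
with replacement, refitting the selected family on each resample (the
family is held fixed); a parametric mode (sampling from the fitted
distribution) is available behind a flag.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemistry import ReferenceEngine, SpeciationEngine, WaterSample
from .gbam import (
    GBAMModel,
    combined_applicability,
    load_models,
    predict_lc50_dissolved,
    q50_from_observation,
)
from .toxdb import ToxRecord, assign_model

__all__ = [
    "SSDError",
    "FAMILY_PREFERENCE",
    "SpeciesSensitivity",
    "SSDFit",
    "BootstrapResult",
    "HC5Result",
    "aggregate_species",
    "normalize_to_water",
    "fit_family",
    "fit_ssd",
    "anderson_darling",
    "hc5",
    "bootstrap_hc5",
    "derive_hc5",
]


class SSDError(ValueError):
    """Invalid SSD input (too few species, degenerate values...)."""


#: Fit families, keyed by name: (scipy distribution, fit kwargs, needs log10
#: values strictly positive).  Families are fitted to x = log10(ug/L).
_FAMILIES: dict[str, tuple] = {
    "normal": (stats.norm, {}, False),
    "log-normal": (stats.lognorm, {"floc": 0.0}, True),
    "logistic": (stats.logistic, {}, False),
    "gamma": (stats.gamma, {"floc": 0.0}, True),
    "weibull": (stats.weibull_min, {"floc": 0.0}, True),
    "gumbel": (stats.gumbel_r, {}, False),
}

#: Deterministic tie-break order for equal Anderson-Darling statistics.
FAMILY_PREFERENCE = ("normal", "log-normal", "logistic", "gamma", "weibull", "gumbel")


@dataclass(frozen=True)
class SpeciesSensitivity:
    """One species' averaged intrinsic sensitivity entering the SSD."""

    species: str
    endpoint: str
    duration_h: float
    mean_q50: float
    n_records: int
    model_id: str
    source_record_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SSDFit:
    """One candidate distribution fitted to the log10 normalized values."""

    family: str
    params: tuple[float, ...]
    ad_stat: float | None
    ad_pvalue: float | None
    ok: bool
    message: str = ""

    def frozen(self):
        dist, _, _ = _FAMILIES[self.family]
        return dist(*self.params)


@dataclass(frozen=True)
class BootstrapResult:
    hc5_5: float
    hc5_50: float
    hc5_95: float
    b_requested: int
    b_failed: int
    seed: int | None
    parametric: bool
    unreliable: bool


@dataclass(frozen=True)
class HC5Result:
    """Site-specific acute hazard threshold for one target water."""

    water_id: str
    normalized_lc50: dict[str, float]  # species -> ug dissolved Ni/L
    fits: dict[str, SSDFit]
    best_family: str
    hc5_best_fit: float  # HC5 of the full-data best fit, ug/L
    hc5_50: float  # bootstrap median (reported point estimate)
    hc5_5: float
    hc5_95: float
    b: int
    seed: int | None
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "water_id": self.water_id,
            "n_species": len(self.normalized_lc50),
            "normalized_lc50_ug_l": dict(self.normalized_lc50),
            "fits": {
                name: {
                    "ok": f.ok,
                    "params": list(f.params),
                    "ad_stat": f.ad_stat,
                    "ad_pvalue": f.ad_pvalue,
                    "message": f.message,
                }
                for name, f in self.fits.items()
            },
            "best_family": self.best_family,
            "hc5_best_fit_ug_l": self.hc5_best_fit,
            "hc5_50_ug_l": self.hc5_50,
            "hc5_5_ug_l": self.hc5_5,
            "hc5_95_ug_l": self.hc5_95,
            "bootstrap_B": self.b,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Aggregation and normalization
# ---------------------------------------------------------------------------


def _normalize_species_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    key = " ".join(name.split()).lower()
    if synonyms:
        key = synonyms.get(key, key)
    return key


def aggregate_species(
    records: list[ToxRecord],
    models: dict[str, GBAMModel] | None = None,
    engine: SpeciationEngine | None = None,
    synonyms: dict[str, str] | None = None,
) -> list[SpeciesSensitivity]:
    """Collapse retained records to one intrinsic sensitivity per species.

    Per species: Direction-1 Q50 per record, grouped by (endpoint,
    duration); arithmetic mean per group; the group with the highest mean
    Q50 (most sensitive endpoint/duration) is selected.  Life stages are
    pooled.  Species with no retained records are omitted.
    """
    models = models if models is not None else load_models()
    engine = engine if engine is not None else ReferenceEngine()
    by_species: dict[str, dict[tuple[str, float], list]] = defaultdict(lambda: defaultdict(list))
    display: dict[str, str] = {}
    for record in records:
        if record.retained is False:
            continue
        key = _normalize_species_name(record.species, synonyms)
        display.setdefault(key, record.species)
        model = models[assign_model(record.taxon_group)]
        res = engine.speciate(record.water, record.lc50)
        q50 = q50_from_observation(
            model, res.activity_ni2, record.water.ph, res, allow_outside_range=True
        )
        by_species[key][(record.endpoint, record.duration_h)].append(
            (q50, record.record_id, model.model_id)
        )
    out = []
    for key in sorted(by_species):
        groups = by_species[key]
        best = max(
            groups.items(), key=lambda item: (float(np.mean([q for q, _, _ in item[1]])), item[0])
        )
        (endpoint, duration), entries = best
        q50s = [q for q, _, _ in entries]
        out.append(
            SpeciesSensitivity(
                species=display[key],
                endpoint=endpoint,
                duration_h=duration,
                mean_q50=float(np.mean(q50s)),
                n_records=len(entries),
                model_id=entries[0][2],
                source_record_ids=tuple(rid for _, rid, _ in entries),
            )
        )
    return out


def normalize_to_water(
    sensitivities: list[SpeciesSensitivity],
    target: WaterSample,
    models: dict[str, GBAMModel] | None = None,
    engine: SpeciationEngine | None = None,
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Direction-2 normalized dissolved L(E)C50 (ug/L) per species.

    Target waters outside the combined applicability window of the model set
    produce a warning tag on the result, not a failure.
    """
    models = models if models is not None else load_models()
    engine = engine if engine is not None else ReferenceEngine()
    warnings: list[str] = []
    used = {models[s.model_id].model_id: models[s.model_id] for s in sensitivities}
    if used:
        window = combined_applicability(list(used.values()))
        if not window.contains(target.ph, target.hardness_mg_caco3):
            warnings.append(
                f"target water {target.water_id or ''} outside combined applicability "
                f"(pH {window.ph_range}, hardness {window.hardness_range} mg CaCO3/L)"
            )
    values = {}
    for s in sensitivities:
        values[s.species] = predict_lc50_dissolved(
            models[s.model_id], s.mean_q50, target, engine, allow_outside_range=True
        )
    return values, tuple(warnings)


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


def anderson_darling(x: np.ndarray, cdf) -> float:
    """Anderson-Darling statistic of a sample against a fitted CDF."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    z = np.clip(cdf(xs), 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2.0 * i - 1.0) * (np.log(z) + np.log(1.0 - z[::-1]))))


def _ad_pvalue_normal(a2: float, n: int) -> float:
    """Stephens/D'Agostino approximation for the normal family with
    estimated mean and variance (also exact for the log-normal family, whose
    maximum-likelihood fit is the normal fit of the log data)."""
    a = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a >= 0.6:
        return math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    if a >= 0.34:
        return math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    if a > 0.2:
        return 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    return 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)


def fit_family(x: np.ndarray, family: str, compute_ad: bool = True) -> SSDFit:
    """Maximum-likelihood fit of one family to log10-transformed values.

    ``compute_ad=False`` skips the Anderson-Darling statistic (used by the
    bootstrap, which only needs refitted quantiles).
    """
    dist, fit_kwargs, needs_positive = _FAMILIES[family]
    if needs_positive and np.any(x <= 0.0):
        return SSDFit(
            family,
            (),
            None,
            None,
            False,
            "inapplicable: log10 values <= 0 (support violation, not shifted)",
        )
    try:
        with np.errstate(all="ignore"):
            if family == "normal":  # closed-form MLE, identical to dist.fit
                params = (float(np.mean(x)), float(np.std(x)))
            elif family == "log-normal":  # MLE with loc=0: normal fit of ln x
                logs = np.log(x)
                params = (float(np.std(logs)), 0.0, float(np.exp(np.mean(logs))))
            else:
                params = dist.fit(x, **fit_kwargs)
            frozen = dist(*params)
            a2 = anderson_darling(x, frozen.cdf) if compute_ad else None
        if not all(np.isfinite(params)) or (a2 is not None and not np.isfinite(a2)):
            return SSDFit(family, tuple(params), None, None, False, "non-finite fit")
    except Exception as exc:  # scipy fit failures become non-fatal records
        return SSDFit(family, (), None, None, False, f"fit failed: {exc}")
    if a2 is None:
        return SSDFit(family, tuple(float(p) for p in params), None, None, True)
    pvalue = _ad_pvalue_normal(a2, x.size) if family in ("normal", "log-normal") else None
    return SSDFit(family, tuple(float(p) for p in params), a2, pvalue, True)


def fit_ssd(values_ug_l, min_n: int = 10) -> tuple[dict[str, SSDFit], str]:
    """Fit all six families to log10(values); best = minimum AD statistic.

    Ties are broken by the fixed family preference order.  Raises when fewer
    than ``min_n`` values or fewer than 2 distinct values are supplied, or
    when no family converges.
    """
    values = np.asarray(list(values_ug_l), dtype=float)
    if values.size < min_n:
        raise SSDError(f"SSD fitting needs >= {min_n} species, got {values.size}")
    if np.unique(values).size < 2:
        raise SSDError("SSD fitting needs >= 2 distinct values")
    if np.any(values <= 0.0):
        raise SSDError("normalized toxicity values must be > 0")
    x = np.log10(values)
    fits = {family: fit_family(x, family) for family in FAMILY_PREFERENCE}
    converged = [f for f in fits.values() if f.ok]
    if not converged:
        raise SSDError("no distribution family converged")
    best = min(converged, key=lambda f: (f.ad_stat, FAMILY_PREFERENCE.index(f.family)))
    return fits, best.family


def hc5(fit: SSDFit, quantile: float = 0.05) -> float:
    """HC at the given fraction affected: 10^(quantile of the log10 fit)."""
    if not fit.ok:
        raise SSDError(f"cannot take HC5 of failed fit {fit.family}")
    return float(10.0 ** fit.frozen().ppf(quantile))


def bootstrap_hc5(
    values_ug_l,
    family: str,
    b: int = 1000,
    seed: int | None = None,
    parametric: bool = False,
    quantile: float = 0.05,
) -> BootstrapResult:
    """Bootstrap 90% confidence interval for the HC5 of the selected family.

    Default: nonparametric resampling of the n species values with
    replacement, refitting ``family`` on each resample.  ``parametric=True``
    instead draws resamples of size n from the full-data fit.  Fully
    reproducible given the seed; more than 20% resample failures flag the
    result as unreliable.
    """
    if b < 100:
        raise SSDError(f"bootstrap needs B >= 100, got {b}")
    values = np.asarray(list(values_ug_l), dtype=float)
    n = values.size
    x = np.log10(values)
    rng = np.random.default_rng(seed)
    base = fit_family(x, family)
    if not base.ok:
        raise SSDError(f"cannot bootstrap a failed fit ({family}: {base.message})")
    frozen = base.frozen()
    hc5s = []
    failed = 0
    z = stats.norm.ppf(quantile)
    for _ in range(b):
        xs = frozen.rvs(size=n, random_state=rng) if parametric else rng.choice(x, size=n)
        if family == "normal":  # closed-form refit + quantile
            hc5s.append(10.0 ** (np.mean(xs) + z * np.std(xs)))
            continue
        f = fit_family(xs, family, compute_ad=False)
        if f.ok:
            hc5s.append(10.0 ** f.frozen().ppf(quantile))
        else:
            failed += 1
    if not hc5s:
        raise SSDError("all bootstrap resamples failed to fit")
    lo, mid, hi = np.percentile(hc5s, [5.0, 50.0, 95.0])
    return BootstrapResult(
        hc5_5=float(lo),
        hc5_50=float(mid),
        hc5_95=float(hi),
        b_requested=b,
        b_failed=failed,
        seed=seed,
        parametric=parametric,
        unreliable=failed > 0.2 * b,
    )


def derive_hc5(
    sensitivities: list[SpeciesSensitivity],
    target: WaterSample,
    models: dict[str, GBAMModel] | None = None,
    engine: SpeciationEngine | None = None,
    b: int = 1000,
    seed: int | None = 42,
    parametric: bool = False,
    min_n: int = 10,
) -> HC5Result:
    """Full target-water pipeline: normalize, fit, select, bootstrap."""
    values, warnings = normalize_to_water(sensitivities, target, models, engine)
    fits, best_family = fit_ssd(values.values(), min_n=min_n)
    point = hc5(fits[best_family])
    boot = bootstrap_hc5(values.values(), best_family, b=b, seed=seed, parametric=parametric)
    warn = list(warnings)
    if boot.unreliable:
        warn.append(f"bootstrap unreliable: {boot.b_failed}/{b} resample fits failed")
    return HC5Result(
        water_id=target.water_id or "target",
        normalized_lc50=values,
        fits=fits,
        best_family=best_family,
        hc5_best_fit=point,
        hc5_50=boot.hc5_50,
        hc5_5=boot.hc5_5,
        hc5_95=boot.hc5_95,
        b=b,
        seed=seed,
        warnings=tuple(warn),
    )


def plot_ssd(result: HC5Result, path) -> None:
    """Empirical SSD points with the fitted best-family curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.sort(np.array(list(result.normalized_lc50.values())))
    n = values.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    frozen = result.fits[result.best_family].frozen()
    grid = np.linspace(math.log10(values.min()) - 0.5, math.log10(values.max()) + 0.5, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(values, ecdf, "o", mec="k", mfc="tab:blue", label="species")
    ax.semilogx(10.0 ** grid, frozen.cdf(grid), "-", color="tab:red", label=result.best_family)
    ax.axhline(0.05, color="grey", lw=0.8, ls=":")
    ax.axvline(result.hc5_50, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("normalized L(E)C50 (ug dissolved Ni/L)")
    ax.set_ylabel("fraction of species affected")
    ax.set_title(f"{result.water_id}: HC5-50 = {result.hc5_50:.3g} ug/L")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
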