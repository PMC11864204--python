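"""Model-performance statistics and per-dataset intrinsic-sensitivity calibration.

The overall model performance score (MPS) is the arithmetic mean of three
[0, 1] metrics computed on log10 toxicity: the coefficient of determination
r2 (clamped to 0 when the model does worse than the dataset-mean null
model), the factor of agreement FA (fraction of predictions within 2-fold
of the observations, boundary inclusive), and the total residual score
Tot RS quantifying bias of the residuals against the toxicity-modifying
factors (pH, DOC, Ca, Mg).

The Tot RS formula used here is a documented stand-in: RS_f = 1 - |Pearson
correlation(residuals, factor)|, aggregated by arithmetic mean over the
factors present.  It preserves the semantics (1 = unbiased, bounded [0, 1])
of the residual score but is not a replication of any published formula, so
printed Tot RS values from validation tables are not comparison targets;
the MPS aggregation arithmetic is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import ReferenceEngine, SpeciationEngine
from .gbam import GBAMModel, predict_lc50_dissolved, q50_from_observation
from .toxdb import ToxRecord

__all__ = [
    "PerfError",
    "PerformanceReport",
    "calibrate_q50",
    "r_squared",
    "factor_agreement",
    "residual_scores",
    "mps",
    "evaluate_dataset",
    "plot_observed_predicted",
]

#: Records enter Q50 calibration only when Ca and Mg are each below this
#: total concentration (mol/L), excluding extreme-hardness waters.
CALIBRATION_CA_MG_MAX_MOL = 3e-3

_FA_EPS = 1e-9  # boundary-inclusive 2-fold comparison, robust to rounding


class PerfError(ValueError):
    """Invalid performance-evaluation input."""


def calibrate_q50(
    records: list[ToxRecord],
    model: GBAMModel,
    engine: SpeciationEngine | None = None,
) -> float:
    """Arithmetic-mean Direction-1 Q50 of a dataset.

    Only records whose test water has Ca and Mg each < 3 mmol/L enter the
    mean (the calibration rule used for per-dataset intrinsic
    sensitivities).
    """
    engine = engine if engine is not None else ReferenceEngine()
    q50s = []
    for record in records:
        water = record.water
        ca = water.ca if water.ca is not None else 0.0
        mg = water.mg if water.mg is not None else 0.0
        if ca >= CALIBRATION_CA_MG_MAX_MOL or mg >= CALIBRATION_CA_MG_MAX_MOL:
            continue
        res = engine.speciate(water, record.lc50)
        q50s.append(
            q50_from_observation(
                model, res.activity_ni2, water.ph, res, allow_outside_range=True
            )
        )
    if not q50s:
        raise PerfError("no records eligible for Q50 calibration (Ca/Mg < 3 mM)")
    return float(np.mean(q50s))


def r_squared(observed_log10, predicted_log10) -> float | None:
    """1 - SSR/SST on log10 values, clamped to 0; None when SST = 0."""
    obs = np.asarray(observed_log10, dtype=float)
    pred = np.asarray(predicted_log10, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise PerfError("observed and predicted must be equal-length 1-D arrays")
    if obs.size < 2:
        raise PerfError("r_squared needs n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        return None  # undefined for a constant observed vector
    ssr = float(np.sum((pred - obs) ** 2))
    return max(0.0, 1.0 - ssr / sst)


def factor_agreement(observed, predicted) -> float:
    """Fraction of predictions within 2-fold of observations (inclusive)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise PerfError("observed and predicted must be equal-length, non-empty 1-D arrays")
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise PerfError("factor agreement needs positive toxicity values")
    ratio = np.abs(np.log10(pred / obs))
    return float(np.mean(ratio <= math.log10(2.0) + _FA_EPS))


def residual_scores(
    residuals_log10, tmf_values: dict[str, "np.ndarray"]
) -> tuple[dict[str, float], float | None]:
    """Per-factor residual scores RS_f = 1 - |Pearson r| and their mean.

    Zero-variance factors are skipped; factors need n >= 3.  Returns
    (per-factor scores, Tot RS) with Tot RS None when no factor is scorable.
    """
    res = np.asarray(residuals_log10, dtype=float)
    # residual spread below 1e-10 log10 units carries no detectable bias;
    # correlations of machine-precision residuals would be noise
    degenerate = np.ptp(res) < 1e-10
    scores: dict[str, float] = {}
    for name, values in tmf_values.items():
        v = np.asarray(values, dtype=float)
        if v.shape != res.shape:
            raise PerfError(f"factor {name!r} length does not match residuals")
        if res.size < 3:
            raise PerfError("residual scores need n >= 3")
        if np.ptp(v) == 0.0:
            continue
        if degenerate:
            scores[name] = 1.0
            continue
        r = float(np.corrcoef(res, v)[0, 1])
        scores[name] = 1.0 - abs(r)
    tot = float(np.mean(list(scores.values()))) if scores else None
    return scores, tot


def mps(r2: float, fa: float, tot_rs: float) -> float:
    """Arithmetic mean of r2, FA and Tot RS, reported to 2 decimals."""
    for name, value in (("r2", r2), ("fa", fa), ("tot_rs", tot_rs)):
        if not 0.0 <= value <= 1.0:
            raise PerfError(f"{name} must lie in [0, 1], got {value}")
    return round((r2 + fa + tot_rs) / 3.0, 2)


@dataclass(frozen=True)
class PerformanceReport:
    """Performance of one bioavailability model on one dataset."""

    dataset_id: str
    n: int
    r2: float | None
    fa: float
    rs_per_tmf: dict[str, float] = field(default_factory=dict)
    tot_rs: float | None = None
    mps: float | None = None
    q50_calibrated: float | None = None
    observed_log10: tuple[float, ...] = ()
    predicted_log10: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "n": self.n,
            "r2": self.r2,
            "fa": self.fa,
            "rs_per_tmf": dict(self.rs_per_tmf),
            "tot_rs": self.tot_rs,
            "mps": self.mps,
            "q50_calibrated": self.q50_calibrated,
        }


def evaluate_dataset(
    records: list[ToxRecord],
    model: GBAMModel,
    engine: SpeciationEngine | None = None,
    dataset_id: str = "dataset",
) -> PerformanceReport:
    """Calibrate Q50 on the dataset, predict each record, score the model.

    Predictions are dissolved-level L(E)C50s from the calibrated Q50
    (Direction 2 plus back-translation to dissolved Ni); observed and
    predicted are compared on the log10 scale.
    """
    if not records:
        raise PerfError("empty dataset")
    engine = engine if engine is not None else ReferenceEngine()
    q50_cal = calibrate_q50(records, model, engine)
    obs_log, pred_log = [], []
    tmf = {"ph": [], "doc": [], "ca": [], "mg": []}
    for record in records:
        water = record.water
        predicted = predict_lc50_dissolved(
            model, q50_cal, water, engine, allow_outside_range=True
        )
        obs_log.append(math.log10(record.lc50))
        pred_log.append(math.log10(predicted))
        res = engine.speciate(water, record.lc50)
        tmf["ph"].append(water.ph)
        tmf["doc"].append(water.doc if water.doc is not None else 0.0)
        tmf["ca"].append(res.activity_ca2)
        tmf["mg"].append(res.activity_mg2)
    obs = np.array(obs_log)
    pred = np.array(pred_log)
    r2 = r_squared(obs, pred) if obs.size >= 2 else None
    fa = factor_agreement(10.0 ** obs, 10.0 ** pred)
    residuals = pred - obs
    if obs.size >= 3:
        rs, tot_rs = residual_scores(residuals, {k: np.array(v) for k, v in tmf.items()})
    else:
        rs, tot_rs = {}, None
    score = mps(r2, fa, tot_rs) if r2 is not None and tot_rs is not None else None
    return PerformanceReport(
        dataset_id=dataset_id,
        n=len(records),
        r2=r2,
        fa=fa,
        rs_per_tmf=rs,
        tot_rs=tot_rs,
        mps=score,
        q50_calibrated=q50_cal,
        observed_log10=tuple(obs),
        predicted_log10=tuple(pred),
    )


def plot_observed_predicted(report: PerformanceReport, path) -> None:
    """Observed-vs-predicted scatter with the 2-fold agreement band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.asarray(report.observed_log10)
    pred = np.asarray(report.predicted_log10)
    fig, ax = plt.subplots(figsize=(5, 5))
    lims = (min(obs.min(), pred.min()) - 0.3, max(obs.max(), pred.max()) + 0.3)
    ax.plot(lims, lims, "k-", lw=1)
    offset = math.log10(2.0)
    ax.plot(lims, [v + offset for v in lims], "k--", lw=0.8)
    ax.plot(lims, [v - offset for v in lims], "k--", lw=0.8)
    ax.scatter(obs, pred, s=25, edgecolor="k", facecolor="tab:blue", zorder=3)
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.set_xlabel("observed log10 L(E)C50 (ug dissolved Ni/L)")
    ax.set_ylabel("predicted log10 L(E)C50 (ug dissolved Ni/L)")
    ax.set_title(f"{report.dataset_id}: MPS = {report.mps}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
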