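"""Species aggregation, normalization, SSD fitting and bootstrap HC5."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from nibam.chemistry import WaterSample
from nibam.gbam import predict_lc50_dissolved
from nibam.ssd import (
    FAMILY_PREFERENCE,
    SSDError,
    SpeciesSensitivity,
    aggregate_species,
    anderson_darling,
    bootstrap_hc5,
    derive_hc5,
    fit_family,
    fit_ssd,
    hc5,
    normalize_to_water,
)
from nibam.synthetic import make_water
from nibam.toxdb import ToxRecord


def record(species, lc50, water, record_id, endpoint="immobilization", duration=48.0,
           taxon="cladoceran"):
    return ToxRecord(
        record_id=record_id,
        species=species,
        taxon_group=taxon,
        endpoint=endpoint,
        duration_h=duration,
        lc50=lc50,
        basis="dissolved",
        medium="natural",
        water=water,
        retained=True,
    )


def sensitivity(species, q50, model_id="avg_invertebrate"):
    return SpeciesSensitivity(
        species=species, endpoint="immobilization", duration_h=48.0,
        mean_q50=q50, n_records=1, model_id=model_id, source_record_ids=("r",),
    )


class TestAggregateSpecies:
    def test_single_record_passes_through(self, engine, models):
        water = make_water(7.4, 1.0, 80.0)
        lc50 = predict_lc50_dissolved(models["avg_invertebrate"], 5.3, water, engine)
        out = aggregate_species([record("Daphnia magna", lc50, water, "r1")], models, engine)
        assert len(out) == 1
        assert out[0].mean_q50 == pytest.approx(5.3, abs=1e-7)
        assert out[0].n_records == 1

    def test_most_sensitive_endpoint_selected(self, engine, models):
        model = models["avg_invertebrate"]
        water = make_water(7.4, 1.0, 80.0)
        lc_low_q = predict_lc50_dissolved(model, 5.1, water, engine)
        lc_high_q = predict_lc50_dissolved(model, 5.4, water, engine)
        records = [
            record("Hyalella azteca", lc_low_q, water, "r1", endpoint="mortality",
                   duration=96.0, taxon="amphipod"),
            record("Hyalella azteca", lc_high_q, water, "r2", endpoint="immobilization",
                   duration=96.0, taxon="amphipod"),
        ]
        out = aggregate_species(records, models, engine)
        assert out[0].endpoint == "immobilization"
        assert out[0].mean_q50 == pytest.approx(5.4, abs=1e-7)

    def test_most_sensitive_duration_group_selected(self, engine, models):
        model = models["avg_invertebrate"]
        water = make_water(7.4, 1.0, 80.0)
        records = [
            record("Hyalella azteca", predict_lc50_dissolved(model, 5.0, water, engine),
                   water, "r1", endpoint="mortality", duration=96.0, taxon="amphipod"),
            record("Hyalella azteca", predict_lc50_dissolved(model, 5.6, water, engine),
                   water, "r2", endpoint="mortality", duration=168.0, taxon="amphipod"),
        ]
        out = aggregate_species(records, models, engine)
        # lowest LC50 <-> highest Q50 group wins
        assert out[0].duration_h == 168.0
        assert out[0].mean_q50 == pytest.approx(5.6, abs=1e-7)

    def test_duplicate_records_average_idempotently(self, engine, models):
        water = make_water(7.4, 1.0, 80.0)
        lc50 = predict_lc50_dissolved(models["avg_invertebrate"], 5.3, water, engine)
        single = aggregate_species([record("D m", lc50, water, "r1")], models, engine)
        double = aggregate_species(
            [record("D m", lc50, water, "r1"), record("D m", lc50, water, "r2")],
            models, engine,
        )
        assert double[0].mean_q50 == pytest.approx(single[0].mean_q50, rel=1e-12)
        assert double[0].n_records == 2

    def test_rejected_records_ignored(self, engine, models):
        water = make_water(7.4, 1.0, 80.0)
        rejected = dataclasses.replace(
            record("D m", 1.0, water, "r1"), retained=False, rejection_reason="x"
        )
        assert aggregate_species([rejected], models, engine) == []

    def test_species_names_normalized_case_insensitively(self, engine, models):
        water = make_water(7.4, 1.0, 80.0)
        lc50 = predict_lc50_dissolved(models["avg_invertebrate"], 5.0, water, engine)
        out = aggregate_species(
            [record("Daphnia magna", lc50, water, "r1"),
             record("daphnia  MAGNA", lc50, water, "r2")],
            models, engine,
        )
        assert len(out) == 1 and out[0].n_records == 2


class TestNormalizeToWater:
    def test_round_trip_to_own_water(self, engine, models):
        water = make_water(7.4, 1.0, 80.0, water_id="own")
        lc50 = predict_lc50_dissolved(models["avg_invertebrate"], 5.3, water, engine)
        sens = aggregate_species([record("D m", lc50, water, "r1")], models, engine)
        values, warnings = normalize_to_water(sens, water, models, engine)
        assert values["D m"] == pytest.approx(lc50, rel=1e-6)
        assert warnings == ()

    def test_higher_doc_target_raises_all_values(self, engine, models):
        sens = [sensitivity(f"sp{i}", 4.5 + 0.1 * i) for i in range(3)]
        low, _ = normalize_to_water(sens, make_water(7.5, 1.0, 100.0), models, engine)
        high, _ = normalize_to_water(sens, make_water(7.5, 15.0, 100.0), models, engine)
        assert all(high[s] > low[s] for s in low)

    def test_species_order_invariance(self, engine, models):
        sens = [sensitivity(f"sp{i}", 4.5 + 0.1 * i) for i in range(4)]
        target = make_water(7.0, 2.0, 60.0)
        a, _ = normalize_to_water(sens, target, models, engine)
        b, _ = normalize_to_water(list(reversed(sens)), target, models, engine)
        assert a == b

    def test_identical_waters_give_identical_results(self, engine, models):
        sens = [sensitivity(f"sp{i}", 4.5 + 0.1 * i) for i in range(3)]
        w1 = make_water(7.3, 3.0, 120.0, water_id="a")
        w2 = make_water(7.3, 3.0, 120.0, water_id="b")
        v1, _ = normalize_to_water(sens, w1, models, engine)
        v2, _ = normalize_to_water(sens, w2, models, engine)
        assert v1 == v2

    def test_out_of_window_target_warns_not_fails(self, engine, models):
        sens = [sensitivity(f"sp{i}", 4.5) for i in range(2)]
        target = WaterSample(ph=5.2, doc=1.0, ca=2e-4, mg=7e-5, water_id="acidic")
        values, warnings = normalize_to_water(sens, target, models, engine)
        assert len(values) == 2
        assert any("applicability" in w for w in warnings)


class TestFitSSD:
    def test_normal_data_prefers_thin_tailed_families(self):
        rng = np.random.default_rng(1234)
        x = rng.normal(2.0, 0.5, size=5000)
        values = 10.0 ** x
        fits, best = fit_ssd(values)
        # at n=5000 a normal sample must beat the clearly mis-specified
        # heavy/skew families on the Anderson-Darling statistic
        assert fits["normal"].ad_stat < fits["gumbel"].ad_stat
        assert fits["normal"].ad_stat < fits["logistic"].ad_stat
        assert best in ("normal", "log-normal", "gamma")

    def test_location_shift_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.5, 0.4, size=200)
        f1 = fit_family(x, "normal")
        f2 = fit_family(x + 2.0, "normal")
        assert f2.params[0] == pytest.approx(f1.params[0] + 2.0, abs=1e-9)
        assert f2.params[1] == pytest.approx(f1.params[1], abs=1e-9)
        g1 = fit_family(x, "gumbel")
        g2 = fit_family(x + 2.0, "gumbel")
        assert g2.params[0] == pytest.approx(g1.params[0] + 2.0, abs=1e-6)

    def test_ad_statistic_finite_positive(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        fit = fit_family(x, "normal")
        assert fit.ok and fit.ad_stat > 0 and math.isfinite(fit.ad_stat)

    def test_ad_statistic_matches_scipy_for_normal(self):
        # independent cross-check of the AD formula against scipy.stats.anderson
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        import warnings

        ours = anderson_darling(x, stats.norm(x.mean(), x.std(ddof=1)).cdf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            scipy_a2 = stats.anderson(x, dist="norm").statistic
        assert ours == pytest.approx(scipy_a2, rel=1e-10)

    def test_nonpositive_log_values_mark_positive_families_inapplicable(self):
        values = np.concatenate([[0.5], 10.0 ** np.random.default_rng(3).normal(1.5, 0.3, 19)])
        fits, best = fit_ssd(values)
        assert not fits["gamma"].ok and "inapplicable" in fits["gamma"].message
        assert not fits["log-normal"].ok and not fits["weibull"].ok
        assert fits["normal"].ok and best in ("normal", "logistic", "gumbel")

    def test_too_few_species_rejected(self):
        with pytest.raises(SSDError):
            fit_ssd([10.0, 20.0, 30.0])

    def test_degenerate_values_rejected(self):
        with pytest.raises(SSDError):
            fit_ssd([10.0] * 12)

    def test_normal_ad_pvalue_calibration(self):
        # p-values from the Stephens approximation are roughly uniform under H0;
        # check the median over replicates is not extreme
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(100):
            fit = fit_family(rng.normal(size=40), "normal")
            pvals.append(fit.ad_pvalue)
        assert 0.3 < np.median(pvals) < 0.7


class TestHC5:
    def test_closed_form_normal_quantile(self):
        fit = fit_family(np.array([2.0, 2.5, 1.5, 2.0, 2.25, 1.75]), "normal")
        manual = dataclasses.replace(fit, params=(2.0, 0.5))
        assert hc5(manual) == pytest.approx(10.0 ** (2.0 - 1.6448536269514722 * 0.5), rel=1e-9)
        assert hc5(manual) == pytest.approx(15.05, abs=0.01)

    def test_degenerate_scale_limit(self):
        fit = fit_family(np.array([2.0, 2.1, 1.9, 2.0]), "normal")
        tight = dataclasses.replace(fit, params=(2.0, 1e-12))
        assert hc5(tight) == pytest.approx(100.0, rel=1e-6)

    def test_hc5_below_median(self):
        rng = np.random.default_rng(2)
        fit = fit_family(rng.normal(1.0, 0.6, 30), "normal")
        assert hc5(fit) < 10.0 ** fit.frozen().ppf(0.5)


class TestBootstrap:
    def test_quantile_ordering_and_determinism(self):
        rng = np.random.default_rng(8)
        values = 10.0 ** rng.normal(2.0, 0.5, size=25)
        b1 = bootstrap_hc5(values, "normal", b=200, seed=11)
        b2 = bootstrap_hc5(values, "normal", b=200, seed=11)
        b3 = bootstrap_hc5(values, "normal", b=200, seed=12)
        assert b1.hc5_5 <= b1.hc5_50 <= b1.hc5_95
        assert (b1.hc5_5, b1.hc5_50, b1.hc5_95) == (b2.hc5_5, b2.hc5_50, b2.hc5_95)
        assert b1.hc5_50 != b3.hc5_50
        assert not b1.unreliable

    def test_parametric_mode_also_deterministic(self):
        rng = np.random.default_rng(8)
        values = 10.0 ** rng.normal(2.0, 0.5, size=25)
        p1 = bootstrap_hc5(values, "normal", b=150, seed=3, parametric=True)
        p2 = bootstrap_hc5(values, "normal", b=150, seed=3, parametric=True)
        assert p1 == p2

    def test_b_floor(self):
        with pytest.raises(SSDError):
            bootstrap_hc5([1.0, 2.0], "normal", b=50, seed=1)


class TestDeriveHC5:
    def test_full_pipeline_contract(self, engine, models):
        rng = np.random.default_rng(17)
        sens = [sensitivity(f"sp{i:02d}", float(rng.normal(5.0, 0.6))) for i in range(15)]
        target = make_water(7.5, 2.0, 100.0, water_id="target")
        result = derive_hc5(sens, target, models, engine, b=200, seed=99)
        assert result.hc5_5 <= result.hc5_50 <= result.hc5_95
        assert result.best_family in FAMILY_PREFERENCE
        converged = [f for f in result.fits.values() if f.ok]
        assert result.fits[result.best_family].ad_stat == min(f.ad_stat for f in converged)
        assert len(result.normalized_lc50) == 15
        payload = result.to_dict()
        assert payload["bootstrap_B"] == 200 and payload["seed"] == 99
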