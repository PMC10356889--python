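import numpy as np
import pytest

from cbmndose import (
    LQCurve,
    SimulationConfig,
    build_error_model,
    correct_counts,
    dispersion_index,
    fit_lq,
    mn_frequency,
    predict_yield,
    simulate_distribution,
    simulate_study,
    corrupt_scoring,
)
from cbmndose.scoring import ScoringErrorModel

TABLE1_DOSES = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0)

ZERO_MODEL = ScoringErrorModel((0.0, 4.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))


class TestSimulateDistribution:
    def test_flat_zero_curve_puts_all_cells_in_class_zero(self):
        dist = simulate_distribution(LQCurve(0, 0, 0), 2.0, 500, seed=3)
        assert dist.counts[0] == 500
        assert dist.n_mn == 0

    def test_determinism_per_seed(self, manual_curve):
        a = simulate_distribution(manual_curve, 2.0, 5000, seed=42)
        b = simulate_distribution(manual_curve, 2.0, 5000, seed=42)
        assert a == b

    def test_mean_frequency_matches_curve_at_top_dose(self, manual_curve):
        """Over 50 seeds at 4 Gy the mean simulated MN frequency sits within
        3 standard errors of the curve yield."""
        lam = predict_yield(manual_curve, 4.0)
        n = 18000
        freqs = [
            mn_frequency(simulate_distribution(manual_curve, 4.0, n, seed=s))
            for s in range(50)
        ]
        se_mean = np.sqrt(lam / n) / np.sqrt(50)
        assert np.mean(freqs) == pytest.approx(lam, abs=3 * se_mean)

    def test_poisson_mode_dispersion_is_unity_on_average(self, manual_curve):
        """Mean dispersion index over 200 Poisson replicates at 1 Gy lies
        in [0.98, 1.02]."""
        dis = [
            dispersion_index(simulate_distribution(manual_curve, 1.0, 2000, seed=s))
            for s in range(200)
        ]
        assert 0.98 <= np.mean(dis) <= 1.02

    def test_overdispersed_mode_hits_target_index(self, manual_curve):
        target = 1.12
        dis = [
            dispersion_index(
                simulate_distribution(
                    manual_curve, 2.0, 5000, seed=s,
                    dispersion="overdispersed", target_di=target,
                )
            )
            for s in range(100)
        ]
        assert np.mean(dis) == pytest.approx(target, abs=0.02)

    def test_invalid_dispersion_arguments(self, manual_curve):
        with pytest.raises(ValueError):
            simulate_distribution(manual_curve, 1.0, 100, 1, dispersion="weird")
        with pytest.raises(ValueError):
            simulate_distribution(
                manual_curve, 1.0, 100, 1, dispersion="overdispersed", target_di=1.0
            )


class TestCorruptScoring:
    def test_zero_error_model_is_identity(self, manual_curve):
        dist = simulate_distribution(manual_curve, 2.0, 3000, seed=5)
        auto, rec = corrupt_scoring(dist, ZERO_MODEL, seed=5)
        assert auto == dist
        assert (rec.n_fp_bn, rec.n_fp_mn, rec.n_fn_mn) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_manual_correction_round_trip_restores_totals(
        self, manual_curve, table2, seed
    ):
        """Corrupting then applying the manual correction returns the exact
        BN and MN totals of the original distribution, for any seed."""
        model = build_error_model(table2)
        for dose in (0.0, 1.0, 4.0):
            dist = simulate_distribution(manual_curve, dose, 4000, seed=seed)
            auto, rec = corrupt_scoring(dist, model, seed=seed + 100)
            restored = correct_counts(auto, rec, "manual")
            assert restored.n_bn == dist.n_bn
            assert restored.n_mn == dist.n_mn

    def test_error_draw_means_match_model_rates(self, manual_curve, table2):
        """At 4 Gy on 18,000 cells the binomial corruption draws average to
        the model rates (1.46% added, 10.78% removed) within 3 SDs."""
        model = build_error_model(table2)
        n = 18000
        dist = simulate_distribution(manual_curve, 4.0, n, seed=0)
        fp, fn = [], []
        for s in range(100):
            _, rec = corrupt_scoring(dist, model, seed=s)
            fp.append(rec.n_fp_mn)
            fn.append(rec.n_fn_mn)
        for vals, pct in ((fp, 1.46), (fn, 10.78)):
            p = pct / 100
            se = np.sqrt(n * p * (1 - p) / 100)
            assert np.mean(vals) == pytest.approx(n * p, abs=3 * se)


class TestSimulateStudy:
    def _config(self, curve, **kw):
        defaults = dict(
            curve=curve, doses=TABLE1_DOSES, n_bn_per_dose=18000, seed=1,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_identical_config_gives_identical_outputs(self, manual_curve, table2):
        cfg = self._config(
            manual_curve, error_model=build_error_model(table2),
            blind_doses=(0.0, 1.0, 2.5), n_bn_per_dose=2000,
        )
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.clean.points == b.clean.points
        assert a.corrupted.points == b.corrupted.points
        assert a.samples == b.samples
        assert a.truth == b.truth

    def test_clean_fit_recovers_generating_curve(self, manual_curve):
        study = simulate_study(self._config(manual_curve))
        fitted = fit_lq(study.clean)
        assert abs(fitted.c - manual_curve.c) < 3 * fitted.se_c
        assert abs(fitted.alpha - manual_curve.alpha) < 3 * fitted.se_alpha
        assert abs(fitted.beta - manual_curve.beta) < 3 * fitted.se_beta

    def test_blind_samples_carry_truth_key(self, manual_curve):
        study = simulate_study(
            self._config(manual_curve, n_bn_per_dose=1000,
                         blind_doses=(0.5, 2.0), n_bn_blind=1500)
        )
        assert len(study.samples) == 2
        for s in study.samples:
            assert study.truth[s.sample_id] == s.delivered_dose
            assert s.n_bn == 1500

    def test_donor_baseline_multipliers_raise_background(self, manual_curve):
        """A 1.4x female background multiplier raises the pooled 0 Gy yield
        above the unstratified one at matched seeds."""
        plain = simulate_study(self._config(manual_curve, n_bn_per_dose=30000))
        mixed = simulate_study(
            self._config(
                manual_curve, n_bn_per_dose=30000,
                donor_baseline_multipliers=(1.0, 1.0, 1.0, 1.4, 1.4, 1.4),
            )
        )
        y0_plain = mn_frequency(plain.clean.points[0])
        y0_mixed = mn_frequency(mixed.clean.points[0])
        assert y0_mixed > y0_plain * 1.05

    def test_corruption_depresses_the_quadratic_coefficient(
        self, manual_curve, table2
    ):
        """Dose-increasing missed MN depress high-dose yields, so fits on
        corrupted data show a lower quadratic coefficient than clean fits
        (median over seeds)."""
        model = build_error_model(table2)
        clean_b, corrupt_b = [], []
        for seed in range(10):
            cfg = self._config(
                manual_curve, seed=seed, n_bn_per_dose=6000, error_model=model
            )
            study = simulate_study(cfg)
            clean_b.append(fit_lq(study.clean).beta)
            corrupt_b.append(fit_lq(study.corrupted).beta)
        assert np.median(corrupt_b) < np.median(clean_b)
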