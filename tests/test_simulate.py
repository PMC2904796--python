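"""Synthetic screen generator: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from chronoscreen import (
    ScreenConfig,
    evaluate_recovery,
    simulate_pool_dynamics,
    simulate_screen,
    simulate_tag_intensities,
    simulate_truth,
    survival_fraction,
)
from chronoscreen.errors import ConfigurationError, InputError, SimulationError

from conftest import noiseless_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_long": 0.7, "frac_short": 0.5},
            {"frac_long": -0.1},
            {"timepoints": (3, 9, 9, 15)},
            {"timepoints": (9, 11, 15), "reference_day": 3},
            {"noise_sigma": -1.0},
            {"long_t50_multiplier": 0.9},
            {"short_t50_multiplier": 1.2},
            {"background_level": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ScreenConfig(**kwargs)


class TestSimulateTruth:
    def test_degenerate_fractions_all_neutral(self):
        truth = simulate_truth(ScreenConfig(n_strains=50, frac_long=0, frac_short=0))
        assert (truth.table["true_class"] == "neutral").all()

    def test_same_seed_identical_truth(self):
        cfg = ScreenConfig(n_strains=100, seed=42)
        pd.testing.assert_frame_equal(simulate_truth(cfg).table, simulate_truth(cfg).table)

    def test_rounding_rule_exact_class_counts(self):
        truth = simulate_truth(ScreenConfig(n_strains=1000, frac_long=0.05, frac_short=0.12))
        counts = truth.table["true_class"].value_counts()
        assert counts["long"] == 50
        assert counts["short"] == 120

    def test_t50_floor_and_class_consistency(self):
        cfg = ScreenConfig(n_strains=400, pool_t50_mean=4.0, pool_t50_sd=3.0,
                           frac_long=0.1, frac_short=0.1, seed=3)
        truth = simulate_truth(cfg)
        t = truth.table
        base = np.where(
            t["true_class"] == "long", t["true_t50"] / cfg.long_t50_multiplier,
            np.where(t["true_class"] == "short", t["true_t50"] / cfg.short_t50_multiplier,
                     t["true_t50"]),
        )
        assert (base >= cfg.timepoints[0] - 1e-9).all()


class TestPoolDynamics:
    def test_identical_t50_constant_shares(self):
        cfg = noiseless_config(pool_t50_sd=0.0, frac_long=0, frac_short=0)
        truth = simulate_truth(cfg)
        viable, _ = simulate_pool_dynamics(truth, cfg)
        shares = viable.to_numpy() / viable.to_numpy().sum(axis=0)
        assert np.allclose(shares, shares[:, [0]])

    def test_regrowth_strictly_raises_late_pool_cfu(self):
        cfg = noiseless_config(pool_t50_sd=0.0, regrow_gain=10.0, regrow_day=12)
        truth = simulate_truth(cfg)
        truth.table.loc[0, "regrows"] = True
        viable_re, cfu_re = simulate_pool_dynamics(truth, cfg)
        truth.table.loc[0, "regrows"] = False
        viable_no, cfu_no = simulate_pool_dynamics(truth, cfg)
        late_re = cfu_re.query("replicate == 1 and day == 15")["cfu_per_ml"].iloc[0]
        late_no = cfu_no.query("replicate == 1 and day == 15")["cfu_per_ml"].iloc[0]
        assert late_re > late_no
        # pre-regrowth days untouched
        assert np.allclose(viable_re[9], viable_no[9])

    def test_survival_matches_closed_form_sigmoid(self):
        # t50 = 9, tau = 2, normalized at day 3: S(9) = f(9)/f(3) with
        # f(t) = 1/(1 + exp((t - 9)/2)); f(9) = 0.5, f(3) = 1/(1 + e^-3)
        cfg = noiseless_config(n_strains=1, pool_t50_mean=9.0, pool_t50_sd=0.0,
                               slope_tau=2.0, frac_long=0, frac_short=0)
        truth = simulate_truth(cfg)
        viable, _ = simulate_pool_dynamics(truth, cfg)
        expected = 0.5 / (1.0 / (1.0 + np.exp(-3.0)))
        got = viable[9].iloc[0] / viable[3].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5248935, abs=1e-6)

    def test_pool_cfu_conserves_strain_sum_before_jitter(self):
        cfg = noiseless_config(n_strains=80)
        truth = simulate_truth(cfg)
        viable, cfu = simulate_pool_dynamics(truth, cfg)
        for rep in (1, 2):
            sub = cfu[cfu["replicate"] == rep].set_index("day")["cfu_per_ml"]
            assert np.allclose(sub.reindex(viable.columns), viable.sum(axis=0))

    def test_reference_day_percent_exactly_100(self):
        cfg = ScreenConfig(n_strains=50, seed=2)
        _, cfu = simulate_pool_dynamics(simulate_truth(cfg), cfg)
        ref = cfu[cfu["day"] == cfg.reference_day]["percent_survival"]
        assert (ref == 100.0).all()


class TestTagIntensities:
    def test_symmetric_strains_equal_intensities(self):
        cfg = noiseless_config(n_strains=10, pool_t50_sd=0.0, frac_long=0, frac_short=0)
        truth = simulate_truth(cfg)
        viable, _ = simulate_pool_dynamics(truth, cfg)
        inten = simulate_tag_intensities(viable, truth, cfg)
        spread = inten.groupby(["tag", "replicate", "day"])["intensity"].agg(np.ptp)
        assert (spread < 1e-9).all()

    def test_doubling_abundance_doubles_intensity(self):
        cfg = noiseless_config(n_strains=5, pool_t50_sd=0.0)
        truth = simulate_truth(cfg)
        viable, _ = simulate_pool_dynamics(truth, cfg)
        inten1 = simulate_tag_intensities(viable, truth, cfg)
        viable2 = viable.copy()
        viable2.iloc[0] *= 2  # double one strain at every day
        inten2 = simulate_tag_intensities(viable2, truth, cfg)
        sid = viable.index[0]
        a = inten1[inten1.strain_id == sid].set_index(["tag", "replicate", "day"])["intensity"]
        b = inten2[inten2.strain_id == sid].set_index(["tag", "replicate", "day"])["intensity"]
        total1 = viable.sum(axis=0)
        total2 = viable2.sum(axis=0)
        scale = (2.0 * total1 / total2).reindex(b.index.get_level_values("day")).to_numpy()
        assert np.allclose(b.to_numpy(), a.to_numpy() * scale)

    def test_background_tags_uncorrelated_with_abundance(self):
        # over many seeds, a both-tags-background strain's day-20 intensity
        # carries no information about its true abundance
        cors_bg, cors_ok = [], []
        for seed in range(50):
            cfg = ScreenConfig(n_strains=40, frac_background_tags=0.0, noise_sigma=0.2,
                               pool_t50_sd=2.0, seed=seed)
            truth = simulate_truth(cfg)
            truth.table.loc[:9, ["uptag_background", "downtag_background"]] = True
            viable, _ = simulate_pool_dynamics(truth, cfg)
            inten = simulate_tag_intensities(viable, truth, cfg)
            day20 = (
                inten[(inten.day == 20) & (inten.replicate == 1) & (inten.tag == "up")]
                .set_index("strain_id")["intensity"]
            )
            abundance = viable[20]
            bg_ids, ok_ids = viable.index[:10], viable.index[10:]
            cors_bg.append(np.corrcoef(abundance[bg_ids], day20[bg_ids])[0, 1])
            cors_ok.append(np.corrcoef(abundance[ok_ids], day20[ok_ids])[0, 1])
        assert abs(np.mean(cors_bg)) < 0.15
        assert np.mean(cors_ok) > 0.5

    def test_extinct_pool_raises(self):
        cfg = noiseless_config(n_strains=3)
        truth = simulate_truth(cfg)
        viable, _ = simulate_pool_dynamics(truth, cfg)
        viable.loc[:, 20] = 0.0
        with pytest.raises(SimulationError):
            simulate_tag_intensities(viable, truth, cfg)

    def test_full_screen_deterministic_for_seed(self):
        cfg = ScreenConfig(n_strains=60, seed=5)
        _, _, cfu_a, inten_a = simulate_screen(cfg)
        _, _, cfu_b, inten_b = simulate_screen(cfg)
        pd.testing.assert_frame_equal(inten_a, inten_b)
        pd.testing.assert_frame_equal(cfu_a, cfu_b)


class TestEvaluateRecovery:
    def test_perfect_calls(self):
        truth = simulate_truth(ScreenConfig(n_strains=100, frac_long=0.1, frac_short=0.2))
        metrics = evaluate_recovery(truth, truth.classes())
        assert (metrics["precision"] == 1.0).all()
        assert (metrics["recall"] == 1.0).all()

    def test_no_calls_convention(self):
        truth = simulate_truth(ScreenConfig(n_strains=40, frac_long=0.25, frac_short=0.25))
        metrics = evaluate_recovery(truth, {})
        assert (metrics["recall"] == 0.0).all()
        assert metrics["precision"].isna().all()
        assert metrics["no_calls"].all()

    def test_random_calls_on_balanced_truth(self):
        rng = np.random.default_rng(0)
        truth = simulate_truth(ScreenConfig(n_strains=2000, frac_long=0.5, frac_short=0.5,
                                            seed=1))
        calls = pd.Series(rng.choice(["short", "long"], size=2000), index=truth.strain_ids)
        metrics = evaluate_recovery(truth, calls)
        assert metrics.loc["short", "precision"] == pytest.approx(0.5, abs=0.05)
        assert metrics.loc["long", "precision"] == pytest.approx(0.5, abs=0.05)

    def test_unknown_strains_rejected(self):
        truth = simulate_truth(ScreenConfig(n_strains=10))
        with pytest.raises(InputError):
            evaluate_recovery(truth, {"nonexistent": "short"})
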