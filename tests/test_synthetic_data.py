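import numpy as np
import pytest
from scipy import stats

from atikit.lexicons import generate_control_lexicon, load_lexicon
from atikit.synthetic_data import (GeneratorConfig, deaths_slope_for_target,
                                   simulate_covariates, simulate_latent,
                                   simulate_study, simulate_survey_panel,
                                   simulate_word_panel, substream)


@pytest.fixture(scope="module")
def en_lexicon():
    return load_lexicon("en", "absolutist")


@pytest.fixture(scope="module")
def control_lexicon():
    return generate_control_lexicon(19, seed=99)


class TestLatent:
    def test_noise_free_latent_is_constant_baseline(self):
        cfg = GeneratorConfig(sigma_lat=0.0, delta=0.0, t0=1, seed=0)
        lat = simulate_latent(cfg)
        assert np.allclose(lat, cfg.mu)

    def test_pure_step(self):
        cfg = GeneratorConfig(sigma_lat=0.0, delta=4.0, t0=56, n_weeks=104)
        lat = simulate_latent(cfg)[0]
        assert np.allclose(lat[:55], cfg.mu)
        assert np.allclose(lat[55:], cfg.mu + 4.0)

    def test_ar1_autocorrelation_matches_phi(self):
        cfg = GeneratorConfig(n_weeks=5000, phi=0.6, sigma_lat=1.0,
                              delta=0.0, t0=1, seed=5)
        x = simulate_latent(cfg)[0] - cfg.mu  # detrended latent
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.6, abs=0.1)

    def test_cubic_trend_enters_latent(self):
        cfg = GeneratorConfig(n_weeks=16, sigma_lat=0.0, delta=0.0, t0=1,
                              trend=(0.0, 0.0, 0.01))
        lat = simulate_latent(cfg)[0]
        tc = np.arange(1, 17) - np.arange(1, 17).mean()
        assert np.allclose(lat, cfg.mu + 0.01 * tc**3)

    def test_regions_draw_independent_noise(self):
        cfg = GeneratorConfig(n_regions=3, n_weeks=50, delta=0.0, t0=1, seed=2)
        lat = simulate_latent(cfg)
        assert lat.shape == (3, 50)
        assert not np.allclose(lat[0], lat[1])


class TestWordPanel:
    def test_constant_latent_zero_noise_gives_all_100(self, en_lexicon):
        cfg = GeneratorConfig(sigma_lat=0.0, sigma_word=0.0, delta=0.0, t0=1)
        lat = simulate_latent(cfg)[0]
        panel, diag = simulate_word_panel(lat, en_lexicon, cfg)
        assert np.all(panel.values == 100.0)
        assert diag["censored"] == 0

    def test_identical_loadings_zero_noise_alpha_one(self, en_lexicon):
        from atikit.ati_index import cronbach_alpha
        cfg = GeneratorConfig(sigma_word=0.0, seed=4)
        lat = simulate_latent(cfg)[0]
        panel, _ = simulate_word_panel(lat, en_lexicon, cfg)
        assert cronbach_alpha(panel) == pytest.approx(1.0, abs=1e-12)

    def test_every_series_attains_100_before_censoring(self, en_lexicon):
        cfg = GeneratorConfig(seed=6)
        lat = simulate_latent(cfg)[0]
        panel, _ = simulate_word_panel(lat, en_lexicon, cfg)
        assert np.allclose(panel.values.max(axis=1), 100.0)

    def test_censored_count_matches_brute_force(self, en_lexicon):
        # low baseline + heavy noise pushes cells under 1% of each term's max
        cfg = GeneratorConfig(mu=8.0, sigma_word=4.0, delta=0.0, t0=1, seed=7)
        lat = simulate_latent(cfg)[0]
        panel, diag = simulate_word_panel(lat, en_lexicon, cfg)
        raw = cfg.lam * lat[None, :] + diag["noise"]
        raw = np.where(raw < 0, 0.0, raw)
        scaled = raw * (100.0 / raw.max(axis=1)[:, None])
        expected = int((scaled < 1.0).sum())
        assert expected > 0
        assert diag["censored"] == expected
        assert int((panel.values == 0.0).sum()) == expected


class TestSurveyAndCovariates:
    def test_noise_free_link_is_monotone_in_latent(self):
        cfg = GeneratorConfig(n_weeks=30, sigma_survey=0.0, tau_region=0.0,
                              delta=0.0, t0=1, seed=8)
        lat = simulate_latent(cfg)
        survey = simulate_survey_panel(lat, cfg)
        rho = stats.spearmanr(lat[0], survey.depression[0]).statistic
        assert rho == pytest.approx(1.0)

    def test_null_link_gives_no_association(self):
        cfg = GeneratorConfig(n_weeks=300, gamma=0.0, delta=0.0, t0=1, seed=9)
        lat = simulate_latent(cfg)
        survey = simulate_survey_panel(lat, cfg)
        r = np.corrcoef(lat[0], survey.depression[0])[0, 1]
        assert abs(r) < 0.15

    def test_identity_deaths_link(self):
        cfg = GeneratorConfig(n_weeks=40, deaths_slope=1.0, sigma_deaths=0.0,
                              deaths_intercept=50.0, delta=0.0, t0=1, seed=10)
        lat = simulate_latent(cfg)[0]
        cov = simulate_covariates(lat, cfg)
        assert np.allclose(cov.new_deaths_per_million - 50.0, lat - cfg.mu)

    def test_null_deaths_link(self):
        cfg = GeneratorConfig(n_weeks=400, deaths_slope=0.0, delta=0.0, t0=1,
                              seed=11)
        lat = simulate_latent(cfg)[0]
        cov = simulate_covariates(lat, cfg)
        assert abs(np.corrcoef(lat, cov.new_deaths_per_million)[0, 1]) < 0.15

    def test_target_slope_calibration(self):
        cfg = GeneratorConfig(n_weeks=5000, delta=0.0, t0=1, seed=12)
        b = deaths_slope_for_target(0.5, cfg)
        cfg = cfg.replace(deaths_slope=b, deaths_intercept=100.0)
        lat = simulate_latent(cfg)[0]
        cov = simulate_covariates(lat, cfg)
        r = np.corrcoef(lat, cov.new_deaths_per_million)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_independent_cases_mode(self):
        cfg = GeneratorConfig(n_weeks=400, cases_mode="independent",
                              delta=0.0, t0=1, seed=13)
        lat = simulate_latent(cfg)[0]
        cov = simulate_covariates(lat, cfg)
        assert abs(np.corrcoef(cov.new_deaths_per_million,
                               cov.new_cases_per_million)[0, 1]) < 0.15


class TestStudy:
    def test_bit_identical_reproduction(self, en_lexicon, control_lexicon):
        cfg = GeneratorConfig(seed=21)
        a = simulate_study(cfg, en_lexicon, control_lexicon)
        b = simulate_study(cfg, en_lexicon, control_lexicon)
        assert np.array_equal(a.word_panel.values, b.word_panel.values)
        assert np.array_equal(a.control_panel.values, b.control_panel.values)
        assert np.array_equal(a.truth.latent, b.truth.latent)
        assert a.truth.true_ati_effect == b.truth.true_ati_effect

    def test_substreams_are_independent_and_named(self):
        assert substream(0, "latent").standard_normal() != \
            substream(0, "words").standard_normal()
        with pytest.raises(ValueError, match="substream"):
            substream(0, "weather")

    def test_null_intervention_leaves_no_systematic_shift(self, en_lexicon,
                                                          control_lexicon):
        diffs = []
        for i in range(200):
            cfg = GeneratorConfig(delta=0.0, seed=3000 + i)
            study = simulate_study(cfg, en_lexicon, control_lexicon)
            ati = study.word_panel.values.mean(axis=0)
            diffs.append(ati[cfg.t0 - 1:].mean() - ati[:cfg.t0 - 1].mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_truth_effect_tracks_nominal_step(self, en_lexicon, control_lexicon):
        study = simulate_study(GeneratorConfig(seed=22), en_lexicon,
                               control_lexicon)
        # nominal step 3.2 is rescaled by the observed normalisation (~1.05x)
        assert 2.5 < study.truth.true_ati_effect < 4.5

    def test_truth_json_round_trips(self, tmp_path, en_lexicon, control_lexicon):
        import json
        study = simulate_study(GeneratorConfig(seed=23, n_weeks=60, t0=30),
                               en_lexicon, control_lexicon)
        study.truth.to_json(tmp_path / "truth.json")
        payload = json.loads((tmp_path / "truth.json").read_text())
        cfg = GeneratorConfig.from_dict(payload["config"])
        assert cfg == study.truth.config
        assert payload["true_ati_effect"] == study.truth.true_ati_effect


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"t0": 0}, {"t0": 200}, {"phi": 1.0}, {"sigma_lat": -1.0},
        {"lam": 0.0}, {"cases_mode": "weird"}, {"n_weeks": 1},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)
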