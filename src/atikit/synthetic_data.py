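"""Synthetic search-volume, survey and covariate data with known truth.

The generator emulates the observables the analysis consumes:

* a latent regional distress process — baseline + optional polynomial trend
  on centered week + an additive level step of ``delta`` index points from
  the intervention week ``t0`` on + stationary AR(1) noise;
* per-term relative search volumes — each dictionary term loads linearly on
  the latent, gets independent Gaussian noise, is max-normalised to the
  0–100 scale within the generated window (each series hits 100 at its own
  maximum week, as the search platform's within-query scaling does), and
  sub-unit values are censored to 0 exactly like the platform's "<1" rule;
* survey panels — the percentage of respondents above a clinical
  depression/anxiety cutoff, linked to the latent through a linear slope
  ``gamma`` (depression), while anxiety follows its own quadratic-trend
  process so the index can track depression but not anxiety dynamics;
* epidemic covariates — weekly deaths per million linked linearly to the
  latent, cases a scaled noisy multiple of deaths.

All randomness flows from one seed through named substreams (latent / words
/ survey / covariates / controls), so identical configs reproduce
bit-identical data and each piece can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicons import Lexicon
from .trends_io import WEEK, CovariateSeries, TrendsPanel, WeeklySeries, assemble_panel

__all__ = [
    "GeneratorConfig",
    "SurveyPanel",
    "SyntheticTruth",
    "SyntheticStudy",
    "substream",
    "simulate_latent",
    "simulate_word_panel",
    "simulate_survey_panel",
    "simulate_covariates",
    "simulate_study",
    "deaths_slope_for_target",
]

_SUBSTREAMS = {"latent": 0, "words": 1, "survey": 2, "covariates": 3,
               "controls": 4, "anxiety": 5}

#: default first week (a Monday) so 104 weeks span two calendar years
DEFAULT_START = dt.date(2018, 12, 31)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    try:
        key = _SUBSTREAMS[name]
    except KeyError:
        raise ValueError(f"unknown substream {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Defaults reproduce the joint impact-study conditions: 104 weekly
    observations spanning two years, a single geography, an additive
    intervention step of 3.2 index points starting at week 56 (1-based),
    and a 19-term dictionary loading uniformly on the latent.
    """

    n_weeks: int = 104
    n_regions: int = 1
    mu: float = 85.0                 # latent baseline, index points
    phi: float = 0.6                 # AR(1) coefficient, |phi| < 1
    sigma_lat: float = 1.0           # latent innovation sd
    t0: int = 56                     # intervention week, 1-based, post starts here
    delta: float = 3.2               # additive step on the latent, index points
    trend: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (c1, c2, c3) on centered week
    lam: float = 1.0                 # common term loading on the latent
    sigma_word: float = 2.0          # per-term observation noise sd
    gamma: float = 0.23              # survey %-above-cutoff per index point
    survey_intercept: float = 15.0   # baseline depression %, above-cutoff share
    sigma_survey: float = 1.0        # survey sampling noise sd (% points)
    tau_region: float = 1.0          # sd of region random intercepts (survey)
    anxiety_intercept: float = 20.0
    anxiety_quad: float = 0.05       # quadratic trend coefficient of the anxiety latent
    sigma_anxiety: float = 1.0
    deaths_intercept: float = 5.0    # weekly deaths per million at baseline
    deaths_slope: float = 0.8        # deaths per million per latent index point
    sigma_deaths: float = 1.5
    cases_per_death: float = 200.0
    sigma_cases_rel: float = 0.1     # relative noise of cases around the scaled deaths
    cases_mode: str = "scaled"       # "scaled" (multiple of deaths) | "independent"
    start_week: dt.date = DEFAULT_START
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 2 or self.n_regions < 1:
            raise ValueError("need n_weeks >= 2 and n_regions >= 1")
        if not 1 <= self.t0 <= self.n_weeks:
            raise ValueError(f"t0={self.t0} outside 1..{self.n_weeks}")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1 (stationary AR(1))")
        for name in ("sigma_lat", "sigma_word", "sigma_survey", "sigma_anxiety",
                     "sigma_deaths", "sigma_cases_rel", "tau_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lam <= 0:
            raise ValueError("term loading lam must be > 0")
        if self.cases_mode not in ("scaled", "independent"):
            raise ValueError(f"unknown cases_mode {self.cases_mode!r}")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @property
    def week_axis(self) -> tuple[dt.date, ...]:
        return tuple(self.start_week + i * WEEK for i in range(self.n_weeks))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_week"] = self.start_week.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "start_week" in d and isinstance(d["start_week"], str):
            d["start_week"] = dt.date.fromisoformat(d["start_week"])
        if "trend" in d:
            d["trend"] = tuple(d["trend"])
        return cls(**d)

    @classmethod
    def france_validation(cls, **kw) -> "GeneratorConfig":
        """Survey-validation conditions: 16 weekly waves x 12 regions,
        no intervention, depression linked to the index with slope 0.23."""
        base = dict(n_weeks=16, n_regions=12, t0=1, delta=0.0, gamma=0.23,
                    start_week=dt.date(2020, 3, 23))
        base.update(kw)
        return cls(**base)

    @classmethod
    def impact_study(cls, delta: float = 3.2, t0: int = 56, **kw) -> "GeneratorConfig":
        """Two-year, single-geo intervention conditions (104 weeks)."""
        return cls(delta=delta, t0=t0, **kw)


@dataclass(frozen=True)
class SurveyPanel:
    """Per-region weekly survey outcomes (% of respondents above cutoff)."""

    regions: tuple[str, ...]
    week_start: tuple[dt.date, ...]
    depression: np.ndarray   # regions x weeks
    anxiety: np.ndarray      # regions x weeks
    ati: np.ndarray          # regions x weeks, the index the survey links to

    def __post_init__(self) -> None:
        for name in ("depression", "anxiety", "ati"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.regions), len(self.week_start)):
                raise ValueError(f"{name} shape {arr.shape} mismatches panel")
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per region x wave, columns for mixed models."""
        rows = []
        for i, region in enumerate(self.regions):
            for t, week in enumerate(self.week_start):
                rows.append({
                    "region": region, "wave": t + 1, "week": week.isoformat(),
                    "ati": self.ati[i, t],
                    "depression": self.depression[i, t],
                    "anxiety": self.anxiety[i, t],
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record: everything needed to re-simulate and to score.

    ``true_ati_effect`` is the realised post-period effect on the observed
    index scale: the mean difference between the index of the generated panel
    and the index of a counterfactual panel built from the same noise draws
    with the intervention step removed. Max-normalisation rescales the latent
    step, so this realised value — not the nominal ``delta`` — is the
    estimand an impact analysis should recover.
    """

    config: GeneratorConfig
    latent: np.ndarray            # regions x weeks, with intervention
    latent_nostep: np.ndarray     # regions x weeks, step removed
    censored_cells: int
    clipped_cells: int
    true_ati_effect: float | None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "latent": self.latent.tolist(),
            "latent_nostep": self.latent_nostep.tolist(),
            "censored_cells": self.censored_cells,
            "clipped_cells": self.clipped_cells,
            "true_ati_effect": self.true_ati_effect,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass(frozen=True)
class SyntheticStudy:
    """One generated study: panels, survey, covariates and the truth record."""

    word_panel: TrendsPanel
    control_panel: TrendsPanel
    survey: SurveyPanel
    covariates: CovariateSeries
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# latent process


def _trend_values(config: GeneratorConfig) -> np.ndarray:
    t = np.arange(1, config.n_weeks + 1, dtype=float)
    tc = t - t.mean()
    c1, c2, c3 = config.trend
    return c1 * tc + c2 * tc**2 + c3 * tc**3


def _step(config: GeneratorConfig) -> np.ndarray:
    t = np.arange(1, config.n_weeks + 1)
    return np.where(t >= config.t0, config.delta, 0.0)


def simulate_latent(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Latent distress series per region (regions x weeks).

    latent_t = mu + trend(t) + delta * 1[t >= t0] + AR(1) noise, with the
    AR(1) started from its stationary distribution and independent draws per
    region. Deterministic under the config's seed.
    """
    rng = rng if rng is not None else substream(config.seed, "latent")
    n_r, n_w = config.n_regions, config.n_weeks
    noise = np.zeros((n_r, n_w))
    if config.sigma_lat > 0:
        eps = rng.standard_normal((n_r, n_w)) * config.sigma_lat
        stationary_sd = config.sigma_lat / np.sqrt(1.0 - config.phi**2)
        noise[:, 0] = rng.standard_normal(n_r) * stationary_sd
        for t in range(1, n_w):
            noise[:, t] = config.phi * noise[:, t - 1] + eps[:, t]
    deterministic = config.mu + _trend_values(config) + _step(config)
    return deterministic[None, :] + noise


# ---------------------------------------------------------------------------
# word panels


def _normalise_and_censor(
    raw: np.ndarray,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Max-normalise each row to [0, 100], then censor values < 1 to 0.

    ``scale`` overrides the per-row scale factor (used to re-express a
    counterfactual panel on a factual panel's observed scale). Returns
    (panel values, per-row censored counts, clipped-negative count, the
    per-row scale factors applied).
    """
    raw = np.array(raw, dtype=float)
    clipped = int((raw < 0).sum())
    raw[raw < 0] = 0.0
    if scale is None:
        maxes = raw.max(axis=1)
        if np.any(maxes <= 0):
            raise ValueError("a term series is non-positive everywhere; cannot scale")
        scale = 100.0 / maxes
    scaled = np.clip(raw * scale[:, None], 0.0, 100.0)
    censored = (scaled < 1.0).sum(axis=1)
    out = np.where(scaled < 1.0, 0.0, scaled)
    return out, censored, clipped, scale


def simulate_word_panel(
    latent: np.ndarray,
    lexicon: Lexicon,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    geo: str = "SYN",
    noise: np.ndarray | None = None,
) -> tuple[TrendsPanel, dict]:
    """Generate one geo's term panel from a latent series.

    raw_jt = lam * latent_t + noise_jt; each term is max-normalised to the
    0–100 relative-volume scale and sub-unit values are censored to 0.
    Returns the panel and a diagnostics dict with the censoring/clipping
    counts and, for reuse, the noise matrix actually drawn.
    """
    latent = np.asarray(latent, dtype=float).ravel()
    k = len(lexicon.terms)
    if noise is None:
        rng = rng if rng is not None else substream(config.seed, "words")
        noise = rng.standard_normal((k, len(latent))) * config.sigma_word
    raw = config.lam * latent[None, :] + noise
    values, censored_rows, clipped, scale = _normalise_and_censor(raw)
    weeks = tuple(config.start_week + i * WEEK for i in range(len(latent)))
    series = [
        WeeklySeries(term=term, geo=geo, week_start=weeks, values=values[j],
                     censored=int(censored_rows[j]))
        for j, term in enumerate(lexicon.terms)
    ]
    panel = assemble_panel(series, role=lexicon.role)
    diag = {"censored": int(censored_rows.sum()), "clipped": clipped,
            "noise": noise, "scale": scale}
    return panel, diag


# ---------------------------------------------------------------------------
# survey and covariates


def simulate_survey_panel(
    latent: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> SurveyPanel:
    """Survey %-above-cutoff series per region x week.

    Depression links monotonically to the latent index:
    depression = intercept + region effect + gamma * (latent - mu) + noise,
    bounded in [0, 100]. Anxiety follows its own quadratic-trend latent (plus
    noise), independent of the distress latent, so index-depression tracking
    and index-anxiety divergence are both exercisable.
    """
    rng = rng if rng is not None else substream(config.seed, "survey")
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    n_r, n_w = latent.shape
    region_fx = (rng.standard_normal(n_r) * config.tau_region
                 if config.tau_region > 0 else np.zeros(n_r))
    dep_noise = rng.standard_normal((n_r, n_w)) * config.sigma_survey
    depression = (config.survey_intercept + region_fx[:, None]
                  + config.gamma * (latent - config.mu) + dep_noise)

    t = np.arange(1, n_w + 1, dtype=float)
    tc = t - t.mean()
    anx_rng = substream(config.seed, "anxiety")
    anx_region_fx = (anx_rng.standard_normal(n_r) * config.tau_region
                     if config.tau_region > 0 else np.zeros(n_r))
    anx_noise = anx_rng.standard_normal((n_r, n_w)) * config.sigma_anxiety
    anxiety = (config.anxiety_intercept + anx_region_fx[:, None]
               + config.anxiety_quad * tc[None, :] ** 2 + anx_noise)

    regions = tuple(f"R{i + 1:02d}" for i in range(n_r))
    weeks = tuple(config.start_week + i * WEEK for i in range(n_w))
    return SurveyPanel(
        regions=regions,
        week_start=weeks,
        depression=np.clip(depression, 0.0, 100.0),
        anxiety=np.clip(anxiety, 0.0, 100.0),
        ati=latent,
    )


def deaths_slope_for_target(rho: float, config: GeneratorConfig) -> float:
    """Raw deaths-on-latent link giving a standardized index-on-deaths slope
    of ``rho`` in expectation (stationary, trend-free latent)."""
    if not 0 <= abs(rho) < 1:
        raise ValueError("target standardized slope must lie in (-1, 1)")
    sd_lat = config.sigma_lat / np.sqrt(1.0 - config.phi**2)
    if sd_lat == 0:
        raise ValueError("latent has zero variance; no link can hit the target")
    return rho * config.sigma_deaths / (sd_lat * np.sqrt(1.0 - rho**2))


def simulate_covariates(
    latent: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    geo: str = "SYN",
) -> CovariateSeries:
    """Weekly cases/deaths per million linked to a latent series.

    deaths = intercept + slope * (latent - mu) + noise (floored at 0);
    cases = cases_per_death * deaths * (1 + relative noise), floored at 0.
    """
    rng = rng if rng is not None else substream(config.seed, "covariates")
    latent = np.asarray(latent, dtype=float).ravel()
    n_w = len(latent)
    deaths = (config.deaths_intercept
              + config.deaths_slope * (latent - config.mu)
              + rng.standard_normal(n_w) * config.sigma_deaths)
    deaths = np.clip(deaths, 0.0, None)
    if config.cases_mode == "scaled":
        cases = config.cases_per_death * deaths * (
            1.0 + rng.standard_normal(n_w) * config.sigma_cases_rel)
    else:  # independent of both deaths and the latent (null-link testbed)
        cases = config.cases_per_death * config.deaths_intercept * (
            1.0 + rng.standard_normal(n_w) * max(config.sigma_cases_rel, 0.05))
    cases = np.clip(cases, 0.0, None)
    weeks = tuple(config.start_week + i * WEEK for i in range(n_w))
    return CovariateSeries(geo=geo, week_start=weeks,
                           new_cases_per_million=cases,
                           new_deaths_per_million=deaths)


# ---------------------------------------------------------------------------
# full study


def simulate_study(
    config: GeneratorConfig,
    lexicon: Lexicon,
    control_lexicon: Lexicon,
    geo: str = "SYN",
) -> SyntheticStudy:
    """Generate a complete single-geo study with a scored truth record.

    The target word panel loads on the intervention latent; the control-word
    panel loads on the same latent with the step removed (controls share the
    distress process' baseline and autocorrelation but are unaffected by the
    event). The truth records the realised index-scale effect, computed by
    rebuilding the target panel from identical noise draws without the step.

    With ``n_regions > 1`` the survey panel spans all regions while the word
    panel and covariates are driven by the first region's latent (one search
    extraction per geo).
    """
    latent = simulate_latent(config)
    latent_nostep = latent - _step(config)[None, :]

    panel, diag = simulate_word_panel(latent[0], lexicon, config, geo=geo)
    control_panel, _ = simulate_word_panel(
        latent_nostep[0], control_lexicon, config,
        rng=substream(config.seed, "controls"), geo=geo)

    # realised truth: the no-step panel re-expressed on the observed scale
    # (same noise draws, same per-term scale factors as the factual panel)
    raw_cf = config.lam * latent_nostep[0][None, :] + diag["noise"]
    cf_values, _, _, _ = _normalise_and_censor(raw_cf, scale=diag["scale"])
    ati = panel.values.mean(axis=0)
    ati_cf = cf_values.mean(axis=0)
    post = np.arange(1, config.n_weeks + 1) >= config.t0
    true_effect = float((ati[post] - ati_cf[post]).mean())

    survey = simulate_survey_panel(latent, config)
    covariates = simulate_covariates(latent[0], config, geo=geo)
    truth = SyntheticTruth(
        config=config,
        latent=latent,
        latent_nostep=latent_nostep,
        censored_cells=diag["censored"],
        clipped_cells=diag["clipped"],
        true_ati_effect=true_effect,
    )
    return SyntheticStudy(word_panel=panel, control_panel=control_panel,
                          survey=survey, covariates=covariates, truth=truth)
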