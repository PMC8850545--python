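"""Bayesian structural time-series counterfactual for event-impact estimation.

To quantify how an exogenous event (here, a pandemic's onset) shifted the
weekly index, the index is modelled over the pre-event period as a local
level plus a static regression on control series — search volumes for
randomly chosen neutral words that share the platform's sampling dynamics
but are theoretically unaffected by the event:

    observation:  y_t = mu_t + beta' x_t + eps_t,   eps_t ~ N(0, sigma_eps^2)
    state:        mu_t = mu_{t-1} + eta_t,          eta_t ~ N(0, sigma_eta^2)

Posterior sampling is by Gibbs: states by forward-filter backward-sampling
(simulation smoothing), both variances by conjugate inverse-gamma updates,
and regression weights by a conjugate normal (ridge) update. Each retained
draw is propagated over the post-event period using the observed controls,
giving a posterior predictive counterfactual; the pointwise gap
``y_t - yhat_t`` is the effect, and its post-period mean is the absolute
average effect in index points. Controls are standardized on pre-period
statistics only, so no post-period information leaks into the fit.

Priors are weakly informative and scale with the pre-period sample variance;
the regression prior sd per (standardized) control equals the pre-period sd
of the target. A deterministic weekly-seasonality block (trigonometric
regressors) can be toggled on; it is off by default.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ati_index import AtiSeries, compute_ati
from .trends_io import TrendsPanel

__all__ = [
    "ImpactConfig",
    "ImpactResult",
    "CalibrationReport",
    "ImpactError",
    "build_control_index",
    "fit_counterfactual",
    "null_calibration",
]

logger = logging.getLogger(__name__)


class ImpactError(ValueError):
    """Invalid input or pathological posterior in the impact analysis."""


@dataclass(frozen=True)
class ImpactConfig:
    """Counterfactual-analysis settings.

    ``t0`` is the 1-based week at which the post-period starts; the
    pre-period is weeks 1..t0-1. Prior scales are fractions of the
    pre-period sd of the target (see module docstring).
    """

    t0: int
    n_draws: int = 1000
    burn_in: int = 100
    seed: int = 0
    obs_prior_df: float = 2.0
    obs_prior_sd_frac: float = 0.8    # prior guess for eps sd, x pre-period sd
    level_prior_df: float = 2.0
    level_prior_sd_frac: float = 0.1  # prior guess for eta sd, x pre-period sd
    reg_prior_sd_scale: float = 1.0   # weight prior sd, x pre-period sd
    control_mode: str = "average"     # average | per_word | both
    seasonal_harmonics: int = 0       # trig terms at period 52; 0 = off

    def __post_init__(self) -> None:
        if self.t0 < 2:
            raise ImpactError("t0 must leave a non-empty pre-period")
        if not self.n_draws > self.burn_in >= 0:
            raise ImpactError("need draws > burn_in >= 0")
        if self.control_mode not in ("average", "per_word", "both"):
            raise ImpactError(f"unknown control_mode {self.control_mode!r}")
        if self.seasonal_harmonics < 0:
            raise ImpactError("seasonal_harmonics must be >= 0")


@dataclass(frozen=True)
class ImpactResult:
    """Counterfactual trajectory and averaged effect over the post-period."""

    week_start: tuple          # post-period weeks
    observed: np.ndarray       # post-period observed index
    counterfactual: np.ndarray # posterior predictive mean
    lower: np.ndarray          # pointwise 2.5% band
    upper: np.ndarray          # pointwise 97.5% band
    abs_effect: float          # mean observed - counterfactual, index points
    abs_ci: tuple[float, float]
    rel_effect: float          # % of the counterfactual level
    rel_ci: tuple[float, float]
    p: float                   # one-sided posterior tail probability
    effect_draws: np.ndarray   # per-draw average effects
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.abs_ci
        if not lo - 1e-9 <= self.abs_effect <= hi + 1e-9:
            raise ImpactError("credible interval does not bracket the estimate")
        if not 0.0 < self.p <= 1.0:
            raise ImpactError(f"invalid tail probability {self.p}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "abs_effect": self.abs_effect,
            "abs_ci": list(self.abs_ci),
            "rel_effect": self.rel_effect,
            "rel_ci": list(self.rel_ci),
            "p": self.p,
            "n_post_weeks": len(self.observed),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str))},
        }, indent=2), encoding="utf-8")

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["week", "observed", "counterfactual", "lower", "upper"])
        for i, week in enumerate(self.week_start):
            writer.writerow([week.isoformat(), repr(float(self.observed[i])),
                             repr(float(self.counterfactual[i])),
                             repr(float(self.lower[i])), repr(float(self.upper[i]))])
        Path(path).write_text(buf.getvalue(), encoding="utf-8")


def build_control_index(panel: TrendsPanel, mode: str = "average") -> pd.DataFrame:
    """Candidate control regressors from a random-word panel.

    ``average`` returns the single cross-word mean series; ``per_word`` one
    column per word; ``both`` the average plus the per-word columns.
    """
    if panel.n_terms < 1:
        raise ImpactError("empty control panel")
    if mode not in ("average", "per_word", "both"):
        raise ImpactError(f"unknown control mode {mode!r}")
    frame = panel.frame.copy()
    avg = frame.mean(axis=1)
    if mode == "average":
        return pd.DataFrame({"control_avg": avg})
    if mode == "per_word":
        return frame
    out = frame.copy()
    out.insert(0, "control_avg", avg)
    return out


def _seasonal_block(n: int, harmonics: int, period: float = 52.0) -> np.ndarray:
    t = np.arange(n, dtype=float)
    cols = []
    for h in range(1, harmonics + 1):
        w = 2.0 * np.pi * h * t / period
        cols += [np.sin(w), np.cos(w)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _ffbs(z: np.ndarray, sig_eps2: float, sig_eta2: float,
          m0: float, p0: float, snorm: np.ndarray) -> np.ndarray:
    """Forward-filter backward-sample the local level given data ``z``.

    ``snorm`` supplies the standard-normal draws (one per state), keeping the
    sampler's randomness seed-stable and scale-equivariant.
    """
    n = len(z)
    m = np.empty(n)
    p = np.empty(n)
    m_pred, p_pred = m0, p0
    for t in range(n):
        if t > 0:
            m_pred, p_pred = m[t - 1], p[t - 1] + sig_eta2
        k = p_pred / (p_pred + sig_eps2)
        m[t] = m_pred + k * (z[t] - m_pred)
        p[t] = (1.0 - k) * p_pred
    mu = np.empty(n)
    mu[n - 1] = m[n - 1] + np.sqrt(max(p[n - 1], 0.0)) * snorm[n - 1]
    for t in range(n - 2, -1, -1):
        c = p[t] / (p[t] + sig_eta2)
        mean = m[t] + c * (mu[t + 1] - m[t])
        var = p[t] * (1.0 - c)
        mu[t] = mean + np.sqrt(max(var, 0.0)) * snorm[t]
    return mu


def _one_step_residuals(z: np.ndarray, sig_eps2: float, sig_eta2: float,
                        m0: float, p0: float) -> tuple[np.ndarray, np.ndarray]:
    """Standardized one-step-ahead prediction errors from the Kalman filter."""
    n = len(z)
    innov = np.empty(n)
    innov_sd = np.empty(n)
    m_prev, p_prev = m0, p0
    for t in range(n):
        if t > 0:
            p_prev = p_prev + sig_eta2
        f = p_prev + sig_eps2
        innov[t] = z[t] - m_prev
        innov_sd[t] = np.sqrt(f)
        k = p_prev / f
        m_prev = m_prev + k * innov[t]
        p_prev = (1.0 - k) * p_prev
    return innov, innov_sd


def fit_counterfactual(
    target: AtiSeries,
    controls: TrendsPanel,
    config: ImpactConfig,
) -> ImpactResult:
    """Estimate the event's effect on the index via a BSTS counterfactual.

    Fits the local-level + static-regression model on the pre-period
    (weeks 1..t0-1, at least 20 weeks), then simulates the posterior
    predictive over the post-period using the observed control series.
    Deterministic under ``config.seed``.
    """
    if tuple(target.week_start) != tuple(controls.week_start):
        raise ImpactError("target and control week axes differ")
    y = np.asarray(target.values, dtype=float)
    n_total = len(y)
    if not 2 <= config.t0 <= n_total:
        raise ImpactError(f"t0={config.t0} outside the series (n={n_total})")
    n_pre = config.t0 - 1
    n_post = n_total - n_pre
    if n_pre < 20:
        raise ImpactError(f"pre-period has {n_pre} weeks; need >= 20")
    if n_post < 1:
        raise ImpactError("empty post-period")

    X_frame = build_control_index(controls, config.control_mode)
    X = X_frame.to_numpy(dtype=float)
    if config.seasonal_harmonics:
        X = np.hstack([X, _seasonal_block(n_total, config.seasonal_harmonics)])
    # standardize every regressor on pre-period statistics only
    mean_pre = X[:n_pre].mean(axis=0)
    sd_pre_x = X[:n_pre].std(axis=0, ddof=1)
    keep = sd_pre_x > 0
    X = (X[:, keep] - mean_pre[keep]) / sd_pre_x[keep]
    n_reg = X.shape[1]

    y_pre = y[:n_pre]
    var_pre = float(y_pre.var(ddof=1))
    if var_pre == 0.0:
        raise ImpactError("constant pre-period target")
    sd_pre = np.sqrt(var_pre)

    a_eps = config.obs_prior_df / 2.0
    b_eps = a_eps * (config.obs_prior_sd_frac * sd_pre) ** 2
    a_eta = config.level_prior_df / 2.0
    b_eta = a_eta * (config.level_prior_sd_frac * sd_pre) ** 2
    tau2 = (config.reg_prior_sd_scale * sd_pre) ** 2
    m0, p0 = float(y_pre.mean()), 1e4 * var_pre

    rng = np.random.default_rng(config.seed)
    beta = np.zeros(n_reg)
    sig_eps2 = 0.5 * var_pre
    sig_eta2 = (config.level_prior_sd_frac * sd_pre) ** 2

    n_keep = config.n_draws - config.burn_in
    effect_draws = np.empty(n_keep)
    yhat_draws = np.empty((n_keep, n_post))
    eps2_draws = np.empty(n_keep)
    eta2_draws = np.empty(n_keep)
    beta_sum = np.zeros(n_reg)
    XtX = X[:n_pre].T @ X[:n_pre]

    for it in range(config.n_draws):
        z = y_pre - X[:n_pre] @ beta
        mu = _ffbs(z, sig_eps2, sig_eta2, m0, p0,
                   rng.standard_normal(n_pre))
        resid = z - mu
        sig_eps2 = ((b_eps + 0.5 * float(resid @ resid))
                    / rng.gamma(a_eps + 0.5 * n_pre))
        dmu = np.diff(mu)
        sig_eta2 = ((b_eta + 0.5 * float(dmu @ dmu))
                    / rng.gamma(a_eta + 0.5 * (n_pre - 1)))
        if n_reg:
            u = y_pre - mu
            prec = XtX / sig_eps2 + np.eye(n_reg) / tau2
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, X[:n_pre].T @ u / sig_eps2)
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(n_reg))

        if it >= config.burn_in:
            j = it - config.burn_in
            steps = rng.standard_normal(n_post) * np.sqrt(sig_eta2)
            mu_post = mu[-1] + np.cumsum(steps)
            yhat = (mu_post + (X[n_pre:] @ beta if n_reg else 0.0)
                    + rng.standard_normal(n_post) * np.sqrt(sig_eps2))
            yhat_draws[j] = yhat
            effect_draws[j] = float((y[n_pre:] - yhat).mean())
            eps2_draws[j] = sig_eps2
            eta2_draws[j] = sig_eta2
            beta_sum += beta

    floor = np.finfo(float).tiny * 1e6
    if (np.mean(eps2_draws < floor) > 0.99) or (np.mean(eta2_draws < floor) > 0.99):
        raise ImpactError(
            "variance posterior collapsed at the boundary "
            f"(median eps2={np.median(eps2_draws):.3e}, "
            f"eta2={np.median(eta2_draws):.3e}); the model is degenerate "
            "for these data"
        )

    abs_effect = float(effect_draws.mean())
    lo, hi = np.quantile(effect_draws, [0.025, 0.975])
    cf_level_draws = yhat_draws.mean(axis=1)
    rel_draws = 100.0 * effect_draws / cf_level_draws
    rel_effect = float(rel_draws.mean())
    rlo, rhi = np.quantile(rel_draws, [0.025, 0.975])

    sign = 1.0 if abs_effect >= 0 else -1.0
    tail = float(np.mean(sign * effect_draws <= 0.0))
    p = max(tail, 1.0 / (n_keep + 1))

    # pre-period sanity at posterior-mean parameters
    z_bar = y_pre - (X[:n_pre] @ (beta_sum / n_keep) if n_reg else 0.0)
    innov, innov_sd = _one_step_residuals(
        z_bar, float(eps2_draws.mean()), float(eta2_draws.mean()), m0, p0)
    # skip the diffuse first step when summarising
    diag = {
        "pre_resid_mean": float(innov[1:].mean()),
        "pre_resid_mean_sd": float(innov_sd[1:].mean() / np.sqrt(n_pre - 1)),
        "sigma_eps": float(np.sqrt(eps2_draws.mean())),
        "sigma_eta": float(np.sqrt(eta2_draws.mean())),
        "n_pre": n_pre,
        "n_post": n_post,
        "n_regressors": n_reg,
        "n_retained_draws": n_keep,
    }

    return ImpactResult(
        week_start=tuple(target.week_start[n_pre:]),
        observed=y[n_pre:],
        counterfactual=yhat_draws.mean(axis=0),
        lower=np.quantile(yhat_draws, 0.025, axis=0),
        upper=np.quantile(yhat_draws, 0.975, axis=0),
        abs_effect=abs_effect,
        abs_ci=(float(lo), float(hi)),
        rel_effect=rel_effect,
        rel_ci=(float(rlo), float(rhi)),
        p=float(p),
        effect_draws=effect_draws,
        diagnostics=diag,
    )


@dataclass(frozen=True)
class CalibrationReport:
    """Null-replicate coverage of the impact estimator's credible interval."""

    n_replicates: int
    n_excluding_zero: int
    exclusion_rate: float
    binomial_ci: tuple[float, float]
    abs_effects: tuple[float, ...]


def null_calibration(
    config: ImpactConfig,
    n_replicates: int,
    generator_config,
) -> CalibrationReport:
    """How often the 95% credible interval excludes 0 when there is no effect.

    Runs the whole chain — generate a no-intervention study, average the word
    panel into the index, fit the counterfactual — over seeded replicates and
    reports the CI-exclusion rate with a Clopper-Pearson binomial interval.
    A well-calibrated estimator excludes 0 in about 5% of null replicates.
    """
    from .lexicons import generate_control_lexicon, load_lexicon
    from .synthetic_data import simulate_study

    if n_replicates < 10:
        raise ImpactError("need at least 10 replicates for a calibration run")
    lexicon = load_lexicon("en", "absolutist")
    n_excl = 0
    effects = []
    for i in range(n_replicates):
        rep_seed = (generator_config.seed + 1000003 * (i + 1)) % (2**31)
        gcfg = generator_config.replace(seed=rep_seed)
        controls_lex = generate_control_lexicon(19, seed=rep_seed)
        study = simulate_study(gcfg, lexicon, controls_lex)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ati = compute_ati(study.word_panel)
        result = fit_counterfactual(
            ati, study.control_panel,
            dataclasses.replace(config, seed=rep_seed),
        )
        effects.append(result.abs_effect)
        lo, hi = result.abs_ci
        if lo > 0.0 or hi < 0.0:
            n_excl += 1
    rate = n_excl / n_replicates
    blo, bhi = stats.binomtest(n_excl, n_replicates).proportion_ci(0.95)
    return CalibrationReport(
        n_replicates=n_replicates,
        n_excluding_zero=n_excl,
        exclusion_rate=rate,
        binomial_ci=(float(blo), float(bhi)),
        abs_effects=tuple(effects),
    )
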