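"""Linear mixed-effects models for index-survey panels and covariate links.

Three model families recur in the validation of a search-based mental-health
index against survey panels:

1. association models — survey outcome ~ 1 + index + wave with random
   intercepts and slopes by region, testing whether a 1-point index increase
   tracks a rise in the % of respondents above a clinical cutoff;
2. polynomial trend models — outcome ~ 1 + wave + wave^2 (+ wave^3) with a
   random intercept by region, testing whether the index shares the cubic
   dynamic of depression rates but not the quadratic dynamic of anxiety;
3. covariate models — index ~ 1 + cases + deaths + weeks with a random
   intercept by country (or by year), linking the index to epidemic burden.

Estimation is restricted maximum likelihood via statsmodels' ``MixedLM``;
with no random terms the fit reduces exactly to ordinary least squares.
Inference is Wald (normal approximation): estimates, 95% CIs and two-sided
p-values; both the raw and the fully standardized (z-scored outcome and
covariates) scales are always reported. Wave/week enters polynomials
centered, as raw powers, so coefficients stay interpretable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .ati_index import AtiSeries
from .trends_io import CovariateSeries

__all__ = [
    "ModelSpec",
    "TermEstimate",
    "MixedModelResult",
    "PanelModelError",
    "fit_mixed",
    "fit_polynomial_trend",
    "fit_covariate_model",
]

logger = logging.getLogger(__name__)


class PanelModelError(ValueError):
    """Invalid data or specification for a panel model."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists covariate column names (the intercept is implicit);
    ``poly_degree`` > 0 adds centered powers of the ``wave`` column up to the
    given degree (1-3). ``random`` lists random terms: ``"1"`` for a random
    intercept plus any fixed-term names as random slopes. ``group`` names the
    clustering column (region, country, year ...).
    """

    outcome: str
    fixed: tuple[str, ...] = ()
    poly_degree: int = 0
    random: tuple[str, ...] = ()
    group: str | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if self.poly_degree not in (0, 1, 2, 3):
            raise PanelModelError("poly_degree must be in {0, 1, 2, 3}")
        slopes = [r for r in self.random if r != "1"]
        poly_terms = self.poly_terms
        for s in slopes:
            if s not in self.fixed and s not in poly_terms:
                raise PanelModelError(
                    f"random slope {s!r} is not a fixed term"
                )
        if self.random and self.group is None:
            raise PanelModelError("random terms need a grouping factor")

    @property
    def poly_terms(self) -> tuple[str, ...]:
        names = ("wave_c", "wave_c2", "wave_c3")
        return names[: self.poly_degree]

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return self.fixed + self.poly_terms

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) or "1"
        s = f"{self.outcome} ~ {rhs}"
        if self.random:
            re = " + ".join("1" if r == "1" else r for r in self.random)
            if "1" not in self.random:
                re = f"0 + {re}"
            s += f" + ({re} | {self.group})"
        return s


@dataclass(frozen=True)
class TermEstimate:
    """One fixed term's estimate on the raw and standardized scales."""

    estimate: float
    ci_lower: float
    ci_upper: float
    p: float
    std_estimate: float | None = None
    std_ci_lower: float | None = None
    std_ci_upper: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_lower - 1e-9 <= self.estimate <= self.ci_upper + 1e-9:
            raise PanelModelError("CI does not bracket the estimate")

    def covers(self, value: float) -> bool:
        return self.ci_lower <= value <= self.ci_upper

    def std_covers(self, value: float) -> bool:
        return self.std_ci_lower <= value <= self.std_ci_upper


@dataclass(frozen=True)
class MixedModelResult:
    terms: dict[str, TermEstimate]
    n_obs: int
    n_groups: int
    converged: bool
    formula: str
    random_structure: tuple[str, ...]
    variance_components: dict[str, float] = field(default_factory=dict)
    fallback_notes: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> TermEstimate:
        return self.terms[name]


# ---------------------------------------------------------------------------
# internals


def _prepare_data(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    data = data.copy()
    needed = [spec.outcome, *spec.fixed]
    if spec.poly_degree > 0:
        if "wave" not in data.columns:
            raise PanelModelError("poly_degree set but no 'wave' column")
        wc = data["wave"].astype(float) - data["wave"].astype(float).mean()
        data["wave_c"] = wc
        if spec.poly_degree >= 2:
            data["wave_c2"] = wc**2
        if spec.poly_degree >= 3:
            data["wave_c3"] = wc**3
        needed += list(spec.poly_terms)
    if spec.group is not None:
        needed.append(spec.group)
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise PanelModelError(f"data lacks columns {missing}")
    used = data[needed]
    numeric = [c for c in needed if c != spec.group]
    if used[numeric].isna().any().any():
        raise PanelModelError("missing cells in used columns")
    return data


def _check_rank(data: pd.DataFrame, terms: tuple[str, ...]) -> None:
    X = np.column_stack([np.ones(len(data))]
                        + [data[t].to_numpy(float) for t in terms])
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    zero_var = [t for t in terms if np.ptp(data[t].to_numpy(float)) == 0]
    if zero_var:
        raise PanelModelError(
            f"rank-deficient fixed design: zero-variance terms {zero_var}"
        )
    # name a minimal set of columns whose removal restores full rank
    collinear = []
    for j, t in enumerate(terms, start=1):
        Xj = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(Xj) == np.linalg.matrix_rank(X):
            collinear.append(t)
    raise PanelModelError(f"rank-deficient fixed design: collinear terms {collinear}")


def _ols_terms(data: pd.DataFrame, spec: ModelSpec) -> tuple[dict, bool]:
    rhs = " + ".join(spec.fixed_terms) or "1"
    res = smf.ols(f"{spec.outcome} ~ {rhs}", data=data).fit()
    terms = {}
    for name in ("Intercept", *spec.fixed_terms):
        est = float(res.params[name])
        se = float(res.bse[name])
        lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
        terms[name] = (est, lo, hi, p)
    return terms, True


def _mixedlm_terms(data: pd.DataFrame, spec: ModelSpec,
                   random: tuple[str, ...]) -> tuple[dict, bool, dict]:
    rhs = " + ".join(spec.fixed_terms) or "1"
    slopes = [r for r in random if r != "1"]
    re_formula = "~" + (" + ".join(slopes) if slopes else "1")
    if "1" not in random and slopes:
        re_formula = "~0 + " + " + ".join(slopes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{spec.outcome} ~ {rhs}", data=data,
                            groups=data[spec.group], re_formula=re_formula)
        res = model.fit(reml=True)
    k_fe = model.k_fe
    fe = res.params[:k_fe]
    se = res.bse[:k_fe]
    converged = bool(res.converged) and bool(np.all(np.isfinite(se)))
    terms = {}
    for name in ("Intercept", *spec.fixed_terms):
        est = float(fe[name])
        s = float(se[name])
        lo, hi = est - 1.959963984540054 * s, est + 1.959963984540054 * s
        p = float(2 * stats.norm.sf(abs(est / s))) if s > 0 else 0.0
        terms[name] = (est, lo, hi, p)
    vc = {"group_var": float(res.cov_re.iloc[0, 0]) if res.k_re else 0.0,
          "resid_var": float(res.scale)}
    return terms, converged, vc


def _standardized(data: pd.DataFrame, spec: ModelSpec,
                  random: tuple[str, ...]) -> dict:
    """Refit on z-scored outcome and covariates; return per-term tuples."""
    zdata = data.copy()
    for col in (spec.outcome, *spec.fixed_terms):
        v = zdata[col].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise PanelModelError(f"cannot standardize zero-variance column {col!r}")
        zdata[col] = (v - v.mean()) / sd
    if random:
        terms, _, _ = _mixedlm_terms(zdata, spec, random)
    else:
        terms, _ = _ols_terms(zdata, spec)
    return terms


# ---------------------------------------------------------------------------
# public operations


def fit_mixed(data: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML fit of the linear mixed model described by ``spec``.

    Wald 95% CIs and two-sided normal-approximation p-values per fixed term,
    on both the raw scale and (when ``spec.standardize``) the fully z-scored
    scale. If the full random structure fails to converge, random slopes are
    dropped one at a time down to a random intercept, each step logged; a
    single-group dataset with random terms is an error, never a silent fit.
    """
    data = _prepare_data(data, spec)
    _check_rank(data, spec.fixed_terms)
    fallback: list[str] = []

    if not spec.random:
        raw_terms, converged = _ols_terms(data, spec)
        vc: dict[str, float] = {}
        random_used: tuple[str, ...] = ()
        n_groups = int(data[spec.group].nunique()) if spec.group else 1
    else:
        n_groups = int(data[spec.group].nunique())
        if n_groups < 2:
            raise PanelModelError(
                "random terms require at least 2 groups "
                f"(got {n_groups} level of {spec.group!r})"
            )
        # convergence ladder: full structure, then drop slopes, then intercept
        ladders = [spec.random]
        slopes = [r for r in spec.random if r != "1"]
        for i in range(len(slopes) - 1, -1, -1):
            ladders.append(("1", *slopes[:i]) if i else ("1",))
        raw_terms = None
        for attempt in ladders:
            try:
                raw_terms, converged, vc = _mixedlm_terms(data, spec, attempt)
            except (np.linalg.LinAlgError, ValueError) as exc:
                converged = False
                vc = {}
                note = f"random structure {attempt} failed: {exc}"
                logger.warning(note)
                fallback.append(note)
                raw_terms = None
                continue
            if converged:
                random_used = attempt
                if attempt != spec.random:
                    note = (f"random structure reduced from {spec.random} "
                            f"to {attempt} after convergence failure")
                    logger.warning(note)
                    fallback.append(note)
                break
            fallback.append(f"random structure {attempt} did not converge")
        else:
            if raw_terms is None:
                raise PanelModelError(
                    "mixed model failed to fit at every fallback level: "
                    + "; ".join(fallback)
                )
            random_used = ladders[-1]  # last attempt, flagged unconverged

    std_terms = None
    if spec.standardize:
        std_terms = _standardized(data, spec,
                                  random_used if spec.random else ())

    terms = {}
    for name, (est, lo, hi, p) in raw_terms.items():
        if std_terms is not None:
            sest, slo, shi, _ = std_terms[name]
            terms[name] = TermEstimate(est, lo, hi, p, sest, slo, shi)
        else:
            terms[name] = TermEstimate(est, lo, hi, p)

    return MixedModelResult(
        terms=terms,
        n_obs=len(data),
        n_groups=n_groups,
        converged=converged,
        formula=spec.formula,
        random_structure=tuple(random_used) if spec.random else (),
        variance_components=vc if spec.random else {},
        fallback_notes=tuple(fallback),
    )


def fit_polynomial_trend(
    data: pd.DataFrame,
    outcome: str,
    degree: int,
    group: str = "region",
) -> MixedModelResult:
    """Polynomial wave-trend model with a random intercept by group.

    Fits ``outcome ~ 1 + wave + wave^2 (+ wave^3) + (1 | group)`` on centered
    wave. The highest-order coefficient (``wave_c2`` or ``wave_c3``) is the
    term of interest: a cubic dynamic shows a significant ``wave_c3``, a
    quadratic-only dynamic shows a ``wave_c3`` CI covering zero.
    """
    if degree not in (2, 3):
        raise PanelModelError("trend degree must be 2 or 3")
    spec = ModelSpec(outcome=outcome, poly_degree=degree,
                     random=("1",), group=group)
    return fit_mixed(data, spec)


def fit_covariate_model(
    ati_by_group: dict[str, AtiSeries],
    covariates_by_group: dict[str, CovariateSeries],
    group_name: str = "country",
) -> MixedModelResult:
    """Index ~ 1 + cases + deaths + weeks with a random intercept by group.

    ``ati_by_group`` and ``covariates_by_group`` must share keys and, within
    each group, identical weekly axes. ``weeks`` is the within-group week
    number. Standardized coefficients are reported alongside the raw scale.
    """
    if set(ati_by_group) != set(covariates_by_group):
        raise PanelModelError("ati and covariate groups differ")
    rows = []
    for group, ati in ati_by_group.items():
        cov = covariates_by_group[group]
        if tuple(ati.week_start) != tuple(cov.week_start):
            raise PanelModelError(
                f"group {group!r}: index and covariate week axes differ"
            )
        for t in range(len(ati)):
            rows.append({
                group_name: group,
                "weeks": t + 1,
                "ati": ati.values[t],
                "cases": cov.new_cases_per_million[t],
                "deaths": cov.new_deaths_per_million[t],
            })
    frame = pd.DataFrame(rows)
    n_groups = frame[group_name].nunique()
    random = ("1",) if n_groups >= 2 else ()
    spec = ModelSpec(outcome="ati", fixed=("cases", "deaths", "weeks"),
                     random=random, group=group_name if random else None)
    return fit_mixed(frame, spec)
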