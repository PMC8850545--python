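# atikit

Population mental-health surveillance from online search behaviour.

Survey-based monitoring of population depression is expensive, slow, and
usually yields only a handful of time points. `atikit` implements a
complementary behavioural measure: the **Absolute Thinking Index (ATI)**, the
weekly average of relative search volumes for a fixed dictionary of
*absolutist* words ("absolutely", "all", "never", ...). Elevated absolutist
language is an established linguistic marker of depression, so the rate at
which such words slip into search queries — regardless of what is being
searched — tracks population-level distress. The package is aimed at
researchers in infodemiology and psychiatric epidemiology who want to build,
validate, and stress-test such an index end to end.

## What it computes

Given weekly relative-search-volume series `x_jt` (0–100 scale, one per
dictionary term *j*), the index is the unweighted mean

    ATI_t = (1/k) Σ_j x_jt,

gated by Cronbach's α = (k/(k−1))(1 − Σ_j var_j / var_total) as a
reliability check. Validation against survey panels (% of respondents above
a clinical depression/anxiety cutoff, per region × week) uses Pearson
correlations with Fisher-z intervals, regression-on-time detrending with
residual re-correlation, and linear mixed models such as

    depression = 1 + ATI + wave + (1 + ATI + wave | region).

The impact of an exogenous event (e.g. a pandemic's onset at week t₀) is
estimated with a Bayesian structural time-series counterfactual fit on the
pre-event period,

    y_t = μ_t + β′x_t + ε_t,      μ_t = μ_{t−1} + η_t,

where the regressors x_t are search series for randomly generated neutral
control words. Gibbs sampling (simulation smoothing for the states,
conjugate updates for variances and weights) yields a posterior predictive
counterfactual over the post-period; the mean gap between the observed index
and that counterfactual is the *absolute average effect* in index points.

A first-class synthetic-data generator produces word panels, survey panels,
and epidemic covariates from a latent AR(1) distress process with a known
injected step, so every estimator in the package can be checked against
ground truth.

## Worked example

```bash
ati --seed 5 --out-dir sim simulate --n-weeks 104 --t0 56   # two years, event at week 56
ati --out-dir idx ati sim/word_panel.csv                    # average into the index
ati --seed 5 --out-dir imp impact idx/ati.csv sim/control_panel.csv --t0 56 --draws 500
```

which prints

```
absolute average effect: +3.42 index points 95%CI[+2.04, +4.75], relative +3.7%, p = 0.002
```

The generator injected a step of 3.2 index points on the latent process at
week 56; per-term max-normalisation rescales it to a realised index-scale
effect of ≈3.4 points (recorded in `sim/truth.json`), which the
counterfactual recovers: the posterior mean is +3.42, the 95% credible
interval comfortably covers the truth, and the posterior probability that
the effect is on the other side of zero is 0.002. The same library calls are
available in Python:

```python
import atikit as ak

lexicon = ak.load_lexicon("en", "absolutist")          # 19 terms
controls = ak.generate_control_lexicon(19, seed=5)
study = ak.simulate_study(ak.GeneratorConfig(seed=5), lexicon, controls)
ati = ak.compute_ati(study.word_panel)                 # AtiSeries with alpha
result = ak.fit_counterfactual(ati, study.control_panel,
                               ak.ImpactConfig(t0=56, seed=5))
print(result.abs_effect, result.abs_ci)
```

`ati validate sim/survey.csv` runs the survey-side validation (raw and
detrended correlations plus the mixed models), and `ati calibrate` reports
how often the counterfactual's 95% interval excludes zero on no-event
replicates.

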