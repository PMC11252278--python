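# audiencesync

Physiological synchrony in concert audiences: do listeners' bodies — heart
rate (HR), heart-rate variability (HRV, RMSSD), respiration rate (RR),
breathing movements (RESP) and phasic skin conductance (SCR) — co-vary
during a shared musical performance, and does each listener's degree of
synchrony relate to their affect, personality and aesthetic experience?

`audiencesync` is a tested pipeline for this question, aimed at researchers
working with multi-person physiological recordings (concerts, cinemas,
classrooms, group therapy). It implements:

1. **Surrogate synchrony (SUSY) for a dyad.** Two feature series are cut
   into 30-s segments; within each aligned segment pair, Pearson
   cross-correlations are computed at every lag in ±5 s (a 10-s
   cross-correlation range *L*), Fisher-Z transformed
   (*Z* = arctanh *r*), averaged over lags and then over segments. The
   sign is kept: *Z* > 0 is in-phase, *Z* < 0 anti-phase synchrony. A null
   distribution comes from re-pairing the segments of one series with
   random derangements of the other's; the effect size is

   *ES* = (*Z* − mean *Z*<sub>surr</sub>) / SD *Z*<sub>surr</sub>.

2. **Audience aggregation.** An audience of *N* listeners defines
   *N*(*N*−1)/2 dyads; audience synchrony is their mean *Z*, and each
   listener's **synchrony contribution** is the mean of the *N*−1 dyadic
   synchronies they take part in. Presence of synchrony per channel is a
   paired t-test of observed vs surrogate contributions across listeners.

3. **Hierarchical regressions.** Contributions (as effect sizes) are
   regressed on survey covariates — affect change (pre − post)/SD<sub>pre</sub>,
   Big-Five traits, experience factors, per-piece items — in linear mixed
   models with a random intercept per concert (REML, `statsmodels`),
   predictors centered within concert except personality.

4. **A synthetic-concert generator** with known ground truth: a smooth
   shared stimulus driver per concert, per-listener coupling strengths and
   response lags, autocorrelated noise, an *uncoupled* breathing-waveform
   channel, and surveys whose covariates carry planted effects on coupling —
   so the whole pipeline runs and is validated without any external data.

## Worked example

```python
import numpy as np
from audiencesync import (SimulationConfig, SusyParams, generate_driver,
                          generate_audience, all_dyads, contributions,
                          presence_test)

cfg = SimulationConfig(n_concerts=1, n_participants_per_concert=15,
                       duration_s=600, seed=3)
driver = generate_driver(cfg, "concert01")
series, truth = generate_audience(cfg, driver, "concert01")

params = SusyParams(n_surrogates=50, rng_seed=3)
for channel in ("HR", "RESP"):
    dyads = all_dyads(series, channel, params)
    res = presence_test(contributions(dyads, "concert01"))
    print(f"{channel}: mean Z = {res.mean_Z:.4f}, mean Zsurr = "
          f"{res.mean_Zsurr:.4f}, t = {res.t_statistic:.2f}, "
          f"p = {res.p_value:.2g}, mean ES = {res.mean_ES:.2f}")
```

Output:

```
HR: mean Z = 0.0849, mean Zsurr = 0.0045, t = 5.92, p = 3.7e-05, mean ES = 6.17
RESP: mean Z = 0.0000, mean Zsurr = -0.0003, t = 0.48, p = 0.64, mean ES = 0.15
```

The heart-rate channel, coupled to the shared driver, synchronizes far above
its surrogate level (15 listeners, 105 dyads, t-test across the 15
contributions), while the independent breathing-waveform channel stays at
chance — the qualitative signature the method is designed to expose.

## Command-line pipeline

```sh
audiencesync simulate  --config cfg.yaml --seed 1 --out data/   # + --raw
audiencesync features  --config cfg.yaml                        # raw -> features
audiencesync synchrony --config cfg.yaml                        # dyads.csv, contributions.csv, presence_tests.csv
audiencesync analyze   --config cfg.yaml                        # models.csv, report.md
```

All tables are long-format CSV (UTF-8, `NA` for missing); the scope column
takes `concert` or a piece label. See `docs/methods.md` for the model
details and every tunable parameter.

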