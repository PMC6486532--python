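# irtmarkov

Longitudinal item-response-theory modelling with minimal continuous-time
Markov dependence, for daily ordinal questionnaire (diary) data — built
around the 14-item COPD symptom e-diary setting (9 items scored 0–4, 5
scored 0–3, one fully-completed-or-absent questionnaire per day), but
usable for any daily multi-item ordinal instrument.

Daily diaries produce long, strongly autocorrelated ordinal series:
today's "how breathless" answer depends on yesterday's, not just on how
sick the patient is.  Classical IRT treats repeated observations as
independent given the latent trait and badly mispredicts day-to-day
transitions and symptom-defined exacerbation events.  `irtmarkov` couples
the two standard pieces:

* a **graded response model** per item *j*:
  `P(Y_j >= k | D) = expit(a_j (D − b_{j,k}))`, with latent disease
  severity `D_i(t) = D_{i,0} + slope_i · t/365`, `D_{i,0} ~ N(0,1)`;
* a **minimal continuous-time Markov chain** over each item's score
  categories, whose stationary law is the item's steady-state IRT
  distribution and whose single dependence parameter is the mean
  equilibrium time (MET): `λ_up(k) + λ_down(k) = 1/MET` for every adjacent
  category pair, with detailed balance fixing the ratio.  Between
  observations, probabilities evolve as `P(Δt) = expm(Q Δt)`; after each
  observation the state collapses onto the observed score.  The first
  observation of a chain follows the steady state.  Larger MET = stickier
  scores; MET → 0 recovers the independence model.

The package simulates such studies (including realistic whole-day
missingness and dropout), estimates all parameters jointly by Laplace
marginal likelihood (adaptive Gauss–Hermite as an accuracy oracle),
produces the standard model diagnostics (item-score / transition /
total-score visual predictive checks, residual item-correlation maps,
per-item Fisher information), and detects symptom-defined exacerbations
(total-score rises of ≥12 over 2 or ≥9 over 3 consecutive days above a
rolling 4-weekly baseline).  See `docs/methods.md` for the full model and
numerical details.

## Worked example

```python
import irtmarkov as im

# 1. simulate a study-like diary: 40 subjects, 120 days, 14 items,
#    whole-day gaps and dropout as in a year-long observational study
ds = im.generate_fixture(40, 120, seed=7)
print("records:", len(ds.records), "subjects:", ds.n_subjects)

# 2. symptom-defined exacerbations and the cumulative first-event curve
events = im.detect_all(ds)
curve = im.cumulative_event_curve(events, ds.n_subjects, 120)
print(f"first-event incidence by day 120: {curve['proportion'].iloc[-1]:.2f}")

# 3. which items carry the most information about a typical subject
info = im.information_by_percentile(im.default_population(), (5, 50, 95))
print(info[info.percentile == 50].nlargest(3, "information").round(2))
```

prints

```
records: 56854 subjects: 40
first-event incidence by day 120: 0.60
 item_id  percentile   D  information
       9          50 0.0         1.71
       5          50 0.0         1.51
       6          50 0.0         1.45
```

56,854 long-format records (40 subjects × ~118 observed days × 14 items,
minus missing days); 60% of subjects have had at least one symptom-defined
exacerbation by day 120 under the default study-like population; and the
most informative items for a typical (median-severity) subject are the
high-discrimination ones (items 9, 5, 6 of the default catalogue).

Estimation, on a small two-item study:

```python
import numpy as np, pandas as pd
from irtmarkov import ItemSpec, PopulationParams, fit, compare_models, \
    sample_subject_effects
from irtmarkov.simulate import simulate_dataset

items = (ItemSpec(1, 4, 1.6, (-1.0, 0.1, 1.2)),
         ItemSpec(2, 4, 2.2, (-0.6, 0.5, 1.5)))
truth = PopulationParams(items=items, met0=1.5, met_iiv_sd=0.25)
eff = sample_subject_effects(truth, 25, seed=31)
design = pd.concat([pd.DataFrame({"subject_id": s + 1, "day": np.arange(1, 41)})
                    for s in range(25)], ignore_index=True)
ds = simulate_dataset(truth, eff, design, seed=32)

res = fit(ds, fixed={"slope_sd": 0.0})                                  # joint model
ref = fit(ds, init=res.estimates, fixed={"met0": 0.1, "met_iiv_sd": 0})  # no-Markov
print(f"MET estimate: {res.estimates.met0:.2f} days (simulated with 1.5)")
print(f"OFV joint model {res.ofv:.1f} vs no-Markov reference {ref.ofv:.1f}")
print(compare_models(res.ofv, ref.ofv, df=2)["delta_ofv"])
```

prints

```
MET estimate: 1.55 days (simulated with 1.5)
OFV joint model 3149.2 vs no-Markov reference 4336.8
1187.6051592079002
```

The one-parameter Markov component is recovered (1.55 vs 1.5 days) and
removing it (fixing MET to 0.1 days, the independence reference) costs
~1188 OFV units — overwhelming evidence of day-to-day dependence on the
chi-square scale, where a drop of 3.84 is already significant at one
degree of freedom.

A command-line surface wraps the same pipeline:

```bash
irtmarkov simulate --subjects 40 --days 120 --seed 7 --out-dir run/
irtmarkov fit run/diary.csv --out-dir run/
irtmarkov vpc run/diary.csv --estimates run/estimates.json \
    --kind transitions --n-sim 1000 --seed 11 --out-dir run/
irtmarkov events run/diary.csv --out-dir run/
```

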