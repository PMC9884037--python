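# occucam

Camera-trap community analysis and single-season occupancy modelling for
terrestrial mammal surveys.

Camera-trap grids are the workhorse of large-mammal monitoring, but raw
image streams overstate activity (one animal loitering in front of a camera
produces dozens of pictures) and raw detection maps understate occurrence
(a species can use a site and still be missed).  `occucam` implements the
full analysis chain that field studies of apex predators and their prey
run on such data:

- **Independent events** — image sequences of a species at a station are
  collapsed into events separated by ≥ 60 minutes, and trap rates are
  expressed as the relative abundance index, RAI = events per 100
  operational trap-days.
- **Community structure** — observed and first-order Jackknife richness
  (S&#770; = S_obs + f₁(n−1)/n), analytic sample-based rarefaction, Shannon–Wiener
  H′ = −Σ pᵢ ln pᵢ and Gini–Simpson Ds = 1 − Σ pᵢ² diversity from global RAI
  proportions, and Jaccard J = A/(A+B+C) / Sørensen CC = 2A/(2A+B+C)
  similarity between assemblages.
- **Occupancy with imperfect detection** — site × occasion detection
  histories (at most one detection per 24 h, collapsed into 5–11-day
  occasions, stations operational < 80% of occasions dropped) feed the
  standard zero-inflated detection likelihood

      L_i = ψ_i ∏_t p_i^{y_it} (1−p_i)^{1−y_it}        if the site has a detection
      L_i = ψ_i ∏_t (1−p_i) + (1−ψ_i)                  otherwise

  with logit links on both space-use probability ψ and detection
  probability p, fitted by multi-start maximum likelihood.
- **Fit diagnostics and model selection** — MacKenzie–Bailey parametric
  bootstrap goodness-of-fit with overdispersion ĉ = χ²_obs / mean(χ²_boot),
  occasion length chosen by the ĉ-closest-to-1 rule, z-scoring and VIF > 3
  collinearity screening, two-stage (p first, then ψ) additive model
  selection under QAICc = −2logL/ĉ + 2K + 2K(K+1)/(n−K−1), retention at
  ΔQAICc < 2 and Akaike weight > 0.10, and per-covariate evidence tiers
  from 95% confidence intervals.
- **Synthetic surveys** — a generator with known logit-linear parameters,
  within-day image bursts and random station failures, so every stage of
  the pipeline is testable against ground truth without field data.

## Worked example

Simulate a protected-region survey (73 stations, 151 days) with a leopard
whose space-use rises with distance from human habitation and whose daily
detection falls with altitude, then run the pipeline:

```python
import occucam as oc
from scipy.special import logit

spec = oc.region_spec("protected", seed=42)
spec.species_params["leopard"] = oc.SpeciesParams(
    beta_psi={"(intercept)": logit(0.85), "habitation_dist_km": 0.8},
    beta_p={"(intercept)": logit(0.035), "altitude": -0.4},
    body_mass_kg=35.0, guild="carnivore",
)
survey = oc.generate_survey(spec)

events = oc.deduplicate_events(survey.records, interval_minutes=60)
effort = oc.effort_days(survey.operation_log, spec.survey_window)
rai = oc.compute_rai(events, effort)
print(f"{len(survey.records)} images -> {len(events)} events, "
      f"RAI = {oc.global_rai(rai)['leopard']:.2f} events/100 trap-days")

daily = oc.daily_history(events, survey.operation_log, "leopard", spec.survey_window)
design, report = oc.screen_covariates(survey.covariates)
k, table = oc.select_occasion_length(
    daily, design, oc.ModelSpec(("habitation_dist_km",), ("altitude",)),
    ks=(5, 7, 9, 11), n_boot=200, seed=1)
print(f"chosen occasion length: {k} days "
      f"(c-hat {table.loc[table.k == k, 'c_hat'].iloc[0]:.2f})")

history, _ = oc.filter_stations(oc.collapse_occasions(daily, k), 0.80)
model = oc.fit_occupancy(history, design,
                         oc.ModelSpec(("habitation_dist_km",), ("altitude",)), seed=1)
naive = oc.naive_occupancy(history)
print(f"naive occupancy {naive.psi_naive:.3f} over {naive.n_sampled_sites} sites; "
      f"psi-slope on habitation distance = {model.beta_psi[1]:.2f} "
      f"(SE {model.se_psi[1]:.2f})")
```

which prints

```
779 images -> 425 events, RAI = 3.98 events/100 trap-days
chosen occasion length: 11 days (c-hat 0.93)
naive occupancy 0.829 over 70 sites; psi-slope on habitation distance = 0.61 (SE 0.36)
```

Read: the 60-minute rule halves the image stream into 425 independent
events, a trap rate of about 4 events per 100 trap-days.  The 11-day
occasion grid is the one whose global-model bootstrap ĉ sits closest to 1,
i.e. no evidence of overdispersion at that grain.  83% of adequately
operational stations recorded the species at least once, and the fitted
habitation-distance slope (on the z-score scale) is positive — sites
further from habitation are more likely to be used — though at 70 sites
its confidence interval still overlaps zero ("medium" evidence under
`classify_evidence`).

## Analysis scripts

`analysis/01_simulate_surveys.py` … `05_model_selection.py` run the whole
two-region comparison as a narrative: paired survey generation, events and
RAI, community structure and similarity, occasion-length choice with the
global occupancy fit, and two-stage QAICc selection with covariate
evidence.  Each writes its tables under `results/`.

The same steps are available as shell subcommands (`occucam simulate`,
`events`, `rai`, `community`, `history`, `fit`, `select`), each taking
`--config`, `--out`, `--seed` and `--log-level`.

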