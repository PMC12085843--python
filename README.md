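# gidiet

Gene–diet survival analysis for gastrointestinal (GI) cancer: scoring a
**dietary index for gut microbiota (DI-GM)** from multi-recall dietary
data, building an incidence-weighted **composite polygenic risk score
(CPRS)**, and estimating their independent and joint effects on time to
esophageal (EC), gastric (GC) and colorectal (CRC) cancer.

The package is aimed at epidemiologists studying diet–gene interplay in
cohort data. Individual-level cohort data of this kind are access-restricted,
so the package ships a first-class synthetic cohort generator that emulates
the relevant structure — multi-recall zero-inflated intake, biallelic SNP
dosages, covariates with missingness, and Weibull proportional-hazards
event times — making every stage runnable and testable end to end.

## The model

Habitual intake is the mean over a participant's 24-hour recalls. Each of
13 dietary components scores 1 point when consumption is on the favorable
side of its sex-specific median (≥ median for beneficial components such
as fiber, whole grains and fermented dairy; < median for adverse ones such
as red and processed meat; the high-fat component instead scores
favorably below 40% of energy from fat):

    DI-GM_i = Σ_c s_ic ∈ {0, …, 13},   grouped low (0–4) / moderate (5–6) / high (≥7)

Genetic risk combines per-cancer polygenic scores with age-standardized
incidence weights h_k:

    PRS_ik = Σ_j β_jk · dosage_ij        CPRS_i = Σ_k h_k · PRS*_ik

(PRS* z-standardized by default), grouped by quintile (lowest = low,
2–4 = moderate, top = high). Associations with time to first GI cancer are
estimated with multivariable Cox models (HRs with 95% CIs, Schoenfeld
diagnostics, trend tests, restricted cubic splines with 4 knots at the
5/35/65/95th percentiles). The joint DI-GM × genetic-risk analysis uses
nine cells with low-diet/high-risk as reference and quantifies additive
interaction by the relative excess risk due to interaction and the
attributable proportion,

    RERI = HR11 − HR10 − HR01 + 1        AP = RERI / HR11

with delta-method CIs, plus a likelihood-ratio test for multiplicative
interaction. See `docs/methods.md` for the full account.

## Worked example

```python
import gidiet as g

cfg = g.SimulationConfig(n_participants=20_000, seed=3, baseline_scale=120)
tables = g.simulate_dataset(cfg)                   # registry, intake, dosages, weights
built = g.build_analytic_cohort(tables, cfg=cfg)   # exclusions -> scoring -> follow-up
cohort = built["cohort"]
print("n", len(cohort), "events", cohort.event_overall.sum())

fit = g.fit_cox(cohort, g.ModelSpec("digm_group"))
print(fit.summary.loc[fit.exposure_terms, ["hr", "ci_low", "ci_high"]].round(3))

res = g.compute_reri_ap(g.fit_joint_model(cohort))
print("RERI", round(res.reri, 3), "CI", [round(v, 3) for v in res.reri_ci])
```

Output:

```
n 17716 events 1629
                         hr  ci_low  ci_high
digm_group[moderate]  0.941   0.788    1.123
digm_group[high]      0.907   0.766    1.073
RERI -0.258 CI [-0.711, 0.195]
```

17,716 of the 20,000 simulated participants survive the exclusion cascade
and 1,629 develop a GI cancer (the `baseline_scale` here is lowered to get
a higher event rate than the cohort-realistic ~1.5% default, so a small
example is informative). The moderate and high diet groups show hazard
ratios below 1 against the low group, consistent with the planted
protective per-SD effect; a per-SD fit of the genetic score
(`g.fit_cox(cohort, g.ModelSpec("cprs_sd"))`) recovers HR ≈ 1.49 against
the planted exp(0.39) ≈ 1.48. The negative RERI point estimate says the
doubly-favorable cell (high diet, low genetic risk) sits below the
additive expectation, though its CI spans 0 at this sample size.

The same analysis runs from the shell:

```bash
gidiet run --scenario main-effects --n 20000 --seed 3 --out-dir run1
```

writing every intermediate table (TSV), the exclusion-cascade report, the
baseline-characteristics table, tidy Cox summaries, the 9-cell joint grid
with the interaction block (JSON), a data dictionary, and a manifest with
content digests so identical seeds reproduce identical outputs.

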