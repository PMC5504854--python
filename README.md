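# wcr — IPT-weighted competing-risks analysis

`wcr` is a Python toolkit for survival analysis when an event of interest
(for example, a urinary adverse event after prostate-cancer treatment)
competes with death, *and* treatment assignment is confounded, as in
observational claims-registry cohorts. It combines the two corrections a
naive Kaplan-Meier analysis is missing:

1. **Competing risks.** The naive "1 − KM" cumulative incidence, computed
   by censoring deaths, over-states the probability of the event, because
   subjects removed by death can never experience it. The
   **Aalen-Johansen** estimator fixes this by accumulating cause-specific
   hazard increments weighted by all-cause survival:

   `CIF_k(t) = Σ_{t_j ≤ t} (d_kj / n_j) · Ŝ(t_j−)`,

   the discrete analogue of `CIF_k(t) = ∫₀ᵗ λ_k(x) S(x) dx`. It always
   satisfies `Σ_k CIF_k(t) + Ŝ(t) = 1` and is never above the naive KM CIF.
2. **Confounding.** Stabilized inverse-probability-of-treatment (IPT)
   weights — `P(arm) / P(arm | X)`, optionally as a two-stage product of a
   case/control membership weight and a treatment-among-cases weight, with
   truncation at a percentile (default: cap at the 99th) — re-weight the
   cohort so measured covariates are balanced across arms. All estimators
   (KM, naive CIF, Aalen-Johansen CIF, cause-specific Cox) accept the
   weights; Cox confidence intervals use a robust sandwich variance, and
   weighted CIF uncertainty comes from a subject-level bootstrap.

A synthetic-cohort simulator generates confounded multi-arm two-cause data
with exponential cause-specific hazards, so the closed-form truth
`CIF_1(t) = λ₁/(λ₁+λ₂)·(1 − e^{−(λ₁+λ₂)t})` and the true hazard ratios are
known exactly and every claim the package makes can be checked against
them.

## Worked example

```python
import wcr

cohort, truth = wcr.generate_cohort(wcr.SimulationConfig(n=20_000, seed=1))
ws = wcr.iptw_from_cohort(cohort)            # stabilized, 99th-pct capped
print(f"weight mean {ws.mean():.3f}")
fit = wcr.fit_cause_specific_cox(
    cohort, cause=1, covariates=["age", "comorbidity", "baseline_event"],
    weights=ws.align_to(cohort),
)
row = fit.hazard_ratios.loc["arm=RP+EBRT"]
print(f"RP+EBRT HR {row['hr']:.2f} (95% CI {row['ci_low']:.2f}, {row['ci_high']:.2f}); "
      f"true {truth.hr1['RP+EBRT']}")
```

prints

```
weight mean 0.992
RP+EBRT HR 3.56 (95% CI 3.30, 3.83); true 3.7
```

i.e. the IPT-weighted cause-specific Cox model recovers the generator's
true hazard ratio for the most strongly confounded arm to within a few
percent (the unweighted fit on the same data gives 4.43, a ~20% bias),
and the mean stabilized weight is ≈ 1 as stabilization requires.

The full four-way comparison — un-weighted/IPT-weighted × naive-KM /
competing-risks 10-year cumulative incidence per arm, plus both Cox
variants — is one call (`wcr.run_analysis(cohort)`) or one shell command:

```bash
wcr simulate --n 20000 --seed 1 --out cohort.csv
wcr all --input cohort.csv --reference control --out report/
```

`examples/` contains short narrative scripts, one per capability.

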