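# surrokit

Trial-level surrogacy evaluation for time-to-event oncology endpoints.

When individual patient data (IPD) are unavailable, the association between a
surrogate endpoint (progression-free survival, PFS) and the true endpoint
(overall survival, OS) can still be quantified at the trial level by (1)
reconstructing pseudo-IPD from published Kaplan–Meier curves and their
numbers-at-risk tables, (2) extracting arm-level statistics robust to
non-proportional hazards — survival quantiles (Q1, median, Q3), restricted
mean survival time (RMST) at fixed horizons, survival rates — and (3)
regressing the true-endpoint statistic on the surrogate statistic across
arms, weighting by arm sample size. `surrokit` implements this pipeline for
trials of systemic therapies (immune-checkpoint inhibitors, ICI, and
multikinase inhibitors, MKI) in advanced hepatocellular carcinoma, together
with a synthetic trial generator that provides ground truth for every stage.

## What it computes

- **Pseudo-IPD reconstruction** from digitized KM coordinates constrained by
  the published numbers-at-risk (the Guyot algorithm): integer event counts
  from the KM recursion S(t_k) = S(t_{k-1})(1 − d_k/n_k) with
  carry-corrected rounding, censorings placed within each risk interval and
  adjusted until the implied at-risk count matches the published one exactly.
- **Endpoint statistics** with 95% CIs: product-limit S-hat with Greenwood
  variance; quantile times by inverted complementary log-log bands;
  RMST(τ) = ∫₀^τ S-hat(u) du with the standard event-time variance sum;
  survival rate at a time point.
- **Random-effects pooled survival curves**: per-interval conditional
  survivals pooled on the cloglog scale by DerSimonian–Laird, with τ² and
  I² heterogeneity per interval and pooled quantiles.
- **Proportional-hazards diagnostics between PFS and OS** per arm: Breslow
  Cox fit of the endpoint indicator, the Grambsch–Therneau scaled-Schoenfeld
  test, and — when PH fails — time-dependent Cox models
  HR(t) = exp(β₀ + β₁ g(t)) for g ∈ {t, log t, 1{t ≥ 6 mo}}, selected by AIC.
- **Surrogacy meta-regression**: weighted least squares of the OS statistic
  on the PFS statistic with R² = (Σw·dx·dy)² / (Σw·dx²·Σw·dy²), Olkin–Finn
  Wald CIs (untruncated, so weak associations can have negative lower
  bounds), percentile-bootstrap CIs as a sensitivity method, ORR vs OS-rate
  regression, and subgroup interaction p-values.

The published arm-level summary table of the ICI trials and the per-arm
6/12-month RMST table are packaged as fixtures
(`surrokit.load_ici_arm_table()`, `surrokit.load_rmst_table()`).

## Worked example

```python
import surrokit as sk

arms = sk.load_ici_arm_table()
fits = sk.surrogacy_suite(arms, rmst=sk.load_rmst_table())
for key in [("median", "ICI"), ("q1", "ICI"), ("rmst6", "ICI"), ("rmst12", "ICI")]:
    f = fits[key]
    print(f"{key[0]:>7} ({key[1]}): R2 = {f.r2:.2f}  "
          f"(95% CI {f.r2_ci_low:.2f} to {f.r2_ci_high:.2f}, {f.n_arms} arms)")
```

prints

```
 median (ICI): R2 = 0.38  (95% CI 0.03 to 0.72, 8 arms)
     q1 (ICI): R2 = 0.88  (95% CI 0.78 to 0.98, 7 arms)
  rmst6 (ICI): R2 = 0.80  (95% CI 0.64 to 0.96, 7 arms)
 rmst12 (ICI): R2 = 0.80  (95% CI 0.63 to 0.96, 7 arms)
```

i.e. among ICI arms the surrogacy of PFS for OS is weak on the median scale
but strong for the first quartile and for 6- and 12-month RMSTs: roughly 80%
of the between-arm variance in the OS statistic is predictable from the PFS
statistic.

The same pipeline runs end-to-end on synthetic trials from the shell:

```bash
surrokit run --seed 42 --out report/          # simulate -> ... -> surrogacy
surrokit simulate --seed 42 --out sim/        # arms.csv, IPD, digitized curves
surrokit reconstruct --points sim/trial000_arm0_os_points.csv \
    --risk sim/trial000_arm0_os_risk.csv --out ipd.csv
surrokit surrogacy --subgroups controlled,phase,line --out surrogacy.csv
```

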