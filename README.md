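# mpsquant

Quantification of **reversible ischemic defects on myocardial-perfusion SPECT
polar maps**, for researchers studying observer and software variability in
ischemia assessment.

Guidelines recommend revascularization when more than ~10% of the left
ventricle is ischemic, so the reported *percent ischemic myocardium* directly
drives patient management — yet different readers and different software
packages produce widely varying numbers for the same study.  `mpsquant`
provides the computational pieces needed to study (and reduce) that
variability:

* **polar-map model** — bullseye grids with polar-Jacobian area weights,
  percent-of-maximum normalization, rest−stress difference maps, and an
  AHA-style 17-segment partition;
* **two-stage automatic delineation** — stage 1 finds *stress defects* with
  seeded active contours (snakes of circular topology driven by edge and
  intensity information); stage 2 extracts the strictly reversible
  *difference defects* by smoothing and thresholding the rest−stress
  difference inside them;
* **per-study quantities** — defect *extent* (area-weighted % of LV) and
  *SD%* (summed difference score over 17 segments scored 0–4, as % of the
  maximum 4 × 17 = 68);
* **agreement statistics** — ICC(2,1) from the two-way random-effects
  (patients × observers) ANOVA with Shrout–Fleiss 95% CI, between-observer
  SD, Bland–Altman limits of agreement, exact Wilcoxon signed-rank, and
  paired method contrasts for balanced designs;
* **synthetic data** — stress/rest map pairs with parametric ground-truth
  defects, and multi-rater extent panels with known variance components, so
  every estimator is testable against known answers;
* a packaged **reference table** of per-patient extent and SD% values
  reported by four commercial quantification programs (EXINI, ECT, QPS, 4DM)
  for 25 patients with reversible ischemia, used to exercise the descriptive
  statistics.

## Worked example

```python
import mpsquant as mq

grid = mq.make_polar_grid(64, 32)

# one fully reversible defect: 90-degree sector over the outer half-radius,
# 60% uptake reduction at the core, 2% multiplicative noise
defect = mq.DefectSpec(center_theta=90, center_r=0.75, half_width_theta=45,
                       half_width_r=0.25, severity=0.6, reversibility=1.0,
                       edge_softness=0.02)
stress, rest, truth = mq.simulate_study(grid, [defect], noise_level=0.02, seed=1)
print(f"true reversible extent: {truth.true_extent_percent:.2f}% LV")

stress_defects, diff_defects = mq.delineate(stress, rest)
res = mq.quantify_study(mq.normalize_uptake(stress), mq.normalize_uptake(rest),
                        diff_defects)
print(f"estimated extent: {res.extent_percent:.2f}% LV, SD%: {res.sd_percent:.2f}")
```

prints

```
true reversible extent: 18.75% LV
estimated extent: 18.75% LV, SD%: 8.82
```

i.e. the delineation recovers the simulated 18.75% reversible extent
exactly at this noise level, and the independent 17-segment route scores 6
of the 68 possible difference points (8.82% ischemic myocardium — the two
routes measure different things and need not agree).

Agreement statistics on the packaged program-comparison table:

```python
df = mq.load_reference_panel()
s = mq.column_summary(df["exini_extent"].to_numpy())
print(f"extent: mean {s.mean:.1f} (SD {s.sd:.1f}), median {s.median:.0f}, "
      f"range {s.min:.0f}-{s.max:.0f}")
```

```
extent: mean 17.0 (SD 14.6), median 16, range 0-59
```

The same operations are available from the shell:

```bash
mpsquant simulate --seed 1 --out study/
mpsquant delineate --stress study/stress.csv --rest study/rest.csv --out study/
mpsquant agreement --reference-panel --out agreement.json
```

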