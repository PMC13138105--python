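# refkin

Noninvasive kinetic quantification of dynamic PET scans from regional
time–activity curves, built around the simplified reference tissue
model (SRTM) family.

Dynamic PET of a receptor- or SV2A-type tracer yields, per brain
region, a time–activity curve (TAC): the decay-corrected activity
concentration averaged over each acquisition frame. Full quantification
requires arterial blood sampling to measure the plasma input function —
accurate but invasive and clinically impractical. Reference-tissue
models replace the blood data with the TAC of a region devoid of
specific binding. `refkin` implements that workflow end to end for
researchers evaluating whether a reference-tissue protocol (and a
shortened scan) can stand in for the invasive baseline:

* **Models** — one-tissue compartment (1TC) fitting against a plasma
  input (the baseline, `DV = K1/k2`); SRTM with free `(R1, k2, k2a)`;
  **SRTMC**, a coupled fit sharing one reference clearance `k2'` across
  all regions of a scan; and **SRTM2** with `k2'` fixed to a population
  value. Outcomes: relative delivery `R1 = K1/K1'`, binding potential
  `BP_ND = k2/k2a − 1`, and distribution volume ratio `DVR = BP_ND + 1`.
* **Reliability filtering** — estimates with a relative standard error
  above 25% are flagged and excluded from downstream aggregates.
* **Model agreement** — OLS regression and R² of reference-model
  outcomes against the 1TC baseline, plus the coupling between bias in
  `k2'` and bias in the outcomes.
* **Time stability** — refit at truncated durations (10–80 min) and
  find the minimum scan time whose mean percentage difference vs the
  full scan stays within 5% with inter-subject SD within 10%.
* **Test–retest** — signed TRV (difference over pair mean, %) and
  absolute TRV per region/outcome across paired sessions.
* **Synthetic cohorts** — a generator producing multi-subject
  test–retest cohorts of TACs from known one-tissue ground truth under
  a tri-exponential plasma input, with a decay-weighted frame-variance
  noise model, so every stage of the pipeline is testable against
  truth. No scanner data are required anywhere.

The model equations, estimation choices and generator calibration are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a reference region (white matter, `K1' = 0.17`,
`k2' = 0.059 /min) and a high-binding target (`R1 = 1.6`,
`BP_ND = 3.0`), add measurement noise, and fit SRTM2 with the
population `k2'`:

```python
import refkin

sched = refkin.default_schedule()          # 90-min, 27 frames
aif   = refkin.default_input()             # tri-exponential bolus
ref   = refkin.simulate_1tc_tac(aif, 0.17, 0.059, sched,
                                region_id="centrum_semiovale")
tac   = refkin.simulate_1tc_tac(aif, 1.6 * 0.17, 1.6 * 0.059 / 4.0,
                                sched, region_id="putamen")
noisy = refkin.add_noise(tac, sched, refkin.NoiseModel(scale=1.5), seed=7)

res = refkin.SRTM2(noisy, ref, k2prime=0.059).fit()
print(res.summary())
```

```
SRTM2 fit — region putamen  (k2' fixed at 0.059/min)
  frames: 27   t_end: 90 min   free params: 2   converged: True
  WRSS: 1779   AIC: 117.1
  param       estimate          SE     rSE %
  R1            1.6135        0.06      3.72
  k2a         0.025959     0.00148      5.70
  BP_ND         2.6672      0.0946      3.55
  k2          0.095195     0.00354      3.72
```

Reading the table: delivery in the putamen is estimated at 1.61× the
reference (truth 1.6); the binding potential estimate 2.67 sits within
noise of the simulated truth 3.0, with a relative standard error of
3.6% — far below the 25% reliability cutoff, so this fit would be kept.
`res.plot()` overlays the fitted curve on the frame data, and
`refkin.fit_srtmc(...)`/`refkin.fit_1tc(...)` provide the coupled and
plasma-input fits with the same results interface.

The same pipeline is scriptable from the shell:

```bash
refkin simulate --out cohort --seed 1          # synthetic test–retest cohort
refkin fit cohort/manifest.yaml --model srtm2 --k2prime 0.059 --out fits.tsv
refkin stability cohort/manifest.yaml --model srtm2
refkin trt cohort/manifest.yaml
```

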