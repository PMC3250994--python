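# pgpkin

PET tracer kinetic modeling of P-glycoprotein (P-gp) function at the
blood–brain barrier, built around the ¹¹C-desmethylloperamide (¹¹C-dLop)
mouse paradigm: quantify P-gp efflux by fitting compartment models to
dynamic brain curves driven by an arterial input function obtained
*without* arterial blood sampling.

## Who this is for

Small-animal PET groups quantifying transporter function with a P-gp
substrate tracer. Arterial sampling in mice is close to impossible
(fragile vessels, ~1.7 mL total blood), so the input function is derived
from a left-ventricle ROI — delineated on a co-registered ¹⁸F-FDG scan and
copied onto the dynamic tracer images — and validated against a
blood-counter trace deconvolved for catheter dispersion.

## What it computes

**Input function.** The whole-blood curve (image ROI or counter trace) is
corrected by, in order:

- dispersion (counter only): `C_a(t) = g(t) + τ_disp · dg/dt`, default
  τ_disp = 28 s;
- plasma scaling: plasma = whole blood × 0.64 (mean plasma-to-whole-blood
  activity ratio);
- metabolites: multiplication by the group-specific parent fraction f(t),
  interpolated through the HPLC measurements at 1/10/30 min with anchor
  f(0) = 1.

Agreement between the two routes is scored directly (percent AUC
difference) and indirectly (percent error of the fitted K1/k2).

**Kinetics.** One- and two-tissue compartment models with a fractional
blood-volume term,

    1TC:  dC_T/dt = K1·C_p − k2·C_T
    2TC:  dC_1/dt = K1·C_p − (k2+k3)·C_1 + k4·C_2,   dC_2/dt = k3·C_1 − k4·C_2
    C_model = (1−vB)·C_T + vB·C_wb

fitted by bounded multistart weighted least squares (statsmodels-style
`CompartmentModel(...).fit()` → results object with estimates, %COV =
100·SE/estimate, AIC, residuals, `summary()`). Model selection ranks by
AIC = n·ln(RSS/n) + 2p, flags poorly identified fits by %COV, and prefers
the simplest model within ΔAIC ≤ 2. The headline P-gp functionality index
is the equilibrium distribution ratio **K1/k2** (≈0.4 in wild-type mice
vs ≈2.0 when P-gp is knocked out or blocked with cyclosporine). A
2-minute-window refit separates fast transporter-driven efflux from slow
passive efflux.

**Cohort analysis.** SUV = A/(ID/BW) in g/mL, brain-to-blood SUV ratios,
and one-way ANOVA with pooled-variance Bonferroni post hoc tests across
the WT-saline / WT-cyclo / KO groups.

**Synthetic ground truth.** Because no raw scans are distributed, a
generator produces arterial boluses, dispersion-blurred counter traces,
compartment-model tissue curves, 4D NIfTI phantoms with labeled
heart/brain regions, and cohorts drawn around the published per-animal
rate constants — so every pipeline stage is testable against known truth.

## Worked example

```python
import pgpkin as pk

truth = pk.KineticParams(K1=0.054, k2=0.190, vB=0.03)   # wild-type-like
gt = pk.GroundTruth(kinetics={"brain": truth}, group="WT-saline",
                    noise_scale=0.05, seed=42)
phantom, _ = pk.build_phantom(gt)

lv = pk.extract_roi_tac(phantom, "heart-LV")
brain = pk.extract_roi_tac(phantom, "brain")
cp = pk.build_input_function(lv, plasma_ratio=0.64,
        parent_fraction=pk.reference.PARENT_FRACTIONS["WT-saline"])
wb = pk.build_input_function(lv, plasma_ratio=1.0)

res = pk.CompartmentModel(brain, cp, wb, model="1tc").fit()
print(res.summary())
```

prints

```
Compartment model fit [1tc]
  frames: 27   window: 0-1800 s   weighting: frame-duration
  RSS (weighted): 5.51645e-05   AIC: -347.728   converged: True
  param     estimate          SE      %COV  unit
  K1         0.05395     0.00003       0.1  mL/cc/min
  k2         0.18996     0.00012       0.1  1/min
  vB         0.03009     0.00003       0.1
  K1/k2: 0.284 mL/cc
```

i.e. the generating parameters (K1 = 0.054 mL/cc/min, k2 = 0.190 /min,
vB = 0.03) are recovered through the full image-extraction + correction
chain despite 5% count noise, with sub-percent identifiability, and the
K1/k2 of 0.28 mL/cc flags intact P-gp function.

The same flow is available from the shell:

```sh
pgpkin simulate --seed 1 --out sim/           # cohort curves (CSV)
pgpkin run --seed 1 --out report/             # full pipeline + statistics
pgpkin fit --tac brain.csv --input input.csv --wb wb.csv --model 1tc
pgpkin stats --table report/results.csv --outcome K1_k2
```

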