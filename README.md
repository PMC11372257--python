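# petkin — compartmental kinetic analysis of dynamic total-body PET

`petkin` is an analysis pipeline for 90-minute total-body dynamic PET
studies with an image-derived whole-blood input function, built for tracers
whose tissue kinetics follow one- or two-tissue compartment models — the
motivating application is quantifying activated-T-cell tracer uptake in
organs, lymph nodes and tumor subregions before and after immunotherapy.
It is aimed at researchers who have regional time–activity curves (TACs)
and want microparameters, macroparameters and their reliability, without
trusting SUV snapshots.

The measured regional signal is modeled as

    C_m(t) = v_b · C_wb(t − t_d) + (1 − v_b) · C_t(t)

where `C_t` solves the 1-tissue model (rates `K_1, k_2`) or the serial
2-tissue model (`K_1, k_2, k_3, k_4`), `v_b` is the fractional blood
volume and `t_d` the arrival delay. Three candidate models (1T4P, 2T5P,
2T6P, named by fitted-parameter count) are fitted by bound-constrained
multi-start least squares with `t_d` estimated jointly, and compared by
the small-sample-corrected Akaike criterion
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`. Derived quantities: net
influx rate `K_i = K_1 k_3/(k_2+k_3)`, total volume of distribution
`V_T = (K_1/k_2)(1 + k_3/k_4)`, its blood-volume-corrected equilibrium
limit `V_T(v_b) = v_b + (1−v_b)V_T`, window SUVR, and the Logan graphical
slope `K_Logan` (t* = 30 min). A Monte-Carlo practical-identifiability
module quantifies bias/SD/RMSE of every estimate under a count-statistics
noise model, and exact small-sample statistics (permutation Spearman,
enumerated Wilcoxon signed-rank) handle the group comparisons.

Because the clinical TACs behind such studies are not generally public,
the package ships a ground-truth synthetic study generator
(`petkin.synthetic_data`) that emulates the study design: two blood inputs
(aorta, right ventricle), ~15 organs, 7 tumor subregions, mediastinal and
axillary/pelvic nodes, paired pre/post-therapy scans with increased
trapping (`k_3`) and decreased efflux (`k_4`) after therapy.

## Worked example

Simulate the default cohort, fit one scan, and test the therapy effect:

```bash
python analysis/01_simulate_cohort.py --seed 20240901
python analysis/02_fit_models.py
python analysis/03_identifiability.py
python analysis/04_group_stats.py
```

`01` writes six TAC tables (4 healthy, patient pre/post) plus
`ground_truth.csv` under `results/cohort/`. `02` fits all three models per
region; on the default noisy cohort it ends with

```
V_T recovery over 124 regions: median -0.5%, IQR [-3.5, +2.4]%
AICc selection: {'2T6P': 106, '2T5P': 12, '1T4P': 6}
```

(the reversible 2-tissue model wins nearly everywhere; the 1-tissue model
in the right-ventricle myocardium). `03` prints the sensitivity peaks and
the identifiability panel:

```
sensitivity of v_b peaks at 0.38 min
sensitivity of K_1 peaks at 1.08 min
tumor            V_T bias +0.68%  SD  5.06%  RMSE  5.08%
...
V_T bias range over panel: -0.19% .. +2.53%
fixing the delay changes SD% by: {'K_1': 0.09, 'V_T': -0.1, 'k_2': 0.41,
                                  'k_3': 1.38, 'k_4': 0.98, 'v_b': -15.35}
60- vs 90-min V_T RMSE difference: +7.25 percentage points
```

so V_T is estimated with ≤2.5% bias and ~5% spread at the calibrated
noise; fixing the arrival delay collapses the blood-volume spread (−15
percentage points); truncating to 60 min costs ~7 points of V_T RMSE on
this slow-equilibrating tumor preset. `04` runs the surrogacy
correlations over the healthy organs of all subjects and the exact paired
tests over the 7 tumor subregions:

```
SUVR vs V_T(v_b)         rho=+0.985  p=2.8e-46  n=60
K_Logan vs V_T(v_b)      rho=+0.993  p=1.3e-55  n=60
...
SUVR     n=7  W=0.0  p=0.015625  median change +2.86
K_Logan  n=7  W=0.0  p=0.015625  median change +4.54
V_T      n=7  W=0.0  p=0.015625  median change +4.52
K_1      n=7  W=8.0  p=0.375     median change +0.0238
k_3      n=7  W=1.0  p=0.03125   median change +0.0288
k_4      n=7  W=0.0  p=0.015625  median change -0.0062
```

The macroparameters and the trapping/efflux rates change consistently in
all (or all but one) subregions while the delivery parameters do not — a
consistent change in all 7 pairs yields the exact two-sided
p = 2/2⁷ = 0.015625 (0.016 at printed precision); one discordant pair
carrying rank 2 would give 6/128 = 0.046875 (0.047).

A `petkin` console script wraps the same stages
(`petkin simulate|fit|identify|stats|all`), writing a JSON run manifest
next to each output.

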