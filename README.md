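# symbiotherm

Quantitative analysis of ramp-and-hold heat-stress experiments on
symbiotic cnidarians (built around the sea anemone *Exaiptasia diaphana*
and its dinoflagellate endosymbionts). The package turns raw instrument
exports — temperature-logger series, optical-O₂ sensor-dish traces,
two-channel SNARF-1 fluorescence tables, ¹³C isotope-ratio results, and
phenotype measurements — into the experiment's result surface: thermal
dose, metabolic thermal optima, intracellular pH, photosynthate
translocation, bleaching phenotypes, and the statistics tying them
together. A synthetic-experiment generator with explicit ground truth
makes every stage testable end to end.

## What it computes

**Thermal dose (eDHW).** Daily 24 h means per container (with a pooled
bath-vs-container offset correction) accumulate experimental degree
heating weeks:

```
eDHW = (1/7) · Σ_{days: T̄_d > MMM+1} |T̄_d − MMM|      [°C week⁻¹]
```

with the mean monthly maximum MMM = 25 °C (the pre-experiment holding
temperature) and a strict 26 °C threshold.

**Respirometry.** Each vial×irradiance O₂ trace yields an OLS slope over
the most linear admissible window (5–10 min, ≥30 s after the light
change, chosen by exhaustive R² maximization). Slopes are blank-corrected
per (temperature, light), converted to total O₂ (×4 ml vial volume), and
normalized to host protein. Animals whose uncorrected dark slope lies
within ±1 SE of the dark blanks are flagged below the limit of detection
and excluded. A penalized cubic spline (GCV-selected penalty) smooths each
photosynthesis–irradiance curve; P_max is the maximum of the prediction
over the observed light range and LEDR is the dark rate. A second smooth
of P_max (or LEDR magnitude) on temperature gives the thermal optimum
T_opt at the + → − zero crossing of its first derivative, with a seeded
bootstrap over individuals for the SE.

**Intracellular pH.** Per cell, the background-corrected ratio
(I₅₈₅−bg)/(I₆₄₀−bg) maps to pH through a four-parameter logistic
calibration fitted to same-microscope standards; animals are summarized
by the median pH of their cells per class (symbiocyte / non-symbiocyte).

**¹³C enrichment.** δ¹³C ↔ atom-% via the VPDB ratio R = 0.0111802
(AP = 100·R·(δ/1000+1)/(1+R·(δ/1000+1)); natural abundance ≈ 1.1057
atom-%), with Tukey-adjusted contrasts validating the pulse ordering
symbiont > symbiotic host > aposymbiotic host.

**Statistics.** Candidate models (linear, container-random-intercept
mixed, spline smooth) are fitted by ML and ranked by AICc; effects are
followed up with Tukey HSD contrasts (studentized range, compact letter
display). Multivariate phenotype profiles use PERMANOVA (pseudo-F on
Euclidean distances of z-scored variables, seeded free permutations) and
PCA.

## Worked example

Generate a synthetic experiment and compute the exposure table and
thermal optima:

```
$ symbiotherm synth --out demo --seed 17
$ symbiotherm thermal --logs demo/temperature_logs.csv \
      --pairs demo/offset_pairs.csv --out demo/exposure.csv
cohort  treatment    mean_c  max_daily_mean_c  edhw_c_week  hot_days
    HD         25 24.869037         24.871644     0.000000         0
    HD         27 26.506043         26.897339     3.789296        14
    HD         29 27.836245         28.840575     7.244085        14
    HD         31 28.931263         30.767157    10.099967        14
    ...
```

25 °C controls accumulate no dose; the 31 °C treatment accumulates
~10 °C week⁻¹ over the 18-day ramp-and-hold. Then:

```
$ symbiotherm respiro --traces demo/o2_traces.csv --platemap demo/plate_map.csv \
      --protein demo/protein.csv --out demo/resp --bootstrap 100 --seed 17
 symbiotic metric   t_opt_c  t_opt_se_c  edf  n_bootstrap
      True  p_max 26.371535    0.169738  3.0          100
      True   ledr 27.068552    0.135730  3.0          100
```

For symbiotic animals the fitted optimum for net photosynthesis sits near
26.4 °C and for light-enhanced dark respiration near 27.1 °C — i.e. both
below the hottest treatments, the signature of metabolic impairment at
31 °C. The generating truth for this run was 26.4 / 27.2 °C.

The full pipeline (`symbiotherm all --config run.yaml`) adds pH tables,
enrichment contrasts, model-selection reports, PERMANOVA/PCA, and a
manifest with seeds and output hashes.

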