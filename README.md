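# gdperf — goal-directed perfusion analytics

During cardiopulmonary bypass (CPB) the heart-lung machine replaces the
circulation, and the perfusionist chooses the pump flow. Conventional
practice fixes the flow at an average cardiac index (CI) of
2.2–2.4 L/min/m². Goal-directed perfusion (GDP) instead keeps the
*indexed oxygen delivery*

```
DO2i = CI · 10 · CaO2,      CaO2 = 1.36 · Hb · SaO2 + 0.003 · PaO2
```

above a threshold (280 mL/min/m²) by adjusting flow to the patient's
haemoglobin: haemodilution by the circuit prime lowers CaO₂, so the same
flow can silently drop DO2i below the level at which end-organ injury
becomes more likely. `gdperf` is a tested pipeline for this analysis,
aimed at perfusionists and clinical-data analysts:

* **physiology** — oxygen-transport calculators (CaO₂, DO2i, required
  CI, O₂ER, Fick VO₂i);
* **synthetic** — a seeded generator of realistic multi-patient CPB
  time series (haemodilution drift, transient pump-flow reductions,
  SvO₂ coupled to flow through a latent consumption, plus injected
  duplicate/empty rows and missing cells) standing in for clinical data;
* **platform** — merge per-patient CSVs into one time-indexed dataset,
  deduplicate, drop empty rows, interpolate short gaps, derive CI /
  DO2i / O₂ER;
* **gdp_filter** — the GDP retention constraints (DO2i ≥ 280 mL/min/m²,
  SvO₂ > 68 %, MAP > 60 mmHg) and a CI-bin density filter (bins of
  0.1 L/min/m² need ≥ 100 Hb measurements);
* **iso_do2** — iso-DO2i bands at 280/330/380 mL/min/m², weighted
  quadratic fits of CI on Hb (triangular kernel on |DO2i − level|), the
  exact closed-form hyperbola `ci = level / (10·CaO2(hb))`, and a
  pump-flow recommendation calculator;
* **reporting / cli** — Table-1-style cohort summaries, the standard
  figures, and a `gdperf` command-line front end.

## Worked example

How hard should the pump run for a patient diluted to Hb 8 g/dL if the
delivery goal is 280 mL/min/m²?

```console
$ gdperf recommend --hb 8 --bsa 1.95
DO2i target 280 mL/min/m^2 at Hb 8 g/dL: CI >= 2.6 L/min/m^2 (pump flow 5.0 L/min at BSA 1.95 m^2)
```

280/(10·1.36·8) = 2.57 L/min/m², i.e. a patient at Hb 8 needs roughly
CI 2.6 — well above the conventional 2.2 setting, which *is* sufficient
at Hb 10:

```console
$ gdperf calc do2i --ci 2.2 --hb 10
DO2i = 299.2 mL/min/m^2
```

The full pipeline — simulate a 272-patient cohort (~350 k rows), build
and clean the platform dataset, filter, fit, recommend, plot — is one
command:

```console
$ gdperf run-all --seed 0 --out gdp_run
$ gdperf fit --filtered-csv gdp_run/filtered.csv --out gdp_run/iso_fits.json
level 280: ci = 6.0338 -0.6272*hb +0.02255*hb^2 on hb [7.58, 11.03] (n=12344)
level 330: ci = 5.8158 -0.4839*hb +0.01365*hb^2 on hb [8.11, 13.37] (n=52821)
level 380: ci = 6.1190 -0.4640*hb +0.01189*hb^2 on hb [9.11, 12.88] (n=29966)
```

Each fitted curve is the empirical iso-delivery contour: CI falls as Hb
rises, and at any haemoglobin the 380-curve sits above the 330-curve
above the 280-curve. `gdp_run/` also contains the cleaned datasets, the
row-accounting and filter reports, figures (scatter coloured by DO2i,
iso-curves), a cohort demographics table and a `manifest.json` with the
config hash and per-stage row counts; the same seed reproduces it
byte-for-byte.

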