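# Methods

## Oxygen-transport model

Arterial oxygen content (mL O₂/dL) is the haemoglobin-bound fraction
plus dissolved oxygen:

    CaO2 = 1.36 · Hb · SaO2 + 0.003 · PaO2

with Hb in g/dL, SaO₂ a fraction and PaO₂ in mmHg. Indexed delivery is

    DO2i = CI · 10 · CaO2        [mL O2/min/m²],  CI = pump flow / BSA

The factor 10 converts per-decilitre content times per-litre flow into
mL/min; clinical shorthand often omits it, but without it the standard
GDP threshold of 280 mL/min/m² would be unreachable at conventional
flows (CI 2.2, Hb 10 gives 2.2·10·13.6 = 299.2). The inverse,
`required_ci(target, hb, …) = target / (10·CaO2)`, is exact and
round-trips through `do2i` to machine precision; `vo2i_fick` is the
Fick difference of arterial and venous contents, and O₂ER =
(SaO₂ − SvO₂)/SaO₂.

Saturations are stored as fractions; external surfaces (raw CSVs, CLI)
use percent, the clinical convention, and convert at the boundary.
"g%" for haemoglobin is read as g/dL.

**Reference conditions.** Iso-DO2i closed-form curves and the flow
recommendation default to SaO₂ = 1.0 and PaO₂ = 0 (dissolved oxygen
neglected). This is a documented convention, not a physical claim: the
canonical worked value — CI ≈ 2.6 L/min/m² to hold 280 mL/min/m² at
Hb 8 — equals 280/(10·1.36·8) only under exactly these conditions. The
general calculators accept any SaO₂/PaO₂.

## Synthetic cohort generator

The generator replaces a clinical dataset and therefore defines the
study conditions; its defaults are fixed once and tested as-is:

* **Scale.** 272 patients, 5-s sampling, case duration uniform in
  80–135 min → ≈1,290 rows per case and ≈350 k rows overall. A 5-s tick
  with realistic bypass times was chosen over slower sampling because
  clinically plausible case durations and the target row scale cannot
  otherwise coexist.
* **Demographics.** Age ~ N(62.5, 12.4²) y, 73.6 % male,
  BSA ~ N(1.95, 0.21²) m², BMI ~ N(28.38, 4.78²), procedure mix
  CABG 48.9 % / other single 34.9 % / double 15.8 % / triple 0.4 %.
* **Cardiac index.** Per-patient set point ~ N(2.3, 0.15²) (the
  conventional 2.2–2.4 band), a slow random walk and white noise, plus
  Poisson-placed transient flow reductions (2/h, 30–120 s, −45 %)
  emulating surgical manipulation. Core mass sits in 1.3–2.8 L/min/m².
* **Haemoglobin.** A starting level ~ N(11.3, 0.9²) g/dL diluted by
  ≈1.2 g/dL with a 10-min time constant (circuit prime), leaving the
  core mass in 9–12 g/dL.
* **SvO₂ via inverse Fick.** A latent consumption VO₂i ~ N(90, 10²)
  mL/min/m² gives CvO₂ = CaO₂ − VO₂i/(10·CI), hence SvO₂. Low-flow
  episodes thereby depress DO2i, SvO₂ and MAP *together*, so the GDP
  constraints interact coherently, and ≈15 % of rows fall below
  280 mL/min/m² — transient low-delivery episodes rather than noise.
* **Corruption pass.** Duplicated rows (1 %), fully empty rows (0.4 %,
  placed at half-tick timestamps), and missing cells (0.8 %), all
  recorded in a ledger together with the per-row ground-truth DO2i.
  This ledger is the oracle for the cleaning-accounting and
  filter-equivalence tests.

What the generator does **not** emulate: surgical phases, temperature
management, vasoactive drugs, sensor drift/recalibration artefacts, or
between-variable measurement error correlations beyond the Fick
coupling. Passing tests therefore demonstrate the pipeline's
correctness under a physiologically coherent data-generating process,
not the cohort-specific statistics of any real dataset.

## Platform cleaning

Per-patient raw CSVs are merged on (patient_id, timestamp). Timestamps
are normalised to whole seconds. A *duplicate* is a row identical in
key and every measurement field (no fuzzy matching); remaining same-key
ties keep the first occurrence. An *empty* row has every measurement
missing. The conservation identity ingested = cleaned + duplicates +
empty is asserted against the generator ledger, and cleaning is
idempotent.

Missing cells are filled by linear interpolation in time, strictly
within patient and only when the flanking measured values are at most
`max_gap` = 120 s apart (a guard against inventing long stretches of
data; the interpolation method itself is the most conservative common
reading of "from nearby points"). Leading/trailing gaps stay missing;
such rows carry no derived values and drop out at the constraint stage.
Filled cells are flagged `interpolated_<field>`.

## GDP filtering

Retention: DO2i ≥ 280 mL/min/m² (non-strict — "at least"), SvO₂ > 0.68
and MAP > 60 mmHg (strict). Set-intersection semantics make the filter
idempotent and order-independent; removals are attributed to the first
failing criterion (incomplete → DO2i → SvO₂ → MAP) for reporting only.

Density filter: CI binned at 0.1 L/min/m² (left-closed, right-open, the
resolution at which CI ranges are usually quoted); rows in bins with
fewer than 100 Hb measurements are removed in a single pass (counts are
not re-evaluated after removal). Constraints run before the density
filter, following the narrative order of the analysis.

## Iso-DO2i bands and fits

The band at level L keeps rows with |DO2i − L| < tolerance (default
±10 mL/min/m²; the value is a package choice, as no tolerance is
standard) with triangular-kernel weights w = 1 − |DO2i − L|/tol.
Boundary rows would get weight 0 and are excluded, keeping all weights
in (0, 1]. "Weighted regression of second order" is implemented as
weighted least squares of CI on (1, Hb, Hb²) — CI on Hb, not the
reverse, because the clinical use reads a flow off a measured
haemoglobin. The solve is the closed-form sqrt-weighted `lstsq`
(deterministic); bands need ≥ 10 distinct Hb values and full column
rank. Fitted curves are never evaluated outside the band's observed Hb
range (no extrapolation).

Against the exact hyperbola the quadratic is an approximation; on
noise-free bands over Hb 8–12 the discrepancy is below 0.01 L/min/m²
(tested at < 0.05). On the default synthetic cohort the three fitted
curves are each monotonically decreasing and strictly ordered
380 > 330 > 280 over their common Hb range.

## Numerical and design notes

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed gives
  byte-identical raw files and manifests.
* Raw CSVs store full float precision (round-trip exact), so derived
  DO2i agrees with the generator's ground truth to ~1e-13, and the
  ledger-equivalence tests can demand exact row sets.
* Degenerate inputs: zero-haemoglobin content is 0; a positive DO2i
  target with zero content raises; empty datasets pass through cleaning
  and constraint filtering as empty; an empty iso-band raises
  "insufficient data".
* Figures (scatter coloured by DO2i with a sequential map — darker =
  lower — and the iso-curve panel) are by-products; every claim they
  visualise is asserted on the underlying arrays in the test suite.
  Scatter plots down-sample to 20 k points for tractable vector output.
* Problem sizes in the test suite: unit tests run on 6–30-patient
  cohorts; the full 272-patient pipeline is exercised once per session
  to verify the iso-curve structure at scale.

## Known limitations

* The quadratic is a local smoother: outside well-populated Hb ranges
  its tails are not physiologic (the true contour is a hyperbola).
* DO2i here is recomputed from flow, Hb, SaO₂ and PaO₂; a monitor's
  internal DO2i may use different conventions for the dissolved term.
* The density filter's bin width and count interact with cohort size;
  the defaults assume a ~10⁵-row dataset.
* VCO₂-based indices (DO2i/VCO2i) and outcome modelling are out of
  scope, as are acid-base/temperature corrections of the dissociation
  curve and pressure-targeted (higher-MAP) variants of the analysis.
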