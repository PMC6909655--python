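"""Synthetic cardiopulmonary-bypass cohort generator.

Emulates the structure of a multi-patient intra-operative CPB dataset:
per-patient time series of pump flow, haemoglobin, saturations, PaO2 and
MAP sampled at a fixed interval, plus a demographics table.  The
generator is the study-condition oracle for the rest of the pipeline:

* every uncorrupted row carries a ground-truth DO2i, so the GDP filter
  can be checked against a known low-delivery ledger;
* SvO2 is derived from a latent oxygen consumption via the inverse Fick
  relation, so transient pump-flow reductions depress DO2i, SvO2 and MAP
  together, the way they co-move on a real bypass run;
* a corruption pass injects duplicate rows, fully empty rows and missing
  cells at configured rates, and records exactly what it injected.

Output is deterministic for a fixed seed (byte-identical tables).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import physiology

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "CorruptionLedger",
    "generate_cohort",
    "write_raw_workbook",
    "MEASUREMENT_COLUMNS",
    "RAW_COLUMNS",
]

#: internal (post-ingest) measurement column names; saturations are fractions
MEASUREMENT_COLUMNS = ["flow", "hb", "sao2", "svo2", "pao2", "map"]

#: on-disk raw CSV dialect: ISO-8601 timestamps, saturations in percent
RAW_COLUMNS = [
    "timestamp", "patient_id", "flow_lpm", "hb_gdl",
    "sao2_pct", "svo2_pct", "pao2_mmhg", "map_mmhg",
]

_PROCEDURES = ("CABG", "other single procedure", "double procedure", "triple procedure")
_PROCEDURE_P = (0.489, 0.349, 0.158, 0.004)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the described cohort: 272 patients, cardiac index
    mass in 1.3-2.8 L/min/m**2 around an initial set point of ~2.2-2.4,
    haemoglobin mass in 9-12 g/dL after haemodilution, BSA 1.95 +/- 0.21
    m**2, age 62.5 +/- 12.4 y, 73.6 % male, and enough rows per case
    (5-s ticks over 80-135 min of bypass) to total ~350k rows.
    """

    n_patients: int = 272
    sampling_interval_s: float = 5.0
    duration_minutes: tuple[float, float] = (80.0, 135.0)

    # cardiac-index process
    ci_setpoint_mean: float = 2.3
    ci_setpoint_sd: float = 0.15
    ci_range: tuple[float, float] = (1.3, 2.8)   # documented core mass
    ci_noise_sd: float = 0.04
    ci_walk_sd: float = 0.004                     # per-tick random-walk step

    # haemoglobin process (haemodilution by circuit prime)
    hb_range: tuple[float, float] = (9.0, 12.0)  # documented core mass
    hb_start_mean: float = 11.3
    hb_start_sd: float = 0.9
    hb_dilution_drop: float = 1.2                # g/dL lost to prime, tau 10 min
    hb_walk_sd: float = 0.002

    # transient pump-flow reductions (surgical manipulation)
    low_flow_episode_rate: float = 2.0           # episodes per hour
    low_flow_depth: float = 0.45                 # fractional flow reduction
    low_flow_duration_s: tuple[float, float] = (30.0, 120.0)

    # gas exchange and metabolism
    sao2_mean: float = 0.98
    sao2_sd: float = 0.004
    pao2_mean: float = 250.0
    pao2_sd: float = 40.0
    pvo2: float = 40.0
    vo2i_mean: float = 90.0                      # mL O2/min/m**2, anaesthetised
    vo2i_sd: float = 10.0

    # corruption rates
    duplicate_row_rate: float = 0.01
    empty_row_rate: float = 0.004
    missing_cell_rate: float = 0.008

    # demographics
    bsa_mean: float = 1.95
    bsa_sd: float = 0.21
    male_fraction: float = 0.736
    age_mean: float = 62.5
    age_sd: float = 12.4
    bmi_mean: float = 28.38
    bmi_sd: float = 4.78

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_row_rate", "empty_row_rate", "missing_cell_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("duration_minutes", "ci_range", "hb_range", "low_flow_duration_s"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range is empty")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")


@dataclass
class CorruptionLedger:
    """Exactly what the corruption pass injected, and the pre-corruption truth.

    ``per_patient`` has one row per patient with the clean row count and
    the numbers of injected duplicates, empty rows and missing cells.
    ``truth`` holds, for every uncorrupted row, the true DO2i and whether
    it falls below the GDP threshold of 280 mL/min/m**2.
    """

    per_patient: pd.DataFrame
    truth: pd.DataFrame
    do2i_threshold: float = 280.0

    @property
    def n_duplicates(self) -> int:
        return int(self.per_patient["n_duplicates"].sum())

    @property
    def n_empty(self) -> int:
        return int(self.per_patient["n_empty"].sum())

    @property
    def n_missing_cells(self) -> int:
        return int(self.per_patient["n_missing_cells"].sum())

    @property
    def n_clean_rows(self) -> int:
        return int(self.per_patient["n_rows_clean"].sum())


@dataclass
class Cohort:
    """A generated cohort: demographics, raw per-patient tables, truth ledger."""

    profiles: pd.DataFrame
    series: dict[str, pd.DataFrame] = field(repr=False)
    ledger: CorruptionLedger = field(repr=False)
    config: GeneratorConfig = GeneratorConfig()

    @property
    def n_rows(self) -> int:
        return int(sum(len(df) for df in self.series.values()))


def _sample_profiles(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    width = max(3, len(str(max(n, 1))))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 95).round(0)
    sex = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
    bsa = np.clip(rng.normal(cfg.bsa_mean, cfg.bsa_sd, n), 1.3, 2.6).round(2)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 16, 50).round(2)
    procedure = rng.choice(_PROCEDURES, size=n, p=_PROCEDURE_P)
    return pd.DataFrame(
        {"patient_id": ids, "age": age, "sex": sex, "bsa": bsa,
         "bmi": bmi, "procedure": procedure})


def _episode_mask(n: int, interval: float, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiplier series with flat fractional flow reductions."""
    mult = np.ones(n)
    hours = n * interval / 3600.0
    k = rng.poisson(cfg.low_flow_episode_rate * hours)
    for _ in range(k):
        dur = rng.uniform(*cfg.low_flow_duration_s)
        start = rng.uniform(0, max(n * interval - dur, interval))
        i0 = int(start / interval)
        i1 = min(n, i0 + max(int(dur / interval), 1))
        mult[i0:i1] = 1.0 - cfg.low_flow_depth
    return mult


def _generate_patient(pid: str, bsa: float, start: pd.Timestamp,
                      cfg: GeneratorConfig, rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (clean series in internal units, truth rows) for one patient."""
    interval = cfg.sampling_interval_s
    duration_s = rng.uniform(*cfg.duration_minutes) * 60.0
    n = int(duration_s / interval) + 1
    t = start + pd.to_timedelta(np.arange(n) * interval, unit="s")

    ci_set = float(np.clip(rng.normal(cfg.ci_setpoint_mean, cfg.ci_setpoint_sd), 1.8, 2.8))
    walk = np.cumsum(rng.normal(0.0, cfg.ci_walk_sd, n))
    ci = (ci_set + walk + rng.normal(0.0, cfg.ci_noise_sd, n)) * _episode_mask(
        n, interval, cfg, rng)
    ci = np.clip(ci, 0.8, 3.2)
    flow = ci * bsa

    hb0 = float(np.clip(rng.normal(cfg.hb_start_mean, cfg.hb_start_sd), 8.5, 14.0))
    elapsed = np.arange(n) * interval
    dilution = cfg.hb_dilution_drop * (1.0 - np.exp(-elapsed / 600.0))
    hb = np.clip(hb0 - dilution + np.cumsum(rng.normal(0.0, cfg.hb_walk_sd, n)), 7.0, 14.5)

    sao2 = np.clip(rng.normal(cfg.sao2_mean, cfg.sao2_sd)
                   + rng.normal(0.0, 0.001, n), 0.94, 1.0)
    pao2 = np.clip(rng.normal(cfg.pao2_mean, cfg.pao2_sd)
                   + rng.normal(0.0, 15.0, n), 80.0, 500.0)

    # mixed-venous saturation from a latent consumption via inverse Fick:
    # CvO2 = CaO2 - VO2i/(10*CI); low flow raises extraction, lowering SvO2
    vo2i = np.clip(rng.normal(cfg.vo2i_mean, cfg.vo2i_sd)
                   + rng.normal(0.0, 3.0, n), 60.0, 160.0)
    cao2 = physiology.arterial_o2_content(hb, sao2, pao2, validate=False)
    cvo2 = cao2 - vo2i / (10.0 * ci)
    svo2 = (cvo2 - physiology.DEFAULT_CONSTANTS.dissolved_o2_coeff * cfg.pvo2) / (
        physiology.DEFAULT_CONSTANTS.hb_o2_capacity * hb)
    svo2 = np.clip(svo2, 0.25, sao2)

    mean_map = 60.0 + 18.0 * (ci - 2.0) + rng.normal(5.0, 6.0)
    map_ = np.clip(mean_map + rng.normal(0.0, 4.0, n), 35.0, 110.0)

    clean = pd.DataFrame({
        "timestamp": t, "patient_id": pid, "flow": flow, "hb": hb,
        "sao2": sao2, "svo2": svo2, "pao2": pao2, "map": map_,
    })
    do2i_true = physiology.do2i(flow, bsa, hb, sao2, pao2, validate=False)
    truth = pd.DataFrame({
        "patient_id": pid, "timestamp": t, "do2i_true": do2i_true,
        "below_do2i_min": do2i_true < 280.0,
    })
    return clean, truth


def _corrupt(clean: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    n = len(clean)
    df = clean.copy()

    n_missing = int(round(cfg.missing_cell_rate * n * len(MEASUREMENT_COLUMNS)))
    if n_missing:
        flat = rng.choice(n * len(MEASUREMENT_COLUMNS), size=n_missing, replace=False)
        rows, cols = np.divmod(flat, len(MEASUREMENT_COLUMNS))
        vals = df[MEASUREMENT_COLUMNS].to_numpy()
        vals[rows, cols] = np.nan
        df[MEASUREMENT_COLUMNS] = vals

    n_dup = int(round(cfg.duplicate_row_rate * n))
    dup = df.iloc[rng.choice(n, size=n_dup, replace=False)] if n_dup else df.iloc[:0]

    n_empty = int(round(cfg.empty_row_rate * n))
    if n_empty:
        # placed at half-tick offsets so timestamps never collide with real rows
        picks = rng.choice(n - 1, size=min(n_empty, n - 1), replace=False) if n > 1 else []
        empty = pd.DataFrame({
            "timestamp": clean["timestamp"].iloc[picks].to_numpy()
            + pd.to_timedelta(cfg.sampling_interval_s / 2.0, unit="s"),
            "patient_id": clean["patient_id"].iloc[0],
        })
        for c in MEASUREMENT_COLUMNS:
            empty[c] = np.nan
        n_empty = len(empty)
    else:
        empty = df.iloc[:0]

    out = pd.concat([df, dup, empty], ignore_index=True)
    out = out.sort_values("timestamp", kind="stable", ignore_index=True)
    counts = {"n_rows_clean": n, "n_duplicates": n_dup,
              "n_empty": n_empty, "n_missing_cells": n_missing}
    return out, counts


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort described by *config*.

    Returns a :class:`Cohort` whose ``series`` map patient id to the raw
    (corrupted) time-series table in internal units, and whose ``ledger``
    records both the injected corruption and the pre-corruption DO2i
    ground truth for every real row.
    """
    cfg = config or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root)
    profiles = _sample_profiles(cfg, rng)

    base_start = pd.Timestamp("2017-06-01 08:00:00")
    series: dict[str, pd.DataFrame] = {}
    truths, counts = [], []
    for i, (pid, bsa) in enumerate(zip(profiles["patient_id"], profiles["bsa"])):
        prng = np.random.default_rng(root.spawn(1)[0])
        start = base_start + pd.Timedelta(days=i)
        clean, truth = _generate_patient(pid, float(bsa), start, cfg, prng)
        corrupted, c = _corrupt(clean, cfg, prng)
        series[pid] = corrupted
        truths.append(truth)
        counts.append({"patient_id": pid, **c})

    per_patient = pd.DataFrame(
        counts, columns=["patient_id", "n_rows_clean", "n_duplicates",
                         "n_empty", "n_missing_cells"])
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=["patient_id", "timestamp",
                                        "do2i_true", "below_do2i_min"]))
    return Cohort(profiles=profiles, series=series,
                  ledger=CorruptionLedger(per_patient=per_patient, truth=truth),
                  config=cfg)


_DATA_DICTIONARY = """\
# Raw CPB workbook — data dictionary

One CSV per patient (`<patient_id>.csv`), one row per monitor tick.

| column      | unit        | description                                   |
|-------------|-------------|-----------------------------------------------|
| timestamp   | ISO-8601    | sample time, one row per sampling tick        |
| patient_id  | —           | joins to demographics.csv                     |
| flow_lpm    | L/min       | arterial pump flow                            |
| hb_gdl      | g/dL        | haemoglobin concentration                     |
| sao2_pct    | %           | arterial oxygen saturation                    |
| svo2_pct    | %           | mixed venous oxygen saturation                |
| pao2_mmhg   | mmHg        | arterial oxygen tension                       |
| map_mmhg    | mmHg        | mean arterial pressure                        |

`demographics.csv`: patient_id, age (years), sex (M/F), bsa (m^2), bmi,
procedure. Empty measurement cells are missing readings; fully empty rows
and duplicated rows may occur and are removed by the platform cleaning
stage.
"""


def write_raw_workbook(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write the cohort as raw CSV files under *directory*.

    One time-series CSV per patient in the documented dialect
    (saturations in percent), a ``demographics.csv``, and a
    ``data_dictionary.md``.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pid, df in cohort.series.items():
        out = pd.DataFrame({
            "timestamp": df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.%f")
                                        .str.replace(r"\.000000$", "", regex=True),
            "patient_id": df["patient_id"],
            "flow_lpm": df["flow"],
            "hb_gdl": df["hb"],
            "sao2_pct": df["sao2"] * 100.0,
            "svo2_pct": df["svo2"] * 100.0,
            "pao2_mmhg": df["pao2"],
            "map_mmhg": df["map"],
        })
        path = directory / f"{pid}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    demo = directory / "demographics.csv"
    cohort.profiles.to_csv(demo, index=False)
    written.append(demo)
    dd = directory / "data_dictionary.md"
    dd.write_text(_DATA_DICTIONARY)
    written.append(dd)
    return written
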