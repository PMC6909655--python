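"""Build the common analysis platform from raw per-patient CPB files.

The raw workbook (one CSV per patient, see the data dictionary written
by :mod:`gdperf.synthetic`) is merged into a single time-indexed table,
scrubbed of duplicated and fully empty rows, short gaps are linearly
interpolated within patient, and the derived oxygen-transport columns
(CI, DO2i, O2ER) are computed through :mod:`gdperf.physiology`.

Every stage returns a new DataFrame plus a small report object so that
row accounting (ingested = cleaned + duplicates + empty) can be verified
against the generator's corruption ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import physiology
from .synthetic import MEASUREMENT_COLUMNS

__all__ = [
    "CleanReport",
    "InterpolationReport",
    "ingest_and_merge",
    "clean",
    "interpolate_gaps",
    "derive_columns",
    "DERIVED_COLUMNS",
]

DERIVED_COLUMNS = ["ci", "do2i", "o2er"]

_RAW_TO_INTERNAL = {
    "flow_lpm": "flow", "hb_gdl": "hb", "sao2_pct": "sao2",
    "svo2_pct": "svo2", "pao2_mmhg": "pao2", "map_mmhg": "map",
}
_PERCENT_COLUMNS = ("sao2", "svo2")


@dataclass(frozen=True)
class CleanReport:
    """Row accounting for one cleaning pass."""

    n_in: int
    n_exact_duplicates: int
    n_empty: int
    n_key_ties: int
    n_out: int

    @property
    def n_duplicates(self) -> int:
        """All rows removed as duplications (exact copies plus key ties)."""
        return self.n_exact_duplicates + self.n_key_ties

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InterpolationReport:
    n_cells_filled: int
    n_cells_left_missing: int

    def to_dict(self) -> dict:
        return asdict(self)


def ingest_and_merge(directory: str | Path) -> pd.DataFrame:
    """Read every patient CSV under *directory* into one merged table.

    Timestamps are parsed strictly: an unparseable value raises
    ``ValueError`` naming the file and line.  Patient ids appearing in a
    time series but absent from ``demographics.csv`` are a join failure.
    Row provenance (source file and 1-based data row) is retained.
    """
    directory = Path(directory)
    demo_path = directory / "demographics.csv"
    if not demo_path.exists():
        raise FileNotFoundError(f"missing demographics file: {demo_path}")
    demographics = pd.read_csv(demo_path)
    known = set(demographics["patient_id"].astype(str))

    frames = []
    for path in sorted(directory.glob("*.csv")):
        if path.name == "demographics.csv":
            continue
        raw = pd.read_csv(path)
        missing = {"timestamp", "patient_id"} - set(raw.columns)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
        ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="mixed")
        if ts.isna().any():
            i = int(ts.isna().idxmax())
            raise ValueError(
                f"{path}, line {i + 2}: unparseable timestamp "
                f"{raw['timestamp'].iloc[i]!r}")
        unknown = set(raw["patient_id"].astype(str)) - known
        if unknown:
            raise ValueError(
                f"{path}: patient id(s) {sorted(unknown)} not in demographics.csv")
        df = pd.DataFrame({"timestamp": ts, "patient_id": raw["patient_id"].astype(str)})
        for src, dst in _RAW_TO_INTERNAL.items():
            col = pd.to_numeric(raw[src], errors="coerce") if src in raw else np.nan
            df[dst] = col / 100.0 if dst in _PERCENT_COLUMNS else col
        df["source_file"] = path.name
        df["source_row"] = np.arange(1, len(raw) + 1)
        frames.append(df)

    if not frames:
        cols = ["timestamp", "patient_id", *MEASUREMENT_COLUMNS,
                "source_file", "source_row"]
        return pd.DataFrame(columns=cols)
    merged = pd.concat(frames, ignore_index=True)
    return merged.sort_values(["patient_id", "timestamp"],
                              kind="stable", ignore_index=True)


def clean(dataset: pd.DataFrame) -> tuple[pd.DataFrame, CleanReport]:
    """Remove duplicated and fully empty rows; idempotent.

    Timestamps are normalised (floored) to whole seconds first.  A
    duplicate is a row identical to an earlier one in timestamp, patient
    and every measurement field; remaining same-key rows with differing
    values keep the first occurrence.  A row is empty when every
    measurement field is missing.
    """
    df = dataset.copy()
    n_in = len(df)
    if n_in == 0:
        return df, CleanReport(0, 0, 0, 0, 0)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.floor("s")
    df = df.sort_values(["patient_id", "timestamp"], kind="stable", ignore_index=True)

    subset = ["patient_id", "timestamp", *MEASUREMENT_COLUMNS]
    exact = df.duplicated(subset=subset, keep="first")
    df = df.loc[~exact]

    empty = df[MEASUREMENT_COLUMNS].isna().all(axis=1)
    df = df.loc[~empty]

    ties = df.duplicated(subset=["patient_id", "timestamp"], keep="first")
    df = df.loc[~ties].reset_index(drop=True)

    return df, CleanReport(
        n_in=n_in, n_exact_duplicates=int(exact.sum()),
        n_empty=int(empty.sum()), n_key_ties=int(ties.sum()), n_out=len(df))


def _fill_column(ts: np.ndarray, values: pd.Series, max_gap: float
                 ) -> tuple[pd.Series, np.ndarray]:
    """Linear interpolation in time, interior only, flanks within max_gap."""
    s = values.copy()
    isna = s.isna().to_numpy()
    if not isna.any() or isna.all():
        return s, np.zeros(len(s), bool)
    t = ts.astype("int64") / 1e9  # seconds
    valid = ~isna
    # time of the previous / next valid sample for every row
    prev_t = pd.Series(np.where(valid, t, np.nan)).ffill().to_numpy()
    next_t = pd.Series(np.where(valid, t, np.nan)).bfill().to_numpy()
    fillable = isna & ~np.isnan(prev_t) & ~np.isnan(next_t) & (next_t - prev_t <= max_gap)
    if fillable.any():
        interp = np.interp(t, t[valid], s.to_numpy()[valid])
        out = s.to_numpy(dtype=float)
        out[fillable] = interp[fillable]
        s = pd.Series(out, index=values.index)
    return s, fillable


def interpolate_gaps(dataset: pd.DataFrame, max_gap: float = 120.0
                     ) -> tuple[pd.DataFrame, InterpolationReport]:
    """Fill missing measurement cells by linear interpolation in time.

    Interpolation is strictly within patient and only when the flanking
    measured values are at most *max_gap* seconds apart; leading and
    trailing gaps and long gaps are left missing (and the affected rows
    are later excluded from analysis).  Filled cells are flagged in
    companion ``interpolated_<field>`` columns (0/1).
    """
    df = dataset.copy()
    for col in MEASUREMENT_COLUMNS:
        flag = f"interpolated_{col}"
        if flag not in df.columns:
            df[flag] = 0
    if len(df) == 0:
        return df, InterpolationReport(0, 0)

    n_filled = 0
    for _, idx in df.groupby("patient_id", sort=False).groups.items():
        sub = df.loc[idx]
        ts = sub["timestamp"].to_numpy()
        for col in MEASUREMENT_COLUMNS:
            filled, mask = _fill_column(ts, sub[col], max_gap)
            if mask.any():
                df.loc[idx, col] = filled.to_numpy()
                df.loc[idx, f"interpolated_{col}"] = (
                    df.loc[idx, f"interpolated_{col}"].to_numpy() | mask).astype(int)
                n_filled += int(mask.sum())
    n_left = int(df[MEASUREMENT_COLUMNS].isna().to_numpy().sum())
    return df, InterpolationReport(n_cells_filled=n_filled, n_cells_left_missing=n_left)


def derive_columns(dataset: pd.DataFrame, demographics: pd.DataFrame) -> pd.DataFrame:
    """Attach BSA and compute CI, DO2i and O2ER for every complete row.

    Rows missing any required measurement keep missing derived cells and
    are flagged ``complete = 0``.  The derived values are exactly the
    physiology-module formulas evaluated on the row.
    """
    demo = demographics[["patient_id", "bsa"]].copy()
    demo["patient_id"] = demo["patient_id"].astype(str)
    without = set(dataset["patient_id"].astype(str)) - set(demo["patient_id"])
    if without:
        raise ValueError(f"patient(s) without BSA in demographics: {sorted(without)}")
    if demo["bsa"].isna().any() or (demo["bsa"] <= 0).any():
        bad = demo.loc[demo["bsa"].isna() | (demo["bsa"] <= 0), "patient_id"]
        raise ValueError(f"invalid BSA for patient(s): {sorted(bad)}")

    df = dataset.merge(demo, on="patient_id", how="left")
    df["ci"] = df["flow"] / df["bsa"]
    df["do2i"] = physiology.do2i(
        df["flow"].to_numpy(), df["bsa"].to_numpy(), df["hb"].to_numpy(),
        df["sao2"].to_numpy(), df["pao2"].to_numpy(), validate=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["o2er"] = (df["sao2"] - df["svo2"]) / df["sao2"]
    df["complete"] = df[MEASUREMENT_COLUMNS].notna().all(axis=1).astype(int)
    incomplete = df["complete"] == 0
    df.loc[incomplete, DERIVED_COLUMNS] = np.nan
    return df
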