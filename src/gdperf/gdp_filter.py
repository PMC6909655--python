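"""Goal-directed-perfusion constraint and density filtering.

Two stages, applied in narrative order: first the physiological GDP
constraints (DO2i at least 280 mL/min/m**2, SvO2 above 68 %, MAP above
60 mmHg), then a measurement-density filter that discards rows whose
cardiac-index bin holds fewer than 100 haemoglobin measurements, which
suppresses sparse outlier regions of the (CI, Hb) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["GdpThresholds", "ConstraintReport", "DensityReport",
           "apply_constraints", "density_filter"]


@dataclass(frozen=True)
class GdpThresholds:
    """GDP retention thresholds and density-filter parameters.

    DO2i uses a non-strict bound (rows *at least* ``do2i_min`` are
    kept); SvO2 and MAP are strict (must exceed their minima).
    """

    do2i_min: float = 280.0      # mL/min/m**2
    svo2_min: float = 0.68       # fraction
    map_min: float = 60.0        # mmHg
    ci_bin_width: float = 0.1    # L/min/m**2
    min_bin_count: int = 100     # Hb measurements per CI bin

    def __post_init__(self) -> None:
        for name in ("do2i_min", "svo2_min", "map_min", "ci_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_bin_count < 0:
            raise ValueError("min_bin_count must be non-negative")


@dataclass(frozen=True)
class ConstraintReport:
    """Rows removed per criterion, attributed to the first failing one
    in the order incomplete -> DO2i -> SvO2 -> MAP."""

    n_in: int
    n_out: int
    removed_incomplete: int
    removed_do2i: int
    removed_svo2: int
    removed_map: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DensityReport:
    n_in: int
    n_out: int
    n_bins_total: int
    n_bins_kept: int
    n_removed: int

    def to_dict(self) -> dict:
        return asdict(self)


def apply_constraints(dataset: pd.DataFrame,
                      thresholds: GdpThresholds = GdpThresholds()
                      ) -> tuple[pd.DataFrame, ConstraintReport]:
    """Retain exactly the rows meeting every GDP constraint.

    Keeps rows with ``do2i >= do2i_min`` and ``svo2 > svo2_min`` and
    ``map > map_min``; rows with a missing value in any of the three
    fields are removed as incomplete.  Set-intersection semantics, so
    the operation is idempotent and criterion order only affects the
    removal attribution in the report, never the retained set.
    """
    for col in ("do2i", "svo2", "map"):
        if col not in dataset.columns:
            raise ValueError(f"missing derived column {col!r}; run derive_columns first")
    do2i = dataset["do2i"].to_numpy(dtype=float)
    svo2 = dataset["svo2"].to_numpy(dtype=float)
    map_ = dataset["map"].to_numpy(dtype=float)

    incomplete = np.isnan(do2i) | np.isnan(svo2) | np.isnan(map_)
    ok_do2i = do2i >= thresholds.do2i_min
    ok_svo2 = svo2 > thresholds.svo2_min
    ok_map = map_ > thresholds.map_min
    keep = ~incomplete & ok_do2i & ok_svo2 & ok_map

    fail_do2i = ~incomplete & ~ok_do2i
    fail_svo2 = ~incomplete & ok_do2i & ~ok_svo2
    fail_map = ~incomplete & ok_do2i & ok_svo2 & ~ok_map
    report = ConstraintReport(
        n_in=len(dataset), n_out=int(keep.sum()),
        removed_incomplete=int(incomplete.sum()),
        removed_do2i=int(fail_do2i.sum()),
        removed_svo2=int(fail_svo2.sum()),
        removed_map=int(fail_map.sum()))
    return dataset.loc[keep].reset_index(drop=True), report


def ci_bin_index(ci: np.ndarray, bin_width: float) -> np.ndarray:
    """Left-closed right-open fixed-width bin index for CI values."""
    if bin_width <= 0:
        raise ValueError("ci_bin_width must be strictly positive")
    return np.floor(np.asarray(ci, dtype=float) / bin_width).astype(np.int64)


def density_filter(dataset: pd.DataFrame,
                   thresholds: GdpThresholds = GdpThresholds()
                   ) -> tuple[pd.DataFrame, DensityReport]:
    """Drop rows in sparsely measured cardiac-index bins.

    CI values are binned at ``ci_bin_width``; a row is kept when its bin
    holds at least ``min_bin_count`` rows with a valid Hb measurement.
    Single pass: bin counts are taken once, before any removal.
    """
    if "ci" not in dataset.columns:
        raise ValueError("missing derived column 'ci'; run derive_columns first")
    if len(dataset) == 0:
        return dataset.copy(), DensityReport(0, 0, 0, 0, 0)
    bins = ci_bin_index(dataset["ci"].to_numpy(), thresholds.ci_bin_width)
    has_hb = dataset["hb"].notna().to_numpy()
    counts = pd.Series(bins[has_hb]).value_counts()
    bin_count = pd.Series(bins).map(counts).fillna(0).to_numpy()
    keep = bin_count >= thresholds.min_bin_count
    kept_bins = counts[counts >= thresholds.min_bin_count]
    report = DensityReport(
        n_in=len(dataset), n_out=int(keep.sum()),
        n_bins_total=int(len(np.unique(bins))),
        n_bins_kept=int(len(kept_bins)),
        n_removed=int((~keep).sum()))
    return dataset.loc[keep].reset_index(drop=True), report
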