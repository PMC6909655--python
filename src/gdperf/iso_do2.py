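"""Iso-oxygen-delivery curves: CI as a function of Hb at fixed DO2i.

For each target delivery level (defaults 280, 330 and 380 mL/min/m**2)
the filtered dataset is sliced into an iso-band of rows whose DO2i lies
within a tolerance of the level, each row weighted by a triangular
kernel on its distance to the level.  A weighted degree-2 polynomial of
CI on Hb is then fitted to the band by closed-form least squares.  The
exact physiology gives the hyperbola ``ci = level / (10 * CaO2(hb))``;
the quadratic is its empirical stand-in and the two are compared in the
test-suite oracle checks.

The same inversion powers the bedside calculator
:func:`recommend_flow`: given a haemoglobin, what pump flow keeps DO2i
at the goal-directed-perfusion target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import physiology
from .physiology import PhysioConstants, DEFAULT_CONSTANTS

__all__ = [
    "IsoBand", "QuadraticFit", "FlowRecommendation",
    "extract_band", "fit_quadratic", "closed_form_curve", "recommend_flow",
    "DEFAULT_LEVELS", "DEFAULT_TOLERANCE",
]

DEFAULT_LEVELS = (280.0, 330.0, 380.0)   # mL/min/m**2
DEFAULT_TOLERANCE = 10.0                 # half-width of the iso band

#: reference conditions for closed-form curves: fully saturated blood,
#: dissolved oxygen neglected
REFERENCE_SAO2 = 1.0
REFERENCE_PAO2 = 0.0


@dataclass
class IsoBand:
    """Rows of the dataset within ``tolerance`` of one DO2i level.

    ``weights`` follow a triangular kernel, 1 at the level and falling
    linearly to 0 at the band edge; zero-weight boundary rows are not
    members, so all weights lie in (0, 1].
    """

    level: float
    tolerance: float
    data: pd.DataFrame = field(repr=False)   # columns ci, hb, do2i
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.weights):
            raise ValueError("weights must align with band rows")
        if len(self.weights) and not ((self.weights > 0) & (self.weights <= 1)).all():
            raise ValueError("band weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def hb_support(self) -> tuple[float, float]:
        hb = self.data["hb"]
        return float(hb.min()), float(hb.max())


def extract_band(dataset: pd.DataFrame, level: float,
                 tolerance: float = DEFAULT_TOLERANCE) -> IsoBand:
    """Slice the iso-DO2i band at *level* out of a filtered dataset."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    for col in ("ci", "hb", "do2i"):
        if col not in dataset.columns:
            raise ValueError(f"missing column {col!r}")
    dist = (dataset["do2i"] - level).abs()
    if tolerance == 0:
        member = dist == 0
        weights = np.ones(int(member.sum()))
    else:
        member = dist < tolerance          # open at the edge: weight must be > 0
        weights = 1.0 - dist[member].to_numpy() / tolerance
    if not member.any():
        raise ValueError(
            f"insufficient data: no rows within +/-{tolerance} of DO2i {level}")
    data = dataset.loc[member, ["ci", "hb", "do2i"]].reset_index(drop=True)
    return IsoBand(level=float(level), tolerance=float(tolerance),
                   data=data, weights=np.asarray(weights, dtype=float))


@dataclass
class QuadraticFit:
    """One weighted degree-2 fit ``ci = a0 + a1*hb + a2*hb**2``.

    Evaluation is restricted to the Hb support of the band the fit came
    from; the curve is never extrapolated.
    """

    level: float
    coefficients: tuple[float, float, float]   # (a0, a1, a2)
    n_points: int
    weighted_rss: float
    hb_min: float
    hb_max: float

    def __call__(self, hb, *, extrapolate: bool = False):
        h = np.asarray(hb, dtype=float)
        if not extrapolate and (np.any(h < self.hb_min) or np.any(h > self.hb_max)):
            raise ValueError(
                f"hb outside the fitted domain [{self.hb_min:.3g}, {self.hb_max:.3g}]; "
                "pass extrapolate=True to override")
        a0, a1, a2 = self.coefficients
        out = a0 + a1 * h + a2 * h * h
        return float(out) if np.ndim(hb) == 0 else out

    def derivative(self, hb):
        a0, a1, a2 = self.coefficients
        h = np.asarray(hb, dtype=float)
        out = a1 + 2.0 * a2 * h
        return float(out) if np.ndim(hb) == 0 else out

    def is_decreasing_on_domain(self) -> bool:
        # the derivative of a quadratic is linear: checking both
        # endpoints of the domain covers the whole interval
        return (self.derivative(self.hb_min) < 0) and (self.derivative(self.hb_max) < 0)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "coefficients": list(self.coefficients),
            "n_points": self.n_points,
            "weighted_rss": self.weighted_rss,
            "hb_min": self.hb_min,
            "hb_max": self.hb_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticFit":
        return cls(level=d["level"], coefficients=tuple(d["coefficients"]),
                   n_points=d["n_points"], weighted_rss=d["weighted_rss"],
                   hb_min=d["hb_min"], hb_max=d["hb_max"])


MIN_DISTINCT_HB = 10


def fit_quadratic(band: IsoBand) -> QuadraticFit:
    """Weighted least-squares degree-2 fit of CI on Hb over the band.

    Solved in closed form on the sqrt-weighted design matrix; fully
    deterministic.  Requires at least ``MIN_DISTINCT_HB`` distinct Hb
    values; a rank-deficient design (e.g. all Hb equal) is unfittable.
    """
    hb = band.data["hb"].to_numpy(dtype=float)
    ci = band.data["ci"].to_numpy(dtype=float)
    if len(np.unique(hb)) < MIN_DISTINCT_HB:
        raise ValueError(
            f"band at level {band.level:g} has fewer than {MIN_DISTINCT_HB} "
            "distinct Hb values; unfittable")
    X = np.column_stack([np.ones_like(hb), hb, hb * hb])
    sw = np.sqrt(band.weights)
    Xw, yw = X * sw[:, None], ci * sw
    if np.linalg.matrix_rank(Xw) < 3:
        raise ValueError(f"band at level {band.level:g} is rank deficient; unfittable")
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = ci - X @ coef
    rss = float(np.sum(band.weights * resid * resid))
    lo, hi = band.hb_support
    return QuadraticFit(level=band.level, coefficients=tuple(float(c) for c in coef),
                        n_points=len(band), weighted_rss=rss, hb_min=lo, hb_max=hi)


def fit_all_levels(dataset: pd.DataFrame,
                   levels: tuple[float, ...] = DEFAULT_LEVELS,
                   tolerance: float = DEFAULT_TOLERANCE) -> list[QuadraticFit]:
    """Extract and fit the iso-band at every requested level."""
    return [fit_quadratic(extract_band(dataset, lvl, tolerance)) for lvl in levels]


def save_fits(fits: list[QuadraticFit], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([f.to_dict() for f in fits], indent=2))
    return path


def load_fits(path: str | Path) -> list[QuadraticFit]:
    return [QuadraticFit.from_dict(d) for d in json.loads(Path(path).read_text())]


def closed_form_curve(level: float, sao2: float = REFERENCE_SAO2,
                      pao2: float = REFERENCE_PAO2,
                      constants: PhysioConstants = DEFAULT_CONSTANTS
                      ) -> Callable[[np.ndarray], np.ndarray]:
    """The exact iso-DO2i hyperbola ``hb -> required CI`` at *level*.

    Strictly decreasing and convex in Hb; tends to 0 as Hb grows.
    """
    if level < 0:
        raise ValueError("level must be non-negative")

    def curve(hb):
        # mathematical curve: no physiologic range validation, so it can
        # be evaluated in limits (hb -> infinity gives ci -> 0)
        return physiology.required_ci(level, hb, sao2, pao2, constants,
                                      validate=False)

    return curve


@dataclass(frozen=True)
class FlowRecommendation:
    """Pump-flow advice meeting a DO2i target at the current Hb."""

    level: float
    hb: float
    sao2: float
    pao2: float
    bsa: float
    ci: float          # L/min/m**2, full precision
    flow: float        # L/min, full precision

    @property
    def ci_rounded(self) -> float:
        return round(self.ci, 1)

    @property
    def flow_rounded(self) -> float:
        return round(self.flow, 1)

    def __str__(self) -> str:
        return (f"DO2i target {self.level:g} mL/min/m^2 at Hb {self.hb:g} g/dL: "
                f"CI >= {self.ci_rounded:.1f} L/min/m^2 "
                f"(pump flow {self.flow_rounded:.1f} L/min at BSA {self.bsa:g} m^2)")


def recommend_flow(hb: float, bsa: float, level: float = 280.0,
                   sao2: float = REFERENCE_SAO2, pao2: float = REFERENCE_PAO2
                   ) -> FlowRecommendation:
    """Minimum pump flow sustaining *level* mL/min/m**2 of oxygen delivery.

    The cardiac index is the closed-form inversion of the delivery
    equation and the flow is ``ci * bsa``; values are carried at full
    precision and rounded to 0.1 only for display.
    """
    ci = physiology.required_ci(level, hb, sao2, pao2)
    return FlowRecommendation(level=float(level), hb=float(hb), sao2=float(sao2),
                              pao2=float(pao2), bsa=float(bsa),
                              ci=float(ci), flow=float(ci) * float(bsa))
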