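"""Cohort summary tables and the standard figures.

Figures are by-products of arrays the pipeline already holds; every
scientific claim a figure makes (colour ordering, the arch-shaped cut
left by the DO2i filter, iso-curve ordering) is asserted in the test
suite on the underlying arrays, never on pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .iso_do2 import QuadraticFit

__all__ = ["CohortSummary", "cohort_table", "scatter_do2i", "plot_iso_curves"]

_CMAP = "viridis"          # sequential: darker shades = lower DO2i
_FIGSIZE = (7.0, 5.0)
_MAX_POINTS = 20000        # scatter down-sampling cap, for tractable vector output


@dataclass(frozen=True)
class CohortSummary:
    """Demographic summary mirroring a standard Table-1 layout."""

    n: int
    age_mean: float
    age_sd: float
    male_n: int
    male_pct: float
    bsa_mean: float
    bsa_sd: float
    bmi_mean: float
    bmi_sd: float
    procedure_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Number of patients (n)", f"{self.n}"),
            ("Age (years), mean +/- SD", f"{self.age_mean:.1f} +/- {self.age_sd:.1f}"),
            ("Gender male, n (%)", f"{self.male_n} ({self.male_pct:.1f})"),
            ("Body surface area (m^2), mean +/- SD",
             f"{self.bsa_mean:.2f} +/- {self.bsa_sd:.2f}"),
            ("Body mass index, mean +/- SD",
             f"{self.bmi_mean:.2f} +/- {self.bmi_sd:.2f}"),
        ]
        rows += [(f"Type of surgery: {name}, n (%)",
                  f"{cnt} ({100.0 * cnt / self.n:.1f})")
                 for name, cnt in self.procedure_counts.items()]
        return pd.DataFrame(rows, columns=["characteristic", "value"])

    def to_text(self) -> str:
        frame = self.to_frame()
        width = frame["characteristic"].str.len().max() + 2
        return "\n".join(f"{c:<{width}}{v}" for c, v in frame.itertuples(index=False))


def cohort_table(profiles: pd.DataFrame) -> CohortSummary:
    """Summarise a demographics table (one row per patient)."""
    if len(profiles) == 0:
        raise ValueError("no patient profiles to summarise")
    n = len(profiles)
    male = int((profiles["sex"] == "M").sum())
    sd = lambda s: float(s.std(ddof=1)) if n > 1 else 0.0
    counts = (profiles["procedure"].value_counts().to_dict()
              if "procedure" in profiles.columns else {})
    return CohortSummary(
        n=n,
        age_mean=float(profiles["age"].mean()), age_sd=sd(profiles["age"]),
        male_n=male, male_pct=100.0 * male / n,
        bsa_mean=float(profiles["bsa"].mean()), bsa_sd=sd(profiles["bsa"]),
        bmi_mean=float(profiles["bmi"].mean()), bmi_sd=sd(profiles["bmi"]),
        procedure_counts={str(k): int(v) for k, v in counts.items()})


def _subsample(df: pd.DataFrame, max_points: int, seed: int = 0) -> pd.DataFrame:
    if len(df) <= max_points:
        return df
    return df.sample(n=max_points, random_state=seed)


def scatter_do2i(dataset: pd.DataFrame, stage: str, out_path: str | Path,
                 max_points: int = _MAX_POINTS) -> list[Path]:
    """Hb-vs-CI scatter coloured by DO2i (darker = lower); SVG + PNG.

    *stage* ('full' or 'filtered') only labels the figure; on filtered
    data the DO2i constraint leaves the characteristic arch-shaped lower
    cut along the iso-280 hyperbola.
    """
    import matplotlib.pyplot as plt

    pts = dataset.dropna(subset=["hb", "ci", "do2i"])
    if len(pts) == 0:
        raise ValueError("empty dataset: nothing to plot")
    pts = _subsample(pts, max_points)
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    sc = ax.scatter(pts["hb"], pts["ci"], c=pts["do2i"], cmap=_CMAP,
                    s=4, alpha=0.5, linewidths=0, rasterized=True)
    fig.colorbar(sc, ax=ax, label="DO$_2$i (mL/min/m$^2$)")
    ax.set_xlabel("Haemoglobin (g/dL)")
    ax.set_ylabel("Cardiac index (L/min/m$^2$)")
    ax.set_title(f"Oxygen delivery on bypass ({stage} dataset)")
    return _save(fig, out_path)


def plot_iso_curves(fits: list[QuadraticFit], dataset: pd.DataFrame | None,
                    out_path: str | Path, max_points: int = _MAX_POINTS) -> list[Path]:
    """The fitted iso-DO2i curves, each clipped to its own Hb domain."""
    import matplotlib.pyplot as plt

    if not fits:
        raise ValueError("no fits to plot")
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    if dataset is not None and len(dataset):
        pts = _subsample(dataset.dropna(subset=["hb", "ci"]), max_points)
        ax.scatter(pts["hb"], pts["ci"], s=2, alpha=0.15, color="grey",
                   linewidths=0, rasterized=True)
    for f in sorted(fits, key=lambda f: f.level):
        hb = np.linspace(f.hb_min, f.hb_max, 200)
        ax.plot(hb, f(hb), label=f"DO$_2$i = {f.level:g} mL/min/m$^2$")
    ax.set_xlabel("Haemoglobin (g/dL)")
    ax.set_ylabel("Cardiac index (L/min/m$^2$)")
    ax.set_title("Iso-oxygen-delivery curves (weighted quadratic fits)")
    ax.legend()
    return _save(fig, out_path)


def _save(fig, out_path: str | Path) -> list[Path]:
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("svg", "png"):
        p = out_path.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths
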