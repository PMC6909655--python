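"""End-to-end orchestration: simulate -> platform -> filter -> fit -> recommend -> plot.

Stages communicate through files under the run directory so that any
stage can be re-run or tested in isolation; ``manifest.json`` records
the configuration hash, the seed, and input/output row counts of every
stage, which makes two runs with the same config and seed comparable
manifest-for-manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gdp_filter, iso_do2, platform, reporting, synthetic
from .config import RunConfig, config_hash, save_config

__all__ = ["run_all"]

log = logging.getLogger("gdperf")


def _stage(manifest: dict, name: str, n_in: int, n_out: int, outputs: list) -> None:
    manifest["stages"].append({
        "name": name, "rows_in": int(n_in), "rows_out": int(n_out),
        "outputs": [str(Path(p).name) for p in outputs]})
    log.info("stage %-14s rows %8d -> %8d", name, n_in, n_out)


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure propagates as ``RuntimeError`` naming the stage.
    Identical config + seed give an identical manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "seed": config.seed,
                      "stages": []}
    save_config(config, out / "config.yaml")

    stage = "simulate"
    try:
        cohort = synthetic.generate_cohort(config.generator)
        raw_dir = out / "raw"
        files = synthetic.write_raw_workbook(cohort, raw_dir)
        _stage(manifest, stage, 0, cohort.n_rows, files[-2:])

        stage = "build-platform"
        merged = platform.ingest_and_merge(raw_dir)
        cleaned, clean_rep = platform.clean(merged)
        interped, interp_rep = platform.interpolate_gaps(cleaned, config.max_gap_s)
        demographics = pd.read_csv(raw_dir / "demographics.csv")
        derived = platform.derive_columns(interped, demographics)
        platform_csv = out / "platform.csv"
        derived.to_csv(platform_csv, index=False)
        accounting = {"clean": clean_rep.to_dict(),
                      "interpolation": interp_rep.to_dict()}
        (out / "platform_accounting.json").write_text(json.dumps(accounting, indent=2))
        _stage(manifest, stage, len(merged), len(derived), [platform_csv])

        stage = "filter"
        constrained, c_rep = gdp_filter.apply_constraints(derived, config.thresholds)
        filtered, d_rep = gdp_filter.density_filter(constrained, config.thresholds)
        filtered_csv = out / "filtered.csv"
        filtered.to_csv(filtered_csv, index=False)
        (out / "filter_report.json").write_text(json.dumps(
            {"constraints": c_rep.to_dict(), "density": d_rep.to_dict()}, indent=2))
        _stage(manifest, stage, len(derived), len(filtered), [filtered_csv])

        stage = "fit"
        fits = iso_do2.fit_all_levels(filtered, config.iso_levels, config.iso_tolerance)
        fits_json = iso_do2.save_fits(fits, out / "iso_fits.json")
        _stage(manifest, stage, len(filtered), len(fits), [fits_json])

        stage = "recommend"
        start, stop, step = config.recommend_hb_grid
        hb_grid = np.arange(start, stop + step / 2, step)
        bsa = float(config.generator.bsa_mean)
        rows = [{"level": lvl, "hb": float(h),
                 "ci_required": iso_do2.recommend_flow(h, bsa, lvl).ci_rounded,
                 "flow_at_mean_bsa": iso_do2.recommend_flow(h, bsa, lvl).flow_rounded}
                for lvl in config.iso_levels for h in hb_grid]
        rec_csv = out / "recommendations.csv"
        pd.DataFrame(rows).to_csv(rec_csv, index=False)
        _stage(manifest, stage, len(fits), len(rows), [rec_csv])

        stage = "plot"
        figs = []
        figs += reporting.scatter_do2i(derived, "full", out / "fig_full_scatter")
        figs += reporting.scatter_do2i(filtered, "filtered", out / "fig_filtered_scatter")
        figs += reporting.plot_iso_curves(fits, filtered, out / "fig_iso_curves")
        summary = reporting.cohort_table(cohort.profiles)
        (out / "cohort_table.txt").write_text(summary.to_text() + "\n")
        summary.to_frame().to_csv(out / "cohort_table.csv", index=False)
        _stage(manifest, stage, len(filtered), len(figs), figs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
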