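"""End-to-end pipeline: synthetic panel -> typing -> group statistics.

``run_pipeline`` executes every stage on a synthetic panel, writes
report CSVs (descriptive statistics, factor loadings, cluster summary,
chi-square table) plus a JSON manifest carrying the config hash and seed,
and optionally renders and measures one demo smear image.  Reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import published
from .config import PipelineConfig
from .groupstats import (
    GroupingScheme,
    categorize,
    group_comparison_report,
    subpop_chisq,
)
from .morphometry import measure_image
from .shape import add_shape_columns
from .subpop import type_cells
from .synthetic import (
    FEATURE_COLUMNS,
    ImageSpec,
    MixtureSpec,
    generate_sheep_panel,
    generate_smear_image,
    ground_truth_frame,
)

logger = logging.getLogger("erymorph")

__all__ = ["run_pipeline", "ingest_cells"]

_NUMERIC_POSITIVE = ("outline", "convex", "area", "length", "breadth",
                     "roundness", "form_factor", "contour_index",
                     "ellipticity", "solidity")


class IngestError(ValueError):
    pass


def ingest_cells(path: str | Path) -> pd.DataFrame:
    """Load and validate a per-cell feature CSV.

    The header must contain ``cell_id`` and the 11 morphometric columns
    (``sheep_id`` optional).  Rows with missing values, non-positive size
    measures or breadth > length are rejected with their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in ("cell_id", *FEATURE_COLUMNS) if c not in table.columns]
    if missing:
        raise IngestError(f"{path}: missing columns {missing}")
    bad: list[int] = []
    values = table[list(FEATURE_COLUMNS)]
    bad_mask = values.isna().any(axis=1)
    for col in _NUMERIC_POSITIVE:
        bad_mask |= ~(values[col] > 0)
    bad_mask |= values["elongation"] < 0
    bad_mask |= values["breadth"] > values["length"] * (1 + 1e-9)
    if bad_mask.any():
        # +2: header line and 0- vs 1-based offset
        lines = [int(i) + 2 for i in table.index[bad_mask]]
        raise IngestError(
            f"{path}: {len(lines)} invalid rows at lines {lines[:20]}"
            + ("..." if len(lines) > 20 else "")
        )
    return table


def _descriptive_report(cells: pd.DataFrame) -> pd.DataFrame:
    """Panel-wide descriptive statistics, one row per variable."""
    rows = []
    for var in FEATURE_COLUMNS:
        x = cells[var].to_numpy(dtype=float)
        rows.append(
            {
                "variable": var,
                "mean": x.mean(),
                "median": float(np.median(x)),
                "sd": x.std(ddof=1),
                "cv_pct": 100.0 * x.std(ddof=1) / x.mean(),
                "min": x.min(),
                "max": x.max(),
            }
        )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all reports under ``config.output_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "outputs": {},
        "timings_s": {},
    }

    def record(stage: str, name: str, path: Path, t_start: float) -> None:
        manifest["outputs"][name] = str(path)
        manifest["timings_s"][stage] = round(time.time() - t_start, 3)
        logger.info("%s -> %s (%.2fs)", stage, path, time.time() - t_start)

    # --- synthetic panel ---------------------------------------------------
    t = time.time()
    sheep, cells, true_labels = generate_sheep_panel(
        config.n_sheep, config.cells_per_sheep, seed=int(rng.integers(2**31)),
        mix=MixtureSpec(),
    )
    _write_csv(sheep, out / "sheep.csv")
    _write_csv(cells, out / "cells.csv")
    record("synthetic_panel", "cells", out / "cells.csv", t)
    manifest["outputs"]["sheep"] = str(out / "sheep.csv")

    # --- demo smear image: render, segment, measure ------------------------
    if config.demo_image:
        t = time.time()
        spec = ImageSpec(
            calibration=config.calibration, n_cells=config.demo_image_cells,
            n_debris=2,
        )
        img, truth = generate_smear_image(spec, seed=int(rng.integers(2**31)))
        iio.imwrite(out / "demo_smear.png", img)
        _write_csv(ground_truth_frame(truth), out / "demo_smear_truth.csv")
        measured = measure_image(
            img, config.calibration, config.segmentation(), image_id="demo"
        )
        measured = add_shape_columns(measured)
        _write_csv(measured, out / "demo_smear_measurements.csv")
        record("demo_image", "demo_measurements",
               out / "demo_smear_measurements.csv", t)

    # --- descriptive statistics (per-cell, whole panel) ---------------------
    t = time.time()
    _write_csv(_descriptive_report(cells), out / "descriptives.csv")
    record("descriptives", "descriptives", out / "descriptives.csv", t)

    # --- subpopulation typing ----------------------------------------------
    t = time.time()
    model, summary, fm = type_cells(
        cells,
        seed=int(rng.integers(2**31)),
        k_range=config.k_range,
        strict_multiplier=config.strict_multiplier,
        min_proportion=config.min_proportion,
    )
    loadings = fm.loadings.copy()
    loadings.insert(0, "variable", loadings.index)
    loadings.loc["eigenvalue"] = ["eigenvalue", *fm.eigenvalues[: fm.n_retained]]
    loadings.loc["explained_pct"] = ["explained_pct", *fm.explained_pct]
    _write_csv(loadings, out / "loadings.csv")
    _write_csv(summary, out / "cluster_summary.csv")
    labeled = cells.copy()
    labeled["es"] = model.es_labels()
    labeled["held_out_strict"] = model.outlier_flags
    _write_csv(labeled, out / "cells_labeled.csv")
    record("typing", "cluster_summary", out / "cluster_summary.csv", t)
    manifest["typing"] = {
        "k": model.k,
        "representatives": list(model.feature_names),
        "retained_factors": fm.n_retained,
    }

    # --- group statistics ---------------------------------------------------
    t = time.time()
    if config.groupings is None:
        schemes = dict(published.GROUPING_SCHEMES)
    else:
        schemes = {
            p: GroupingScheme(p, float(c), r)
            for p, (c, r) in config.groupings.items()
        }
    chisq_rows, cmp_frames = [], []
    for param, scheme in schemes.items():
        glabels = categorize(sheep, scheme)
        cell_groups = labeled["sheep_id"].map(
            dict(zip(sheep["sheep_id"], glabels))
        )
        counts = pd.crosstab(cell_groups, labeled["es"])
        counts = counts.reindex(index=[1, 2],
                                columns=["ES1", "ES2", "ES3"], fill_value=0)
        from .groupstats import ContingencyTable

        tab = ContingencyTable(
            counts.to_numpy(), (f"{param}_1", f"{param}_2"),
            ("ES1", "ES2", "ES3"),
        )
        chi2, df, p = subpop_chisq(tab)
        pct = 100.0 * tab.counts / tab.counts.sum(axis=1, keepdims=True)
        for i, row_label in enumerate(tab.row_labels):
            chisq_rows.append(
                {
                    "parameter": param,
                    "group": row_label,
                    "n_cells": int(tab.counts[i].sum()),
                    "ES1_pct": pct[i, 0],
                    "ES2_pct": pct[i, 1],
                    "ES3_pct": pct[i, 2],
                    "chi2": chi2,
                    "df": df,
                    "p": p,
                }
            )
        cmp_frames.append(
            group_comparison_report(
                labeled, sheep, scheme, list(FEATURE_COLUMNS)
            )
        )
    _write_csv(pd.DataFrame(chisq_rows), out / "subpop_chisq.csv")
    _write_csv(pd.concat(cmp_frames, ignore_index=True),
               out / "group_comparison.csv")
    record("group_stats", "subpop_chisq", out / "subpop_chisq.csv", t)

    manifest["total_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
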