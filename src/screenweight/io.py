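"""CSV contracts, run configuration and the full analysis pipeline.

All tables are UTF-8 CSV with "." as decimal separator and empty cells for
missing values.  The pipeline mirrors the two-step procedure: decompose
screen times per group-by-scale cell, derive attentiveness weights, fit the
multi-group GPCM per scale with and without the attentiveness adjustment,
run the validity checks, optionally regress C/IER proportions on scale
characteristics, and write a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import betareg, gpcm, timing, validity
from .exceptions import SchemaError

logger = logging.getLogger(__name__)

SCREEN_RECORD_COLUMNS = ["respondent_id", "group_id", "scale_id",
                         "time_seconds", "n_items", "sampling_weight"]


@dataclasses.dataclass
class RowError:
    line: int
    message: str


def read_screen_records(path):
    """Read and validate the long-format screen-record CSV.

    Returns ``(records, errors)``: a typed DataFrame of the valid rows and a
    list of :class:`RowError` for rejected rows (negative/unparseable time,
    non-positive weight or item count).  Missing or zero times are kept --
    the decomposition assigns them weight 1 and a "not assessed" flag.

    Raises :class:`SchemaError` if a required column is absent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCREEN_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)

    def numeric(col, required):
        raw = df[col].str.strip()
        empty = raw == ""
        vals = pd.to_numeric(raw.where(~empty), errors="coerce")
        bad = (~empty) & vals.isna()
        for i in np.nonzero(bad.to_numpy())[0]:
            errors.append(RowError(i + 2, f"unparseable {col}: {raw.iloc[i]!r}"))
            keep[i] = False
        if required:
            for i in np.nonzero(empty.to_numpy())[0]:
                errors.append(RowError(i + 2, f"missing {col}"))
                keep[i] = False
        return vals

    t = numeric("time_seconds", required=False)   # empty => not assessed
    j = numeric("n_items", required=True)
    v = numeric("sampling_weight", required=True)

    for i in np.nonzero((t < 0).to_numpy())[0]:
        if keep[i]:
            errors.append(RowError(i + 2, "negative time_seconds"))
            keep[i] = False
    for i in np.nonzero(((j < 1) | (j % 1 != 0)).to_numpy())[0]:
        if keep[i]:
            errors.append(RowError(i + 2, "n_items must be a positive integer"))
            keep[i] = False
    for i in np.nonzero((v <= 0).to_numpy())[0]:
        if keep[i]:
            errors.append(RowError(i + 2, "sampling_weight must be positive"))
            keep[i] = False

    out = pd.DataFrame({
        "respondent_id": df["respondent_id"],
        "group_id": df["group_id"],
        "scale_id": df["scale_id"],
        "time_seconds": t,
        "n_items": j,
        "sampling_weight": v,
    })[keep].reset_index(drop=True)
    out["n_items"] = out["n_items"].astype(int)
    for e in errors:
        logger.warning("screen-record row rejected (line %d): %s",
                       e.line, e.message)
    return out, errors


def read_responses_wide(path):
    """Read a wide per-scale response CSV (respondent_id, group_id,
    item_1..item_J; empty cell = missing)."""
    df = pd.read_csv(path)
    for col in ("respondent_id", "group_id"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        raise SchemaError("missing required column(s): item_1..item_J")
    return df


def read_scale_covariates(path):
    df = pd.read_csv(path)
    required = ["scale_id", "screen_position", "n_items", "n_options",
                "avg_length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def write_csv(df: pd.DataFrame, path):
    # default float repr is shortest-round-trip: lossless read-back
    df.to_csv(path, index=False)


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def summaries_to_json(summaries: dict) -> dict:
    return {f"{g}|{s}": val for (g, s), val in summaries.items()}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    screen_records: str = None
    responses: dict = None           # scale_id -> path of wide CSV
    scale_covariates: str = None
    output_dir: str = "screenweight_out"
    max_components: int = 9
    transform: str = "per-item"      # or "total"
    thresholds: tuple = (2.0, 1.0)
    nt_fraction: float = 0.30
    n_quadrature: int = 61
    betareg_method: str = "ml"       # "ml", "bayes" or "none"
    seed: int = 0
    gpcm_max_cycles: int = 1000
    gpcm_param_tol: float = 1e-5


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-step analysis and write all outputs.

    Returns the report dictionary (also written to ``report.json``).
    Partial outputs are preserved on stage failure; the CLI maps raised
    errors to exit codes.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)

    records, errors = read_screen_records(config.screen_records)
    responses = {sid: read_responses_wide(p)
                 for sid, p in (config.responses or {}).items()}

    # Step 1: screen-time decomposition -> attentiveness weights
    weights_df, summaries = timing.decompose_screen_times(
        records, max_components=config.max_components,
        transform=config.transform, seed=config.seed)
    write_csv(weights_df, out("attentiveness_weights.csv"))
    write_json(summaries_to_json(summaries), out("decompositions.json"))

    report = {
        "seed": config.seed,
        "n_rejected_rows": len(errors),
        "cells": {},
        "scales": {},
    }
    for (g, s), summ in summaries.items():
        dec = summ.get("decomposition")
        report["cells"][f"{g}|{s}"] = {
            "cier_proportion": dec["cier_proportion"] if dec else None,
            "mean_cier_time_per_item":
                dec["mean_cier_time_per_item"] if dec else None,
            "n_components": (summ["selected"]["n_components"]
                             if summ.get("selected") else None),
        }

    # Step 2: weighted vs unweighted multi-group GPCM per scale
    gconf = gpcm.GpcmConfig(n_quadrature=config.n_quadrature,
                            max_cycles=config.gpcm_max_cycles,
                            param_tol=config.gpcm_param_tol)
    comparison_rows = []
    for sid, resp in responses.items():
        item_cols = [c for c in resp.columns if c.startswith("item_")]
        merged = resp.merge(
            weights_df.loc[weights_df["scale_id"] == sid,
                           ["respondent_id", "attentiveness_weight"]],
            on="respondent_id", how="left")
        merged["attentiveness_weight"] = \
            merged["attentiveness_weight"].fillna(1.0)
        srec = records[records["scale_id"] == sid]
        merged = merged.merge(
            srec[["respondent_id", "sampling_weight"]],
            on="respondent_id", how="left")
        merged["sampling_weight"] = merged["sampling_weight"].fillna(1.0)
        keep = ~merged[item_cols].isna().all(axis=1)
        merged = merged[keep]
        data = gpcm.ResponseMatrix.from_dataframe(merged, item_cols)
        v = merged["sampling_weight"].to_numpy(float)
        watt = merged["attentiveness_weight"].to_numpy(float)
        unadj = gpcm.fit_multigroup_gpcm(data, v, gconf)
        adj = gpcm.fit_multigroup_gpcm(data, v * watt, gconf)
        table, summary = gpcm.compare_fits(adj, unadj)
        table.insert(0, "scale_id", sid)
        comparison_rows.append(table)
        report["scales"][sid] = {
            "adjusted": adj.to_dict(), "unadjusted": unadj.to_dict(),
            "comparison": summary,
        }
        if not (adj.converged and unadj.converged):
            report["scales"][sid]["convergence_warning"] = True

    if comparison_rows:
        write_csv(pd.concat(comparison_rows, ignore_index=True),
                  out("gpcm_comparison.csv"))

    # validity checks
    checks = validity.validity_report(weights_df, records, responses,
                                      thresholds=config.thresholds,
                                      nt_fraction=config.nt_fraction)
    write_csv(checks, out("validity_checks.csv"))
    lag_tables = []
    for g, sub in weights_df.groupby("group_id", sort=True):
        piv = sub.pivot_table(index="respondent_id", columns="scale_id",
                              values="posterior_cier")
        if piv.shape[1] >= 2:
            lt = validity.lagged_consistency(piv.to_numpy(float))
            lt.insert(0, "group_id", g)
            lag_tables.append(lt)
    if lag_tables:
        write_csv(pd.concat(lag_tables, ignore_index=True),
                  out("lagged_correlations.csv"))

    # Beta regression of cell C/IER proportions on scale characteristics
    if config.betareg_method != "none" and config.scale_covariates:
        cov = read_scale_covariates(config.scale_covariates)
        rows = []
        for (g, s), summ in summaries.items():
            dec = summ.get("decomposition")
            if dec is None:
                continue
            rows.append({"group_id": g, "scale_id": s,
                         "cier_proportion": dec["cier_proportion"]})
        props = pd.DataFrame(rows).merge(cov, on="scale_id", how="inner")
        if props["group_id"].nunique() >= 2 and len(props) >= 4:
            data = betareg.BetaRegressionData.from_dataframe(props)
            fit = betareg.fit_hierarchical_beta(
                data, betareg.BetaRegConfig(method=config.betareg_method,
                                            seed=config.seed,
                                            keep_draws=False))
            write_json(fit.to_dict(), out("beta_regression.json"))
            report["beta_regression"] = fit.to_dict()
        else:
            logger.warning("too few cells for the Beta regression; skipped")

    write_json(report, out("report.json"))
    return report


def write_simulated(dataset, output_dir):
    """Write a SimulatedDataset to the pipeline's CSV contracts."""
    os.makedirs(output_dir, exist_ok=True)
    paths = {"screen_records": os.path.join(output_dir, "screen_records.csv"),
             "scale_covariates": os.path.join(output_dir,
                                              "scale_covariates.csv"),
             "truth": os.path.join(output_dir, "truth.csv"),
             "responses": {}}
    write_csv(dataset.screen_records, paths["screen_records"])
    write_csv(dataset.scale_covariates, paths["scale_covariates"])
    write_csv(dataset.truth, paths["truth"])
    for sid, df in dataset.responses.items():
        p = os.path.join(output_dir, f"responses_{sid}.csv")
        write_csv(df, p)
        paths["responses"][sid] = p
    return paths
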