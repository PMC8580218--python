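"""Synthesis products and the pipeline driver.

Watershed nitrogen-vs-pathogen comparison (log-log regression with residual
outlier classes), load-concentration tables (how much of the global input
the top-k watersheds carry), and ``run_pipeline`` which drives the whole
model — synthetic world, factors, effluent, watersheds, plumes, habitat
exposure, reports — from a single config and seed, writing a manifest with
per-output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effluent as effluent_mod
from . import factors as factors_mod
from . import habitat as habitat_mod
from . import plume as plume_mod
from . import synth as synth_mod
from . import watersheds as watersheds_mod
from .rasters import write_ascii_grid

logger = logging.getLogger(__name__)


@dataclass
class ComparisonSpec:
    """N-vs-FIO comparison settings: log10-log10 OLS with z-scored residual
    outlier classes (|z| above the threshold = disproportionate N)."""

    z_threshold: float = 2.0


def n_fio_comparison(pourpoints: pd.DataFrame, spec: ComparisonSpec = ComparisonSpec()):
    """Fit log10(N) on log10(FIO) across watersheds and classify residuals.

    Only watersheds with both loads positive enter the fit; the rest are
    labelled ``proportional`` (they carry no signal either way). Returns
    ``(table, fit)`` where fit holds slope, intercept, correlation and the
    residual standard deviation.
    """
    df = pourpoints.copy()
    pos = (df["n_total"] > 0) & (df["fio"] > 0)
    if int(pos.sum()) < 3:
        raise ValueError("need >= 3 watersheds with positive N and FIO")
    log_n = np.log10(df.loc[pos, "n_total"].to_numpy(dtype=float))
    log_fio = np.log10(df.loc[pos, "fio"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(log_fio, log_n, 1)
    fitted = intercept + slope * log_fio
    resid = log_n - fitted
    sd = float(resid.std())
    # a residual sd at rounding-noise level means the fit is exact: no outliers
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(log_n).max()))
    z = resid / sd if not degenerate else np.zeros_like(resid)
    classes = np.full(len(resid), "proportional", dtype="<U12")
    classes[z > spec.z_threshold] = "high_N"
    classes[z < -spec.z_threshold] = "low_N"
    df["log_n"] = np.nan
    df["log_fio"] = np.nan
    df["fitted_log_n"] = np.nan
    df["residual"] = np.nan
    df["outlier_class"] = "proportional"
    df.loc[pos, "log_n"] = log_n
    df.loc[pos, "log_fio"] = log_fio
    df.loc[pos, "fitted_log_n"] = fitted
    df.loc[pos, "residual"] = resid
    df.loc[pos, "outlier_class"] = classes
    corr = float(np.corrcoef(log_fio, log_n)[0, 1]) if len(log_n) > 1 else 1.0
    fit = {
        "slope": float(slope),
        "intercept": float(intercept),
        "correlation": corr,
        "residual_sd": sd,
        "n_fit": int(pos.sum()),
    }
    return df, fit


def concentration_table(pourpoints: pd.DataFrame, k_list=(1, 5, 25)):
    """Cumulative-share curve of watershed N loads, descending.

    Returns a dict with the sorted table (id, n_total, cumulative_share),
    top-k shares for each requested k, and the count of zero-load
    watersheds. Shares are of the global (all-pourpoint) total; with a zero
    global total every share is 0.
    """
    if not len(pourpoints):
        raise ValueError("no pourpoints")
    df = pourpoints[["id", "n_total"]].copy()
    df = df.sort_values(["n_total", "id"], ascending=[False, True]).reset_index(drop=True)
    total = float(df.n_total.sum())
    df["cumulative_share"] = (df.n_total.cumsum() / total) if total > 0 else 0.0
    top_k = {}
    for k in k_list:
        k_eff = min(int(k), len(df))
        top_k[int(k)] = float(df.n_total.iloc[:k_eff].sum() / total) if total > 0 else 0.0
    return {
        "table": df,
        "top_k_share": top_k,
        "n_zero_load": int((pourpoints.n_total == 0).sum()),
        "global_total": total,
    }


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_CONFIG = {
    "seed": 0,
    "world": {},  # WorldConfig fields
    "rates": {},  # RemovalRates fields
    "fio_weights": {},  # FIOWeights fields
    "plume": {},  # PlumeParams fields
    "hotspot": {"quantile": 0.975},
    "proximity_km": 1.0,
    "proximity_sources": ["septic", "direct"],
    "comparison": {"z_threshold": 2.0},
    "top_k": [1, 5, 25],
}


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the full model end to end and write a run directory.

    ``config`` follows :data:`DEFAULT_CONFIG`; unknown keys raise before any
    compute. Outputs: world/ (rasters+tables), factor and audit CSVs,
    effluent/plume .asc rasters, basin/pourpoint/country CSVs, habitat
    summary and comparison CSVs, and ``manifest.json`` with parameters,
    seed, package version and a sha256 per output file. Returns the
    manifest dict.
    """
    from . import __version__

    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])

    world_kwargs = dict(cfg["world"])
    world_kwargs.setdefault("rng_seed", seed)
    world_config = synth_mod.WorldConfig(**world_kwargs)
    world_config.validate()
    rates = factors_mod.RemovalRates(**cfg["rates"]).validate()
    weights = factors_mod.FIOWeights(**cfg["fio_weights"]).validate()
    plume_params = plume_mod.PlumeParams(**cfg["plume"]).validate()
    hotspot_rule = habitat_mod.HotspotRule(**cfg["hotspot"]).validate()
    comparison_spec = ComparisonSpec(**cfg["comparison"])

    os.makedirs(outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    logging.getLogger().addHandler(handler)
    outputs = []

    def emit_csv(df, name):
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False, float_format="%.10g")
        outputs.append(path)

    def emit_raster(arr, name):
        path = os.path.join(outdir, name)
        write_ascii_grid(path, arr, world_config.cell_km)
        outputs.append(path)

    try:
        logger.info("stage synth")
        world = synth_mod.generate_world(world_config)
        synth_mod.write_world(world, os.path.join(outdir, "world"))

        logger.info("stage factors")
        factor_table = factors_mod.build_factor_table(
            world.sanitation, world.regions, world.protein_gdp,
            countries=world.countries, rates=rates, fio_weights=weights,
        )
        emit_csv(factor_table.mixes, "factors.csv")
        emit_csv(factor_table.protein, "protein.csv")
        emit_csv(pd.DataFrame(factor_table.audit, columns=["country", "field", "rule"]),
                 "imputation_audit.csv")

        logger.info("stage effluent")
        grid = effluent_mod.build_effluent_grids(
            world, factor_table, rates=rates, fio_weights=weights,
            proximity_km=float(cfg["proximity_km"]),
            proximity_sources=tuple(cfg["proximity_sources"]),
        )
        for name in ("n_sewered", "n_septic", "n_direct"):
            emit_raster(getattr(grid, name), f"effluent_{name}.asc")
        emit_raster(grid.n_total, "effluent_n_total.asc")
        emit_raster(grid.fio_total, "effluent_fio_total.asc")

        logger.info("stage watersheds")
        sheds = watersheds_mod.delineate(world.dem, world.land)
        sheds = watersheds_mod.aggregate(sheds, grid)
        emit_raster(sheds.labels, "basins.asc")
        emit_csv(sheds.basins, "basin_loads.csv")
        pourpoints = watersheds_mod.pourpoint_loads(sheds, world.country)
        emit_csv(pourpoints, "pourpoints.csv")
        emit_csv(watersheds_mod.country_discharge(pourpoints), "country_discharge.csv")

        logger.info("stage plume")
        field = plume_mod.plume_all(pourpoints, world.ocean, plume_params)
        for name in ("n_sewered", "n_septic", "n_direct"):
            emit_raster(getattr(field, name), f"plume_{name}.asc")
        emit_raster(field.n_total, "plume_n_total.asc")

        logger.info("stage habitat")
        summaries = []
        for kind, feats in world.habitats.items():
            hab = habitat_mod.rasterize_habitat(feats, world.land.shape, world_config.cell_km)
            hab = habitat_mod.overlay_exposure(hab, field)
            if hab.presence.any():
                hab = habitat_mod.flag_hotspots(hab, hotspot_rule)
                emit_raster(hab.hotspot.astype(np.uint8), f"hotspots_{kind}.asc")
            summaries.append({"habitat": kind, **habitat_mod.habitat_summary(hab)})
        if summaries:
            emit_csv(pd.DataFrame(summaries), "habitat_summary.csv")

        logger.info("stage report")
        pos = (pourpoints.n_total > 0) & (pourpoints.fio > 0)
        if int(pos.sum()) >= 3:
            comparison, fit = n_fio_comparison(pourpoints, comparison_spec)
            emit_csv(comparison, "n_fio_comparison.csv")
        else:
            fit = None
        conc = concentration_table(pourpoints, cfg["top_k"])
        emit_csv(conc["table"], "concentration.csv")
    except Exception as exc:
        logging.getLogger().removeHandler(handler)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    logging.getLogger().removeHandler(handler)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {
            "world": dataclasses.asdict(world_config),
            "rates": dataclasses.asdict(rates),
            "fio_weights": dataclasses.asdict(weights),
            "plume": dataclasses.asdict(plume_params),
            "hotspot": dataclasses.asdict(hotspot_rule),
            "proximity_km": float(cfg["proximity_km"]),
            "proximity_sources": list(cfg["proximity_sources"]),
        },
        "fit": fit,
        "top_k_share": conc["top_k_share"],
        "n_zero_load_watersheds": conc["n_zero_load"],
        "global_marine_n_g": conc["global_total"],
        "checksums": {os.path.relpath(p, outdir): _sha256(p) for p in sorted(outputs)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
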