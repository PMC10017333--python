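"""End-to-end orchestration: simulate -> render -> detect -> features ->
fit -> genetics, from one config and one master seed.

The pooled monthly ground samples train one predictor per trait (the
best-validation method is applied to every detected tree each month),
and the monthly genetic series is estimated from the predicted traits,
mirroring a breeding-trial phenotyping campaign.  Every stage seed is
derived deterministically from the master seed, stage artifacts are
flat CSV/JSON files (diffable, re-runnable from any checkpoint), and
two runs with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shapely_mapping

from . import canopy_image, genetics, spectral_indices, synthetic_orchard, trait_models
from .raster import BAND_NAMES, read_stack, write_raster
from .synthetic_orchard import (GeneticConfig, LayoutConfig, OpticsConfig,
                                TerrainConfig, MONTHS)

__all__ = ["PipelineConfig", "run_pipeline", "run_from_rasters", "stage_seed"]

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s(master, stage) mod 2^31."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    """Full run description; round-trips through YAML unchanged."""

    layout: LayoutConfig = LayoutConfig()
    genetics: Mapping[str, GeneticConfig] | None = None
    optics: OpticsConfig | None = None
    terrain: TerrainConfig = TerrainConfig()
    months: tuple[str, ...] = MONTHS
    resolution: float = 0.05
    samples_per_month: int = 35
    calibration_fraction: float = 0.8
    model_grids: Mapping[str, Mapping[str, Sequence]] | None = None
    selection_months: tuple[str, ...] | None = None
    selection_k: int | None = None
    genetics_on: str = "predicted"  # "predicted" (imagery workflow) or "true"

    def resolved(self, master_seed: int) -> "PipelineConfig":
        gen = self.genetics or synthetic_orchard.default_genetics(
            seed=stage_seed(master_seed, "traits"))
        opt = self.optics or OpticsConfig(seed=stage_seed(master_seed, "optics"))
        sel = self.selection_months or tuple(self.months)
        return replace(self, genetics=gen, optics=opt, selection_months=sel)

    # -- YAML (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "layout": asdict(self.layout),
            "genetics": {t: asdict(c) for t, c in (self.genetics or {}).items()} or None,
            "optics": asdict(self.optics) if self.optics else None,
            "terrain": asdict(self.terrain),
            "months": list(self.months),
            "resolution": self.resolution,
            "samples_per_month": self.samples_per_month,
            "calibration_fraction": self.calibration_fraction,
            "model_grids": ({m: {k: list(v) for k, v in g.items()}
                             for m, g in self.model_grids.items()}
                            if self.model_grids else None),
            "selection_months": (list(self.selection_months)
                                 if self.selection_months else None),
            "selection_k": self.selection_k,
            "genetics_on": self.genetics_on,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        layout = d.get("layout")
        if layout:
            layout = dict(layout)
            for key in ("sites", "height_range", "crown_radius_range"):
                if key in layout:
                    layout[key] = tuple(layout[key])
            layout = LayoutConfig(**layout)
        else:
            layout = LayoutConfig()
        gen = d.get("genetics")
        if gen:
            gen = {t: GeneticConfig(**{**c, "bounds": tuple(c["bounds"]) if c.get("bounds") else None})
                   for t, c in gen.items()}
        optics = OpticsConfig(**d["optics"]) if d.get("optics") else None
        terrain = TerrainConfig(**d["terrain"]) if d.get("terrain") else TerrainConfig()
        return cls(layout=layout, genetics=gen, optics=optics, terrain=terrain,
                   months=tuple(d.get("months", MONTHS)),
                   resolution=float(d.get("resolution", 0.05)),
                   samples_per_month=int(d.get("samples_per_month", 35)),
                   calibration_fraction=float(d.get("calibration_fraction", 0.8)),
                   model_grids=d.get("model_grids"),
                   selection_months=(tuple(d["selection_months"])
                                     if d.get("selection_months") else None),
                   selection_k=d.get("selection_k"),
                   genetics_on=d.get("genetics_on", "predicted"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _model_specs(config: PipelineConfig, seed: int) -> dict[str, trait_models.ModelSpec]:
    specs = trait_models.default_specs(seed=seed)
    if config.model_grids:
        for method, grid in config.model_grids.items():
            specs[method] = trait_models.ModelSpec(method, grid, seed=seed)
    return specs


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pine_phenomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 master_seed: int = 0) -> dict:
    """Simulate an orchard campaign and analyze it end to end.

    Writes rasters, ground-truth tables, per-month feature tables and
    genetic summaries, the pooled model comparison, the h2 series, the
    breeding-value trajectories and the selection list under
    ``out_dir``; returns the manifest.  Identical config + seed give
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    try:
        cfg = config.resolved(master_seed)
        manifest = {"version": _VERSION, "master_seed": master_seed,
                    "config": cfg.to_dict(), "stage_seeds": {}, "stages": []}

        def stage(name):
            s = stage_seed(master_seed, name)
            manifest["stage_seeds"][name] = s
            manifest["stages"].append(name)
            logger.info("stage %s (seed %d)", name, s)
            return s

        try:
            # -- generation ------------------------------------------------
            layout = synthetic_orchard.make_layout(cfg.layout, seed=stage("layout"))
            layout.trees.to_csv(out / "layout.csv", index=False)
            traits = synthetic_orchard.simulate_traits(layout, cfg.genetics, cfg.months)
            traits.to_csv(out / "traits_true.csv", index=False)
            refl = synthetic_orchard.simulate_reflectance(traits, cfg.optics)
            refl.to_csv(out / "reflectance_true.csv", index=False)

            seed_gt = stage("ground-sampling")
            gt = pd.concat(
                [synthetic_orchard.sample_ground_truth(
                    traits, m, cfg.samples_per_month, seed=stage_seed(seed_gt, m))
                 for m in cfg.months], ignore_index=True)
            gt.to_csv(out / "ground_truth.csv", index=False)

            stage("render")
            rasters = out / "rasters"
            rasters.mkdir(parents=True, exist_ok=True)
            stack0 = synthetic_orchard.render_rasters(
                layout, refl, cfg.months[0], resolution=cfg.resolution,
                terrain=cfg.terrain)
            write_raster(rasters / "dsm.tif", stack0["dsm"], stack0.transform,
                         stack0.nodata)
            write_raster(rasters / "dtm.tif", stack0["dtm"], stack0.transform,
                         stack0.nodata)
            for month in cfg.months:
                mdir = rasters / month
                stack = (stack0 if month == cfg.months[0] else
                         synthetic_orchard.render_rasters(
                             layout, refl, month, resolution=cfg.resolution,
                             terrain=cfg.terrain))
                mdir.mkdir(parents=True, exist_ok=True)
                for b in BAND_NAMES:
                    write_raster(mdir / f"{b}.tif", stack[b], stack.transform,
                                 stack.nodata)
        except Exception as exc:
            _write_json(out / "manifest.json", {**manifest, "error": str(exc),
                                                "failed_stage": manifest["stages"][-1]
                                                if manifest["stages"] else "setup"})
            raise RuntimeError(
                f"pipeline aborted in stage "
                f"{manifest['stages'][-1] if manifest['stages'] else 'setup'}: {exc}"
            ) from exc

        # stage isolation: the analysis half consumes the files written
        # above (not in-memory objects), so it is re-runnable from disk
        # and byte-identical with run_from_rasters on the same artifacts
        return _analyze(cfg, out, master_seed, manifest,
                        raster_dir=rasters,
                        field=pd.read_csv(out / "layout.csv"),
                        ground_truth=pd.read_csv(out / "ground_truth.csv"))
    finally:
        logging.getLogger("pine_phenomics").removeHandler(handler)
        handler.close()


def run_from_rasters(config: PipelineConfig, raster_dir: str | Path,
                     field_csv: str | Path, ground_truth_csv: str | Path,
                     out_dir: str | Path, master_seed: int = 0) -> dict:
    """Analysis-only entry point for pre-existing rasters.

    ``raster_dir`` holds dsm.tif, dtm.tif and one subdirectory per month
    with the five band GeoTIFFs; ``field_csv`` carries planted tree
    records (tree_id, x, y, family, block, site) and ``ground_truth_csv``
    the long trait measurements.  Consuming rasters written by
    ``run_pipeline`` reproduces its analysis outputs exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    try:
        cfg = config.resolved(master_seed)
        manifest = {"version": _VERSION, "master_seed": master_seed,
                    "config": cfg.to_dict(), "stage_seeds": {}, "stages": []}
        field = pd.read_csv(field_csv)
        gt = pd.read_csv(ground_truth_csv)
        return _analyze(cfg, out, master_seed, manifest,
                        raster_dir=Path(raster_dir), field=field,
                        ground_truth=gt)
    finally:
        logging.getLogger("pine_phenomics").removeHandler(handler)
        handler.close()


def _analyze(cfg: PipelineConfig, out: Path, master_seed: int, manifest: dict,
             raster_dir: Path, field: pd.DataFrame,
             ground_truth: pd.DataFrame) -> dict:
    def stage(name):
        s = stage_seed(master_seed, name)
        manifest["stage_seeds"][name] = s
        manifest["stages"].append(name)
        logger.info("stage %s (seed %d)", name, s)
        return s

    current = "detect"
    try:
        # -- detection (geometry is month-invariant: one DSM/DTM) ----------
        stage("detect")
        for fname in ("dsm.tif", "dtm.tif"):
            if not (raster_dir / fname).exists():
                raise FileNotFoundError(f"missing raster file: {raster_dir / fname}")
        surf = read_stack({"dsm": raster_dir / "dsm.tif",
                           "dtm": raster_dir / "dtm.tif"})
        chm = canopy_image.compute_chm(surf["dsm"], surf["dtm"], surf.nodata)
        apexes = canopy_image.detect_trees(chm, surf.transform)
        crowns = canopy_image.delineate_crowns(chm, surf.transform, apexes)
        crowns, unmatched = canopy_image.match_trees(crowns, field)
        _write_json(out / "match_report.json", {
            "n_detected": len(crowns),
            "n_matched": sum(c.matched_id is not None for c in crowns),
            "n_field": len(field),
            "unmatched_field_ids": sorted(unmatched["tree_id"].astype(str))})
        _write_crowns_geojson(out / "crowns.geojson", crowns)

        # -- per-month features --------------------------------------------
        current = "features"
        stage("features")
        labeled = [c for c in crowns if c.matched_id is not None]
        monthly_features: dict[str, pd.DataFrame] = {}
        for month in cfg.months:
            mdir = raster_dir / month
            paths = {b: mdir / f"{b}.tif" for b in BAND_NAMES}
            for b, p in paths.items():
                if not p.exists():
                    raise FileNotFoundError(f"missing raster file: {p}")
            bands = read_stack(paths)
            if bands.transform != surf.transform:
                raise ValueError(f"{month}: band rasters not co-registered with DSM/DTM")
            spectra = canopy_image.extract_spectra(bands, labeled)
            spectra["tree_id"] = [c.matched_id for c in labeled]
            spectra = spectra[~spectra["flagged"]].copy()
            feats = spectral_indices.compute_features(spectra)
            feats = feats[~feats["vi_undefined"]].reset_index(drop=True)
            feats.insert(1, "month", month)
            mdir_out = out / "months" / month
            mdir_out.mkdir(parents=True, exist_ok=True)
            feats.to_csv(mdir_out / "features.csv", index=False)
            monthly_features[month] = feats

        # -- pooled model training on ground-sampled trees -----------------
        current = "models"
        seed_models = stage("models")
        gt_wide = ground_truth.pivot_table(index=["tree_id", "month"],
                                           columns="trait", values="value",
                                           aggfunc="first").reset_index()
        pooled = pd.concat(monthly_features.values(), ignore_index=True).merge(
            gt_wide, on=["tree_id", "month"], how="inner")
        traits = [t for t in ("N", "NSC") if t in pooled.columns]
        split = trait_models.SplitSpec(cfg.calibration_fraction, seed=seed_models)
        specs = _model_specs(cfg, seed_models)
        comparison, results = trait_models.compare_methods(
            pooled, traits=traits, specs=specs, split=split)
        comparison.to_csv(out / "model_results.csv", index=False)
        imp = pd.DataFrame({f"{r.trait}:{r.method}": r.importance
                            for r in results if r.importance is not None})
        imp.rename_axis("predictor").to_csv(out / "variable_importance.csv")

        # -- predict every tree, every month -------------------------------
        current = "predict"
        stage("predict")
        cal, _ = trait_models.split_data(pooled, split)
        best_models = {}
        for trait in traits:
            best_method = comparison[(comparison["trait"] == trait)
                                     & comparison["best"]]["method"].iloc[0]
            best_models[trait] = trait_models.fit_model(specs[best_method], cal, trait)
        predicted_frames = []
        for month, feats in monthly_features.items():
            pred = feats[["tree_id", "month"]].copy()
            for trait in traits:
                pred[trait] = np.ravel(best_models[trait].predict(
                    feats[list(spectral_indices.FEATURE_COLUMNS)]))
            pred = pred.merge(field[["tree_id", "family", "block", "site"]],
                              on="tree_id")
            pred.to_csv(out / "months" / month / "predicted_traits.csv", index=False)
            predicted_frames.append(pred)
        predicted = pd.concat(predicted_frames, ignore_index=True)

        # -- genetics -------------------------------------------------------
        current = "genetics"
        stage("genetics")
        if cfg.genetics_on == "true":
            genetic_input = ground_truth_long_from_true(out)
        else:
            genetic_input = predicted.melt(
                id_vars=["tree_id", "month", "family", "block", "site"],
                value_vars=traits, var_name="trait", value_name="value")
        series = genetics.monthly_genetic_series(genetic_input, months=cfg.months)
        h2_rows, bv_rows = [], []
        for s in series:
            if s.error is not None:
                h2_rows.append({"trait": s.trait, "month": s.month, "h2": np.nan,
                                "var_family": np.nan, "var_block": np.nan,
                                "var_residual": np.nan, "error": s.error})
                continue
            vc = s.components
            h2_rows.append({"trait": s.trait, "month": s.month, "h2": s.h2,
                            "var_family": vc.var_family, "var_block": vc.var_block,
                            "var_residual": vc.var_residual, "error": ""})
            for fam, bv in s.breeding_values.items():
                bv_rows.append({"trait": s.trait, "month": s.month, "family": fam,
                                "family_mean": s.family_means[fam],
                                "breeding_value": bv})
            _write_json(out / "months" / s.month / f"genetics_{s.trait}.json", {
                "trait": s.trait, "month": s.month, "h2": s.h2,
                "population_mean": s.population_mean,
                "var_family": vc.var_family, "var_block": vc.var_block,
                "var_residual": vc.var_residual, "loglik": vc.loglik,
                "boundary": list(vc.boundary)})
        h2_series = pd.DataFrame(h2_rows)
        h2_series.to_csv(out / "h2_series.csv", index=False)
        bv_table = pd.DataFrame(bv_rows)
        bv_table.to_csv(out / "breeding_values.csv", index=False)

        # -- selection ------------------------------------------------------
        current = "selection"
        stage("selection")
        sel_months = [m for m in cfg.selection_months
                      if not bv_table.empty and m in set(bv_table["month"])]
        selected = (genetics.select_families(bv_table, sel_months, k=cfg.selection_k)
                    if sel_months else [])
        _write_json(out / "selection.json", {"months": sel_months,
                                             "rule": "both above mean",
                                             "k": cfg.selection_k,
                                             "selected_families": selected})
        _write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        _write_json(out / "manifest.json", {**manifest, "error": str(exc),
                                            "failed_stage": current})
        raise RuntimeError(f"pipeline aborted in stage {current}: {exc}") from exc


def ground_truth_long_from_true(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "traits_true.csv")


def _write_crowns_geojson(path: Path, crowns) -> None:
    feats = []
    for c in crowns:
        feats.append({
            "type": "Feature",
            "geometry": (shapely_mapping(c.crown)
                         if c.crown is not None else None),
            "properties": {"tree_id": c.tree_id, "matched_id": c.matched_id,
                           "x": c.x, "y": c.y, "height": c.height,
                           "family": c.family, "block": c.block, "site": c.site},
        })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                               sort_keys=True))
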