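"""End-to-end orchestration: synthetic cohort -> heatmaps -> scores -> stats.

Two entry paths exist.  The "heatmap-direct" path plants confidence
heatmaps straight from the synthetic generator (no classifier) and runs
scoring, gray-matter restriction, field-of-view analysis and cohort
statistics; it is fully deterministic given the seed.  The "full" path
additionally renders slide images and runs the classifier sliding window;
it is exercised by the model tests rather than the default pipeline.

Every output file is recorded in a run manifest with its SHA-256 checksum,
so re-running with an identical config and seed can be verified to
reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fov as fov_mod
from .cohort_stats import anova_tukey, spearman_ordinal
from .scoring import MorphologyParams, RegionMask, ScoreResult, compute_score, percent_change
from .synthetic import CLASS_NAMES, SyntheticCohortSpec, generate_cohort, generate_heatmap

logger = logging.getLogger("plaquescope")


@dataclasses.dataclass
class PipelineConfig:
    cohort: SyntheticCohortSpec
    morphology: MorphologyParams = dataclasses.field(default_factory=MorphologyParams)
    fov: fov_mod.FOVConfig | None = None
    fov_n_values: tuple = fov_mod.DEFAULT_N_VALUES
    output_dir: str = "plaquescope_run"
    seed: int = 0
    stages: tuple = ("heatmap", "score", "gm-score", "fov", "stats")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohort = SyntheticCohortSpec(**raw["cohort"])
        kwargs = {"cohort": cohort}
        if "morphology" in raw:
            kwargs["morphology"] = MorphologyParams(**raw["morphology"])
        if "fov" in raw:
            kwargs["fov"] = fov_mod.FOVConfig(**raw["fov"])
        for key in ("output_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    d = dataclasses.asdict(config)
    d.pop("output_dir", None)  # run location is not part of the scientific config
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


SCORE_COLUMNS = ["slide_id", "pathology", "region", "blob_count", "region_area_px", "cnn_score"]


def write_scores(results, path):
    """Write ScoreResult rows to CSV, 12 significant digits."""
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_scores(path) -> pd.DataFrame:
    """Read a score CSV back, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score CSV missing columns: {missing}")
    return df


def load_region_annotation(path, heatmap_shape, wsi_shape=None, stride=16, window=256):
    """Load a region annotation as a heatmap-resolution RegionMask.

    Accepts a single-channel PNG mask (non-zero = inside) at slide
    resolution, or a JSON/YAML polygon file of the form
    ``{"wsi_shape": [H, W], "polygons": [[[x, y], ...], ...]}`` with
    vertices in slide pixels.  Polygons are rasterized at slide resolution,
    then sampled at each heatmap pixel's window centre (nearest neighbor).
    Self-intersecting polygons are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        full = arr > 127
    else:
        with open(path) as fh:
            data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if wsi_shape is None:
            wsi_shape = tuple(data["wsi_shape"])
        polygons = data["polygons"]
        if not polygons:
            import warnings

            warnings.warn("empty annotation: empty region mask")
        from shapely.geometry import Polygon as ShPolygon
        from skimage.draw import polygon as sk_polygon

        full = np.zeros(wsi_shape, dtype=bool)
        for poly in polygons:
            pts = np.asarray(poly, dtype=float)
            if len(pts) >= 3 and not ShPolygon(pts).is_valid:
                raise ValueError("self-intersecting polygon rejected")
            rr, cc = sk_polygon(pts[:, 1], pts[:, 0], shape=wsi_shape)
            full[rr, cc] = True
    hh, wh = heatmap_shape
    rows = np.minimum(np.arange(hh) * stride + window // 2, full.shape[0] - 1)
    cols = np.minimum(np.arange(wh) * stride + window // 2, full.shape[1] - 1)
    mask = full[np.ix_(rows, cols)]
    return RegionMask(mask=mask, label="annotation")


def run_pipeline(config: PipelineConfig):
    """Execute the enabled stages on a synthetic cohort; returns the manifest.

    Outputs under ``config.output_dir``: ``scores.csv`` (tidy per
    slide/class/region), ``percent_change.csv``, ``fov_windows.csv``,
    ``convergence_<class>.csv``, ``stats_report.csv`` and
    ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    t0 = time.time()

    needs_scores = {"score", "gm-score", "fov", "stats"} & stages
    if needs_scores and "heatmap" not in stages:
        raise RuntimeError("stage 'score' requires stage 'heatmap' (missing upstream artifact)")
    if "stats" in stages and "score" not in stages:
        raise RuntimeError("stage 'stats' requires stage 'score' (missing upstream artifact)")

    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    slide_specs, records = generate_cohort(cohort_spec)
    records_path = outdir / "cohort.csv"
    records.to_csv(records_path, index=False, float_format="%.12g")
    logger.info("generated cohort of %d slides", len(slide_specs))

    results: list[ScoreResult] = []
    pct_rows = []
    fov_rows = []
    per_slide_windows: dict = {cls: [] for cls in CLASS_NAMES}

    fov_cfg = config.fov
    for spec, (_, rec) in zip(slide_specs, records.iterrows()):
        slide_id = rec["slide_id"]
        for cls in CLASS_NAMES:
            if cls not in spec.class_densities:
                continue
            heatmap, gt = generate_heatmap(spec, cls)
            tissue = RegionMask(mask=gt.tissue_mask, label="whole_tissue")
            if "score" in stages:
                wt = compute_score(heatmap, cls, config.morphology, tissue, slide_id)
                results.append(wt)
            if "gm-score" in stages:
                gm_region = RegionMask(mask=gt.gm_mask, label="gray_matter")
                gm = compute_score(heatmap, cls, config.morphology, gm_region, slide_id)
                results.append(gm)
                pct_rows.append(
                    {
                        "slide_id": slide_id,
                        "pathology": cls,
                        "percent_change": percent_change(gm, wt),
                    }
                )
            if "fov" in stages and fov_cfg is not None:
                windows = fov_mod.compute_fov_scores(
                    heatmap, cls, config.morphology, gt.tissue_mask, fov_cfg
                )
                per_slide_windows[cls].append(windows)
                for fw in windows:
                    fov_rows.append(
                        {"slide_id": slide_id, "pathology": cls, **dataclasses.asdict(fw)}
                    )
        logger.debug("scored %s", slide_id)

    written = [records_path]
    if "score" in stages:
        scores_path = outdir / "scores.csv"
        write_scores(results, scores_path)
        written.append(scores_path)
    if "gm-score" in stages and pct_rows:
        pct_path = outdir / "percent_change.csv"
        pd.DataFrame(pct_rows).to_csv(pct_path, index=False, float_format="%.12g")
        written.append(pct_path)
    if "fov" in stages and fov_cfg is not None:
        fov_path = outdir / "fov_windows.csv"
        pd.DataFrame(
            fov_rows,
            columns=["slide_id", "pathology", "row", "col", "window_size",
                     "blob_count", "tissue_area_px", "fov_score"],
        ).to_csv(fov_path, index=False, float_format="%.12g")
        written.append(fov_path)

    stats_rows = []
    if "stats" in stages:
        df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        for cls in CLASS_NAMES:
            sub = df[(df.pathology == cls) & (df.region == "whole_tissue")]
            if sub.empty:
                continue
            merged = sub.merge(records, on="slide_id")
            levels = merged[f"level_index_{cls}"].to_numpy()
            rho = spearman_ordinal(merged["cnn_score"].to_numpy(), levels)
            stats_rows.append({"pathology": cls, "metric": "spearman_vs_level", "value": rho})
            by_level = {
                str(lv): merged.loc[merged[f"level_{cls}"] == lv, "cnn_score"].to_numpy()
                for lv in cohort_spec.ordinal_levels
            }
            by_level = {k: v for k, v in by_level.items() if len(v) >= 2}
            if len(by_level) >= 2 and any(np.ptp(v) > 0 for v in by_level.values()):
                cmp_res = anova_tukey(by_level, grouping=f"cerad_like_{cls}")
                stats_rows.append(
                    {"pathology": cls, "metric": "anova_F", "value": cmp_res.f_statistic}
                )
                stats_rows.append(
                    {"pathology": cls, "metric": "anova_p", "value": cmp_res.anova_p}
                )
            if "fov" in stages and fov_cfg is not None and per_slide_windows[cls]:
                conv = fov_mod.convergence_table(
                    per_slide_windows[cls],
                    levels,
                    merged["cnn_score"].to_numpy(),
                    config.fov_n_values,
                )
                conv_path = outdir / f"convergence_{cls}.csv"
                conv.to_csv(conv_path, index=False, float_format="%.12g")
                written.append(conv_path)
        stats_path = outdir / "stats_report.csv"
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False, float_format="%.12g")
        written.append(stats_path)

    manifest = {
        "config_hash": _config_hash(config),
        "package_version": _package_version(),
        "seed": config.seed,
        "stages": sorted(stages),
        "created_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "elapsed_s": round(time.time() - t0, 3),
        "files": {p.name: _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d files", len(written))
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("plaquescope")
    except Exception:
        return "unknown"
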