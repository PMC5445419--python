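"""Readers, writers, run configuration and the end-to-end pipeline.

File formats: TIFF for images (single-page grayscale; written as
float32, or 16-bit unsigned for synthetic scenes), GeoJSON for
geometry, CSV for tabular output, JSON for the calibrated unit /
statistics / run manifest, YAML for configuration.

GeoJSON dialect: a FeatureCollection whose features carry properties
``role`` (one of ``cell``, ``nucleus``, ``aggregation_center``,
``anterior``, ``posterior``), ``cell_id`` and optionally
``stream_position``.  Coordinates are (x, y) = (col, row) in the
pixel-centre frame.  When a cell's features include explicit
``anterior``/``posterior`` polygons (e.g. from manual segmentation),
they take precedence over the programmatic bisection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Point, Polygon, mapping, shape

from . import counting, geometry, stats as polstats
from .calibration import UnitModel, calibrate_unit
from .geometry import CellGeometry, RoiPair, bisect_cell, fit_cell_axes
from .image import FluorescenceImage
from .synthetic import SceneParams, SyntheticScene, make_stream_cohort

logger = logging.getLogger("fishpol")

ROLES = ("cell", "nucleus", "aggregation_center", "anterior", "posterior")


# --------------------------------------------------------------------
# images

def read_image(path, channel: str = "") -> FluorescenceImage:
    """Read a single-page grayscale 2D TIFF as a FluorescenceImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-page grayscale 2D TIFF, got shape {arr.shape} "
            "(multi-page stacks and RGB images are not supported; provide a "
            "maximum-intensity projection)"
        )
    logger.info("read_image path=%s shape=%s dtype=%s", path, arr.shape, arr.dtype)
    return FluorescenceImage(arr.astype(float), channel=channel or path.stem)


def write_image(path, image: FluorescenceImage, dtype: str = "float32") -> None:
    """Write an image as TIFF (``float32`` or rounded/clipped ``uint16``)."""
    px = image.pixels
    if dtype == "uint16":
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        px = px.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(Path(path), px)


# --------------------------------------------------------------------
# geometry (GeoJSON)

def _feature(geom, role: str, cell_id: str, **props) -> dict:
    return {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": {"role": role, "cell_id": cell_id, **props},
    }


def scene_to_features(scene: SyntheticScene, cell_id: str) -> list[dict]:
    nr, nc = scene.nucleus_centroid
    ar, ac = scene.aggregation_point
    pos = scene.params.stream_position
    return [
        _feature(scene.cell_polygon, "cell", cell_id, stream_position=pos),
        _feature(Point(nc, nr), "nucleus", cell_id),
        _feature(Point(ac, ar), "aggregation_center", cell_id),
    ]


def write_rois(path, features: list[dict]) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def roi_pair_to_features(pair: RoiPair, cell_id: str) -> list[dict]:
    return [
        _feature(pair.anterior, "anterior", cell_id),
        _feature(pair.posterior, "posterior", cell_id),
    ]


def read_rois(path) -> dict[str, dict]:
    """Parse the GeoJSON dialect into per-cell geometry dictionaries.

    Returns ``{cell_id: {"cell": CellGeometry|None, "pair": RoiPair|None,
    "features": {role: geometry}}}``.  Invalid features are rejected
    with their index in the collection.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    cells: dict[str, dict] = {}
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        role = props.get("role")
        if role not in ROLES:
            raise ValueError(f"feature {i}: unknown or missing role {role!r}")
        cell_id = props.get("cell_id")
        if cell_id is None:
            raise ValueError(f"feature {i} (role {role}): missing cell_id")
        geom = shape(feat["geometry"])
        if isinstance(geom, Polygon):
            if not geom.is_valid:
                raise ValueError(
                    f"feature {i} (cell {cell_id}, role {role}): invalid polygon "
                    f"({shapely.is_valid_reason(geom)})"
                )
        entry = cells.setdefault(
            str(cell_id), {"features": {}, "stream_position": "single"}
        )
        entry["features"][role] = geom
        if "stream_position" in props:
            entry["stream_position"] = props["stream_position"]

    out: dict[str, dict] = {}
    for cell_id, entry in cells.items():
        feats = entry["features"]
        cellgeom = None
        if "cell" in feats and "nucleus" in feats and "aggregation_center" in feats:
            nuc, agg = feats["nucleus"], feats["aggregation_center"]
            a, b, orient = fit_cell_axes(feats["cell"])
            cellgeom = CellGeometry(
                cell_polygon=feats["cell"],
                nucleus_centroid=(nuc.y, nuc.x),
                aggregation_point=(agg.y, agg.x),
                semi_major=a,
                semi_minor=b,
                orientation=orient,
                cell_id=cell_id,
                stream_position=entry["stream_position"],
            )
        pair = None
        if "anterior" in feats and "posterior" in feats:
            # manually supplied halves take precedence over the programmatic cut
            ant, post = feats["anterior"], feats["posterior"]
            ca, cp = ant.centroid, post.centroid
            d = np.array([ca.y - cp.y, ca.x - cp.x])
            d /= np.linalg.norm(d)
            mid = shapely.union_all([ant, post]).centroid
            pair = RoiPair(
                anterior=ant,
                posterior=post,
                bisect_point=(mid.y, mid.x),
                anterior_direction=(float(d[0]), float(d[1])),
            )
            logger.info("cell %s: using supplied anterior/posterior polygons", cell_id)
        out[cell_id] = {"cell": cellgeom, "pair": pair, "features": feats}
    return out


# --------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """All pipeline parameters with defaults; round-trips via YAML."""

    # cohort / scene
    n_cells: int = 30
    position_labels: list[str] = field(
        default_factory=lambda: ["beginning", "middle", "end"]
    )
    enrichment_by_position: dict[str, float] = field(
        default_factory=lambda: {"beginning": 0.5, "middle": 0.6, "end": 0.7}
    )
    protein_fraction_by_position: dict[str, float] | None = None
    scene: dict = field(default_factory=dict)  # overrides for SceneParams fields
    master_seed: int = 0
    # calibration
    min_separation_px: float = 3.0
    k_sigma: float = 5.0
    window_px: int = 11
    size_bounds: tuple[float, float] = (0.8, 3.0)
    trim_step: float = 0.02
    unimodality_threshold: float = 0.555
    criterion: str = "bimodality"
    # estimation
    n_reps: int = 10
    jitter_px: float = 1.0
    stop_tol: float = 1e-4
    # statistics
    alpha: float = 0.05
    levels: tuple[float, float] = (0.50, 0.99)
    paired: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.size_bounds = tuple(self.size_bounds)  # type: ignore[assignment]
        self.levels = tuple(self.levels)  # type: ignore[assignment]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["size_bounds"] = list(d["size_bounds"])
        d["levels"] = list(d["levels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def scene_params(self) -> SceneParams:
        return SceneParams(seed=self.master_seed, **self.scene)


# --------------------------------------------------------------------
# pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _comparison_to_dict(c: polstats.GroupComparison) -> dict:
    def box(s):
        return {
            "n": s.n,
            "median": s.median,
            "box": [s.box_lo, s.box_hi],
            "bar": [s.bar_lo, s.bar_hi],
            "n_outliers": int(len(s.outliers)),
            "quartiles": [s.q1, s.q3],
        }

    return {
        "group": c.group,
        "labels": list(c.labels),
        "n": list(c.n),
        "t_statistic": c.t_statistic,
        "p_value": c.p_value,
        "test": c.test,
        "mean_mrna_posterior_fraction": c.mean_mrna_posterior_fraction,
        "anterior": box(c.summaries[0]),
        "posterior": box(c.summaries[1]),
    }


def build_records(
    cohort, unit: UnitModel, config: RunConfig
) -> list[polstats.CellRecord]:
    """Bisect, count and measure every cell of a rendered cohort."""
    from .calibration import subtract_background

    records = []
    for i, (scene, mrna, protein) in enumerate(cohort):
        pair = bisect_cell(
            scene.cell_polygon, scene.nucleus_centroid, scene.aggregation_point
        )
        mrna_sub = subtract_background(mrna, scene.cell_polygon)
        prot_sub = subtract_background(protein, scene.cell_polygon)
        lin_ant, lin_post = counting.linear_estimate_pair(mrna_sub, pair, unit)
        sim = counting.simulated_estimate(
            mrna_sub,
            pair,
            unit,
            n_reps=config.n_reps,
            master_seed=scene.params.seed,
            jitter_px=config.jitter_px,
            stop_tol=config.stop_tol,
        )
        a, b, _ = fit_cell_axes(scene.cell_polygon)
        records.append(
            polstats.CellRecord(
                cell_id=f"cell_{i:04d}",
                stream_position=scene.params.stream_position,
                anterior_count=lin_ant,
                posterior_count=lin_post,
                anterior_count_sim=sim["anterior"].sim_count_mean,
                posterior_count_sim=sim["posterior"].sim_count_mean,
                protein_posterior_fraction=geometry.posterior_intensity_fraction(
                    prot_sub, pair
                ),
                eccentricity=geometry.eccentricity(a, b),
            )
        )
    return records


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> calibrate -> bisect -> estimate -> stats, end to end.

    Writes records.csv, unit.json, stats.json and a manifest.json with
    the seed, parameters and output hashes.  Deterministic for a fixed
    ``config.master_seed``.  Returns the stats dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = config.scene_params()
    logger.info("pipeline stage=simulate n_cells=%d seed=%d", config.n_cells, base.seed)
    cohort = make_stream_cohort(
        config.n_cells,
        config.position_labels,
        config.enrichment_by_position,
        base,
        protein_fraction_by_position=config.protein_fraction_by_position,
    )

    logger.info("pipeline stage=calibrate n_images=%d", len(cohort))
    unit, candidates = calibrate_unit(
        [mrna for _, mrna, _ in cohort],
        [scene.cell_polygon for scene, _, _ in cohort],
        min_separation_px=config.min_separation_px,
        k_sigma=config.k_sigma,
        window_px=config.window_px,
        size_bounds=config.size_bounds,
        trim_step=config.trim_step,
        unimodality_threshold=config.unimodality_threshold,
        criterion=config.criterion,
    )
    (out / "unit.json").write_text(json.dumps(unit.to_dict(), indent=1))
    pd.DataFrame(
        [
            {
                "row": c.center[0],
                "col": c.center[1],
                "peak_value": c.peak_value,
                "fit_amplitude": c.fit_amplitude,
                "fit_sigma": c.fit_sigma,
                "fit_background": c.fit_background,
                "fit_rss": c.fit_rss,
                "accepted": c.accepted,
            }
            for c in candidates
        ]
    ).to_csv(out / "candidates.csv", index=False)

    logger.info("pipeline stage=estimate n_reps=%d", config.n_reps)
    records = build_records(cohort, unit, config)
    polstats.records_to_frame(records).to_csv(out / "records.csv", index=False)

    logger.info("pipeline stage=stats")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results: dict = {
            "unit": unit.to_dict(),
            "overall": {
                est: _comparison_to_dict(
                    polstats.compare_anterior_posterior(records, est, config.paired)
                )
                for est in ("linear", "simulated")
            },
            "by_position": [
                _comparison_to_dict(c)
                for c in polstats.compare_by_stream_position(records)
            ],
        }
        for by in ("cell", "position"):
            try:
                r, n = polstats.mrna_protein_correlation(records, by=by)
                results[f"pearson_r_{by}"] = {"r": r, "n": n}
            except ValueError as e:
                results[f"pearson_r_{by}"] = {"error": str(e)}
    (out / "stats.json").write_text(json.dumps(results, indent=1, default=float))

    manifest = {
        "master_seed": config.master_seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline stage=done out=%s", out)
    return results
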