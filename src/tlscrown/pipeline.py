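"""End-to-end orchestration: normalized cloud -> segmented trees ->
stem/crown classification -> per-tree trait table -> treatment statistics.

``PipelineConfig`` collects every stage parameter (strict: unknown keys in a
YAML config are rejected).  ``process_plot`` runs one plot cloud through all
geometric stages and returns a tidy per-tree trait table; the numbered
scripts under ``analysis/`` drive whole synthetic experiments through it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crown_traits as ct
from . import segmentation as seg
from . import stem_traits as st
from .pointcloud_io import PointCloud, build_dtm, normalize_heights
from .stem_classification import StemClassifierParams, classify_stem_points


@dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults."""

    dtm_cell_m: float = 0.5          # DTM raster resolution
    chm_cell_m: float = 0.20         # CHM raster resolution
    min_canopy_height_m: float = 2.0  # treetop / watershed canopy mask
    vwf_slope: float = 0.04          # window radius = max(vwf_min, slope*h)
    vwf_min_radius_m: float = 0.5
    ground_cutoff_m: float = 0.3     # normalized points below this are ground
    min_tree_points: int = 200       # trees with fewer points are skipped
    taper_slice_m: float = 0.5
    crown_slices: int = 10
    slice_mode: str = "equal_count"  # or "equal_height"
    classifier: StemClassifierParams = field(default_factory=StemClassifierParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classifier" in raw:
            cknown = {f.name for f in fields(StemClassifierParams)}
            cunknown = set(raw["classifier"]) - cknown
            if cunknown:
                raise ValueError(f"unknown classifier keys: {sorted(cunknown)}")
            raw["classifier"] = StemClassifierParams(**raw["classifier"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def window_radius_fn(self, h):
        return np.maximum(self.vwf_min_radius_m, self.vwf_slope * np.asarray(h, float))


def process_plot(cloud: PointCloud, config: PipelineConfig | None = None,
                 normalized: bool = False,
                 site: str = "site1", plot: str = "plot1",
                 treatment: str | None = None) -> pd.DataFrame:
    """Run one plot cloud through the full geometric pipeline.

    Returns one row per successfully processed tree with all crown and stem
    traits plus segment metadata; trees that fail a stage (too few points,
    no stem found, too few taper slices) are dropped with a note in the
    ``n_failed`` attribute of the returned frame.
    """
    config = config or PipelineConfig()
    if not normalized:
        dtm = build_dtm(cloud, cell=config.dtm_cell_m)
        cloud = normalize_heights(cloud, dtm)

    chm = seg.rasterize_chm(cloud, cell=config.chm_cell_m)
    tops = seg.detect_treetops_vwf(chm, config.window_radius_fn,
                                   min_height=config.min_canopy_height_m)
    segmap = seg.watershed_crowns(chm, tops, min_height=config.min_canopy_height_m)
    assigned = seg.assign_points(cloud, segmap)

    rows = []
    n_failed = 0
    for tid, tree_pc in seg.split_by_tree(assigned).items():
        if tid == 0:
            continue
        # strip ground returns before classification
        tree_pc = tree_pc.subset(tree_pc.z >= config.ground_cutoff_m)
        if len(tree_pc) < config.min_tree_points:
            n_failed += 1
            continue
        try:
            classified = classify_stem_points(tree_pc, config.classifier, tree_id=tid)
            if not classified.stem_found:
                n_failed += 1
                continue
            height = st.tree_height(tree_pc)
            taper = st.fit_taper_curve(classified.stem, slice_h=config.taper_slice_m)
            dbh_cm, dbh_extra = st.dbh(taper)
            stem_row = {
                "dbh_cm": dbh_cm,
                "dbh_extrapolated": dbh_extra,
                "tree_height_m": height,
                "stem_volume_dm3": st.stem_volume(taper, height),
                "height_50pct_volume_m": st.height_at_volume_fraction(taper, height, 0.5),
                "height_dbh_ratio": st.height_dbh_ratio(height, dbh_cm),
            }
            crown_row = ct.crown_trait_set(classified.crown, taper, height,
                                           n_slices=config.crown_slices,
                                           mode=config.slice_mode)
        except ValueError:
            n_failed += 1
            continue
        top = next(t for t in tops if t.label == tid)
        rows.append({
            "site": site, "plot": plot,
            **({"treatment": treatment} if treatment is not None else {}),
            "tree_id": tid, "x": top.x, "y": top.y,
            "n_points": len(tree_pc), "n_stem_points": len(classified.stem),
            **crown_row, **stem_row,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_failed"] = n_failed
    out.attrs["n_treetops"] = len(tops)
    return out


def process_single_tree(tree_pc: PointCloud, config: PipelineConfig | None = None) -> dict:
    """Traits of one pre-segmented, normalized tree cloud (no ground points).

    The single-tree analogue of :func:`process_plot`, used for oracle
    comparisons: classification, taper reconstruction, and the full crown
    and stem trait set.
    """
    config = config or PipelineConfig()
    classified = classify_stem_points(tree_pc, config.classifier)
    if not classified.stem_found:
        raise ValueError("no stem found")
    height = st.tree_height(tree_pc)
    taper = st.fit_taper_curve(classified.stem, slice_h=config.taper_slice_m)
    dbh_cm, dbh_extra = st.dbh(taper)
    return {
        **ct.crown_trait_set(classified.crown, taper, height,
                             n_slices=config.crown_slices, mode=config.slice_mode),
        "dbh_cm": dbh_cm,
        "dbh_extrapolated": dbh_extra,
        "tree_height_m": height,
        "stem_volume_dm3": st.stem_volume(taper, height),
        "height_50pct_volume_m": st.height_at_volume_fraction(taper, height, 0.5),
        "height_dbh_ratio": st.height_dbh_ratio(height, dbh_cm),
    }
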