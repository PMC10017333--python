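"""Shared fixtures: synthetic scenes and pipeline runs reused across tests.

Everything is generated programmatically at session start from fixed
seeds; the expensive paper-scale render/detect chain and the end-to-end
pipeline runs are built once and shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pine_phenomics import canopy_image, spectral_indices, synthetic_orchard
from pine_phenomics.pipeline import PipelineConfig, run_pipeline
from pine_phenomics.synthetic_orchard import (LayoutConfig, default_genetics,
                                              default_optics, make_layout,
                                              render_rasters,
                                              sample_ground_truth,
                                              simulate_reflectance,
                                              simulate_traits)

PAPER_SEED = 11


@pytest.fixture(scope="session")
def paper_layout():
    """Full trial scale: 2 sites x 20 blocks x 20 families = 800 trees."""
    return make_layout(seed=PAPER_SEED)


@pytest.fixture(scope="session")
def paper_scene(paper_layout):
    """One month of the full-scale campaign, rendered at 5 cm and analyzed."""
    genetics = default_genetics(seed=13)
    traits = simulate_traits(paper_layout, genetics, months=["Jan"])
    refl = simulate_reflectance(traits, default_optics(seed=17))
    stack = render_rasters(paper_layout, refl, "Jan", resolution=0.05)
    chm = canopy_image.compute_chm(stack["dsm"], stack["dtm"], stack.nodata)
    apexes = canopy_image.detect_trees(chm, stack.transform)
    crowns = canopy_image.delineate_crowns(chm, stack.transform, apexes)
    return {"layout": paper_layout, "traits": traits, "reflectance": refl,
            "stack": stack, "chm": chm, "apexes": apexes, "crowns": crowns}


@pytest.fixture(scope="session")
def small_features():
    """~140-row feature table with ground-truth traits, for model tests."""
    layout = make_layout(
        LayoutConfig(blocks_per_site=5, trees_per_block=10, n_families=10,
                     block_cols=2), seed=23)
    genetics = default_genetics(seed=29)
    traits = simulate_traits(layout, genetics, months=["May", "Jun", "Jul", "Aug"])
    refl = simulate_reflectance(traits, default_optics(seed=31))
    gt = pd.concat([sample_ground_truth(traits, m, 35, seed=37 + i)
                    for i, m in enumerate(["May", "Jun", "Jul", "Aug"])],
                   ignore_index=True)
    gt_wide = gt.pivot_table(index=["tree_id", "month"], columns="trait",
                             values="value", aggfunc="first").reset_index()
    return spectral_indices.compute_features(refl).merge(
        gt_wide, on=["tree_id", "month"])


MINI_CONFIG = PipelineConfig(
    layout=LayoutConfig(blocks_per_site=4, trees_per_block=10, n_families=10,
                        block_cols=2),
    months=("Jun", "Jul", "Aug"),
    resolution=0.10,
    samples_per_month=25,
    model_grids={"PLSR": {"n_components": [2, 4, 6]},
                 "SVM": {"C": [1.0, 4.0], "gamma": [0.1]},
                 "GBM": {"learning_rate": [0.1], "n_estimators": [100, 300]},
                 "RF": {"n_estimators": [300]}},
    selection_months=("Jul",))


@pytest.fixture(scope="session")
def mini_runs(tmp_path_factory):
    """Two identical-seed end-to-end pipeline runs, for determinism checks."""
    base = tmp_path_factory.mktemp("pipeline")
    out_a = base / "run_a"
    out_b = base / "run_b"
    run_pipeline(MINI_CONFIG, out_a, master_seed=5)
    run_pipeline(MINI_CONFIG, out_b, master_seed=5)
    return {"config": MINI_CONFIG, "seed": 5, "a": out_a, "b": out_b}


def truth_match(apexes, layout, tolerance=1.0):
    """Precision/recall of detections against planted positions."""
    from scipy.spatial import cKDTree
    det = np.array([[a.x, a.y] for a in apexes])
    truth = layout.trees[["x", "y"]].to_numpy()
    if len(det) == 0:
        return 0.0, 0.0
    dist, idx = cKDTree(truth).query(det)
    tp_mask = dist <= tolerance
    precision = tp_mask.sum() / len(det)
    recall = len(set(idx[tp_mask])) / len(truth)
    return precision, recall
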