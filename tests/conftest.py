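import numpy as np
import pandas as pd
import pytest

from imcscope import segment, simulate
from imcscope.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cr_roi():
    """One rendered CR-like ROI with aggregates and the default planted
    Macrophage-2 / CTL-2 attraction."""
    return simulate.simulate_roi(simulate.cr_default_config(seed=11))


@pytest.fixture(scope="session")
def nr_roi():
    return simulate.simulate_roi(simulate.nr_default_config(seed=12))


@pytest.fixture(scope="session")
def balanced_cohort(panel):
    """8 rendered ROIs with a uniform immune mix giving >= 300 cells per
    phenotype (hepatocytes included), measured on the true masks.

    Returns (cell table, true phenotype labels aligned with the table).
    """
    mix = {p: 1.0 / 11 for p in simulate.IMMUNE_PHENOTYPES}
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    tables, labels = [], []
    for k in range(8):
        cfg = simulate.TissueSimConfig(
            cohort="NR", n_nonimmune=45, n_immune=460,
            phenotype_mix=mix, seed=500 + k,
        )
        roi, truth = simulate.simulate_roi(cfg, roi_id=f"R{k}")
        filt = segment.remove_hot_pixels(roi.stack, 5.0)
        tab = segment.measure_cells(truth.true_mask, filt, panel, roi_id=f"R{k}")
        tables.append(tab)
        labels.append(
            truth.cells.set_index("cell_id").loc[tab["cell_id"], "phenotype"].to_numpy()
        )
    return pd.concat(tables, ignore_index=True), np.concatenate(labels)


@pytest.fixture(scope="session")
def segmented_cr(cr_roi):
    """Full segmentation of the CR ROI: classifier trained on its own
    sparse truth-derived labels, then the standard chain."""
    roi, truth = cr_roi
    params = segment.SegmentationParams()
    stack2x = segment.upscale2x(
        segment.remove_hot_pixels(roi.stack, params.hotpixel_factor)
    )
    labels2x = simulate.training_labels_from_truth(truth, 1500, seed=0)
    clf = segment.train_pixel_classifier([stack2x], [labels2x], seed=0)
    mask, cells = segment.segment_roi(roi, clf, params)
    return roi, truth, clf, mask, cells
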