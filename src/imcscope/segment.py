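"""Single-cell segmentation: hot-pixel removal, 2x upscaling, 3-class pixel
classification, nuclei watershed, cell expansion, 1x measurement, and the
mask-adjacency neighbor graph.

The stage mirrors the conventional IMC workflow: a supervised pixel
classifier (trained from sparse label images rather than interactive
brushing) produces nuclear / cytoplasm-membrane / background probability
maps on the 2x grid; nuclei are thresholded, split by a seeded watershed on
the distance transform, and expanded outward through non-background pixels
to form cell masks, which are rescaled to 1x for measurement. All per-cell
intensities are means over the cell's pixels of the hot-pixel-filtered,
otherwise untransformed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier

from .io import RoiImage
from .panel import MarkerPanel

CLASS_NAMES = {1: "nuclear", 2: "cytoplasm_membrane", 3: "background"}


class TrainingError(ValueError):
    """Raised when pixel-classifier training inputs are incomplete."""


@dataclass
class SegmentationParams:
    """Tunable segmentation settings (2x-grid units where noted)."""

    hotpixel_factor: float = 5.0
    nuclear_prob_threshold: float = 0.5
    min_nucleus_area_px: int = 4        # at 2x
    watershed_min_seed_distance_px: int = 3  # at 2x
    max_expansion_px: float = 5.0       # at 2x

    def __post_init__(self):
        for name in (
            "hotpixel_factor",
            "nuclear_prob_threshold",
            "min_nucleus_area_px",
            "watershed_min_seed_distance_px",
            "max_expansion_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PixelProbabilities:
    """Per-pixel class posteriors on the 2x grid; planes sum to 1."""

    nuclear: np.ndarray
    cytoplasm: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        total = self.nuclear + self.cytoplasm + self.background
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("probability planes must sum to 1 at every pixel")


def remove_hot_pixels(stack: np.ndarray, factor: float = 5.0) -> np.ndarray:
    """Replace isolated outlier pixels by their 3x3 neighborhood median.

    A pixel is a hot pixel when its value exceeds ``factor`` times the
    median of its 3x3 neighborhood (center included). Works on a single
    plane or a channel-first stack; channels are filtered independently.
    """
    if factor <= 1:
        raise ValueError("hotpixel factor must be > 1")
    stack = np.asarray(stack)
    single = stack.ndim == 2
    planes = stack[None] if single else stack
    out = planes.copy()
    for c in range(planes.shape[0]):
        med = ndi.median_filter(planes[c], size=3, mode="reflect")
        hot = planes[c] > factor * med
        out[c][hot] = med[hot]
    return out[0] if single else out


def upscale2x(stack: np.ndarray) -> np.ndarray:
    """Bilinear 2x upscaling of a plane or channel-first stack."""
    stack = np.asarray(stack, dtype=np.float32)
    single = stack.ndim == 2
    planes = stack[None] if single else stack
    h, w = planes.shape[1:]
    out = np.stack(
        [
            resize(p, (2 * h, 2 * w), order=1, preserve_range=True,
                   anti_aliasing=False).astype(np.float32)
            for p in planes
        ]
    )
    return out[0] if single else out


def downscale_mask(mask2x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor 2x -> 1x mask downscaling (top-left of each 2x2
    block), preserving label identity; odd input dims floor the output."""
    mask2x = np.asarray(mask2x)
    h, w = mask2x.shape[0] // 2, mask2x.shape[1] // 2
    return mask2x[: 2 * h : 2, : 2 * w : 2].copy()


def _pixel_features(stack2x: np.ndarray) -> np.ndarray:
    """Multiscale features per channel: Gaussian smoothings (sigma 1, 2, 4),
    gradient magnitude, Laplacian. Returns (h, w, n_features)."""
    stack2x = np.asarray(stack2x, dtype=np.float32)
    feats = []
    for c in range(stack2x.shape[0]):
        plane = stack2x[c]
        for sigma in (1.0, 2.0, 4.0):
            feats.append(ndi.gaussian_filter(plane, sigma))
        feats.append(ndi.gaussian_gradient_magnitude(plane, 1.0))
        feats.append(ndi.gaussian_laplace(plane, 1.0))
    return np.stack(feats, axis=-1).astype(np.float32)


@dataclass
class PixelClassifier:
    """Seeded 3-class (nuclear / cytoplasm / background) pixel classifier."""

    forest: RandomForestClassifier
    n_channels: int

    def predict_probabilities(self, stack2x: np.ndarray) -> PixelProbabilities:
        return predict_probabilities(self, stack2x)


def train_pixel_classifier(
    stacks2x: list[np.ndarray],
    sparse_labels: list[np.ndarray],
    seed: int = 0,
    n_estimators: int = 60,
) -> PixelClassifier:
    """Train the 3-class pixel classifier from sparse label images.

    ``sparse_labels`` use 1 = nuclear, 2 = cytoplasm/membrane,
    3 = background, 0 = unlabeled, on the same 2x grid as the stacks.
    Training is deterministic for a fixed seed.
    """
    if len(stacks2x) != len(sparse_labels):
        raise TrainingError("one label image per training stack required")
    X, y = [], []
    for stack, labels in zip(stacks2x, sparse_labels):
        if labels.shape != stack.shape[1:]:
            raise TrainingError("label image shape must match stack planes")
        feats = _pixel_features(stack)
        sel = labels > 0
        X.append(feats[sel])
        y.append(labels[sel])
    X = np.concatenate(X)
    y = np.concatenate(y)
    for cls, name in CLASS_NAMES.items():
        if not np.any(y == cls):
            raise TrainingError(f"no labeled pixels for class {name!r}")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        min_samples_leaf=2,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return PixelClassifier(forest=forest, n_channels=stacks2x[0].shape[0])


def predict_probabilities(
    classifier: PixelClassifier, stack2x: np.ndarray
) -> PixelProbabilities:
    """Per-pixel class posteriors for a 2x stack."""
    if stack2x.shape[0] != classifier.n_channels:
        raise ValueError(
            f"channel mismatch: classifier trained on {classifier.n_channels} "
            f"channels, stack has {stack2x.shape[0]}"
        )
    h, w = stack2x.shape[1:]
    feats = _pixel_features(stack2x).reshape(-1, classifier.forest.n_features_in_)
    proba = classifier.forest.predict_proba(feats)
    planes = {}
    for cls in (1, 2, 3):
        col = np.where(classifier.forest.classes_ == cls)[0]
        planes[cls] = (
            proba[:, col[0]].reshape(h, w) if col.size else np.zeros((h, w))
        )
    return PixelProbabilities(
        nuclear=planes[1], cytoplasm=planes[2], background=planes[3]
    )


def segment_cells(
    probs: PixelProbabilities, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment the 2x probability maps into a 2x cell label mask.

    Nuclei are connected components of (nuclear >= threshold), split by a
    seeded watershed on the (lightly smoothed) distance transform with
    seeds at least ``watershed_min_seed_distance_px`` apart; components
    below ``min_nucleus_area_px`` are dropped. Cells grow from nuclei by a
    second watershed on the distance-to-nucleus, limited to
    ``max_expansion_px`` and to pixels where background < 0.5, so cells
    never cross each other (boundary pixels go to the nearer seed).
    """
    params = params or SegmentationParams()
    nuclear = probs.nuclear >= params.nuclear_prob_threshold
    if not nuclear.any():
        return np.zeros(nuclear.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(nuclear)
    # light smoothing removes plateau double-peaks in near-circular nuclei
    smooth = ndi.gaussian_filter(dist, 1.0)
    peaks = peak_local_max(
        smooth,
        min_distance=params.watershed_min_seed_distance_px,
        labels=ndi.label(nuclear)[0],
        exclude_border=False,
    )
    markers = np.zeros(nuclear.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    nuclei = watershed(-smooth, markers=markers, mask=nuclear)
    # drop undersized nuclei
    sizes = np.bincount(nuclei.ravel())
    small = np.flatnonzero(sizes < params.min_nucleus_area_px)
    nuclei[np.isin(nuclei, small)] = 0
    if not nuclei.any():
        return np.zeros(nuclear.shape, dtype=np.int32)
    # expand nuclei into cells through non-background pixels
    dist_to_nuc, (iy, ix) = ndi.distance_transform_edt(
        nuclei == 0, return_indices=True
    )
    allowed = ((probs.background < 0.5) | (nuclei > 0)) & (
        dist_to_nuc <= params.max_expansion_px
    )
    cells = watershed(dist_to_nuc, markers=nuclei, mask=allowed)
    return _compact_labels(cells)


def _compact_labels(mask: np.ndarray) -> np.ndarray:
    """Relabel to a contiguous 1..K set, preserving label order."""
    mask = np.asarray(mask)
    present = np.unique(mask)
    present = present[present > 0]
    lut = np.zeros(int(mask.max()) + 1 if mask.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1)
    return lut[mask]


def measure_cells(
    mask: np.ndarray,
    stack_1x: np.ndarray,
    panel: MarkerPanel,
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Per-cell area, centroid and per-marker mean intensity at 1x.

    Intensities are means over the cell's pixels of the raw (hot-pixel
    filtered but otherwise untransformed) counts.
    """
    mask = np.asarray(mask)
    if mask.shape != stack_1x.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack planes "
            f"{stack_1x.shape[1:]}"
        )
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        cols = ["roi_id", "cell_id", "centroid_row", "centroid_col", "area_px"]
        cols += list(panel.markers)
        return pd.DataFrame(columns=cols)
    areas = ndi.sum_labels(np.ones_like(mask), labels=mask, index=labels)
    centroids = np.array(ndi.center_of_mass(np.ones_like(mask), mask, labels))
    table = pd.DataFrame(
        {
            "roi_id": roi_id,
            "cell_id": labels.astype(int),
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
            "area_px": areas.astype(int),
        }
    )
    for ci, marker in enumerate(panel.markers):
        table[marker] = ndi.mean(
            np.asarray(stack_1x[ci], dtype=np.float64), labels=mask, index=labels
        )
    return table


@dataclass
class NeighborGraph:
    """Undirected cell-adjacency graph of one ROI's mask."""

    cell_ids: np.ndarray
    edges: np.ndarray  # (E, 2), each row sorted, lexicographically ordered

    def neighbors_of(self, cell: int) -> np.ndarray:
        hits = self.edges[(self.edges == cell).any(axis=1)]
        return np.setdiff1d(hits.ravel(), [cell])

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_neighbor_graph(mask: np.ndarray, radius_px: float = 4.0) -> NeighborGraph:
    """Cells a, b are neighbors iff dilating a's pixels by a Euclidean disk
    of ``radius_px`` reaches b — equivalently, some pixel of a lies within
    ``radius_px`` of some pixel of b. Computed on cell boundary pixels.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    mask = np.asarray(mask)
    cell_ids = np.unique(mask)
    cell_ids = cell_ids[cell_ids > 0]
    if cell_ids.size < 2:
        return NeighborGraph(cell_ids=cell_ids, edges=np.empty((0, 2), dtype=int))
    # boundary pixels: any 8-neighbor carries a different label
    eroded = ndi.minimum_filter(mask, size=3, mode="constant", cval=0)
    dilated = ndi.maximum_filter(mask, size=3, mode="constant", cval=0)
    boundary = (mask > 0) & ((eroded != mask) | (dilated != mask))
    coords = np.argwhere(boundary)
    labs = mask[boundary]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius_px, output_type="ndarray")
    if len(pairs) == 0:
        return NeighborGraph(cell_ids=cell_ids, edges=np.empty((0, 2), dtype=int))
    la, lb = labs[pairs[:, 0]], labs[pairs[:, 1]]
    keep = la != lb
    edges = np.sort(np.stack([la[keep], lb[keep]], axis=1), axis=1)
    if len(edges) == 0:
        return NeighborGraph(cell_ids=cell_ids, edges=np.empty((0, 2), dtype=int))
    edges = np.unique(edges, axis=0)
    return NeighborGraph(cell_ids=cell_ids, edges=edges)


def segment_roi(
    roi: RoiImage,
    classifier: PixelClassifier,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full per-ROI segmentation: filter, upscale, classify, segment,
    rescale, measure. Returns (1x label mask, cell table)."""
    params = params or SegmentationParams()
    filtered = remove_hot_pixels(roi.stack, params.hotpixel_factor)
    probs = predict_probabilities(classifier, upscale2x(filtered))
    mask2x = segment_cells(probs, params)
    mask = _compact_labels(downscale_mask(mask2x))
    cells = measure_cells(mask, filtered, roi.panel, roi_id=roi.roi_id)
    return mask, cells


def match_cells(
    true_mask: np.ndarray, pred_mask: np.ndarray, iou_threshold: float = 0.5
) -> pd.DataFrame:
    """1:1 matching of true to predicted cells by intersection-over-union.

    At IoU >= 0.5 a match is necessarily unique. Returns one row per true
    cell: best-overlap predicted label, IoU, matched flag, centroid error.
    """
    true_mask = np.asarray(true_mask)
    pred_mask = np.asarray(pred_mask)
    t = true_mask.ravel()
    p = pred_mask.ravel()
    sel = (t > 0) | (p > 0)
    pairs, counts = np.unique(
        np.stack([t[sel], p[sel]]), axis=1, return_counts=True
    )
    t_area = {int(l): int(a) for l, a in zip(*np.unique(t[t > 0], return_counts=True))}
    p_area = {int(l): int(a) for l, a in zip(*np.unique(p[p > 0], return_counts=True))}
    best: dict[int, tuple[int, float]] = {}
    for (tl, pl), inter in zip(pairs.T, counts):
        tl, pl = int(tl), int(pl)
        if tl == 0 or pl == 0:
            continue
        iou = inter / (t_area[tl] + p_area[pl] - inter)
        if iou > best.get(tl, (0, -1.0))[1]:
            best[tl] = (pl, iou)
    t_cent = _centroids(true_mask)
    p_cent = _centroids(pred_mask)
    rows = []
    for tl in sorted(t_area):
        pl, iou = best.get(tl, (0, 0.0))
        matched = iou >= iou_threshold
        err = (
            float(np.linalg.norm(np.subtract(t_cent[tl], p_cent[pl])))
            if matched
            else np.nan
        )
        rows.append(
            {
                "true_label": tl,
                "pred_label": pl,
                "iou": iou,
                "matched": matched,
                "centroid_error_px": err,
            }
        )
    return pd.DataFrame(rows)


def _centroids(mask: np.ndarray) -> dict[int, tuple[float, float]]:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    cents = ndi.center_of_mass(np.ones_like(mask), mask, labels)
    return {int(l): c for l, c in zip(labels, cents)}
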