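"""Synthetic multiplexed-tissue simulator with known ground truth.

Generates 2D multi-channel ROIs emulating liver-allograft immune
microenvironments: a majority of hepatocytes plus immune cells that are
sparse and scattered in no-rejection (NR) tissue and concentrated in dense
mixed aggregates in chronic-rejection (CR) tissue, optionally with planted
pairwise spatial attractions between phenotypes. Every ROI comes with the
true cell mask, per-cell phenotype labels and expression draws, so each
downstream stage (segmentation, clustering, neighborhood testing, cohort
modeling) has an exact oracle.

Cells are non-overlapping disks (>= 1 px gap) with radius ~ N(r, 10%),
clipped at 2 px — liver cell morphology is close to uniform, which is what
makes it a favourable tissue for single-cell segmentation. Expression is a
per-cell lognormal draw (mean-preserving, CV from the profile) rendered as
a constant Poisson rate over the cell disk, plus a small uniform background
rate; the nuclear (iridium) channel is concentrated in a nuclear disk with
a weak whole-cell residue so that nuclear, cytoplasmic and background
pixels are distinguishable classes. Collagen is a smooth banded texture
independent of cell positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import RoiImage
from .panel import MarkerPanel, default_panel

IMMUNE_PHENOTYPES = (
    "B-cell",
    "HLADR+",
    "Naive T-cell",
    "Other Leukocyte",
    "Neutrophil",
    "CTL-1",
    "CTL-2",
    "Macrophage-1",
    "Macrophage-2",
    "Other T-cell-1",
    "Other T-cell-2",
)
NON_IMMUNE_LABEL = "not immune cell"
HEPATOCYTE = "Hepatocyte"

# Mean intensity (counts) per immune marker for each bundled phenotype.
# Marker order: CD20, CD68, CD66a, CD45, CD45RA, CD3, CD8, HLA-DR.
# The "-1"/"-2" pairs share a marker pattern but differ in signal level,
# mirroring how graph clustering separates bright and dim variants of the
# same lineage; macrophages carry no CD3.
_IMMUNE_MEANS = {
    "B-cell":          (20, 0, 0, 3, 0, 0, 0, 0),
    "HLADR+":          (0, 0, 0, 0, 0, 0, 0, 18),
    "Naive T-cell":    (0, 0, 0, 5, 18, 0, 0, 0),
    "Other Leukocyte": (0, 0, 0, 15, 0, 0, 0, 0),
    "Neutrophil":      (0, 0, 18, 4, 0, 0, 0, 0),
    "CTL-1":           (0, 0, 0, 18, 0, 16, 14, 0),
    "CTL-2":           (0, 0, 0, 9, 0, 9, 9, 0),
    "Macrophage-1":    (0, 20, 0, 4, 0, 0, 0, 5),
    "Macrophage-2":    (0, 11, 0, 2, 0, 0, 0, 0),
    "Other T-cell-1":  (0, 0, 0, 16, 0, 14, 0, 0),
    "Other T-cell-2":  (0, 0, 0, 6, 0, 11, 0, 0),
}
_NUCLEAR_MEAN_IMMUNE = 18.0
_NUCLEAR_MEAN_HEPATOCYTE = 20.0
_RADIUS = {HEPATOCYTE: 5.0, "Macrophage-1": 4.0, "Macrophage-2": 4.0}
_DEFAULT_RADIUS = 3.0
_DEFAULT_CV = 0.2

# Fraction of the nuclear-channel mean rendered over the whole cell disk
# (residual cytoplasmic intercalation); gives cytoplasm pixels a signal
# above background on every cell, including marker-null hepatocytes.
CYTOPLASM_NUCLEAR_FRACTION = 0.15
NUCLEUS_RADIUS_FRACTION = 0.55


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


class SimulationError(RuntimeError):
    """Raised when a requested configuration cannot be realised."""


@dataclass(frozen=True)
class PhenotypeProfile:
    """Expression profile and geometry of one simulated cell phenotype."""

    name: str
    immune: bool
    marker_means: np.ndarray
    marker_cv: np.ndarray
    radius_px: float

    def __post_init__(self):
        object.__setattr__(self, "marker_means", np.asarray(self.marker_means, float))
        object.__setattr__(self, "marker_cv", np.asarray(self.marker_cv, float))
        if np.any(self.marker_means < 0):
            raise ConfigurationError(f"{self.name}: marker means must be >= 0")
        if self.marker_means.shape != self.marker_cv.shape:
            raise ConfigurationError(f"{self.name}: means/cv length mismatch")


def default_profiles(panel: MarkerPanel | None = None) -> list[PhenotypeProfile]:
    """The 12 bundled phenotype profiles (11 immune + hepatocyte).

    All profiles have a positive nuclear mean (every cell has a nucleus);
    the hepatocyte profile has zero on all immune markers.
    """
    panel = panel or default_panel()
    known = set(default_panel().markers)
    for m in panel.markers:
        if m not in known:
            raise ConfigurationError(f"unknown marker in panel: {m!r}")
    profiles = []
    immune_order = default_panel().immune_markers
    for name in IMMUNE_PHENOTYPES:
        by_marker = dict(zip(immune_order, _IMMUNE_MEANS[name]))
        means = np.zeros(len(panel))
        for i, (marker, role) in enumerate(zip(panel.markers, panel.roles)):
            if role == "immune":
                means[i] = by_marker.get(marker, 0.0)
            elif role == "nuclear":
                means[i] = _NUCLEAR_MEAN_IMMUNE
        profiles.append(
            PhenotypeProfile(
                name=name,
                immune=True,
                marker_means=means,
                marker_cv=np.full(len(panel), _DEFAULT_CV),
                radius_px=_RADIUS.get(name, _DEFAULT_RADIUS),
            )
        )
    hep_means = np.zeros(len(panel))
    hep_means[panel.index_of(panel.nuclear_marker)] = _NUCLEAR_MEAN_HEPATOCYTE
    profiles.append(
        PhenotypeProfile(
            name=HEPATOCYTE,
            immune=False,
            marker_means=hep_means,
            marker_cv=np.full(len(panel), _DEFAULT_CV),
            radius_px=_RADIUS[HEPATOCYTE],
        )
    )
    return profiles


@dataclass
class TissueSimConfig:
    """Per-ROI simulation settings.

    ``phenotype_mix`` is the categorical distribution of immune phenotypes
    (must sum to 1); hepatocytes are controlled by ``n_nonimmune``. For CR
    cohorts immune cells concentrate in ``aggregate_count`` Gaussian blobs
    of spread ``aggregate_sd_px``; ``planted_pairs`` lists
    (phenotype_A, phenotype_B, adjacency_prob) attractions under which that
    fraction of B cells is placed touching-distance from an A cell.
    """

    cohort: str = "NR"
    roi_shape_px: tuple[int, int] = (300, 300)
    pixel_size_um: float = 1.0
    n_nonimmune: int = 220
    n_immune: int = 40
    phenotype_mix: dict[str, float] = field(default_factory=dict)
    aggregate_count: int = 0
    aggregate_sd_px: float = 18.0
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_model: str = "lognormal-poisson"
    background_rate: float = 0.2
    collagen_amplitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.roi_shape_px) < 64:
            raise ConfigurationError("roi dimensions must be >= 64 px")
        if self.cohort not in ("NR", "CR"):
            raise ConfigurationError("cohort must be NR or CR")
        if self.noise_model not in ("poisson", "lognormal-poisson"):
            raise ConfigurationError("noise_model must be poisson or lognormal-poisson")
        if self.phenotype_mix:
            total = sum(self.phenotype_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"phenotype_mix sums to {total}, not 1")
        for a, b, p in self.planted_pairs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"adjacency_prob {p} outside [0, 1]")


#: Default immune mixes. NR is dominated by scattered neutrophils and
#: unspecified leukocytes with Macrophage-2 absent; CR is enriched for
#: Macrophage-2, CTL-2 and the two unspecified T-cell populations.
NR_MIX = {
    "B-cell": 0.02, "HLADR+": 0.08, "Naive T-cell": 0.10,
    "Other Leukocyte": 0.30, "Neutrophil": 0.30, "CTL-1": 0.08,
    "CTL-2": 0.02, "Macrophage-1": 0.08, "Macrophage-2": 0.0,
    "Other T-cell-1": 0.01, "Other T-cell-2": 0.01,
}
CR_MIX = {
    "B-cell": 0.04, "HLADR+": 0.07, "Naive T-cell": 0.05,
    "Other Leukocyte": 0.08, "Neutrophil": 0.06, "CTL-1": 0.12,
    "CTL-2": 0.18, "Macrophage-1": 0.10, "Macrophage-2": 0.14,
    "Other T-cell-1": 0.08, "Other T-cell-2": 0.08,
}


def nr_default_config(**overrides) -> TissueSimConfig:
    cfg = TissueSimConfig(cohort="NR", n_nonimmune=220, n_immune=40,
                          phenotype_mix=dict(NR_MIX))
    return replace(cfg, **overrides)


def cr_default_config(**overrides) -> TissueSimConfig:
    cfg = TissueSimConfig(
        cohort="CR", n_nonimmune=180, n_immune=200,
        phenotype_mix=dict(CR_MIX), aggregate_count=4, aggregate_sd_px=18.0,
        planted_pairs=[("Macrophage-2", "CTL-2", 0.8)],
    )
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """The simulator's oracle for one ROI.

    ``true_mask`` partitions cell pixels (0 = background, k = cell k);
    ``cells`` is a per-cell table with centroid, radius, phenotype and the
    true per-cell expression draw for every marker.
    """

    roi_id: str
    cohort: str
    true_mask: np.ndarray
    nucleus_mask: np.ndarray
    cells: pd.DataFrame
    planted_pairs: list[tuple[str, str, float]]

    @property
    def phenotype_of_cell(self) -> pd.Series:
        return self.cells.set_index("cell_id")["phenotype"]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _paint_disks(shape, rows, cols, radii, labels, out=None):
    """Rasterise labelled disks; later labels never overwrite earlier ones
    (placement guarantees disjointness anyway)."""
    mask = out if out is not None else np.zeros(shape, dtype=np.int32)
    for y, x, r, lab in zip(rows, cols, radii, labels):
        r_int = int(math.ceil(r))
        y0, y1 = max(0, int(y) - r_int - 1), min(shape[0], int(y) + r_int + 2)
        x0, x1 = max(0, int(x) - r_int - 1), min(shape[1], int(x) + r_int + 2)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        sub = mask[y0:y1, x0:x1]
        sub[disk & (sub == 0)] = lab
    return mask


def _lognormal_mean_preserving(mean, cv, rng):
    """Draw with E[X] = mean and SD/mean = cv (elementwise); zeros stay zero."""
    mean = np.asarray(mean, float)
    cv = np.asarray(cv, float)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(mean.shape)
    return mean * np.exp(sigma * z - 0.5 * sigma**2)


def _collagen_field(shape, amplitude, background, rng):
    """Smooth banded texture independent of cell positions."""
    nrows, ncols = shape
    yy, xx = np.mgrid[0:nrows, 0:ncols].astype(float)
    theta = rng.uniform(0, math.pi)
    wavelength = rng.uniform(60, 120)
    phase = rng.uniform(0, 2 * math.pi)
    coord = yy * math.sin(theta) + xx * math.cos(theta)
    bands = np.maximum(0.0, np.sin(2 * math.pi * coord / wavelength + phase))
    # low-frequency modulation so bands are patchy rather than perfectly even
    coarse = rng.standard_normal((6, 6))
    from scipy.ndimage import zoom

    mod = zoom(coarse, (nrows / 6, ncols / 6), order=3)[:nrows, :ncols]
    mod = (mod - mod.min()) / max(float(np.ptp(mod)), 1e-12)
    return background + amplitude * bands * mod


def simulate_roi(
    config: TissueSimConfig,
    panel: MarkerPanel | None = None,
    profiles: list[PhenotypeProfile] | None = None,
    roi_id: str | None = None,
    render: bool = True,
) -> tuple[RoiImage | None, GroundTruth]:
    """Simulate one ROI; deterministic for a fixed config (incl. seed).

    With ``render=False`` the channel stack is skipped (returns ``None`` in
    its place) but placement, mask and expression draws are identical —
    useful when only the ground-truth cell table is needed.
    """
    panel = panel or default_panel()
    profiles = profiles if profiles is not None else default_profiles(panel)
    by_name = {p.name: p for p in profiles}
    mix = config.phenotype_mix or (dict(CR_MIX) if config.cohort == "CR" else dict(NR_MIX))
    for name in mix:
        if name not in by_name:
            raise ConfigurationError(f"phenotype_mix references unknown profile {name!r}")
    rng = np.random.default_rng(config.seed)
    roi_id = roi_id or f"{config.cohort}-{config.seed}"
    shape = tuple(config.roi_shape_px)

    # --- choose phenotypes -------------------------------------------------
    mix_names = sorted(mix)
    mix_p = np.array([mix[n] for n in mix_names], float)
    mix_p = mix_p / mix_p.sum()
    immune_phen = rng.choice(mix_names, size=config.n_immune, p=mix_p) if config.n_immune else np.array([], dtype=object)
    nonimmune = [p.name for p in profiles if not p.immune]
    hep_name = nonimmune[0] if nonimmune else HEPATOCYTE
    phenotypes = list(immune_phen) + [hep_name] * config.n_nonimmune

    radii = np.array(
        [
            max(2.0, rng.normal(by_name[p].radius_px, 0.1 * by_name[p].radius_px))
            for p in phenotypes
        ]
    )

    # --- build placement specs --------------------------------------------
    n_imm = config.n_immune
    planted_b_idx: dict[int, tuple[str, float]] = {}
    for a_name, b_name, prob in config.planted_pairs:
        b_cells = [i for i in range(n_imm) if phenotypes[i] == b_name]
        n_adj = int(round(prob * len(b_cells)))
        chosen = rng.choice(b_cells, size=n_adj, replace=False) if n_adj else []
        for i in chosen:
            planted_b_idx[int(i)] = (a_name, prob)

    if config.cohort == "CR" and config.aggregate_count > 0:
        margin = 3 * config.aggregate_sd_px
        centers = [
            (
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            )
            for _ in range(config.aggregate_count)
        ]
        center_of = rng.integers(0, config.aggregate_count, size=n_imm)
    else:
        centers, center_of = [], None

    def base_spec(i):
        if center_of is not None:
            return {
                "radius": radii[i],
                "mode": "blob",
                "center": centers[int(center_of[i])],
                "sd": config.aggregate_sd_px,
            }
        return {"radius": radii[i], "mode": "uniform"}

    # Placement order: anchor-phenotype cells first (so planted partners
    # find uncrowded anchors), then planted B cells, then the remaining
    # immune cells, then hepatocytes fill the remaining space.
    anchor_names = {a for a, _, _ in config.planted_pairs}
    anchor_cells = [
        i for i in range(n_imm)
        if phenotypes[i] in anchor_names and i not in planted_b_idx
    ]
    free_imm = [
        i for i in range(n_imm)
        if i not in planted_b_idx and i not in anchor_cells
    ]
    order = (
        anchor_cells + sorted(planted_b_idx) + free_imm
        + list(range(n_imm, len(phenotypes)))
    )

    rows = np.empty(len(phenotypes))
    cols = np.empty(len(phenotypes))
    placed_order: list[int] = []
    for i in order:
        prev = np.array(placed_order, dtype=int)
        if i in planted_b_idx:
            a_name, _ = planted_b_idx[i]
            anchors = [j for j in placed_order if phenotypes[j] == a_name]
            if not anchors:
                raise SimulationError(
                    f"planted pair requires phenotype {a_name!r} but none were placed"
                )
            y = x = None
            for j in rng.permutation(anchors):
                spec = {
                    "radius": radii[i],
                    "mode": "adjacent",
                    "anchor_yx": (rows[int(j)], cols[int(j)]),
                    "anchor_radius": radii[int(j)],
                }
                try:
                    y, x = _place_one(
                        shape, spec, rows[prev], cols[prev], radii[prev], rng,
                        max_attempts=60,
                    )
                    break
                except SimulationError:
                    continue
            if y is None:
                raise SimulationError(
                    f"could not place a planted-pair cell adjacent to any "
                    f"{a_name!r} anchor; reduce cell density"
                )
        else:
            spec = base_spec(i) if i < n_imm else {"radius": radii[i], "mode": "uniform"}
            y, x = _place_one(shape, spec, rows[prev], cols[prev], radii[prev], rng)
        rows[i], cols[i] = y, x
        placed_order.append(i)

    # --- ground truth ------------------------------------------------------
    labels = np.arange(1, len(phenotypes) + 1)
    true_mask = _paint_disks(shape, rows, cols, radii, labels)
    nuc_radii = np.maximum(1.5, NUCLEUS_RADIUS_FRACTION * radii)
    nucleus_mask = _paint_disks(shape, rows, cols, nuc_radii, labels)

    if not phenotypes:
        expr = np.zeros((0, len(panel)))
    elif config.noise_model == "lognormal-poisson":
        expr = np.vstack(
            [
                _lognormal_mean_preserving(
                    by_name[p].marker_means, by_name[p].marker_cv, rng
                )
                for p in phenotypes
            ]
        )
    else:
        expr = np.vstack([by_name[p].marker_means for p in phenotypes])

    cells = pd.DataFrame(
        {
            "roi_id": roi_id,
            "cell_id": labels,
            "phenotype": phenotypes,
            "immune": [by_name[p].immune for p in phenotypes],
            "centroid_row": rows,
            "centroid_col": cols,
            "radius_px": radii,
        }
    )
    for ci, marker in enumerate(panel.markers):
        cells[marker] = expr[:, ci]

    truth = GroundTruth(
        roi_id=roi_id,
        cohort=config.cohort,
        true_mask=true_mask,
        nucleus_mask=nucleus_mask,
        cells=cells,
        planted_pairs=list(config.planted_pairs),
    )
    if not render:
        return None, truth

    # --- render channels ---------------------------------------------------
    nuc_idx = panel.index_of(panel.nuclear_marker)
    rate = np.full((len(panel),) + shape, config.background_rate, dtype=np.float64)
    cell_disk = true_mask > 0
    nuc_disk = nucleus_mask > 0
    for ci in range(len(panel)):
        if ci == nuc_idx:
            whole = expr[:, ci] * CYTOPLASM_NUCLEAR_FRACTION
            rate[ci][cell_disk] += whole[true_mask[cell_disk] - 1]
            rate[ci][nuc_disk] += (expr[:, ci] * (1 - CYTOPLASM_NUCLEAR_FRACTION))[
                nucleus_mask[nuc_disk] - 1
            ]
        elif panel.roles[ci] == "structural":
            rate[ci] = _collagen_field(
                shape, config.collagen_amplitude, config.background_rate, rng
            )
        else:
            rate[ci][cell_disk] += expr[:, ci][true_mask[cell_disk] - 1]
    stack = rng.poisson(rate).astype(np.uint16)
    roi = RoiImage(
        roi_id=roi_id,
        stack=stack,
        panel=panel,
        cohort=config.cohort,
        pixel_size_um=config.pixel_size_um,
    )
    return roi, truth


def _place_one(shape, spec, prev_rows, prev_cols, prev_radii, rng, max_attempts=300):
    r = spec["radius"]
    nrows, ncols = shape
    for attempt in range(max_attempts):
        mode = spec["mode"]
        if mode == "uniform":
            y = rng.uniform(r, nrows - r)
            x = rng.uniform(r, ncols - r)
        elif mode == "blob":
            cy, cx = spec["center"]
            # aggregates saturate: widen gradually when packing gets tight
            sd = spec["sd"] * (1.0 + attempt / 100.0)
            y = rng.normal(cy, sd)
            x = rng.normal(cx, sd)
        else:  # adjacent
            ay, ax = spec["anchor_yx"]
            # any gap below the 4 px adjacency radius keeps the pair
            # neighbors; later attempts explore the wider ring
            gap = rng.uniform(1.0, 2.0 if attempt < 60 else 3.5)
            d = spec["anchor_radius"] + r + gap
            theta = rng.uniform(0.0, 2.0 * math.pi)
            y = ay + d * math.sin(theta)
            x = ax + d * math.cos(theta)
        if not (r <= y <= nrows - r and r <= x <= ncols - r):
            continue
        if len(prev_rows):
            d2 = (prev_rows - y) ** 2 + (prev_cols - x) ** 2
            if np.any(d2 < (prev_radii + r + 1.0) ** 2):
                continue
        return y, x
    density = (
        (len(prev_rows) + 1)
        * math.pi
        * float(np.mean(np.append(prev_radii, r))) ** 2
        / (nrows * ncols)
    )
    raise SimulationError(
        f"could not place a cell after {max_attempts} attempts "
        f"(approximate disk density {density:.2f}); reduce cell counts or "
        f"enlarge the ROI"
    )


def generate_cohort(
    n_nr_roi: int,
    n_cr_roi: int,
    nr_config: TissueSimConfig | None = None,
    cr_config: TissueSimConfig | None = None,
    seed: int = 0,
    panel: MarkerPanel | None = None,
    profiles: list[PhenotypeProfile] | None = None,
    render: bool = True,
) -> list[tuple[RoiImage | None, GroundTruth]]:
    """Simulate a cohort of ROIs (default shape mirrors the 8 NR / 24 CR
    study design); per-ROI seeds derive reproducibly from the master seed."""
    if n_nr_roi < 1 or n_cr_roi < 1:
        raise ConfigurationError("cohort requires at least one ROI per group")
    nr_config = nr_config or nr_default_config()
    cr_config = cr_config or cr_default_config()
    seeds = np.random.SeedSequence(seed).generate_state(n_nr_roi + n_cr_roi)
    out = []
    for k in range(n_nr_roi):
        cfg = replace(nr_config, seed=int(seeds[k]) % (2**31))
        out.append(
            simulate_roi(cfg, panel, profiles, roi_id=f"NR-{k + 1:02d}", render=render)
        )
    for k in range(n_cr_roi):
        cfg = replace(cr_config, seed=int(seeds[n_nr_roi + k]) % (2**31))
        out.append(
            simulate_roi(cfg, panel, profiles, roi_id=f"CR-{k + 1:02d}", render=render)
        )
    return out


def training_labels_from_truth(
    truth: GroundTruth, n_per_class: int = 1500, seed: int = 0
) -> np.ndarray:
    """Sparse 3-class pixel labels on the 2x grid derived from ground truth.

    Classes: 1 = nuclear, 2 = cytoplasm/membrane, 3 = background; 0 =
    unlabeled. Stands in for interactive brush labeling when training the
    pixel classifier on synthetic data.
    """
    rng = np.random.default_rng(seed)
    cell2x = np.kron(truth.true_mask, np.ones((2, 2), dtype=np.int32))
    nuc2x = np.kron(truth.nucleus_mask, np.ones((2, 2), dtype=np.int32))
    classes = np.where(nuc2x > 0, 1, np.where(cell2x > 0, 2, 3)).astype(np.uint8)
    labels = np.zeros_like(classes)
    for cls in (1, 2, 3):
        idx = np.flatnonzero(classes.ravel() == cls)
        take = min(n_per_class, idx.size)
        chosen = rng.choice(idx, size=take, replace=False)
        labels.ravel()[chosen] = cls
    return labels


def simulate_cohort_features(
    n_nr: int,
    n_cr: int,
    panel: MarkerPanel | None = None,
    immune_shift: float = 2.2,
    roi_cv: float = 0.3,
    load_cv: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-ROI median-marker feature vectors with a planted CR shift.

    Draws each ROI's median marker signal as a lognormal around a
    cohort-level mean, with CR ROIs shifted up by ``immune_shift`` on all
    immune markers — the feature-level analogue of a cohort whose immune
    infiltrate raises every immune marker. A shared per-ROI infiltrate-load
    factor (lognormal, CV ``load_cv``) multiplies all immune markers, so
    they co-vary across ROIs and the leading principal component draws
    balanced contributions from every immune marker. Returns
    (features, cohorts).
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    base = {"immune": 2.0, "structural": 3.0, "nuclear": 8.0}
    means = np.array([base[r] for r in panel.roles])
    is_immune = np.array([r == "immune" for r in panel.roles])
    rows, cohorts, ids = [], [], []
    for k in range(n_nr + n_cr):
        is_cr = k >= n_nr
        load = _lognormal_mean_preserving(
            np.array([1.0]), np.array([load_cv]), rng
        )[0]
        mu = means * np.where(is_immune, (immune_shift if is_cr else 1.0) * load, 1.0)
        rows.append(_lognormal_mean_preserving(mu, np.full(len(panel), roi_cv), rng))
        cohorts.append("CR" if is_cr else "NR")
        ids.append(f"{'CR' if is_cr else 'NR'}-{k + 1:02d}")
    feats = pd.DataFrame(rows, columns=list(panel.markers), index=ids)
    return feats, pd.Series(cohorts, index=ids, name="cohort")
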