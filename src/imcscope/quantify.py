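"""Per-ROI summary statistics and cohort comparisons.

Two per-ROI feature families: the median marker signal over ALL cells
(immune and not) per marker, and immune subpopulation counts/proportions
where the denominator is the ROI's total immune cells (non-immune cells
excluded). Group differences use the two-sided Wilcoxon rank-sum test —
exact when both groups have n <= 10 and no ties, tie-corrected normal
approximation otherwise — reported with Benjamini-Hochberg q-values
alongside the raw p (the raw p is the headline convention here; q is
provided for transparency).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phenotype import NON_IMMUNE_LABEL

logger = logging.getLogger(__name__)


def median_marker_per_roi(cells: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Median over all of an ROI's cells of the per-cell mean intensity,
    per marker. ROIs with no cells are simply absent from the output."""
    if cells.empty:
        return pd.DataFrame(columns=list(markers))
    return cells.groupby("roi_id")[list(markers)].median()


def immune_counts(
    cells: pd.DataFrame, cell_labels: np.ndarray
) -> pd.DataFrame:
    """ROI x immune-subpopulation cell counts (zero-filled)."""
    df = pd.DataFrame(
        {"roi_id": cells["roi_id"].to_numpy(), "label": np.asarray(cell_labels)}
    )
    df = df[df["label"] != NON_IMMUNE_LABEL]
    counts = (
        df.groupby(["roi_id", "label"]).size().unstack(fill_value=0).sort_index(axis=1)
    )
    # ROIs with zero immune cells still get a (all-zero) row
    all_rois = pd.Index(cells["roi_id"].unique(), name="roi_id")
    return counts.reindex(all_rois, fill_value=0)


def immune_proportions(
    cells: pd.DataFrame, cell_labels: np.ndarray
) -> pd.DataFrame:
    """Per ROI: subpopulation count / total immune count.

    ROIs with zero immune cells get missing (NaN) proportions, not zeros —
    the quantity is undefined there.
    """
    counts = immune_counts(cells, cell_labels)
    totals = counts.sum(axis=1)
    props = counts.divide(totals.replace(0, np.nan), axis=0)
    n_empty = int((totals == 0).sum())
    if n_empty:
        logger.warning("%d ROI(s) have no immune cells; proportions are missing", n_empty)
    return props


def standardize_counts(features: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores over ROIs (population SD; zero-SD columns -> 0).

    The zero point of each column is the average cell frequency of that
    subpopulation across ROIs.
    """
    if len(features) < 2:
        raise ValueError("standardization requires >= 2 ROIs")
    return _column_z(features)


def _column_z(frame: pd.DataFrame) -> pd.DataFrame:
    """Population z-scores per column; (near-)constant columns -> 0.

    SD below float roundoff of the column mean is treated as zero, so
    constant columns cannot blow up into garbage z-scores.
    """
    mu = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=0)
    tol = 1e-9 * np.maximum(1.0, np.abs(mu))
    sd = sd.where(sd > tol, np.inf)
    return (frame - mu).divide(sd, axis=1)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact null when both n <= 10 and no
    ties, tie-corrected normal approximation otherwise; identical pooled
    values give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_cohorts(
    features: pd.DataFrame, cohorts: pd.Series
) -> pd.DataFrame:
    """Per-variable NR-vs-CR Wilcoxon rank-sum over ROI features.

    ``cohorts`` maps roi_id -> NR/CR. Missing feature values (e.g.
    proportions of ROIs without immune cells) are dropped per variable.
    Returns statistic, raw p, and Benjamini-Hochberg q per variable.
    """
    cohorts = cohorts.reindex(features.index)
    rows = []
    for var in features.columns:
        col = features[var]
        x = col[(cohorts == "NR") & col.notna()].to_numpy()
        y = col[(cohorts == "CR") & col.notna()].to_numpy()
        if len(x) == 0 or len(y) == 0:
            rows.append(
                {"variable": var, "n_nr": len(x), "n_cr": len(y),
                 "statistic": np.nan, "p": np.nan}
            )
            continue
        stat, p = rank_sum_test(x, y)
        rows.append(
            {"variable": var, "n_nr": len(x), "n_cr": len(y),
             "statistic": stat, "p": p}
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def summarize_cohort_counts(counts: pd.DataFrame) -> dict[str, float]:
    """Aggregate per-cohort cell totals into the headline cohort numbers.

    ``counts`` has one row per cohort with columns ``cohort``,
    ``total_cells``, ``immune_cells``. Returns overall totals, each
    cohort's share of all immune cells (percent), and each cohort's
    within-cohort immune fraction (percent) — two distinct denominators
    that are easy to conflate, so both are reported explicitly.
    """
    counts = counts.set_index("cohort")
    total_cells = int(counts["total_cells"].sum())
    total_immune = int(counts["immune_cells"].sum())
    out: dict[str, float] = {
        "total_cells": total_cells,
        "total_immune_cells": total_immune,
    }
    for cohort, row in counts.iterrows():
        share = 100.0 * row["immune_cells"] / total_immune if total_immune else np.nan
        within = (
            100.0 * row["immune_cells"] / row["total_cells"]
            if row["total_cells"]
            else np.nan
        )
        out[f"pct_of_all_immune_in_{cohort}"] = share
        out[f"pct_immune_within_{cohort}"] = within
    return out


def collapse_by_patient(
    features: pd.DataFrame, patient_of_roi: pd.Series
) -> pd.DataFrame:
    """Average ROI features within patient (for designs with 1-2 ROIs per
    patient where ROI-level independence is in doubt)."""
    groups = patient_of_roi.reindex(features.index)
    return features.groupby(groups).mean()
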