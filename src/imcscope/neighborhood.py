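"""Permutation-based pairwise spatial interaction / avoidance testing.

For an ordered phenotype pair (A, B) within one ROI, the statistic is the
mean number of B-phenotype neighbors per A-phenotype cell on the fixed
cell-adjacency graph. The null distribution comes from uniformly permuting
phenotype labels over cells (the graph never changes); two one-tailed
Monte-Carlo p-values with the +1 pseudo-count,

    p_high = (1 + #{perm stat >= observed}) / (n_perm + 1)
    p_low  = (1 + #{perm stat <= observed}) / (n_perm + 1)

yield a verdict of interaction (p_high < alpha), avoidance (p_low < alpha)
or none. All pairs of an ROI share the same matched permutation stream.
Two permutation scopes are supported: over all cells (the 29-cluster style
analysis) or over immune cells only (the immune-focused analysis), selected
by the ``permutable`` mask. Across ROIs, each pair's verdicts aggregate to
a signed percentage where one interaction and one avoidance cancel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import NeighborGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseNeighborhoodResult:
    roi_id: str
    phenotype_a: str
    phenotype_b: str
    observed_stat: float
    p_high: float
    p_low: float
    verdict: str  # interaction | avoidance | none


def ordered_pairs(phenotypes: list[str]) -> list[tuple[str, str]]:
    """All ordered (A, B) pair hypotheses, self-pairs included — the 11
    immune subpopulations give 11^2 = 121 hypotheses."""
    return [(a, b) for a in phenotypes for b in phenotypes]


def pct_significant(n_significant: int, phenotypes: list[str]) -> float:
    """Percent of the ordered pair hypotheses that were significant."""
    n_pairs = len(ordered_pairs(phenotypes))
    return 100.0 * n_significant / n_pairs


def _label_arrays(graph: NeighborGraph, labels: pd.Series):
    cell_ids = graph.cell_ids
    lab = pd.Series(labels).reindex(cell_ids)
    if lab.isna().any():
        missing = cell_ids[lab.isna().to_numpy()][:5]
        raise ValueError(f"labels missing for cells {missing.tolist()}")
    pos_of = {int(c): i for i, c in enumerate(cell_ids)}
    if len(graph.edges):
        u = np.array([pos_of[int(a)] for a in graph.edges[:, 0]])
        v = np.array([pos_of[int(b)] for b in graph.edges[:, 1]])
    else:
        u = v = np.empty(0, dtype=int)
    return lab.to_numpy(), u, v


def pair_statistic(
    graph: NeighborGraph, labels: pd.Series, a: str, b: str
) -> float | None:
    """Mean count of B-neighbors per A-cell; ``None`` when A is absent.

    A = B is allowed (a cell is never its own neighbor).
    """
    lab, u, v = _label_arrays(graph, labels)
    n_a = int(np.sum(lab == a))
    if n_a == 0:
        logger.info("phenotype %r absent; pair statistic undefined", a)
        return None
    count = int(np.sum((lab[u] == a) & (lab[v] == b)))
    count += int(np.sum((lab[v] == a) & (lab[u] == b)))
    return count / n_a


def permutation_test(
    graph: NeighborGraph,
    labels: pd.Series,
    n_perm: int = 5000,
    alpha: float = 0.01,
    seed: int = 0,
    phenotypes: list[str] | None = None,
    permutable: pd.Series | None = None,
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Matched-permutation interaction/avoidance test for every ordered
    pair of ``phenotypes`` present in one ROI.

    ``labels`` maps cell_id -> phenotype for every cell in the graph.
    ``permutable`` (cell_id -> bool) restricts the label shuffle to a
    subset of cells (immune-only mode); unlisted cells keep their labels
    under the null. Pairs whose A phenotype is absent are omitted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lab, u, v = _label_arrays(graph, labels)
    if phenotypes is None:
        phenotypes = sorted(pd.unique(lab))
    cats = sorted(set(pd.unique(lab)) | set(phenotypes))
    code = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    codes = np.array([code[c] for c in lab])
    if permutable is None:
        perm_pos = np.arange(len(codes))
    else:
        pm = pd.Series(permutable).reindex(graph.cell_ids).fillna(False)
        perm_pos = np.flatnonzero(pm.to_numpy(dtype=bool))

    def count_matrix(c):
        if len(u) == 0:
            return np.zeros((k, k), dtype=np.int64)
        flat = np.bincount(c[u] * k + c[v], minlength=k * k)
        flat += np.bincount(c[v] * k + c[u], minlength=k * k)
        return flat.reshape(k, k)

    observed = count_matrix(codes)
    ge = np.zeros((k, k), dtype=np.int64)
    le = np.zeros((k, k), dtype=np.int64)
    rng = np.random.default_rng(seed)
    work = codes.copy()
    base = codes[perm_pos]
    for _ in range(n_perm):
        work[perm_pos] = base[rng.permutation(len(perm_pos))]
        counts = count_matrix(work)
        ge += counts >= observed
        le += counts <= observed

    n_of = {c: int(np.sum(codes == code[c])) for c in cats}
    rows = []
    for a, b in ordered_pairs(list(phenotypes)):
        if n_of.get(a, 0) == 0:
            logger.info("ROI %s: phenotype %r absent; pair (%s, %s) skipped",
                        roi_id, a, a, b)
            continue
        ia, ib = code[a], code[b]
        p_high = (1 + ge[ia, ib]) / (n_perm + 1)
        p_low = (1 + le[ia, ib]) / (n_perm + 1)
        if p_high < alpha:
            verdict = "interaction"
        elif p_low < alpha:
            verdict = "avoidance"
        else:
            verdict = "none"
        rows.append(
            {
                "roi_id": roi_id,
                "phenotype_a": a,
                "phenotype_b": b,
                "observed_stat": observed[ia, ib] / n_of[a],
                "p_high": p_high,
                "p_low": p_low,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "roi_id", "phenotype_a", "phenotype_b",
            "observed_stat", "p_high", "p_low", "verdict",
        ],
    )


def exhaustive_test(
    graph: NeighborGraph,
    labels: pd.Series,
    phenotypes: list[str] | None = None,
    roi_id: str = "roi",
    max_cells: int = 8,
) -> pd.DataFrame:
    """Exact enumeration over all label permutations (oracle for tiny ROIs).

    p_high = #{perm stat >= observed} / n!, the limit of the Monte-Carlo
    estimator; feasible only for graphs of <= ``max_cells`` cells.
    """
    lab, u, v = _label_arrays(graph, labels)
    n = len(lab)
    if n > max_cells:
        raise ValueError(f"exhaustive enumeration limited to {max_cells} cells")
    if phenotypes is None:
        phenotypes = sorted(pd.unique(lab))
    cats = sorted(set(pd.unique(lab)) | set(phenotypes))
    code = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    codes = np.array([code[c] for c in lab])

    def count_matrix(c):
        if len(u) == 0:
            return np.zeros((k, k), dtype=np.int64)
        flat = np.bincount(c[u] * k + c[v], minlength=k * k)
        flat += np.bincount(c[v] * k + c[u], minlength=k * k)
        return flat.reshape(k, k)

    observed = count_matrix(codes)
    ge = np.zeros((k, k), dtype=np.int64)
    le = np.zeros((k, k), dtype=np.int64)
    total = 0
    for perm in itertools.permutations(range(n)):
        counts = count_matrix(codes[list(perm)])
        ge += counts >= observed
        le += counts <= observed
        total += 1
    n_of = {c: int(np.sum(codes == code[c])) for c in cats}
    rows = []
    for a, b in ordered_pairs(list(phenotypes)):
        if n_of.get(a, 0) == 0:
            continue
        ia, ib = code[a], code[b]
        rows.append(
            {
                "roi_id": roi_id,
                "phenotype_a": a,
                "phenotype_b": b,
                "observed_stat": observed[ia, ib] / n_of[a],
                "p_high": ge[ia, ib] / total,
                "p_low": le[ia, ib] / total,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(results: pd.DataFrame) -> pd.DataFrame:
    """Signed percentage of significant events per pair across ROIs.

    score = 100 x (#interaction ROIs - #avoidance ROIs) / #testable ROIs;
    a pair testable in no ROI is absent. One interaction and one avoidance
    cancel. Values lie in [-100, 100].
    """
    if results.empty:
        return pd.DataFrame(columns=["phenotype_a", "phenotype_b", "score",
                                     "n_testable", "n_interaction", "n_avoidance"])
    grouped = results.groupby(["phenotype_a", "phenotype_b"])
    rows = []
    for (a, b), grp in grouped:
        n_test = len(grp)
        n_int = int((grp["verdict"] == "interaction").sum())
        n_avd = int((grp["verdict"] == "avoidance").sum())
        rows.append(
            {
                "phenotype_a": a,
                "phenotype_b": b,
                "score": 100.0 * (n_int - n_avd) / n_test,
                "n_testable": n_test,
                "n_interaction": n_int,
                "n_avoidance": n_avd,
            }
        )
    return pd.DataFrame(rows)


def summary_matrix(summary: pd.DataFrame, phenotypes: list[str]) -> pd.DataFrame:
    """Pivot the cohort summary into a phenotype x phenotype score matrix
    (NaN where a pair was never testable)."""
    mat = pd.DataFrame(np.nan, index=list(phenotypes), columns=list(phenotypes))
    for _, row in summary.iterrows():
        if row["phenotype_a"] in mat.index and row["phenotype_b"] in mat.columns:
            mat.loc[row["phenotype_a"], row["phenotype_b"]] = row["score"]
    return mat
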