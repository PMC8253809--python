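"""Drug x cell-line sensitivity profiling from AUC matrices.

The AUC of each fitted dose-response curve summarizes how active a drug
is in a cell line.  Subtracting each drug's median AUC across lines
removes intrinsic potency and leaves a selectivity signal (normalized
AUC); the drug maximizing normalized AUC in a line is that line's most
selectively effective drug.  Lines that are unusually sensitive to
nearly every drug are flagged as outliers by a robust
median + k*MAD rule on per-line median normalized AUC.  For heatmap-style
views, the most active quarter of drugs (by median AUC) is z-scored per
drug and clustered hierarchically (1 - Pearson distance, average
linkage) over both drugs and lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import median_abs_deviation

__all__ = [
    "ClusterResult",
    "build_auc_matrix",
    "normalize_auc",
    "most_selective_drug",
    "flag_outlier_lines",
    "select_top_active",
    "zscore_by_drug",
    "hierarchical_cluster",
    "profile_screen",
]


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_heights: np.ndarray
    col_heights: np.ndarray
    subset_used: list[str] = field(default_factory=list)


def build_auc_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    """Pivot a fits table into a drugs x cell-lines AUC matrix (NaN = missing).

    Duplicate (compound, line) pairs are rejected: replicates must be
    pooled before fitting, so one curve summary per pair is the contract.
    """
    if fits.empty:
        return pd.DataFrame()
    dup = fits.duplicated(subset=["compound_id", "cell_line"])
    if dup.any():
        pairs = fits.loc[dup, ["compound_id", "cell_line"]].to_records(index=False)
        raise ValueError(f"duplicate (drug, line) fits: {list(pairs)[:5]}")
    mat = fits.pivot(index="compound_id", columns="cell_line", values="auc")
    return mat.sort_index(axis=0).sort_index(axis=1)


def normalize_auc(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each drug's median AUC across lines (selectivity view).

    Medians ignore missing entries; a fully missing drug row is an error.
    Every returned row has median 0 over its non-missing entries.
    """
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"drug rows with no AUC values: {bad}")
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def most_selective_drug(view: pd.DataFrame, cell_line: str) -> tuple[str, float, bool]:
    """Drug maximizing normalized AUC in one line.

    Returns (drug, margin over runner-up, tie flag); ties break
    lexicographically by drug id.
    """
    if cell_line not in view.columns:
        raise KeyError(f"unknown cell line {cell_line!r}")
    col = view[cell_line].dropna()
    if col.empty:
        raise ValueError(f"cell line {cell_line!r} has no normalized AUC values")
    col = col.sort_index(kind="mergesort")
    best = col.max()
    winners = col.index[col == best]
    drug = winners[0]
    others = col.drop(drug)
    margin = float(best - others.max()) if not others.empty else float("inf")
    return str(drug), margin, len(winners) > 1


def flag_outlier_lines(view: pd.DataFrame, k: float = 3.0) -> list[str]:
    """Flag pan-sensitive cell lines.

    A line's score is its median normalized AUC across drugs; lines with
    score > median + k * MAD (normal-consistent MAD) are flagged.  Such
    lines respond more than their peers to nearly every drug and distort
    downstream comparisons, so callers typically drop them.
    """
    if view.shape[1] < 3:
        warnings.warn("fewer than 3 cell lines; outlier flagging skipped")
        return []
    scores = view.median(axis=0, skipna=True)
    center = scores.median()
    mad = median_abs_deviation(scores.to_numpy(), scale="normal")
    if not np.isfinite(k):
        return []
    cutoff = center + k * mad
    return sorted(scores.index[scores > cutoff].tolist())


def select_top_active(matrix: pd.DataFrame, fraction: float = 0.25) -> list[str]:
    """The round(fraction * n) drugs with highest median AUC across lines.

    Ranking ties at the cutoff are resolved lexicographically by drug id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.empty:
        raise ValueError("empty AUC matrix")
    n_sel = max(1, int(round(fraction * matrix.shape[0])))
    med = matrix.median(axis=1, skipna=True)
    ranked = med.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort")
    return ranked.index[:n_sel].tolist()


def zscore_by_drug(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each drug row to mean 0, sample sd 1 (non-missing entries).

    Constant rows (sd 0) carry no profile shape and are dropped with a
    warning.
    """
    mean = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    constant = sd.fillna(0) == 0
    if constant.any():
        warnings.warn(f"dropping constant AUC rows: {matrix.index[constant].tolist()}")
    kept = matrix.loc[~constant]
    return kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)


def _correlation_linkage(data: np.ndarray) -> np.ndarray:
    """Average linkage on 1 - Pearson row distances, computed explicitly
    so missing entries use pairwise-complete observations."""
    n = data.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(data[i]) & np.isfinite(data[j])
            if ok.sum() < 2:
                raise ValueError("insufficient overlap for correlation distance")
            a, b = data[i, ok], data[j, ok]
            sa, sb = a.std(), b.std()
            r = 0.0 if sa == 0 or sb == 0 else float(
                np.corrcoef(a, b)[0, 1])
            dist[i, j] = dist[j, i] = 1.0 - r
    return average(squareform(dist, checks=False))


def hierarchical_cluster(zscores: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of drug rows and cell-line columns.

    Distance 1 - Pearson correlation, average linkage; leaf order is
    deterministic for fixed input (rows/columns pre-sorted by id before
    linkage so ties break on identifiers).
    """
    if zscores.shape[0] < 2 or zscores.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    z = zscores.sort_index(axis=0).sort_index(axis=1)
    row_link = _correlation_linkage(z.to_numpy())
    col_link = _correlation_linkage(z.to_numpy().T)
    row_order = [z.index[i] for i in leaves_list(row_link)]
    col_order = [z.columns[i] for i in leaves_list(col_link)]
    return ClusterResult(z, [str(r) for r in row_order], [str(c) for c in col_order],
                         row_link[:, 2].copy(), col_link[:, 2].copy())


def profile_screen(
    fits: pd.DataFrame,
    top_fraction: float = 0.25,
    outlier_k: float = 3.0,
    cluster_on: str = "raw",
) -> dict:
    """Full profiling pass over a fits table.

    Builds the AUC matrix, normalizes, flags outlier lines (excluded from
    selectivity calls), picks each remaining line's most selective drug,
    and clusters z-scored profiles of the top-active drugs.
    ``cluster_on`` selects raw or normalized AUC rows for z-scoring.
    """
    matrix = build_auc_matrix(fits)
    view = normalize_auc(matrix)
    outliers = flag_outlier_lines(view, k=outlier_k)
    kept = view.drop(columns=outliers)
    kept_matrix = matrix.drop(columns=outliers)
    selectivity = {
        line: most_selective_drug(kept, line)
        for line in kept.columns
        if kept[line].notna().any()
    }
    top = select_top_active(kept_matrix, top_fraction)
    basis = kept_matrix if cluster_on == "raw" else kept
    z = zscore_by_drug(basis.loc[top])
    cluster = None
    if z.shape[0] >= 2 and z.shape[1] >= 2:
        cluster = hierarchical_cluster(z)
        cluster.subset_used = top
    return dict(auc_matrix=matrix, normalized_auc=view, outlier_lines=outliers,
                most_selective=selectivity, top_active=top, cluster=cluster)
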