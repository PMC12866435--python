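"""Multiplex cytokine panel analysis.

Implements the 27-plex workflow: limit-of-detection inclusion (a cytokine
is kept only if at least 3 replicates exceeded the LOD in every
experiment), per-experiment normalization to the pooled PBS controls,
z-scores within each cytokine, and agglomerative clustering with
correlation distance (d = 1 - Pearson r) and average (UPGMA) linkage.

Tables are long-format pandas DataFrames with columns::

    cytokine, experiment, culture, treatment, replicate,
    concentration, lod, below_lod

Concentrations are pg/mL.  Below-LOD values of retained cytokines are
imputed (LOD/2 by default) before normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "REQUIRED_COLUMNS",
    "ClusterTree",
    "filter_lod",
    "impute_below_lod",
    "normalize_to_control",
    "zscore_within_cytokine",
    "hcluster",
    "correlation_distances",
]

REQUIRED_COLUMNS = (
    "cytokine",
    "experiment",
    "culture",
    "treatment",
    "replicate",
    "concentration",
    "lod",
    "below_lod",
)


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cytokine table is missing column(s): {sorted(missing)}")


def filter_lod(table: pd.DataFrame, min_replicates: int = 3) -> list[str]:
    """Cytokines with >= ``min_replicates`` above-LOD replicates in *every*
    experiment (any condition counts).  Requires >= 2 experiments; with a
    single experiment the published rule is undefined."""
    _check_table(table)
    experiments = table["experiment"].unique()
    if len(experiments) < 2:
        raise ValueError("LOD rule requires at least 2 experiments")
    counts = (
        table[~table["below_lod"]]
        .groupby(["cytokine", "experiment"], sort=False)
        .size()
        .unstack("experiment", fill_value=0)
        .reindex(columns=experiments, fill_value=0)
    )
    counts = counts.reindex(table["cytokine"].unique(), fill_value=0)
    ok = (counts >= min_replicates).all(axis=1)
    return [c for c in table["cytokine"].unique() if ok.get(c, False)]


def impute_below_lod(table: pd.DataFrame, mode: str = "half") -> pd.DataFrame:
    """Replace below-LOD concentrations with LOD/2 (default), LOD, or LOD/sqrt(2)."""
    _check_table(table)
    divisor = {"half": 2.0, "lod": 1.0, "sqrt2": np.sqrt(2.0)}.get(mode)
    if divisor is None:
        raise ValueError("mode must be 'half', 'lod' or 'sqrt2'")
    out = table.copy()
    below = out["below_lod"].astype(bool)
    out.loc[below, "concentration"] = out.loc[below, "lod"] / divisor
    return out


def normalize_to_control(
    table: pd.DataFrame,
    control_treatment: str = "PBS",
    mode: str = "pooled",
) -> pd.DataFrame:
    """Fold change versus the PBS control mean within each experiment.

    ``mode='pooled'`` pools co- and tri-culture controls within an
    experiment (the clustering path); ``mode='per_culture'`` normalizes
    within culture type (the direct-comparison path).  Cytokines whose
    control mean is non-positive or entirely below LOD in some experiment
    are dropped with a warning.
    """
    _check_table(table)
    if mode not in {"pooled", "per_culture"}:
        raise ValueError("mode must be 'pooled' or 'per_culture'")
    keys = ["cytokine", "experiment"] + (["culture"] if mode == "per_culture" else [])
    ctrl = table[table["treatment"] == control_treatment]
    if ctrl.empty:
        raise ValueError(f"no control treatment {control_treatment!r} in table")
    ctrl_ok = ctrl[~ctrl["below_lod"].astype(bool)]
    ctrl_mean = ctrl_ok.groupby(keys)["concentration"].mean()

    out = table.copy()
    idx = pd.MultiIndex.from_frame(out[keys])
    denom = ctrl_mean.reindex(idx).to_numpy()
    bad = ~np.isfinite(denom) | (denom <= 0)
    if bad.any():
        dropped = sorted(out.loc[bad, "cytokine"].unique())
        warnings.warn(f"dropping cytokine(s) with unusable control mean: {dropped}")
        drop_set = set(dropped)
        keep = ~out["cytokine"].isin(drop_set)
        out, denom = out[keep].copy(), denom[keep.to_numpy()]
    out["fold_change"] = out["concentration"].to_numpy() / denom
    return out


def zscore_within_cytokine(fold_table: pd.DataFrame, value_col: str = "fold_change") -> pd.DataFrame:
    """Standardize each cytokine across all samples: (x - mean)/sd, sample SD.

    Adds a ``zscore`` column; zero-variance cytokines get NaN z-scores and a
    True ``zscore_degenerate`` flag instead of raising.
    """
    if value_col not in fold_table.columns:
        raise ValueError(f"missing value column {value_col!r}")
    out = fold_table.copy()
    grouped = out.groupby("cytokine")[value_col]
    counts = grouped.transform("count")
    if (counts < 2).any():
        raise ValueError("each cytokine needs >= 2 values for z-scoring")
    mean = grouped.transform("mean")
    sd = grouped.transform(lambda x: x.std(ddof=1))
    degenerate = sd == 0
    out["zscore"] = np.where(degenerate, np.nan, (out[value_col] - mean) / sd.replace(0, np.nan))
    out["zscore_degenerate"] = degenerate.to_numpy()
    return out


def correlation_distances(profiles: np.ndarray, labels: list[str]) -> np.ndarray:
    """Condensed 1 - Pearson r distances between rows, rejecting constants."""
    profiles = np.asarray(profiles, dtype=np.float64)
    sd = profiles.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant profile(s) have undefined correlation: {bad}")
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    corr = (centered @ centered.T) / np.outer(norm, norm)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


@dataclass
class ClusterTree:
    """UPGMA merge history over sample or cytokine profiles."""

    linkage_matrix: np.ndarray     # scipy (n-1, 4) linkage encoding
    labels: list[str]
    linkage: str = "average"
    distance: str = "correlation"

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"


def hcluster(
    z_table: pd.DataFrame,
    axis: str = "cols",
    value_col: str = "zscore",
    aggregate: bool = False,
) -> ClusterTree:
    """Average-linkage clustering with correlation distance.

    ``axis='cols'`` clusters samples (profiles across cytokines) and
    ``axis='rows'`` clusters cytokines (profiles across samples), matching
    the two margins of a clustergram.  The input is the long z-score table;
    samples are identified by (experiment, culture, treatment, replicate).
    With ``aggregate=True`` columns are the average z-score per
    (culture, treatment) group, the heatmap-of-averages presentation.
    """
    if axis not in {"rows", "cols"}:
        raise ValueError("axis must be 'rows' or 'cols'")
    if aggregate:
        sample_cols = [c for c in ("culture", "treatment") if c in z_table.columns]
    else:
        sample_cols = [c for c in ("experiment", "culture", "treatment", "replicate") if c in z_table.columns]
    wide = z_table.pivot_table(index="cytokine", columns=sample_cols, values=value_col, sort=False)
    if wide.isna().any().any():
        raise ValueError("missing values in clustered profiles (degenerate z-scores?)")
    if axis == "cols":
        profiles = wide.to_numpy().T
        labels = ["|".join(str(x) for x in (col if isinstance(col, tuple) else (col,))) for col in wide.columns]
    else:
        profiles = wide.to_numpy()
        labels = [str(i) for i in wide.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    dist = correlation_distances(profiles, labels)
    linkage_matrix = hierarchy.linkage(dist, method="average")
    return ClusterTree(linkage_matrix=linkage_matrix, labels=labels)


def plot_clustergram(
    z_table: pd.DataFrame,
    path=None,
    value_col: str = "zscore",
    aggregate: bool = True,
):
    """Heatmap of z-scores with rows and columns in dendrogram leaf order.

    Leaf order comes straight from the merge history (no optimal-leaf
    reordering) so the figure is deterministic.  Returns the matplotlib
    figure; saves to ``path`` (PNG/SVG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col_tree = hcluster(z_table, axis="cols", value_col=value_col, aggregate=aggregate)
    row_tree = hcluster(z_table, axis="rows", value_col=value_col, aggregate=aggregate)
    sample_cols = ["culture", "treatment"] if aggregate else [
        c for c in ("experiment", "culture", "treatment", "replicate") if c in z_table.columns
    ]
    wide = z_table.pivot_table(index="cytokine", columns=sample_cols, values=value_col, sort=False)
    wide.columns = ["|".join(str(x) for x in (c if isinstance(c, tuple) else (c,))) for c in wide.columns]
    wide = wide.loc[row_tree.leaf_order, col_tree.leaf_order]

    fig, ax = plt.subplots(figsize=(max(6, 0.4 * wide.shape[1]), max(4, 0.25 * wide.shape[0])))
    vmax = float(np.nanmax(np.abs(wide.to_numpy()))) or 1.0
    im = ax.imshow(wide.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(wide.shape[0]), wide.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
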