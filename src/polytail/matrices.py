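"""Feature × sample matrices, PCA, tail-length binning, group clustering.

A feature matrix pivots the molecule-count summaries into features (rows) ×
samples (columns) of one statistic: molecule count, mean tail length or
median tail length. PCA treats samples as observations on the features
observed in every sample (features with any missing cell are dropped, not
imputed — a fabricated zero would be a fake length). Binned matrices count
tails in fixed-width windows (frame 10 → 1-10, 11-20, ...) per grouping
value, optionally row-normalized to percentages, and feed the heatmap and
the hierarchical clustering of groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

logger = logging.getLogger(__name__)

STATISTICS = ("count", "avg_polyA_length", "median_polyA_length")
BIN_MODES = ("base", "normalized")


def build_feature_matrix(
    counts: pd.DataFrame,
    statistic: str = "median_polyA_length",
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Pivot per-(feature, sample) molecule summaries into a feature matrix.

    ``counts`` must come from ``count_molecules(..., grouping="sample_name")``.
    Cells are missing where a feature has no reads in a sample.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    matrix = counts.pivot(index="feature_id", columns="grouping_value", values=statistic)
    matrix.index.name = "feature_id"
    matrix.columns.name = "sample_name"
    if sample_order is not None:
        matrix = matrix.reindex(columns=sample_order)
    return matrix


@dataclass
class PcaResult:
    """Principal components of the sample × feature matrix.

    scores: samples × components; loadings: features × components; fractions
    of variance explained are non-increasing. Sign convention: within each
    component, the largest-magnitude loading is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    groups: pd.Series
    n_features_dropped: int


def run_pca(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    grouping_factor: str = "group",
) -> PcaResult:
    """PCA of samples over the complete features, centered but not scaled."""
    if matrix.shape[1] < 2:
        raise ValidationError("PCA requires at least two samples")
    complete = matrix.dropna(axis=0)
    n_dropped = matrix.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("dropped %d features missing in at least one sample", n_dropped)
    if complete.shape[0] < 2:
        raise ValidationError("fewer than two features observed in every sample")
    # samples are the observations: transpose to samples × features
    x = complete.to_numpy(float).T
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix signs so the largest-magnitude loading of each component is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    sample_names = list(matrix.columns)
    group_of = samples.set_index("sample_name")[grouping_factor]
    return PcaResult(
        scores=pd.DataFrame(scores, index=sample_names, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=complete.index, columns=comp_names),
        explained_variance_ratio=ratio,
        column_means=pd.Series(means, index=complete.index),
        groups=group_of.reindex(sample_names),
        n_features_dropped=n_dropped,
    )


def window_label(index: int, frame: int) -> str:
    """ASCII label of the ``index``-th (1-based) window of width ``frame``."""
    lo = (index - 1) * frame + 1
    return f"{lo}-{lo + frame - 1}"


def bin_tail_lengths(
    polya: pd.DataFrame,
    grouping_factor: str = "group",
    frame: int = 15,
    mode: str = "base",
) -> pd.DataFrame:
    """Count tails per fixed-width length window for each grouping value.

    Length L lands in window ceil(L/frame), so with frame 10 a 10-nt tail is
    in "1-10" and an 11-nt tail in "11-20". Windows tile from 1 up to the
    tile containing the longest observed tail. mode="normalized" converts
    each row to percentages summing to 100.
    """
    if frame < 1:
        raise ValidationError("frame must be >= 1")
    if mode not in BIN_MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    if len(polya) == 0:
        raise ValidationError("poly(A) table is empty")
    lengths = polya["polyA_length"].to_numpy()
    windows = np.ceil(lengths / frame).astype(int)
    n_windows = int(windows.max())
    labels = [window_label(i, frame) for i in range(1, n_windows + 1)]
    counts = (
        pd.DataFrame({grouping_factor: polya[grouping_factor].to_numpy(), "window": windows})
        .groupby([grouping_factor, "window"]).size().unstack(fill_value=0)
        .reindex(columns=range(1, n_windows + 1), fill_value=0)
        .sort_index()
    )
    counts.columns = labels
    counts.columns.name = "window"
    if mode == "normalized":
        counts = counts.div(counts.sum(axis=1), axis=0) * 100.0
    counts.attrs.update({"frame": frame, "mode": mode})
    return counts


@dataclass
class Dendrogram:
    """Agglomerative clustering of grouping values (rows of a binned matrix)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = recurse(node.left), recurse(node.right)
            # child branch length = merge height difference (leaves sit at 0)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:g},{right}:{dr:g})"

        return recurse(tree) + ";"


def cluster_groups(binned: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering on Euclidean distances between rows.

    Rows are sorted by label first so ties in the distance matrix break
    deterministically by label order.
    """
    if binned.shape[0] < 2:
        raise ValidationError("clustering requires at least two rows")
    ordered = binned.sort_index()
    dist = pdist(ordered.to_numpy(float), metric="euclidean")
    link = hierarchy.linkage(dist, method="complete")
    return Dendrogram(linkage=link, labels=list(ordered.index))
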