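"""Publication plots: density, volcano, MA, heatmap, PCA, duplicates bar.

All classification and coordinate logic lives in ``prepare_plot_points`` and
the upstream tables, so the plotting layer is a pure renderer: it never
recomputes a statistic, and every figure gets a sidecar TSV of the exact
coordinates drawn (the test surface). Volcano points are log2 fold change
vs -log10 adjusted p; MA points are mean tail length vs log2 fold change;
point classes come straight from the DPG calls (collapsed = shortened tails,
expansion = lengthened, ns = not significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .errors import ValidationError

PLOT_KINDS = ("density", "volcano", "ma", "heatmap", "pca", "duplicates")

#: The six supported two-color heatmap ramps (low → high).
HEATMAP_PALETTES = {
    "red_green": ("red", "green"),
    "green_red": ("green", "red"),
    "blue_green": ("blue", "green"),
    "green_blue": ("green", "blue"),
    "blue_red": ("blue", "red"),
    "red_blue": ("red", "blue"),
}

#: Adjusted p-values are floored here before -log10 so the axis stays finite.
PADJ_FLOOR = 1e-300


@dataclass
class StyleConfig:
    collapsed_color: str = "red"
    expansion_color: str = "green"
    ns_color: str = "grey"
    stat: str = "median"  # dashed-line statistic on density plots
    palette: str = "red_green"
    figsize: tuple[float, float] = (6.0, 4.5)
    dpi: int = 120
    group_colors: dict[str, str] = field(default_factory=dict)


def prepare_plot_points(stats: pd.DataFrame, kind: str = "volcano") -> pd.DataFrame:
    """Turn a feature-stats table into plot-ready (x, y, class) points.

    Untested rows (missing padj) are excluded. Volcano: x = log2fc,
    y = -log10(padj) with padj floored at 1e-300. MA: x = tail-length mean
    pooled over both groups (weighted by group sizes), y = log2fc.
    """
    if kind not in ("volcano", "ma"):
        raise ValidationError(f"unknown point kind {kind!r}")
    for col in ("padj", "log2fc"):
        if col not in stats.columns:
            raise ValidationError(f"stats table lacks required column {col!r}")
    tested = stats[stats["padj"].notna()].copy()
    if kind == "volcano":
        x = tested["log2fc"]
        y = -np.log10(np.maximum(tested["padj"], PADJ_FLOOR))
    else:
        n_c, n_t = tested["n_control"], tested["n_treated"]
        x = (tested["mean_control"] * n_c + tested["mean_treated"] * n_t) / (n_c + n_t)
        y = tested["log2fc"]
    return pd.DataFrame({
        "feature_id": tested["feature_id"].to_numpy(),
        "x": x.to_numpy(float),
        "y": y.to_numpy(float),
        "class": tested["dpg_call"].to_numpy(),
    })


def _write_sidecar(path: str, frame: pd.DataFrame) -> None:
    frame.to_csv(f"{path}.tsv", sep="\t", index=True)


def _scatter_classes(ax, points: pd.DataFrame, style: StyleConfig) -> None:
    colors = {"collapsed": style.collapsed_color, "expansion": style.expansion_color,
              "ns": style.ns_color}
    for cls, color in colors.items():
        sub = points[points["class"] == cls]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=12, c=color, label=cls, alpha=0.8,
                       edgecolors="none")
    ax.legend(frameon=False, fontsize=8)


def _render_density(ax, polya: pd.DataFrame, style: StyleConfig,
                    grouping_factor: str) -> pd.DataFrame:
    import seaborn as sns

    meta_rows = []
    for label, sub in polya.groupby(grouping_factor, sort=True):
        lengths = sub["polyA_length"].to_numpy(float)
        color = style.group_colors.get(label)
        sns.kdeplot(lengths, ax=ax, label=str(label), color=color, fill=False)
        center = float(np.median(lengths) if style.stat == "median" else np.mean(lengths))
        line_color = ax.get_lines()[-1].get_color()
        ax.axvline(center, linestyle="--", color=line_color, linewidth=1)
        meta_rows.append({"group": label, "stat": style.stat, "line_x": center,
                          "n": len(sub)})
    ax.set_xlabel("poly(A) tail length (nt)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    return pd.DataFrame(meta_rows)


def _render_heatmap(fig, ax, binned: pd.DataFrame, style: StyleConfig) -> None:
    if style.palette not in HEATMAP_PALETTES:
        raise ValidationError(
            f"unknown heatmap palette {style.palette!r}; "
            f"choose from {sorted(HEATMAP_PALETTES)}"
        )
    lo, hi = HEATMAP_PALETTES[style.palette]
    cmap = LinearSegmentedColormap.from_list(style.palette, [lo, hi])
    im = ax.imshow(binned.to_numpy(float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(binned.shape[1]))
    ax.set_xticklabels([str(c) for c in binned.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(binned.shape[0]))
    ax.set_yticklabels([str(r) for r in binned.index], fontsize=8)
    ax.set_xlabel("tail-length window (nt)")
    fig.colorbar(im, ax=ax, shrink=0.8)


def render(
    kind: str,
    data,
    out_path: str,
    style: StyleConfig | None = None,
    grouping_factor: str = "group",
) -> str:
    """Render one figure to ``out_path`` (PNG/SVG/PDF by extension).

    ``data`` depends on ``kind``: a poly(A) table for "density", prepared
    points for "volcano"/"ma", a binned matrix for "heatmap", a PcaResult
    for "pca", a DuplicationSummary for "duplicates". A sidecar TSV of the
    plotted coordinates is written next to the image. Inputs are never
    modified.
    """
    if kind not in PLOT_KINDS:
        raise ValidationError(f"unknown plot kind {kind!r}")
    style = style or StyleConfig()
    fig, ax = plt.subplots(figsize=style.figsize, dpi=style.dpi)
    try:
        if kind == "density":
            sidecar = _render_density(ax, data, style, grouping_factor)
        elif kind in ("volcano", "ma"):
            _scatter_classes(ax, data, style)
            ax.set_xlabel("log2 fold change" if kind == "volcano"
                          else "mean poly(A) tail length (nt)")
            ax.set_ylabel("-log10(padj)" if kind == "volcano" else "log2 fold change")
            sidecar = data
        elif kind == "heatmap":
            _render_heatmap(fig, ax, data, style)
            sidecar = data
        elif kind == "pca":
            scores = data.scores
            for label in pd.unique(data.groups):
                mask = (data.groups == label).to_numpy()
                ax.scatter(scores.iloc[mask, 0], scores.iloc[mask, 1], s=30,
                           label=str(label),
                           c=style.group_colors.get(label))
            pc1, pc2 = data.explained_variance_ratio[:2] * 100
            ax.set_xlabel(f"PC1 ({pc1:.1f}%)")
            ax.set_ylabel(f"PC2 ({pc2:.1f}%)")
            ax.legend(frameon=False, fontsize=8)
            sidecar = scores.assign(group=data.groups.to_numpy())
        else:  # duplicates
            frame = data.to_frame()
            ax.bar(frame["class"], frame["count"],
                   color=[style.ns_color, style.collapsed_color, style.expansion_color])
            ax.set_ylabel("reads")
            sidecar = frame
        fig.tight_layout()
        fig.savefig(out_path)
    finally:
        plt.close(fig)
    _write_sidecar(out_path, sidecar)
    return out_path
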