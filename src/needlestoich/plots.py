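"""Optional summary figures; numbers, not figures, are the package's output.

Requires matplotlib (the ``plots`` extra). Three panels: group mean
concentrations with SD bars, a PCA biplot of the needle ratios, and the
needle-soil correlation heatmap.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import GROUP_CODES, SOIL_LAYERS
from .pipeline import AnalysisReport


def write_plots(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # group mean concentrations
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    rows = [r for r in report.group_summaries if r.compartment == "needle"]
    for ax, var, title in zip(axes, ("c", "n", "p"), ("C", "N", "P")):
        sub = {r.group: (r.mean, r.sd) for r in rows if r.variable == var}
        groups = [g for g in GROUP_CODES if g in sub]
        ax.bar(groups, [sub[g][0] for g in groups],
               yerr=[sub[g][1] for g in groups], capsize=3, color="#74a87c")
        ax.set_title(f"{title} (mg/g)")
    fig.tight_layout()
    p = out / "group_means.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    # PCA biplot
    fig, ax = plt.subplots(figsize=(4.5, 4))
    scores = pd.DataFrame(report.pca.scores)
    ax.scatter(scores["PC1"], scores["PC2"], s=18, color="#4c72b0")
    for var, load in report.pca.loadings.items():
        ax.annotate(var, (0, 0), xytext=(load["PC1"] * 2, load["PC2"] * 2),
                    arrowprops=dict(arrowstyle="<-", color="firebrick"), color="firebrick")
    evf = report.pca.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evf[1]:.0%})")
    fig.tight_layout()
    p = out / "pca_biplot.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    # correlation heatmap (r values, one panel per ratio)
    corr = pd.DataFrame([r.model_dump() for r in report.correlations])
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, name in zip(axes, ("c_n", "c_p", "n_p")):
        sub = corr[corr["ratio_name"] == name].pivot(
            index="needle_group", columns="soil_layer", values="r")
        sub = sub.reindex(index=list(GROUP_CODES), columns=list(SOIL_LAYERS))
        im = ax.imshow(sub.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(SOIL_LAYERS)), SOIL_LAYERS, rotation=45, fontsize=7)
        ax.set_yticks(range(len(GROUP_CODES)), GROUP_CODES, fontsize=7)
        ax.set_title(name)
    fig.colorbar(im, ax=axes, shrink=0.8)
    p = out / "correlation_heatmap.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
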