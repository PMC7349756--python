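"""Figure output: delta scatters, composition dots, GSEA bars.

Plots are a convenience view of tables the pipeline also writes as TSV;
they are best-effort and never the only carrier of a number.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = [
    "delta_scatter",
    "species_composition_plot",
    "efficiency_r2_plot",
    "gsea_barplot",
    "plot_suite",
]

_ON, _OFF = "#1f77b4", "#9467bd"


def _save(fig, path_stem):
    paths = []
    for ext in ("png", "pdf"):
        p = f"{path_stem}.{ext}"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def delta_scatter(deltas, title, path_stem):
    """Delta vs initial percent per chromosome; MT flagged, zero guide line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in (("on", _ON), ("off", _OFF)):
        sub = deltas[deltas["target_class"] == cls]
        ax.scatter(
            sub["initial_percent"], sub["delta_percent"],
            c=color, s=25, label=f"{cls}-target", zorder=3,
        )
        mt = sub[sub["is_mito"].astype(bool)]
        if len(mt):
            ax.scatter(
                mt["initial_percent"], mt["delta_percent"],
                facecolors="none", edgecolors="black", s=90, zorder=4,
                label=f"{cls}-target MT",
            )
    ax.axhline(0.0, color="red", linestyle=":", lw=1)
    ax.set_xlabel("initial percent uniquely mapping reads (input)")
    ax.set_ylabel("change in percent (IP − input)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return _save(fig, path_stem)


def species_composition_plot(comp_table, path_stem):
    """Per-sample percent of reads mapping to the first species."""
    fig, ax = plt.subplots(figsize=(5, 4))
    species = comp_table.columns[0]
    x = np.arange(len(comp_table))
    ax.plot(x, comp_table[species], "o-", color=_ON)
    ax.set_xticks(x)
    ax.set_xticklabels(comp_table.index, rotation=45, ha="right")
    ax.set_ylabel(f"% reads mapped to {species}")
    ax.set_ylim(0, 100)
    return _save(fig, path_stem)


def efficiency_r2_plot(report, path_stem):
    off = report[report["target_class"] == "off"]
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        np.arange(len(off)), off["depletion_efficiency"],
        c=off["r_squared"], cmap="viridis", vmin=0, vmax=1, s=60,
    )
    fig.colorbar(sc, ax=ax, label="R²")
    ax.set_xticks(np.arange(len(off)))
    ax.set_xticklabels(off["ip_sample"], rotation=45, ha="right")
    ax.set_ylabel("depletion efficiency")
    ax.set_ylim(0, 1.05)
    return _save(fig, path_stem)


def gsea_barplot(result, title, path_stem, alpha=0.01):
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(result), 4) + 1))
    res = result.sort_values("es")
    colors = ["#9467bd" if p < alpha else "#1f77b4" for p in res["p_adjusted"]]
    ax.barh(res["set_label"], res["es"], color=colors)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("enrichment score")
    ax.set_title(f"{title} (purple: adjusted p < {alpha})")
    return _save(fig, path_stem)


def plot_suite(tables: dict, outdir) -> list[str]:
    """Render every figure whose table is present; returns written paths."""
    import os

    written = []
    for key, (ip, deltas) in tables.get("deltas", {}).items():
        written += delta_scatter(deltas, f"{ip}", os.path.join(outdir, f"delta_{key}"))
    if "species_composition" in tables:
        written += species_composition_plot(
            tables["species_composition"], os.path.join(outdir, "species_composition")
        )
    if "depletion_report" in tables:
        written += efficiency_r2_plot(
            tables["depletion_report"], os.path.join(outdir, "efficiency_r2")
        )
    for key, res in tables.get("gsea", {}).items():
        if len(res):
            written += gsea_barplot(res, key, os.path.join(outdir, f"gsea_{key}"))
    return written
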