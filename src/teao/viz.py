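"""Multi-panel per-position overview figure plus the two-entropies scatter.

Panels (any subset, shared alignment-column x-axis, reference sequence
printed above the first panel and the consensus below the last profile
panel):

- ``entropy_lines``            global vs subgroup-averaged entropy
- ``conservation_specificity`` the two derived scores
- ``presence_matrix``          residue x column presence/absence
- ``variant_counts``           number of distinct residues per column
- ``frequency_stack``          stacked per-residue frequencies
- ``zscale_heatmap``           per-descriptor standard deviations
- ``tree_with_divisions``      rotated UPGMA dendrogram with the level cuts
- ``two_entropies_scatter``    H_global vs H_avg per column

Every panel writes a sidecar TSV of exactly the values drawn; tests (and
users checking a figure) read those tables, never pixels.  Rendering is
deterministic: no randomized layout, colors fixed per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._alphabet import GAP_CODE, STANDARD_RESIDUES
from .entropy import MAX_ENTROPY, EntropyProfile
from .msa_io import Alignment
from .property_scores import PropertyProfile
from .tree import UpgmaTree

__all__ = ["FigureSpec", "render_overview", "consensus_sequence", "RESIDUE_COLORS"]

DEFAULT_PANELS = (
    "entropy_lines",
    "conservation_specificity",
    "presence_matrix",
    "variant_counts",
    "frequency_stack",
    "zscale_heatmap",
    "tree_with_divisions",
)
ALL_PANELS = DEFAULT_PANELS + ("two_entropies_scatter",)

# 20 visually distinct, colorblind-considerate colors, one per residue
RESIDUE_COLORS: dict[str, str] = dict(
    zip(
        STANDARD_RESIDUES,
        [
            "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
            "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
            "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
            "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
        ],
    )
)


@dataclass(frozen=True)
class FigureSpec:
    panels: tuple[str, ...] = DEFAULT_PANELS
    column_range: tuple[int, int] | None = None  # 1-based closed interval
    output_format: str = "svg"
    dpi: int = 150

    def __post_init__(self) -> None:
        bad = [p for p in self.panels if p not in ALL_PANELS]
        if bad:
            raise ValueError(f"unknown panels: {bad}; choose from {ALL_PANELS}")
        if self.output_format not in ("svg", "png", "pdf"):
            raise ValueError("output_format must be svg, png or pdf")


def consensus_sequence(aln: Alignment) -> str:
    """Most frequent standard residue per column, ties alphabetical;
    '-' where a column holds no standard residue."""
    out = []
    for c in range(aln.n_columns):
        col = aln.codes[:, c]
        binc = np.bincount(col[col < GAP_CODE], minlength=20)
        out.append(STANDARD_RESIDUES[int(binc.argmax())] if binc.sum() else "-")
    return "".join(out)


def _frequency_matrix(aln: Alignment) -> np.ndarray:
    """(20, n_columns) relative frequencies over standard residues."""
    freq = np.zeros((20, aln.n_columns))
    for c in range(aln.n_columns):
        col = aln.codes[:, c]
        binc = np.bincount(col[col < GAP_CODE], minlength=20)
        total = binc.sum()
        if total:
            freq[:, c] = binc / total
    return freq


def render_overview(
    aln: Alignment,
    profile: EntropyProfile,
    out_dir: str | Path,
    spec: FigureSpec = FigureSpec(),
    property_profile: PropertyProfile | None = None,
    tree: UpgmaTree | None = None,
    reference_sequence: str | None = None,
    basename: str = "overview",
) -> list[Path]:
    """Render the requested panels; returns all written file paths
    (figure + one sidecar TSV per panel)."""
    if "zscale_heatmap" in spec.panels and property_profile is None:
        raise ValueError("zscale_heatmap panel requested without a property profile")
    if "tree_with_divisions" in spec.panels and tree is None:
        raise ValueError("tree_with_divisions panel requested without a tree")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = spec.column_range or (1, aln.n_columns)
    if not (1 <= lo <= hi <= aln.n_columns):
        raise ValueError(
            f"column_range {spec.column_range} outside 1..{aln.n_columns}"
        )
    cols = np.arange(lo, hi + 1)
    sl = slice(lo - 1, hi)
    written: list[Path] = []

    n_panels = len(spec.panels)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(max(8.0, 0.18 * len(cols)), 2.2 * n_panels),
        sharex=False, squeeze=False,
    )
    axes = axes[:, 0]
    consensus = consensus_sequence(aln)
    freq = _frequency_matrix(aln)

    for ax, panel in zip(axes, spec.panels):
        table: pd.DataFrame
        if panel == "entropy_lines":
            ax.plot(cols, profile.H_global[sl], color="#800000", label="global")
            ax.plot(cols, profile.H_avg[sl], color="#1f4e9c", label="average")
            ax.set_ylabel("entropy (bits)")
            ax.set_ylim(-0.05, MAX_ENTROPY * 1.05)
            ax.legend(loc="upper right", fontsize=7)
            table = pd.DataFrame(
                {"column": cols, "H_global": profile.H_global[sl],
                 "H_avg": profile.H_avg[sl]}
            )
            if reference_sequence is not None:
                for x, aa in zip(cols, reference_sequence[lo - 1 : hi]):
                    ax.annotate(aa, (x, 1.02), xycoords=("data", "axes fraction"),
                                ha="center", fontsize=6, family="monospace")
        elif panel == "conservation_specificity":
            ax.plot(cols, profile.conservation[sl], color="#1f4e9c",
                    label="conservation")
            ax.plot(cols, profile.specificity[sl], color="#d65fa2",
                    label="specificity")
            ax.set_ylabel("score")
            ax.set_ylim(-0.05, 1.05)
            ax.legend(loc="upper right", fontsize=7)
            table = pd.DataFrame(
                {"column": cols, "conservation": profile.conservation[sl],
                 "specificity": profile.specificity[sl]}
            )
        elif panel == "presence_matrix":
            present = (freq[:, sl] > 0).astype(int)
            rgb = np.ones((20, len(cols), 3))
            for r, aa in enumerate(STANDARD_RESIDUES):
                color = matplotlib.colors.to_rgb(RESIDUE_COLORS[aa])
                rgb[r][present[r] == 1] = color
            ax.imshow(rgb, aspect="auto", interpolation="nearest",
                      extent=(lo - 0.5, hi + 0.5, 19.5, -0.5))
            ax.set_yticks(range(20), list(STANDARD_RESIDUES), fontsize=5)
            ax.set_ylabel("residue")
            table = pd.DataFrame(
                present.T, index=pd.Index(cols, name="column"),
                columns=list(STANDARD_RESIDUES),
            ).reset_index()
        elif panel == "variant_counts":
            ax.bar(cols, profile.n_distinct[sl], color="#555555", width=0.8)
            ax.set_ylabel("distinct residues")
            ax.set_ylim(0, 20.5)
            table = pd.DataFrame({"column": cols,
                                  "n_distinct": profile.n_distinct[sl]})
        elif panel == "frequency_stack":
            bottom = np.zeros(len(cols))
            for r, aa in enumerate(STANDARD_RESIDUES):
                vals = freq[r, sl]
                if vals.any():
                    ax.bar(cols, vals, bottom=bottom, width=0.9,
                           color=RESIDUE_COLORS[aa], label=aa)
                bottom += vals
            ax.set_ylabel("frequency")
            ax.set_ylim(0, 1.02)
            table = pd.DataFrame(
                freq[:, sl].T, index=pd.Index(cols, name="column"),
                columns=list(STANDARD_RESIDUES),
            ).reset_index()
        elif panel == "zscale_heatmap":
            assert property_profile is not None
            sd = property_profile.sd[sl].T  # (D, cols)
            im = ax.imshow(sd, aspect="auto", interpolation="nearest",
                           cmap="Purples",
                           extent=(lo - 0.5, hi + 0.5, sd.shape[0] - 0.5, -0.5))
            ax.set_yticks(range(sd.shape[0]),
                          list(property_profile.descriptor_names), fontsize=7)
            fig.colorbar(im, ax=ax, fraction=0.025, pad=0.01)
            table = pd.DataFrame(
                sd.T, index=pd.Index(cols, name="column"),
                columns=[f"sd_{n}" for n in property_profile.descriptor_names],
            ).reset_index()
            for x, aa in zip(cols, consensus[lo - 1 : hi]):
                ax.annotate(aa, (x, -0.08), xycoords=("data", "axes fraction"),
                            ha="center", fontsize=6, family="monospace")
        elif panel == "tree_with_divisions":
            assert tree is not None
            table = _draw_tree(ax, tree)
        elif panel == "two_entropies_scatter":
            ax.scatter(profile.H_avg[sl], profile.H_global[sl], s=12,
                       color="#333333", alpha=0.7)
            ax.plot([0, MAX_ENTROPY], [0, MAX_ENTROPY], ls="--", lw=0.7,
                    color="#999999")
            ax.set_xlabel("average entropy (bits)")
            ax.set_ylabel("global entropy (bits)")
            table = pd.DataFrame(
                {"column": cols, "H_avg": profile.H_avg[sl],
                 "H_global": profile.H_global[sl]}
            )
        else:  # pragma: no cover - guarded by FigureSpec
            raise AssertionError(panel)
        if panel not in ("tree_with_divisions", "two_entropies_scatter"):
            ax.set_xlim(lo - 0.5, hi + 0.5)
        sidecar = out_dir / f"{basename}_{panel}.tsv"
        table.to_csv(sidecar, sep="\t", index=False)
        written.append(sidecar)

    axes[-1].set_xlabel("alignment column")
    fig.tight_layout()
    fig_path = out_dir / f"{basename}.{spec.output_format}"
    fig.savefig(fig_path, dpi=spec.dpi)
    plt.close(fig)
    written.insert(0, fig_path)
    return written


def _leaf_order(tree: UpgmaTree) -> list[int]:
    order: list[int] = []

    def walk(node: int) -> None:
        if node < tree.n_leaves:
            order.append(node)
            return
        a, b = tree.children(node)
        walk(a)
        walk(b)

    walk(tree.root)
    return order


def _draw_tree(ax, tree: UpgmaTree) -> pd.DataFrame:
    """Rotated dendrogram: leaves on y, merge height on x; grey vertical
    lines mark the midpoints between consecutive merge heights (the level
    cuts).  Returns the merge table that was drawn."""
    order = _leaf_order(tree)
    ypos = {leaf: i for i, leaf in enumerate(order)}
    node_y: dict[int, float] = dict(ypos)
    rows = []
    for m, (a, b, h) in enumerate(tree.merges):
        ya, yb = node_y[a], node_y[b]
        ha = tree.heights[a]
        hb = tree.heights[b]
        ax.plot([ha, h], [ya, ya], color="k", lw=0.8)
        ax.plot([hb, h], [yb, yb], color="k", lw=0.8)
        ax.plot([h, h], [ya, yb], color="k", lw=0.8)
        node_y[tree.n_leaves + m] = (ya + yb) / 2
        rows.append({"merge": m + 1, "height": h,
                     "size": len(tree.leaves_below(tree.n_leaves + m))})
    heights = sorted({h for _, _, h in tree.merges})
    cuts = [0.0] + [(heights[i] + heights[i + 1]) / 2 for i in range(len(heights) - 1)]
    for cut in cuts:
        ax.axvline(cut, color="#aaaaaa", lw=0.6, zorder=0)
    ax.set_yticks(range(len(order)),
                  [tree.labels[leaf] for leaf in order], fontsize=5)
    ax.set_xlabel("merge height")
    return pd.DataFrame(rows)
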