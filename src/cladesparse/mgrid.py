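"""Model-grid (M-grid) construction and rendering.

The M-grid is the ranked gene x species view of the ensemble: rows are
the member species with the lowest SCP (most weakly classified first),
columns are the most influential genes, and each cell carries the
ensemble GSC — green shades for concordance (positive), magenta for
discordance (negative), a cross-mark where the species lacks the gene.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import CladeReport  # noqa: E402

__all__ = ["MGrid", "build_mgrid", "render_mgrid", "value_to_color"]

# PiYG: low = magenta family (discordance), high = green family.
_CMAP = plt.get_cmap("PiYG")


@dataclasses.dataclass
class MGrid:
    species_order: list[tuple[str, float]]  # (species, SCP) ascending SCP
    gene_order: list[str]  # descending importance
    cells: pd.DataFrame  # genes (cols) x species (rows)? stored species x genes
    missing: pd.DataFrame
    gene_rank: str
    top_n_species: int
    top_n_genes: int


def build_mgrid(
    report: CladeReport,
    top_species: int = 20,
    top_genes: int = 20,
    gene_rank: str = "mean_abs_gsc",
) -> MGrid:
    """Select and rank the grid's species and genes.

    Species: ascending SCP (the fragile ones first).  Genes: descending
    ``mean_abs_gsc`` (mean |GSC| across member species) or
    ``mean_positive_gsc``; only genes with a nonzero GSC somewhere (i.e.
    selected in at least one retained model) are ranked.  Requests larger
    than the report are clipped, not an error.
    """
    scp_sorted = report.SCP.sort_values(kind="mergesort")
    species = list(scp_sorted.index[: min(top_species, len(scp_sorted))])

    gsc = report.GSC
    selected = gsc.index[(gsc.fillna(0.0) != 0.0).any(axis=1)]
    sub = gsc.loc[selected]
    if gene_rank == "mean_abs_gsc":
        score = sub.abs().mean(axis=1, skipna=True)
    elif gene_rank == "mean_positive_gsc":
        score = sub.clip(lower=0.0).mean(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown gene_rank {gene_rank!r}")
    score = score.sort_values(ascending=False, kind="mergesort")
    genes = list(score.index[: min(top_genes, len(score))])

    cells = gsc.loc[genes, species].T  # species rows, gene columns
    missing = report.missing.loc[genes, species].T
    return MGrid(
        species_order=[(s, float(report.SCP[s])) for s in species],
        gene_order=genes,
        cells=cells,
        missing=missing,
        gene_rank=gene_rank,
        top_n_species=top_species,
        top_n_genes=top_genes,
    )


def value_to_color(value: float, vmax: float) -> tuple[float, float, float, float]:
    """Map a GSC value to RGBA on the symmetric diverging scale.

    Positive values land in the green half, negative in the magenta
    half; the scale is symmetric about 0 at +-vmax.
    """
    if vmax <= 0:
        vmax = 1.0
    x = 0.5 + 0.5 * np.clip(value / vmax, -1.0, 1.0)
    return _CMAP(float(x))


def render_mgrid(m: MGrid, out: str | Path) -> tuple[Path, Path]:
    """Write the M-grid as a PNG heat-grid and a TSV twin.

    ``out`` is a path prefix; returns (png_path, tsv_path).  The TSV has
    species rows (with SCP as the second column) and gene columns, "NA"
    for missing cells.
    """
    out = Path(out)
    png = out.with_suffix(".png")
    tsv = out.with_suffix(".tsv")

    values = m.cells.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
    if vmax == 0:
        vmax = 1.0
    ns, ng = values.shape

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * ng + 2.5), max(3.0, 0.35 * ns + 1.5))
    )
    masked = np.ma.masked_invalid(values)
    ax.pcolormesh(
        masked, cmap=_CMAP, vmin=-vmax, vmax=vmax, edgecolors="0.8", linewidth=0.4
    )
    miss = m.missing.to_numpy()
    ys, xs = np.nonzero(miss)
    if len(ys):
        ax.scatter(xs + 0.5, ys + 0.5, marker="x", c="0.3", s=40, linewidths=1.2)
    ax.set_xticks(np.arange(ng) + 0.5)
    ax.set_xticklabels(m.gene_order, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(ns) + 0.5)
    ax.set_yticklabels(
        [f"{s} ({scp:.2f})" for s, scp in m.species_order], fontsize=7
    )
    ax.invert_yaxis()  # lowest SCP on top
    ax.set_title("M-grid: gene-species concordance")
    fig.tight_layout()
    fig.savefig(png, dpi=150)
    plt.close(fig)

    table = m.cells.copy()
    table.insert(0, "SCP", [scp for _, scp in m.species_order])
    table.index.name = "species"
    table.to_csv(tsv, sep="\t", na_rep="NA", float_format="%.10g")
    return png, tsv


def read_mgrid_tsv(path: str | Path) -> pd.DataFrame:
    """Read back the TSV twin (species index, SCP column, gene columns)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
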