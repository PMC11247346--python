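"""Gene-species concordance, species classification probability, and
clade probability.

A single fitted clade model scores every (gene, member-species) pair by
the gene-species concordance

    gsc(g, s) = sum_k y_s * beta_k * x_sk      (over gene g's columns)

which is positive when the species' residues at the model's selected
sites agree with its placement inside the clade and negative when they
conflict.  The per-model species classification probability is the
model's own logistic output,

    scp(s) = 1 / (1 + exp(-[beta0 + sum_g gsc(g, s)])),

normalized within the model so the best-classified member maps to 1 and
anything the model misclassifies (raw scp < 0.5) maps to 0.

To avoid committing to one sparsity pair, models are fitted over a
(lambda_site, lambda_group) grid; models with fewer than two selected
genes are discarded.  The ensemble summaries are GSC (per-cell median
of gsc over retained models), SCP (mean of normalized scp), and the
clade probability CP = min over member species of SCP.  A low CP flags
a fragile clade, and strongly negative GSC cells point at the specific
gene-species sequences responsible.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .alignment import EncodedDataset
from .solver import (
    ESLModel,
    SparsityPair,
    compute_lambda_max,
    fit_sgl_logistic,
)

__all__ = [
    "GridConfig",
    "ModelEnsemble",
    "CladeReport",
    "gsc_score",
    "gsc_table",
    "scp_raw",
    "normalize_scp",
    "run_grid",
    "ensemble_GSC",
    "ensemble_SCP_CP",
    "build_report",
]

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """No member species is classified above chance (max raw scp <= 0.5)."""


@dataclasses.dataclass(frozen=True)
class GridConfig:
    """Rectangular (lambda_site, lambda_group) sweep configuration."""

    lambda_site_range: tuple[float, float] = (0.1, 0.9)
    lambda_group_range: tuple[float, float] = (0.1, 0.9)
    step: float = 0.1
    quick: bool = False
    min_genes: int = 3
    min_retained_genes: int = 2
    max_iter: int = 100
    tol: float = 1e-5

    def site_values(self) -> np.ndarray:
        lo, hi = self.lambda_site_range
        return _lambda_seq(lo, hi, self.step)

    def group_values(self) -> np.ndarray:
        lo, hi = self.lambda_group_range
        return _lambda_seq(lo, hi, self.step)


def _lambda_seq(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0 <= lo <= hi <= 1):
        raise ValueError("lambda range must satisfy 0 <= lo <= hi <= 1")
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclasses.dataclass
class ModelEnsemble:
    """Retained multigene models plus their per-model score tables."""

    models: list[ESLModel]
    grid_config: GridConfig
    gsc_tables: list[pd.DataFrame]  # genes x member species, one per model
    scp_tables: list[pd.Series]  # normalized scp per member species
    raw_scp_tables: list[pd.Series]
    lambda_group_max: float | None = None
    n_fitted: int = 0
    n_discarded_sparse: int = 0
    n_discarded_degenerate: int = 0

    def __len__(self) -> int:
        return len(self.models)


@dataclasses.dataclass
class CladeReport:
    """Final ensemble summaries for the clade of interest."""

    GSC: pd.DataFrame  # genes x member species; NaN marks missing data
    SCP: pd.Series
    CP: float
    model_counts: pd.Series  # per species: models classifying it correctly
    n_models: int
    missing: pd.DataFrame  # genes x member species boolean missing slice


def gsc_score(
    model: ESLModel, data: EncodedDataset, gene: str, species: str
) -> float:
    """Concordance of one gene in one member species under one model."""
    if gene not in data.group_map:
        raise KeyError(f"unknown gene {gene!r}")
    if species not in data.taxon_order:
        raise KeyError(f"unknown species {species!r}")
    s = data.taxon_index(species)
    y_s = data.y[s]
    if y_s <= 0:
        raise ValueError(f"{species!r} is not a member (+1) species")
    a, b = data.group_map[gene]
    return float(np.sum(y_s * model.beta[a:b] * data.X[s, a:b]))


def gsc_table(model: ESLModel, data: EncodedDataset) -> pd.DataFrame:
    """All gsc scores (genes x member species) for one model, vectorized.

    Missing (gene, species) pairs and unselected genes come out as exact
    zeros: their one-hot block (resp. coefficient block) is all zero.
    """
    members = data.member_taxa()
    rows = [data.taxon_index(t) for t in members]
    contrib = data.X[rows] * model.beta  # y_s = +1 for members
    per_gene = np.empty((len(data.group_map), len(members)))
    for gi, (a, b) in enumerate(data.group_map.values()):
        per_gene[gi] = contrib[:, a:b].sum(axis=1)  # 0 for empty blocks
    return pd.DataFrame(per_gene, index=data.gene_ids, columns=members)


def scp_raw(model: ESLModel, data: EncodedDataset, species: str) -> float:
    """Logistic classification probability of a member species."""
    s = data.taxon_index(species)
    if data.y[s] <= 0:
        raise ValueError(f"{species!r} is not a member (+1) species")
    total = sum(
        gsc_score(model, data, g, species) for g in data.gene_ids
    )
    return float(1.0 / (1.0 + np.exp(-(model.beta0 + total))))


def _scp_raw_vector(model: ESLModel, data: EncodedDataset) -> pd.Series:
    members = data.member_taxa()
    rows = [data.taxon_index(t) for t in members]
    lin = model.beta0 + data.X[rows] @ model.beta
    return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=members)


def normalize_scp(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rescale raw scp so the best member maps to 1: (scp-0.5)/(max-0.5).

    Members the model misclassifies (raw scp < 0.5, i.e. a negative
    predicted response) are set to 0.  Raises
    :class:`DegenerateModelError` when no member exceeds 0.5.
    """
    vals = np.asarray(raw, dtype=float)
    mx = float(np.max(vals))
    if mx <= 0.5:
        raise DegenerateModelError(
            f"max raw scp = {mx:.4f} <= 0.5: model classifies no member"
        )
    out = np.clip((vals - 0.5) / (mx - 0.5), 0.0, None)
    out[vals < 0.5] = 0.0
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index)
    return out


def _evaluate_model(model, data):
    """(gsc table, raw scp, normalized scp) or None when degenerate."""
    raw = _scp_raw_vector(model, data)
    try:
        norm = normalize_scp(raw)
    except DegenerateModelError as exc:
        logger.warning(
            "dropping degenerate model (lambda_site=%s, lambda_group=%s): %s",
            model.sparsity.lambda_site,
            model.sparsity.lambda_group,
            exc,
        )
        return None
    return gsc_table(model, data), raw, norm


def run_grid(
    data: EncodedDataset,
    grid: GridConfig | None = None,
    class_weights: dict | None = None,
) -> ModelEnsemble:
    """Fit the sparsity grid and retain the multigene models.

    FULL mode fits every (lambda_site, lambda_group) pair in the
    rectangle (the conventional 0.1..0.9, step 0.1 sweep gives 81 fits).
    QUICK mode prunes the sweep: at the lowest lambda_site, lambda_group
    is raised until a model keeps only one gene (or the range tops out),
    fixing lambda_group_max for all later rows; the lambda_site loop
    stops after a row produces a model with at most ``min_genes`` genes.
    Models with fewer than ``min_retained_genes`` (default 2) selected
    genes are discarded in both modes, as are models that classify no
    member species above chance.

    Consecutive fits are warm-started along the lambda_group sweep.
    """
    grid = grid or GridConfig()
    lam_max = compute_lambda_max(data, class_weights)
    site_vals = grid.site_values()
    group_vals = grid.group_values()

    models: list[ESLModel] = []
    n_fitted = 0
    lambda_group_cap = float(group_vals[-1])
    stop_site_loop = False

    for i, lam_s in enumerate(site_vals):
        beta_ws, beta0_ws = None, None
        row_min_genes = None
        for lam_g in group_vals:
            if grid.quick and lam_g > lambda_group_cap + 1e-12:
                break
            model = fit_sgl_logistic(
                data,
                SparsityPair(float(lam_s), float(lam_g)),
                class_weights=class_weights,
                max_iter=grid.max_iter,
                tol=grid.tol,
                beta_init=beta_ws,
                beta0_init=beta0_ws,
                lambda_max=lam_max,
            )
            n_fitted += 1
            beta_ws, beta0_ws = model.beta, model.beta0
            models.append(model)
            n_genes = len(model.selected_genes)
            row_min_genes = (
                n_genes if row_min_genes is None else min(row_min_genes, n_genes)
            )
            if grid.quick and i == 0 and n_genes <= 1:
                lambda_group_cap = float(lam_g)
                break
        if grid.quick and row_min_genes is not None and row_min_genes <= grid.min_genes:
            stop_site_loop = True
        if stop_site_loop:
            break

    retained = [
        m for m in models if len(m.selected_genes) >= grid.min_retained_genes
    ]
    n_sparse = len(models) - len(retained)

    kept, gsc_tabs, scp_tabs, raw_tabs = [], [], [], []
    n_degenerate = 0
    for m in retained:
        ev = _evaluate_model(m, data)
        if ev is None:
            n_degenerate += 1
            continue
        kept.append(m)
        gsc_tabs.append(ev[0])
        raw_tabs.append(ev[1])
        scp_tabs.append(ev[2])

    if not kept:
        raise ValueError(
            "no multigene model retained; rerun with a denser or lower "
            "sparsity grid"
        )
    return ModelEnsemble(
        models=kept,
        grid_config=grid,
        gsc_tables=gsc_tabs,
        scp_tables=scp_tabs,
        raw_scp_tables=raw_tabs,
        lambda_group_max=lambda_group_cap if grid.quick else None,
        n_fitted=n_fitted,
        n_discarded_sparse=n_sparse,
        n_discarded_degenerate=n_degenerate,
    )


def ensemble_GSC(e: ModelEnsemble) -> pd.DataFrame:
    """Per-cell median of gsc over retained models (genes x species)."""
    stack = np.stack([t.to_numpy() for t in e.gsc_tables])
    med = np.median(stack, axis=0)
    first = e.gsc_tables[0]
    return pd.DataFrame(med, index=first.index, columns=first.columns)


def ensemble_SCP_CP(e: ModelEnsemble) -> tuple[pd.Series, float]:
    """SCP(s) = mean of normalized scp over models; CP = min SCP."""
    scp = pd.concat(e.scp_tables, axis=1).mean(axis=1)
    return scp, float(scp.min())


def build_report(e: ModelEnsemble, data: EncodedDataset) -> CladeReport:
    """Assemble GSC / SCP / CP with missing-data marks for member species."""
    gsc = ensemble_GSC(e)
    scp, cp = ensemble_SCP_CP(e)
    members = data.member_taxa()
    rows = [data.taxon_index(t) for t in members]
    missing = pd.DataFrame(
        data.missing_mask[rows].T, index=data.gene_ids, columns=members
    )
    gsc = gsc.mask(missing)
    correct = pd.concat(
        [(t > 0.5).astype(int) for t in e.raw_scp_tables], axis=1
    ).sum(axis=1)
    return CladeReport(
        GSC=gsc,
        SCP=scp,
        CP=cp,
        model_counts=correct,
        n_models=len(e),
        missing=missing,
    )


def ensemble_diagnostics(e: ModelEnsemble) -> pd.DataFrame:
    """Per-model table: sparsity pair, gene/site counts, iterations."""
    return pd.DataFrame(
        {
            "lambda_site": [m.sparsity.lambda_site for m in e.models],
            "lambda_group": [m.sparsity.lambda_group for m in e.models],
            "n_genes": [len(m.selected_genes) for m in e.models],
            "n_sites": [m.n_selected_sites for m in e.models],
            "n_iter": [m.n_iter for m in e.models],
            "objective": [m.objective for m in e.models],
        }
    )
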