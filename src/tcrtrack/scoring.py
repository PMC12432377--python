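"""Binned-control gene-signature scoring on expression matrices.

The module score of a cell for a signature is the mean (log-normalized)
expression of the signature genes minus the mean over control genes drawn
from expression-matched bins: all genes are ranked by mean expression across
cells and cut into ``n_bins`` equal-size bins, and each signature gene
contributes ``n_ctrl`` control genes sampled from its own bin (signature
genes excluded from the control pool).  Subtracting bin-matched controls
removes the dependence of a naive signature mean on overall expression
level.  This is the standard single-cell module-score construction; with a
neoantigen-specificity signature it yields the per-cell "neoantigen-specific
score" used to compare CD8 TIL compartments between patient groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SignatureError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of log-normalized expression plus cell metadata.

    ``cell_meta`` is indexed by cell barcode and must carry ``patient_id``;
    ``group`` and ``cluster`` columns are optional.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ParameterError("gene names must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ParameterError("expression values must be finite")
        if "patient_id" not in self.cell_meta.columns:
            raise ParameterError("cell_meta must carry a patient_id column")
        if list(self.cell_meta.index) != list(self.values.columns):
            self.cell_meta = self.cell_meta.loc[self.values.columns]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ModuleScoreResult:
    scores: pd.Series
    signature_used: list[str]
    signature_missing: list[str]
    n_bins: int
    n_ctrl: int
    seed: int


def log_normalize(
    counts: pd.DataFrame,
    cell_meta: Optional[pd.DataFrame] = None,
    scale_total: float = 1e4,
) -> ExpressionMatrix:
    """Library-size normalization: per cell, ln(1 + count / total * scale_total).

    Cells with zero total counts carry no information and are excluded (with
    a logged count) rather than producing NaNs.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("excluding %d zero-total cells", len(zero))
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
    values = np.log1p(counts / totals * scale_total)
    if cell_meta is None:
        cell_meta = pd.DataFrame({"patient_id": "unknown"}, index=values.columns)
    else:
        cell_meta = cell_meta.loc[values.columns]
    return ExpressionMatrix(values=values, cell_meta=cell_meta)


def _expression_bins(values: pd.DataFrame, n_bins: int) -> pd.Series:
    """Assign each gene to one of ``n_bins`` equal-size bins by mean
    expression rank (ties broken by gene name; remainder genes go to the
    lowest bins)."""
    means = values.mean(axis=1)
    order = means.to_frame("mean").sort_index().sort_values(
        "mean", kind="mergesort"
    ).index
    n_genes = len(order)
    base, rem = divmod(n_genes, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    labels = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(labels, index=order, name="bin")


def module_score(
    m: ExpressionMatrix,
    signature: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Per-cell signature score against expression-bin-matched controls.

    For each signature gene present in the matrix, ``n_ctrl`` control genes
    are drawn from its expression bin, excluding all signature genes —
    without replacement when the bin holds enough eligible genes, with
    replacement otherwise.  The score is the mean over signature genes minus
    the mean over the pooled control draw.  Deterministic given
    (matrix, signature, seed); missing signature genes are reported, never
    silently dropped.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ParameterError("n_bins and n_ctrl must be >= 1")
    present = [g for g in signature if g in m.values.index]
    missing = [g for g in signature if g not in m.values.index]
    if not present:
        raise SignatureError("no signature gene present in the matrix")
    if missing:
        logger.warning("%d signature genes absent from matrix", len(missing))

    bins = _expression_bins(m.values, n_bins)
    signature_set = set(present)
    rng = np.random.default_rng(seed)

    control_genes: list[str] = []
    eligible_all = sorted(set(m.values.index) - signature_set)
    for gene in sorted(set(present)):
        bin_id = bins[gene]
        eligible = sorted(
            set(bins.index[bins == bin_id]) - signature_set
        )
        if not eligible:  # degenerate bin made entirely of signature genes
            eligible = eligible_all
        replace = len(eligible) < n_ctrl
        control_genes.extend(rng.choice(eligible, size=n_ctrl, replace=replace))

    sig_mean = m.values.loc[sorted(signature_set)].mean(axis=0)
    ctrl_mean = m.values.loc[control_genes].mean(axis=0)
    scores = (sig_mean - ctrl_mean).rename("module_score")
    return ModuleScoreResult(
        scores=scores,
        signature_used=sorted(signature_set),
        signature_missing=missing,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def top_cluster_frequency(
    scores: pd.Series | ModuleScoreResult,
    clusters: pd.Series,
    patients: pd.Series,
) -> tuple[str, pd.Series, bool]:
    """Identify the cluster with the highest mean score and report, per
    patient, the percentage of that patient's cells falling in it.

    Returns ``(top_cluster, per_patient_pct, tied)``; ties on the mean are
    broken by cluster label order and flagged.  Patients with zero cells do
    not appear in the output.
    """
    if isinstance(scores, ModuleScoreResult):
        scores = scores.scores
    if not scores.index.equals(clusters.index) or not scores.index.equals(
        patients.index
    ):
        raise ParameterError("scores, clusters and patients must share an index")
    means = scores.groupby(clusters).mean().sort_index()
    best = means.max()
    top_candidates = means.index[np.isclose(means, best)]
    tied = len(top_candidates) > 1
    top = sorted(map(str, top_candidates))[0]
    in_top = clusters.astype(str) == top
    pct = (
        in_top.groupby(patients).mean() * 100.0
    ).rename("pct_in_top_cluster")
    return top, pct, tied


def purify_cd8(
    m: ExpressionMatrix,
    cd8_expr: pd.Series,
    cd4_expr: pd.Series,
    cd4_max: float = 0.5,
    max_genes: Optional[int] = 5000,
) -> ExpressionMatrix:
    """Remove contaminating non-CD8 events and outlier cells.

    A cell is dropped when its (imputed) CD4 marker exceeds ``cd4_max``
    while CD8 is exactly zero, or when it has more than ``max_genes``
    detected genes (doublet guard; ``None`` disables).
    """
    cells = m.values.columns
    drop = (cd4_expr.loc[cells] > cd4_max) & (cd8_expr.loc[cells] == 0)
    if max_genes is not None:
        detected = (m.values > 0).sum(axis=0)
        drop = drop | (detected > max_genes)
    keep = cells[~drop.to_numpy()]
    return ExpressionMatrix(
        values=m.values[keep], cell_meta=m.cell_meta.loc[keep]
    )
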