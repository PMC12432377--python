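"""Repertoire filtering and descriptive diversity statistics.

Repertoires are reduced to unique clonotypes — (chain, V, J, CDR3aa) keys —
with a minimum-count filter (default 10 reads/UMIs) before any statistic is
computed.  Statistics provided: unique clonotype / CDR3 counts, Shannon
diversity H = -Σ p_i ln p_i (natural log by default; configurable base),
top-N repertoire occupancy, V-J rearrangement usage, and pairwise
shared-CDR3 overlap between samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRepertoireError, ParameterError
from .models import RepertoireTable

KEY = ["chain", "v_gene", "j_gene", "cdr3_aa"]


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    n_unique_clonotypes: int
    n_unique_cdr3: int
    shannon_H: float
    top_n_occupancy_pct: float
    top_n: int


@dataclass(frozen=True)
class VJUsage:
    """Relative V-J rearrangement usage with marginals.

    ``matrix`` is a V x J frequency table summing to 1; marginals are its
    row/column sums.  Weighting is per unique clonotype by default (each
    clonotype counts once, as in per-clonotype Circos plots); count-weighted
    usage is available via ``vj_usage(..., weight="count")``.
    """

    matrix: pd.DataFrame
    v_marginal: pd.Series
    j_marginal: pd.Series
    n_v: int
    n_vj: int


def filter_clonotypes(table: RepertoireTable, min_count: int = 10) -> RepertoireTable:
    """Aggregate duplicate clonotype keys, then drop low-abundance clonotypes.

    Rows sharing a (chain, V, J, CDR3aa) key are summed *before* the
    threshold is applied, so two sub-threshold rows of the same clonotype can
    jointly survive.  Proportions are recomputed over the survivors.
    """
    if min_count < 1:
        raise ParameterError(f"min_count must be >= 1, got {min_count}")
    df = (
        table.df.groupby(KEY, as_index=False, sort=True)["count"]
        .sum()
        .loc[lambda d: d["count"] >= min_count]
        .reset_index(drop=True)
    )
    return table.with_df(df[KEY + ["count"]])


def shannon_diversity(table: RepertoireTable, base: Optional[float] = None) -> float:
    """Shannon index over clonotype proportions; natural log (nats) unless
    ``base`` is given."""
    if table.n_clonotypes == 0:
        raise EmptyRepertoireError("Shannon diversity undefined on empty repertoire")
    p = table.df["proportion"].to_numpy()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def top_n_occupancy(table: RepertoireTable, n: int = 10) -> float:
    """Percent of repertoire space held by the ``n`` most expanded
    clonotypes; saturates at 100 when the repertoire has fewer than ``n``.

    Ties at the n-th rank are broken by lexicographic CDR3 order so the
    statistic is deterministic.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if table.n_clonotypes == 0:
        raise EmptyRepertoireError("occupancy undefined on empty repertoire")
    if table.n_clonotypes <= n:
        return 100.0
    ordered = table.df.sort_values(
        ["count", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    )
    return float(ordered["proportion"].head(n).sum() * 100.0)


def vj_usage(table: RepertoireTable, weight: str = "clonotype") -> VJUsage:
    if table.n_clonotypes == 0:
        raise EmptyRepertoireError("V-J usage undefined on empty repertoire")
    if weight not in ("clonotype", "count"):
        raise ParameterError(f"weight must be 'clonotype' or 'count', got {weight!r}")
    w = table.df["count"] if weight == "count" else pd.Series(1.0, index=table.df.index)
    long = table.df.assign(w=w).groupby(["v_gene", "j_gene"])["w"].sum()
    matrix = long.unstack(fill_value=0.0).sort_index(axis=0).sort_index(axis=1)
    matrix = matrix / matrix.to_numpy().sum()
    return VJUsage(
        matrix=matrix,
        v_marginal=matrix.sum(axis=1),
        j_marginal=matrix.sum(axis=0),
        n_v=int((matrix.sum(axis=1) > 0).sum()),
        n_vj=int((matrix.to_numpy() > 0).sum()),
    )


def summarize(table: RepertoireTable, top_n: int = 10) -> DiversitySummary:
    return DiversitySummary(
        sample_id=table.sample_id,
        n_unique_clonotypes=table.n_clonotypes,
        n_unique_cdr3=len(table.unique_cdr3()),
        shannon_H=shannon_diversity(table),
        top_n_occupancy_pct=top_n_occupancy(table, top_n),
        top_n=top_n,
    )


def pairwise_shared_cdr3(
    tables: Sequence[RepertoireTable], chain: str
) -> pd.DataFrame:
    """Symmetric matrix of shared unique CDR3aa strings between samples.

    Entry (i, j), i != j, counts CDR3s present in both samples; the diagonal
    is each sample's unique-CDR3 count.  All tables must carry the requested
    chain only.
    """
    if len(tables) < 2:
        raise ParameterError("need at least 2 repertoires")
    sets = []
    for t in tables:
        chains = set(t.df["chain"])
        if chains - {chain}:
            raise ParameterError(
                f"{t.sample_id}: contains chains {sorted(chains)}, expected {chain}"
            )
        sets.append(t.unique_cdr3())
    ids = [t.sample_id for t in tables]
    mat = np.zeros((len(sets), len(sets)), dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            mat[i, j] = len(a) if i == j else len(a & b)
    return pd.DataFrame(mat, index=ids, columns=ids)
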