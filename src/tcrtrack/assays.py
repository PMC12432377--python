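"""Closed-form assay statistics.

Implements the arithmetic behind the wet-lab readouts: relative T-cell
proliferation with its strict responder rule, flow-cytometry percent
cytotoxicity, Incucyte relative green intensity, the Poisson argument for
TCR sampling adequacy, and the antigen-expression cutoff rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError, ValidationError


@dataclass(frozen=True)
class ProliferationMeasurement:
    """Percent CFSE-low CD25+ among CD8 T cells, with antigen-loaded vs
    unloaded dendritic cells."""

    f_loaded: float
    f_unloaded: float

    def __post_init__(self):
        for v in (self.f_loaded, self.f_unloaded):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"frequency {v} outside [0, 100]")


@dataclass(frozen=True)
class KillingMeasurement:
    pct_target: float
    pct_reference: float
    pct_target_control: float
    pct_reference_control: float
    tii_coculture: float = 0.0
    tii_tcell_only: float = 0.0
    tii_tumor_only: float = 0.0

    def __post_init__(self):
        if self.pct_reference <= 0 or self.pct_reference_control <= 0:
            raise ValidationError("reference percentages must be > 0")
        if self.pct_target_control <= 0:
            raise ValidationError("control target percentage must be > 0")


@dataclass(frozen=True)
class SamplingParams:
    n_cells_sequenced: int
    clone_frequency: float
    fraction_of_material: float = 1.0

    def __post_init__(self):
        if self.n_cells_sequenced < 1:
            raise ValidationError("n_cells_sequenced must be positive")
        if not 0.0 <= self.clone_frequency < 1.0:
            raise ValidationError("clone_frequency must be in [0, 1)")


def relative_proliferation(m: ProliferationMeasurement) -> float:
    """Loaded minus unloaded frequency, with negatives scaled to zero."""
    return max(0.0, m.f_loaded - m.f_unloaded)


def call_responder(m: ProliferationMeasurement) -> bool:
    """Detectable response iff proliferation with loaded DCs strictly
    exceeds the unloaded baseline."""
    return m.f_loaded > m.f_unloaded


def responder_rate_pct(n_responders: int, n_total: int, ndigits: int = 1) -> float:
    """Responder percentage as reported: 100*k/n rounded to one decimal."""
    if n_total < 1 or not 0 <= n_responders <= n_total:
        raise ParameterError("need 0 <= n_responders <= n_total, n_total >= 1")
    return round(100.0 * n_responders / n_total, ndigits)


def cytotoxicity_pct(m: KillingMeasurement, clamp: bool = False) -> float:
    """% cytotoxicity = 100 - ((target/reference) / (target_ctrl/reference_ctrl)) * 100.

    The control ratio comes from tumor cells cultured without T cells.
    Negative values (target outgrowth relative to control) are meaningful and
    returned as-is unless ``clamp=True``.
    """
    ratio = m.pct_target / m.pct_reference
    ratio_control = m.pct_target_control / m.pct_reference_control
    value = 100.0 - (ratio / ratio_control) * 100.0
    return max(0.0, value) if clamp else value


def relative_green_intensity(
    tii_coculture, tii_tcell_only, tii_tumor_only
):
    """Dead-cell dye total integrated intensity of the coculture minus both
    monoculture backgrounds; vectorized over timepoints."""
    result = (
        np.asarray(tii_coculture, dtype=float)
        - np.asarray(tii_tcell_only, dtype=float)
        - np.asarray(tii_tumor_only, dtype=float)
    )
    return float(result) if result.ndim == 0 else result


def poisson_miss_probability(p: SamplingParams) -> float:
    """Probability of not sampling a clone of frequency f among n sequenced
    cells: exp(-n*f) under Poisson sampling."""
    lam = p.n_cells_sequenced * p.clone_frequency
    return math.exp(-lam)


def expressed_antigens(
    expr_table: pd.DataFrame, cutoff: float = 5.0
) -> dict[str, set[str]]:
    """Per-sample set of expressed antigens: expression >= cutoff (inclusive).

    ``expr_table`` is genes x samples on whatever normalized scale the
    caller uses; no re-normalization is applied.
    """
    return {
        sample: set(expr_table.index[expr_table[sample] >= cutoff])
        for sample in expr_table.columns
    }


def shared_antigens(
    expressed: Mapping[str, set],
    groups: Mapping[str, Sequence[str]],
    mode: str = "any_per_group",
) -> set[str]:
    """Antigens shared across groups of samples.

    ``any_per_group``: an antigen is shared if expressed by at least one
    sample in every group (intersection of per-group unions).
    ``all_samples``: expressed by every sample of every group.
    """
    if mode not in ("any_per_group", "all_samples"):
        raise ParameterError(f"unknown mode {mode!r}")
    for group, samples in groups.items():
        unknown = [s for s in samples if s not in expressed]
        if unknown:
            raise IntegrityError(f"group {group!r}: unknown samples {unknown}")
    per_group = []
    for group, samples in groups.items():
        sets = [expressed[s] for s in samples]
        if mode == "any_per_group":
            per_group.append(set().union(*sets) if sets else set())
        else:
            per_group.append(set.intersection(*sets) if sets else set())
    return set.intersection(*per_group) if per_group else set()
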