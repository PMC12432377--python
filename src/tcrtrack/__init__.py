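"""tcrtrack — tumor-reactive TCR repertoire tracking.

Quantifies the tumor-reactive CD8 T-cell repertoire from paired blood and
tumor clonotype tables: repertoire filtering and diversity, CDR3 specificity
clustering, blood-to-tumor clonotype tracking (exact and cluster-extended),
HLA-restricted pathogen annotation against an epitope database, assay
statistics, and binned-control gene-signature scoring — plus a synthetic
cohort generator with ground truth.
"""

from importlib import resources

import pandas as pd

from .models import (
    Clonotype,
    EpitopeRecord,
    HLATyping,
    PatientMeta,
    RepertoireTable,
    normalize_gene,
    normalize_hla,
)

__version__ = "0.1.0"

__all__ = [
    "Clonotype",
    "RepertoireTable",
    "EpitopeRecord",
    "HLATyping",
    "PatientMeta",
    "normalize_gene",
    "normalize_hla",
    "load_cohort_roster",
]


def load_cohort_roster():
    """The packaged HR+ breast-cancer cohort roster (23 patients: histology,
    lymph-node status, grade, preoperative treatment) as PatientMeta records."""
    from . import io as tio

    path = resources.files("tcrtrack.data") / "hr_breast_cohort.tsv"
    with resources.as_file(path) as p:
        return tio.read_metadata(p)
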