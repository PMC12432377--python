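"""Blood-to-tumor clonotype tracking and pathogen-specificity annotation.

The headline quantities: the fraction of tumor-infiltrating (TIL) clonotypes
whose CDR3 exactly matches a blood-derived tumor-reactive CDR3; the
cluster-extended fraction additionally counting TIL CDR3s that share a
specificity cluster with a reactive CDR3; and the fraction of TIL clonotypes
matching a pathogen-specific epitope-database entry restricted to one of the
patient's own HLA class-I alleles.

Numerators count unique TIL *clonotypes* matched (a CDR3 shared by two
V/J-distinct clonotypes contributes twice), so numerator and denominator
share units; ``count_sequences=True`` switches to counting unique matched
CDR3 strings instead.  Matching is CDR3aa-only by default ("fully matched"
at the amino-acid level); ``require_vj=True`` additionally requires V and J
gene identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import mannwhitneyu

from .clustering import MotifClusterSet, expand_reactive_set
from .errors import EmptyRepertoireError, IntegrityError, ParameterError
from .models import EpitopeRecord, HLATyping, PatientMeta, RepertoireTable


@dataclass
class SpecificityReport:
    patient_id: str
    chain: str
    n_til_clonotypes: int
    n_exact_matches: int = 0
    n_extended_matches: int = 0
    n_pathogen_matches: int = 0
    exact_fraction: Optional[float] = None
    extended_fraction: Optional[float] = None
    pathogen_fraction: Optional[float] = None
    matched_sequences: list = field(default_factory=list)


def _check_pair(reactive: RepertoireTable, til: RepertoireTable, chain: str):
    for t in (reactive, til):
        extra = set(t.df["chain"]) - {chain}
        if extra:
            raise ParameterError(
                f"{t.sample_id}: contains chains {sorted(extra)}, expected {chain}"
            )
    if til.n_clonotypes == 0:
        raise EmptyRepertoireError("TIL repertoire is empty; fraction undefined")


def exact_match_fraction(
    reactive: RepertoireTable,
    til: RepertoireTable,
    chain: str = "TRB",
    require_vj: bool = False,
    count_sequences: bool = False,
) -> SpecificityReport:
    """Fraction of TIL clonotypes identical to a blood tumor-reactive CDR3."""
    _check_pair(reactive, til, chain)
    if require_vj:
        reactive_keys = set(
            zip(reactive.df["v_gene"], reactive.df["j_gene"], reactive.df["cdr3_aa"])
        )
        hit = til.df.apply(
            lambda r: (r["v_gene"], r["j_gene"], r["cdr3_aa"]) in reactive_keys, axis=1
        )
    else:
        reactive_cdr3 = reactive.unique_cdr3()
        hit = til.df["cdr3_aa"].isin(reactive_cdr3)
    matched = til.df.loc[hit, "cdr3_aa"]
    n_matches = matched.nunique() if count_sequences else int(hit.sum())
    denom = len(til.unique_cdr3()) if count_sequences else til.n_clonotypes
    report = SpecificityReport(
        patient_id=til.patient_id,
        chain=chain,
        n_til_clonotypes=denom,
        n_exact_matches=n_matches,
        exact_fraction=n_matches / denom,
        matched_sequences=sorted((c, "exact") for c in set(matched)),
    )
    return report


def cluster_extended_fraction(
    reactive: RepertoireTable,
    til: RepertoireTable,
    cluster_set: MotifClusterSet,
    chain: str = "TRB",
    count_sequences: bool = False,
) -> SpecificityReport:
    """Exact matches plus TIL clonotypes whose CDR3 shares a specificity
    cluster with a reactive CDR3 (similar but not identical sequences)."""
    report = exact_match_fraction(
        reactive, til, chain=chain, count_sequences=count_sequences
    )
    similar = expand_reactive_set(
        reactive.unique_cdr3(), til.unique_cdr3(), cluster_set
    )
    exact_cdr3 = {c for c, _ in report.matched_sequences}
    extended_hit = til.df["cdr3_aa"].isin(similar | exact_cdr3)
    if count_sequences:
        n_ext = til.df.loc[extended_hit, "cdr3_aa"].nunique()
    else:
        n_ext = int(extended_hit.sum())
    report.n_extended_matches = n_ext
    report.extended_fraction = n_ext / report.n_til_clonotypes
    report.matched_sequences = sorted(
        set(report.matched_sequences) | {(c, "similar") for c in similar}
    )
    return report


def _allele_matches(record: EpitopeRecord, patient_alleles: Iterable[str]) -> bool:
    if record.low_resolution_hla:
        return any(a.startswith(record.mhc_allele) for a in patient_alleles)
    return record.mhc_allele in patient_alleles


def pathogen_fraction(
    til: RepertoireTable,
    epitope_db: Iterable[EpitopeRecord],
    hla: HLATyping,
    chain: str = "TRB",
    count_sequences: bool = False,
) -> SpecificityReport:
    """Fraction of TIL clonotypes whose CDR3 fully matches a pathogen-specific
    database entry restricted to one of the patient's HLA alleles.

    Database entries at group-level HLA resolution (e.g. ``HLA-A*02``) match
    any patient allele in that group; two-field entries must match exactly.
    """
    if til.n_clonotypes == 0:
        raise EmptyRepertoireError("TIL repertoire is empty; fraction undefined")
    if not hla.alleles:
        raise ParameterError("patient HLA typing is empty")
    pathogen_cdr3 = {
        r.cdr3_aa
        for r in epitope_db
        if r.antigen_category == "pathogen"
        and r.chain == chain
        and _allele_matches(r, hla.alleles)
    }
    hit = til.df["cdr3_aa"].isin(pathogen_cdr3)
    if count_sequences:
        n = til.df.loc[hit, "cdr3_aa"].nunique()
        denom = len(til.unique_cdr3())
    else:
        n = int(hit.sum())
        denom = til.n_clonotypes
    return SpecificityReport(
        patient_id=til.patient_id,
        chain=chain,
        n_til_clonotypes=denom,
        n_pathogen_matches=n,
        pathogen_fraction=n / denom,
        matched_sequences=sorted(
            (c, "pathogen") for c in set(til.df.loc[hit, "cdr3_aa"])
        ),
    )


def merge_reports(*parts: SpecificityReport) -> SpecificityReport:
    """Combine partial reports (exact/extended/pathogen) for one patient."""
    base = parts[0]
    out = SpecificityReport(
        patient_id=base.patient_id,
        chain=base.chain,
        n_til_clonotypes=base.n_til_clonotypes,
    )
    seqs = set()
    for p in parts:
        if p.patient_id != base.patient_id or p.chain != base.chain:
            raise IntegrityError("cannot merge reports from different patients/chains")
        if p.exact_fraction is not None:
            out.n_exact_matches, out.exact_fraction = p.n_exact_matches, p.exact_fraction
        if p.extended_fraction is not None:
            out.n_extended_matches = p.n_extended_matches
            out.extended_fraction = p.extended_fraction
        if p.pathogen_fraction is not None:
            out.n_pathogen_matches = p.n_pathogen_matches
            out.pathogen_fraction = p.pathogen_fraction
        seqs |= set(p.matched_sequences)
    out.matched_sequences = sorted(seqs)
    return out


def cohort_report(
    reports: Iterable[SpecificityReport],
    metadata: Mapping[str, PatientMeta],
) -> dict:
    """Cohort summary: per-patient table plus group medians.

    Patients are grouped by lymph-node status (ND excluded from the yes/no
    comparison but kept in the per-patient table) and by histology.  A
    Mann-Whitney rank test on the yes/no groups is attached as a descriptive
    convenience, not an inferential claim.
    """
    rows = []
    for r in reports:
        if r.patient_id not in metadata:
            raise IntegrityError(f"patient {r.patient_id!r} missing from metadata")
        m = metadata[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "chain": r.chain,
                "histology": m.histology,
                "lymph_node_metastasis": m.lymph_node_metastasis,
                "n_til_clonotypes": r.n_til_clonotypes,
                "exact_fraction": r.exact_fraction,
                "extended_fraction": r.extended_fraction,
                "pathogen_fraction": r.pathogen_fraction,
            }
        )
    per_patient = pd.DataFrame(rows)
    value_cols = [
        c for c in ("exact_fraction", "extended_fraction", "pathogen_fraction")
        if per_patient[c].notna().any()
    ]

    ln = per_patient[per_patient["lymph_node_metastasis"].isin(["yes", "no"])]
    by_ln = ln.groupby("lymph_node_metastasis")[value_cols].median()
    by_hist = per_patient.groupby("histology")[value_cols].median()

    pvals = {}
    for col in value_cols:
        yes = ln.loc[ln["lymph_node_metastasis"] == "yes", col].dropna()
        no = ln.loc[ln["lymph_node_metastasis"] == "no", col].dropna()
        if len(yes) and len(no):
            pvals[col] = float(mannwhitneyu(yes, no, alternative="two-sided").pvalue)
    return {
        "per_patient": per_patient,
        "by_lymph_node": by_ln,
        "by_histology": by_hist,
        "mannwhitney_p": pvals,
    }
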