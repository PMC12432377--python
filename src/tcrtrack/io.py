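"""Readers and writers for clonotype tables, epitope databases, HLA typings,
patient metadata and expression matrices.

Two clonotype dialects are supported: AIRR Rearrangement TSV
(``junction_aa`` / ``v_call`` / ``j_call`` / ``duplicate_count`` / ``locus``)
and the MiXCR export TSV (``aaSeqCDR3`` / ``allVHitsWithScore`` /
``allJHitsWithScore`` / ``cloneCount``).  ``dialect="auto"`` sniffs by exact
sentinel column names and refuses ambiguous files rather than guessing.
Gene calls are truncated at the first ``*`` to gene level: allele-level calls
from short-read data are unreliable and all downstream statistics are
gene-level.  CDR3s are uppercased; records containing stop codons (``_`` or
``*``) or non-standard residues are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DialectError, IntegrityError, RowParseError, SchemaError
from .models import (
    CLONOTYPE_COLUMNS,
    EpitopeRecord,
    HLATyping,
    PatientMeta,
    RepertoireTable,
    is_valid_cdr3,
    normalize_gene,
    normalize_hla,
)

logger = logging.getLogger(__name__)

_AIRR_SENTINELS = {"junction_aa", "v_call"}
_MIXCR_SENTINELS = {"aaSeqCDR3", "allVHitsWithScore"}

_AIRR_REQUIRED = ["junction_aa", "v_call", "j_call", "duplicate_count"]
_MIXCR_REQUIRED = ["aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore", "cloneCount"]

#: species labels counted as pathogen-derived when annotating VDJdb matches.
#: Host (self) antigens are deliberately absent.
DEFAULT_PATHOGEN_SPECIES = frozenset(
    {
        "InfluenzaA",
        "CMV",
        "EBV",
        "HIV-1",
        "HCV",
        "HTLV-1",
        "DENV1",
        "DENV2",
        "DENV3/4",
        "SARS-CoV-2",
        "YFV",
        "M.tuberculosis",
        "HSV-2",
        "RSV",
        "StreptococcusPneumoniae",
    }
)


def sniff_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    is_airr = _AIRR_SENTINELS <= cols
    is_mixcr = _MIXCR_SENTINELS <= cols
    if is_airr and is_mixcr:
        raise DialectError("file carries sentinel columns of both dialects")
    if is_airr:
        return "airr"
    if is_mixcr:
        return "mixcr_export"
    raise DialectError(f"unrecognized clonotype dialect; columns: {sorted(cols)}")


def _chain_from_v(v_gene: str) -> Optional[str]:
    for chain in ("TRA", "TRB"):
        if v_gene.startswith(chain + "V"):
            return chain
    return None


def read_clonotypes(
    path: str | Path,
    dialect: str = "auto",
    sample_id: Optional[str] = None,
    patient_id: Optional[str] = None,
    compartment: str = "other",
) -> RepertoireTable:
    """Read a clonotype TSV into an (unfiltered) :class:`RepertoireTable`.

    Raw counts are kept as given (UMI collapsing happens upstream in the
    sequencing kit's pipeline); duplicate (chain, V, J, CDR3) keys survive
    until :func:`tcrtrack.diversity.filter_clonotypes` aggregates them.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "auto":
        dialect = sniff_dialect(raw.columns)
    if dialect == "airr":
        required, cdr3_col, v_col, j_col, count_col = (
            _AIRR_REQUIRED, "junction_aa", "v_call", "j_call", "duplicate_count",
        )
    elif dialect == "mixcr_export":
        required, cdr3_col, v_col, j_col, count_col = (
            _MIXCR_REQUIRED, "aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore",
            "cloneCount",
        )
    else:
        raise DialectError(f"unknown dialect {dialect!r}")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")

    rows = []
    n_dropped = 0
    for idx, rec in enumerate(raw.itertuples(index=False)):
        rec = rec._asdict()
        cdr3 = str(rec[cdr3_col]).strip().upper()
        v_gene = normalize_gene(str(rec[v_col]))
        j_gene = normalize_gene(str(rec[j_col]))
        try:
            count = int(float(str(rec[count_col]).strip()))
        except (TypeError, ValueError):
            raise RowParseError(idx, f"unparseable count {rec[count_col]!r}")
        if not is_valid_cdr3(cdr3):
            n_dropped += 1
            continue
        chain = rec.get("locus") if dialect == "airr" else None
        chain = str(chain).strip().upper() if chain and str(chain) != "nan" else None
        if chain not in ("TRA", "TRB"):
            chain = _chain_from_v(v_gene)
        if chain is None or not j_gene.startswith(chain + "J"):
            n_dropped += 1
            continue
        rows.append((chain, v_gene, j_gene, cdr3, count))
    if n_dropped:
        logger.info("%s: dropped %d invalid clonotype rows", path.name, n_dropped)

    df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
    stem = path.stem
    return RepertoireTable(
        sample_id=sample_id or stem,
        patient_id=patient_id or stem,
        compartment=compartment,
        df=df,
    )


def write_clonotypes(
    table: RepertoireTable, path: str | Path, dialect: str = "airr"
) -> None:
    """Write a repertoire table; ``write ∘ read`` is identity on the model."""
    path = Path(path)
    if dialect == "airr":
        out = pd.DataFrame(
            {
                "junction_aa": table.df["cdr3_aa"],
                "v_call": table.df["v_gene"],
                "j_call": table.df["j_gene"],
                "duplicate_count": table.df["count"],
                "locus": table.df["chain"],
            }
        )
    elif dialect == "mixcr_export":
        out = pd.DataFrame(
            {
                "cloneCount": table.df["count"],
                "aaSeqCDR3": table.df["cdr3_aa"],
                "allVHitsWithScore": table.df["v_gene"],
                "allJHitsWithScore": table.df["j_gene"],
            }
        )
    else:
        raise DialectError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False)


def read_vdjdb(
    path: str | Path,
    pathogen_species: Iterable[str] = DEFAULT_PATHOGEN_SPECIES,
) -> list[EpitopeRecord]:
    """Read a VDJdb-style TSV into epitope records.

    Records whose ``antigen.species`` is in ``pathogen_species`` get
    ``antigen_category="pathogen"``; everything else (notably self antigens,
    e.g. HomoSapiens entries) is ``"other"``.  HLA alleles are normalized;
    group-only alleles are kept at prefix resolution and flagged.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = ["gene", "cdr3", "mhc.a", "antigen.species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"VDJdb table missing columns {missing}")
    pathogen_species = set(pathogen_species)
    records = []
    for rec in df.to_dict("records"):  # dotted column names survive this way
        chain = str(rec["gene"]).strip().upper()
        if chain in ("TRB", "TRBETA", "BETA"):
            chain = "TRB"
        elif chain in ("TRA", "TRALPHA", "ALPHA"):
            chain = "TRA"
        allele, low_res = normalize_hla(str(rec["mhc.a"]))
        species = str(rec["antigen.species"]).strip()
        records.append(
            EpitopeRecord(
                cdr3_aa=str(rec["cdr3"]).strip().upper(),
                chain=chain,
                mhc_allele=allele,
                antigen_species=species,
                antigen_epitope=str(rec.get("antigen.epitope", "") or ""),
                antigen_category="pathogen" if species in pathogen_species else "other",
                low_resolution_hla=low_res,
            )
        )
    return records


def write_vdjdb(records: Iterable[EpitopeRecord], path: str | Path) -> None:
    rows = [
        {
            "gene": r.chain,
            "cdr3": r.cdr3_aa,
            "mhc.a": r.mhc_allele,
            "antigen.species": r.antigen_species,
            "antigen.epitope": r.antigen_epitope,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_hla(path: str | Path) -> dict[str, HLATyping]:
    """Read per-patient HLA typings from a TSV with ``patient_id`` plus
    allele columns (``allele_1`` ... ``allele_6``)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "patient_id" not in df.columns:
        raise SchemaError("HLA table missing patient_id column")
    allele_cols = [c for c in df.columns if c != "patient_id"]
    typings: dict[str, HLATyping] = {}
    for rec in df.itertuples(index=False):
        rec = rec._asdict()
        pid = str(rec["patient_id"])
        if pid in typings:
            raise IntegrityError(f"duplicate patient_id {pid!r} in HLA table")
        alleles = [
            normalize_hla(str(rec[c]))[0]
            for c in allele_cols
            if rec[c] is not None and str(rec[c]) not in ("", "nan")
        ]
        if len(alleles) > 6:
            raise IntegrityError(f"{pid}: more than 6 class-I alleles")
        typings[pid] = HLATyping(patient_id=pid, alleles=frozenset(alleles))
    return typings


def write_hla(typings: Iterable[HLATyping], path: str | Path) -> None:
    rows = []
    for t in typings:
        row = {"patient_id": t.patient_id}
        for i, a in enumerate(sorted(t.alleles), 1):
            row[f"allele_{i}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_metadata(path: str | Path) -> dict[str, PatientMeta]:
    """Read the patient roster (histology, lymph-node status, ...)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = ["patient_id", "histology", "lymph_node_metastasis"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing columns {missing}")
    metas: dict[str, PatientMeta] = {}
    for rec in df.itertuples(index=False):
        rec = rec._asdict()
        pid = str(rec["patient_id"])
        if pid in metas:
            raise IntegrityError(f"duplicate patient_id {pid!r} in metadata")

        def _opt(col, cast):
            v = rec.get(col)
            if v is None or str(v) in ("", "nan", "ND"):
                return None
            return cast(v)

        metas[pid] = PatientMeta(
            patient_id=pid,
            histology=str(rec["histology"]).strip().lower(),
            lymph_node_metastasis=str(rec["lymph_node_metastasis"]).strip(),
            responder=_opt("responder", lambda v: str(v).lower() in ("true", "1", "yes")),
            age=_opt("age", lambda v: int(float(v))),
            grade=_opt("grade", lambda v: int(float(v))),
            preoperative_treatment=_opt("preoperative_treatment", str),
        )
    return metas


def write_metadata(metas: Iterable[PatientMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "patient_id": m.patient_id,
                "histology": m.histology,
                "lymph_node_metastasis": m.lymph_node_metastasis,
                "responder": "" if m.responder is None else str(m.responder).lower(),
                "age": "" if m.age is None else m.age,
                "grade": "" if m.grade is None else m.grade,
                "preoperative_treatment": m.preoperative_treatment or "",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_expression_dense(path: str | Path) -> pd.DataFrame:
    """Read a dense genes x cells expression TSV (gene names in column 0)."""
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def read_expression_mtx(
    matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> pd.DataFrame:
    """Read an MTX triplet (matrix + gene list + barcode list) into a dense
    genes x cells frame.  Intended for the modest matrices this package
    scores, not for atlas-scale data."""
    from scipy.io import mmread

    mat = np.asarray(mmread(str(matrix_path)).todense())
    genes = [line.split("\t")[0].strip() for line in
             Path(genes_path).read_text().splitlines() if line.strip()]
    barcodes = [line.strip() for line in
                Path(barcodes_path).read_text().splitlines() if line.strip()]
    if mat.shape != (len(genes), len(barcodes)):
        raise SchemaError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    return pd.DataFrame(mat, index=genes, columns=barcodes)
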