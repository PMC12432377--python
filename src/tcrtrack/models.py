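"""Core domain types: clonotypes, repertoires, epitope records, patient data.

A clonotype is the atomic unit of a bulk TCR repertoire: one (chain, V gene,
J gene, CDR3 amino-acid sequence) combination with an abundance count (reads
or UMIs).  A repertoire table is the filtered, deduplicated set of clonotypes
for one sample, carrying per-clonotype frequencies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import IntegrityError, ValidationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CDR3_RE = re.compile(rf"^[{AA_ALPHABET}]+$")
CHAINS = ("TRA", "TRB")
HISTOLOGIES = ("ductal", "lobular", "mucinous", "other")
LN_STATUSES = ("yes", "no", "ND")
COMPARTMENTS = ("blood_reactive", "til", "other")

#: canonical column order of the internal clonotype frame
CLONOTYPE_COLUMNS = ["chain", "v_gene", "j_gene", "cdr3_aa", "count"]


def normalize_gene(name: str) -> str:
    """Truncate a V/J gene call to gene level (drop allele / score suffixes).

    ``TRBV27*01`` -> ``TRBV27``; ``TRBV27*00(123.4)`` -> ``TRBV27``.
    Idempotent: ``normalize_gene(normalize_gene(x)) == normalize_gene(x)``.
    """
    name = name.strip().split("(")[0]
    return name.split("*")[0].strip().upper()


def is_valid_cdr3(seq: str, min_len: int = 5) -> bool:
    return len(seq) >= min_len and bool(_CDR3_RE.match(seq))


def normalize_hla(allele: str) -> tuple[str, bool]:
    """Normalize an HLA class-I allele string.

    Returns ``(normalized, low_resolution)`` where two-field calls become
    ``HLA-<locus>*<group>:<protein>`` and group-only calls stay at the
    ``HLA-<locus>*<group>`` prefix with ``low_resolution=True``.
    """
    a = allele.strip().upper().replace("HLA-", "")
    m = re.match(r"^([ABC])\*?(\d{2,3})(?::(\d{2,3}))?", a)
    if not m:
        raise ValidationError(f"unparseable HLA class-I allele: {allele!r}")
    locus, group, protein = m.groups()
    if protein is None:
        return f"HLA-{locus}*{group}", True
    return f"HLA-{locus}*{group}:{protein}", False


@dataclass(frozen=True)
class Clonotype:
    """One (chain, V, J, CDR3aa) record with an abundance count."""

    chain: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValidationError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if not is_valid_cdr3(self.cdr3_aa):
            raise ValidationError(f"invalid CDR3: {self.cdr3_aa!r}")
        if not self.v_gene.startswith(self.chain + "V"):
            raise ValidationError(
                f"V gene {self.v_gene!r} inconsistent with chain {self.chain}"
            )
        if not self.j_gene.startswith(self.chain + "J"):
            raise ValidationError(
                f"J gene {self.j_gene!r} inconsistent with chain {self.chain}"
            )
        if self.count < 0:
            raise ValidationError("count must be >= 0")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class RepertoireTable:
    """A sample's clonotypes with derived per-clonotype proportions.

    ``df`` holds one row per clonotype with columns
    ``chain, v_gene, j_gene, cdr3_aa, count, proportion``; proportions sum
    to 1 over the included clonotypes.  Duplicated keys are allowed only in
    raw (just-read) tables; :func:`tcrtrack.diversity.filter_clonotypes`
    aggregates them.
    """

    sample_id: str
    patient_id: str
    compartment: str
    df: pd.DataFrame

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        self.df = self.df.reset_index(drop=True)
        missing = [c for c in CLONOTYPE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"repertoire frame missing columns {missing}")
        self._recompute_proportions()

    def _recompute_proportions(self):
        total = self.df["count"].sum()
        if len(self.df) and total > 0:
            self.df["proportion"] = self.df["count"] / total
        else:
            self.df["proportion"] = pd.Series(dtype=float)

    @classmethod
    def from_clonotypes(
        cls,
        clonotypes: Iterable[Clonotype],
        sample_id: str = "sample",
        patient_id: str = "patient",
        compartment: str = "other",
    ) -> "RepertoireTable":
        rows = [
            (c.chain, c.v_gene, c.j_gene, c.cdr3_aa, c.count) for c in clonotypes
        ]
        df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
        return cls(sample_id, patient_id, compartment, df)

    def clonotypes(self) -> list[Clonotype]:
        return [
            Clonotype(r.chain, r.cdr3_aa, r.v_gene, r.j_gene, int(r.count))
            for r in self.df.itertuples()
        ]

    @property
    def n_clonotypes(self) -> int:
        return len(self.df)

    def unique_cdr3(self) -> set[str]:
        return set(self.df["cdr3_aa"])

    def with_df(self, df: pd.DataFrame) -> "RepertoireTable":
        return RepertoireTable(self.sample_id, self.patient_id, self.compartment, df)


@dataclass(frozen=True)
class EpitopeRecord:
    """One curated TCR-epitope entry: CDR3, restricting HLA, antigen."""

    cdr3_aa: str
    chain: str
    mhc_allele: str
    antigen_species: str
    antigen_epitope: str = ""
    antigen_category: str = "other"  # "pathogen" | "other"
    low_resolution_hla: bool = False


@dataclass(frozen=True)
class HLATyping:
    """A patient's class-I typing at two-field resolution (up to 6 alleles)."""

    patient_id: str
    alleles: frozenset[str]

    def __post_init__(self):
        if not self.alleles:
            raise IntegrityError(f"{self.patient_id}: HLA typing has no alleles")
        if len(self.alleles) > 6:
            raise IntegrityError(
                f"{self.patient_id}: {len(self.alleles)} class-I alleles (max 6)"
            )
        for a in self.alleles:
            normalize_hla(a)  # raises if unparseable


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    histology: str
    lymph_node_metastasis: str
    responder: Optional[bool] = None
    age: Optional[int] = None
    grade: Optional[int] = None
    preoperative_treatment: Optional[str] = None

    def __post_init__(self):
        if self.histology not in HISTOLOGIES:
            raise ValidationError(f"unknown histology {self.histology!r}")
        if self.lymph_node_metastasis not in LN_STATUSES:
            raise ValidationError(
                f"lymph_node_metastasis must be in {LN_STATUSES}, "
                f"got {self.lymph_node_metastasis!r}"
            )
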