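"""Synthetic paired blood/tumor TCR repertoires and expression matrices.

The generator emits every input the analysis consumes — per-patient blood
tumor-reactive and TIL clonotype tables, a VDJdb-style epitope table, HLA
typings, a patient roster — together with the ground truth that produced
them, so each stage of the pipeline can be tested for parameter recovery
without patient material.

Design of the cohort simulation (defaults are the study conditions):

* clone abundances follow a Zipf law (heavy-tailed clonal expansions) with
  all counts at or above the default filter threshold, so filtering is
  exercised separately via an explicit low-count injection;
* CDR3s are ``C`` + random interior + ``F`` with V/J drawn from a catalog;
* a fraction θ of each patient's TIL clonotypes copy blood-reactive CDR3s
  (⌈θ·n_til⌉ planted exact matches), with θ differing between the
  node-negative and node-positive groups;
* a configured number of TIL CDR3s are *near misses* — exactly one interior
  residue away from a reactive CDR3 — which only the cluster-extended
  matching can recover;
* a fraction of TIL CDR3s are copied from pathogen epitope-database entries
  whose restricting HLA matches the patient's typing.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so any sub-simulation is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .models import (
    AA_ALPHABET,
    CLONOTYPE_COLUMNS,
    EpitopeRecord,
    HLATyping,
    PatientMeta,
    RepertoireTable,
)

TRBV_CATALOG = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-5", "TRBV7-2", "TRBV7-9",
    "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV25-1", "TRBV27", "TRBV28",
    "TRBV29-1", "TRBV30",
)
TRBJ_CATALOG = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)
TRAV_CATALOG = tuple(f"TRAV{i}" for i in (1, 2, 3, 4, 5, 8, 12, 13, 17, 19, 21, 29))
TRAJ_CATALOG = tuple(f"TRAJ{i}" for i in (4, 6, 9, 12, 15, 20, 23, 28, 33, 37, 42, 49))

#: default CDR3 length distribution (amino acids, anchors included)
DEFAULT_CDR3_LENGTHS = {
    10: 0.02, 11: 0.05, 12: 0.10, 13: 0.15, 14: 0.20, 15: 0.18,
    16: 0.12, 17: 0.08, 18: 0.05, 19: 0.03, 20: 0.02,
}

_HLA_POOL = {
    "A": ("HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02"),
    "B": ("HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*35:01", "HLA-B*44:02"),
    "C": ("HLA-C*03:04", "HLA-C*04:01", "HLA-C*05:01", "HLA-C*07:01", "HLA-C*07:02"),
}
_PATHOGEN_SPECIES_POOL = ("InfluenzaA", "CMV", "EBV", "HIV-1", "SARS-CoV-2")


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters; defaults mirror the cohort the analysis targets:
    15 patients with TCR data split 10 node-negative / 5 node-positive, 47
    blood-reactive clonotypes per patient, and a lower tumor-reactive TIL
    fraction in the node-positive group."""

    n_patients: int = 15
    n_node_positive: int = 5
    n_blood_reactive: int = 47
    n_til: int = 150
    theta: Mapping[str, float] = field(
        default_factory=lambda: {"no": 0.05, "yes": 0.01}
    )
    n_near_miss: int = 2
    pathogen_spike: float = 0.02
    zipf_exponent: float = 2.0
    cdr3_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CDR3_LENGTHS)
    )
    chain: str = "TRB"
    v_genes: Sequence[str] = TRBV_CATALOG
    j_genes: Sequence[str] = TRBJ_CATALOG
    min_count: int = 10
    n_low_count: int = 0  # extra below-threshold clonotypes, for filter tests
    n_epitope_db: int = 60
    seed: int = 0

    def __post_init__(self):
        for group, th in self.theta.items():
            if not 0.0 <= th <= 1.0:
                raise ConfigError(f"theta[{group!r}]={th} outside [0, 1]")
        if self.zipf_exponent <= 1.0:
            raise ConfigError("zipf_exponent must be > 1")
        if not self.v_genes or not self.j_genes:
            raise ConfigError("V/J catalogs must be non-empty")
        if not 0.0 <= self.pathogen_spike <= 1.0:
            raise ConfigError("pathogen_spike must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the simulated cohort."""

    theta: dict[str, float]  # per patient
    planted_shared: dict[str, set]  # patient -> exact-match CDR3s
    planted_near_miss: dict[str, set]  # patient -> one-mismatch CDR3s
    planted_pathogen: dict[str, set]  # patient -> DB-copied CDR3s

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta,
                "planted_shared": {k: sorted(v) for k, v in self.planted_shared.items()},
                "planted_near_miss": {
                    k: sorted(v) for k, v in self.planted_near_miss.items()
                },
                "planted_pathogen": {
                    k: sorted(v) for k, v in self.planted_pathogen.items()
                },
            },
            indent=2,
        )


@dataclass
class SimulatedCohort:
    blood: dict[str, RepertoireTable]
    til: dict[str, RepertoireTable]
    epitope_db: list[EpitopeRecord]
    hla: dict[str, HLATyping]
    metadata: dict[str, PatientMeta]
    truth: SyntheticTruth


def _lengths_and_probs(dist: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[l] for l in lengths], dtype=float)
    if (lengths < 7).any():
        raise ConfigError("CDR3 lengths must be >= 7 (anchors + usable interior)")
    return lengths, probs / probs.sum()


def random_cdr3(rng: np.random.Generator, length: int) -> str:
    """One CDR3 with the conserved C...F framing and a uniform interior."""
    interior = "".join(rng.choice(list(AA_ALPHABET), size=length - 2))
    return "C" + interior + "F"


def _draw_unique_cdr3s(
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray,
    probs: np.ndarray,
    forbidden: set[str] = frozenset(),
) -> list[str]:
    out: list[str] = []
    seen = set(forbidden)
    while len(out) < n:
        length = int(rng.choice(lengths, p=probs))
        c = random_cdr3(rng, length)
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _zipf_counts(rng: np.random.Generator, n: int, a: float, min_count: int) -> np.ndarray:
    """Heavy-tailed clone counts, all >= min_count."""
    return (min_count - 1) + rng.zipf(a, size=n)


def simulate_repertoire(
    cfg: CohortConfig,
    n_clonotypes: int,
    seed: int,
    sample_id: str = "sim",
    patient_id: str = "sim",
    compartment: str = "other",
    fixed_cdr3s: Optional[Sequence[str]] = None,
    forbidden_cdr3s: set[str] = frozenset(),
    motif: Optional[str] = None,
    motif_fraction: float = 0.0,
    motif_offset: int = 3,
) -> RepertoireTable:
    """One repertoire of exactly ``n_clonotypes`` unique clonotypes.

    ``fixed_cdr3s`` are placed verbatim (planted sequences); the rest are
    drawn at random, avoiding ``forbidden_cdr3s``.  When ``motif`` is set, a
    ``motif_fraction`` share of the random CDR3s carry it at interior offset
    ``motif_offset`` (positional-bias mode for motif-enrichment testing).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths, probs = _lengths_and_probs(cfg.cdr3_length_distribution)
    fixed = list(fixed_cdr3s or [])
    if len(fixed) > n_clonotypes:
        raise ConfigError("more planted CDR3s than clonotypes requested")
    n_random = n_clonotypes - len(fixed)
    forbidden = set(forbidden_cdr3s) | set(fixed)
    cdr3s = fixed + _draw_unique_cdr3s(rng, n_random, lengths, probs, forbidden)
    if motif is not None and motif_fraction > 0:
        n_mot = int(round(motif_fraction * n_random))
        for i in range(len(fixed), len(fixed) + n_mot):
            c = cdr3s[i]
            pos = 1 + motif_offset  # offset is within the interior
            if pos + len(motif) < len(c):
                cdr3s[i] = c[:pos] + motif + c[pos + len(motif):]

    counts = _zipf_counts(rng, n_clonotypes, cfg.zipf_exponent, cfg.min_count)
    if cfg.n_low_count:
        extra = _draw_unique_cdr3s(rng, cfg.n_low_count, lengths, probs,
                                   forbidden | set(cdr3s))
        cdr3s = cdr3s + extra
        low = rng.integers(1, cfg.min_count, size=cfg.n_low_count)
        counts = np.concatenate([counts, low])

    v = rng.choice(cfg.v_genes, size=len(cdr3s))
    j = rng.choice(cfg.j_genes, size=len(cdr3s))
    df = pd.DataFrame(
        {
            "chain": cfg.chain,
            "v_gene": v,
            "j_gene": j,
            "cdr3_aa": cdr3s,
            "count": counts.astype(int),
        }
    )[CLONOTYPE_COLUMNS]
    return RepertoireTable(sample_id, patient_id, compartment, df)


def _mutate_interior(rng: np.random.Generator, cdr3: str, forbidden: set[str]) -> str:
    """One-residue interior substitution, avoiding ``forbidden`` sequences."""
    for _ in range(200):
        pos = int(rng.integers(1, len(cdr3) - 1))
        new = rng.choice([a for a in AA_ALPHABET if a != cdr3[pos]])
        cand = cdr3[:pos] + new + cdr3[pos + 1:]
        if cand not in forbidden:
            return cand
    raise ConfigError("could not place a near-miss CDR3")


def _simulate_epitope_db(
    rng: np.random.Generator, cfg: CohortConfig
) -> list[EpitopeRecord]:
    lengths, probs = _lengths_and_probs(cfg.cdr3_length_distribution)
    n_pathogen = int(round(cfg.n_epitope_db * 0.75))
    records = []
    alleles = [a for pool in _HLA_POOL.values() for a in pool]
    cdr3s = _draw_unique_cdr3s(rng, cfg.n_epitope_db, lengths, probs)
    for i, c in enumerate(cdr3s):
        pathogen = i < n_pathogen
        records.append(
            EpitopeRecord(
                cdr3_aa=c,
                chain=cfg.chain,
                mhc_allele=str(rng.choice(alleles)),
                antigen_species=(
                    str(rng.choice(_PATHOGEN_SPECIES_POOL)) if pathogen
                    else "HomoSapiens"
                ),
                antigen_epitope="EP" + str(i),
                antigen_category="pathogen" if pathogen else "other",
            )
        )
    return records


def simulate_paired_cohort(cfg: CohortConfig) -> SimulatedCohort:
    """Simulate paired blood-reactive / TIL repertoires for a whole cohort.

    Each patient's TIL table contains, in this order of planting: ⌈θ·n_til⌉
    exact copies of their own blood-reactive CDR3s, ``n_near_miss``
    one-interior-mismatch variants of reactive CDR3s, ``pathogen_spike``
    HLA-compatible copies of pathogen epitope-database CDR3s, and random
    background.  Background draws are rejection-sampled against all planted
    sets, so the ground truth is exact, not merely expected.
    """
    root = np.random.SeedSequence(cfg.seed)
    db_seed, hla_seed, *patient_seeds = root.spawn(2 + cfg.n_patients)
    rng_db = np.random.default_rng(db_seed)
    rng_hla = np.random.default_rng(hla_seed)

    epitope_db = _simulate_epitope_db(rng_db, cfg)
    pathogen_records = [r for r in epitope_db if r.antigen_category == "pathogen"]

    blood, til, hla, metadata = {}, {}, {}, {}
    truth = SyntheticTruth(theta={}, planted_shared={}, planted_near_miss={},
                           planted_pathogen={})

    for i, pseed in enumerate(patient_seeds):
        pid = f"P{i + 1:02d}"
        group = "yes" if i < cfg.n_node_positive else "no"
        theta = float(cfg.theta[group])
        s_blood, s_til, s_misc = pseed.spawn(3)
        rng = np.random.default_rng(s_misc)

        alleles = frozenset(
            a for locus in ("A", "B", "C")
            for a in rng_hla.choice(_HLA_POOL[locus], size=2, replace=False)
        )
        hla[pid] = HLATyping(patient_id=pid, alleles=alleles)
        metadata[pid] = PatientMeta(
            patient_id=pid,
            histology=str(rng.choice(["ductal", "lobular", "mucinous"],
                                     p=[0.6, 0.3, 0.1])),
            lymph_node_metastasis=group,
        )

        blood[pid] = simulate_repertoire(
            cfg, cfg.n_blood_reactive, seed=int(s_blood.generate_state(1)[0] % 2**31),
            sample_id=f"{pid}_blood", patient_id=pid, compartment="blood_reactive",
        )
        reactive_cdr3 = sorted(blood[pid].unique_cdr3())

        n_exact = math.ceil(theta * cfg.n_til)
        if n_exact > len(reactive_cdr3):
            raise ConfigError("theta * n_til exceeds the blood-reactive repertoire")
        shared = list(rng.choice(reactive_cdr3, size=n_exact, replace=False))

        reactive_set = set(reactive_cdr3)
        near = set()
        forbidden = reactive_set | set(shared)
        for _ in range(cfg.n_near_miss):
            src = str(rng.choice(reactive_cdr3))
            nm = _mutate_interior(rng, src, forbidden | near)
            near.add(nm)

        n_path = int(round(cfg.pathogen_spike * cfg.n_til))
        compatible = sorted(
            {r.cdr3_aa for r in pathogen_records
             if r.mhc_allele in alleles and r.cdr3_aa not in forbidden | near}
        )
        n_path = min(n_path, len(compatible))
        spiked = list(rng.choice(compatible, size=n_path, replace=False))

        planted = shared + sorted(near) + spiked
        # background must avoid every reactive and DB CDR3 so the truth is exact
        avoid = reactive_set | near | {r.cdr3_aa for r in epitope_db}
        til[pid] = simulate_repertoire(
            cfg, cfg.n_til, seed=int(s_til.generate_state(1)[0] % 2**31),
            sample_id=f"{pid}_til", patient_id=pid, compartment="til",
            fixed_cdr3s=planted, forbidden_cdr3s=avoid,
        )

        truth.theta[pid] = theta
        truth.planted_shared[pid] = set(shared)
        truth.planted_near_miss[pid] = near
        truth.planted_pathogen[pid] = set(spiked)

    return SimulatedCohort(
        blood=blood, til=til, epitope_db=epitope_db, hla=hla,
        metadata=metadata, truth=truth,
    )


def simulate_expression(
    n_genes: int = 1000,
    n_cells: int = 500,
    n_signature: int = 50,
    delta: float = 1.0,
    spiked_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Counts matrix with a signature spiked into a designated cell subset.

    Baseline counts follow a negative-binomial-like model (gamma-mixed
    Poisson with lognormal gene rates and lognormal cell size factors); the
    signature genes' rates are multiplied by ``exp(delta)`` in the spiked
    cells.  Returns ``(counts genes x cells, signature gene list, labels)``
    with labels in {"spiked", "control"}.
    """
    if n_signature > n_genes:
        raise ConfigError("n_signature cannot exceed n_genes")
    if not 0.0 < spiked_fraction < 1.0:
        raise ConfigError("spiked_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    signature = list(rng.choice(genes, size=n_signature, replace=False))

    gene_rate = rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)
    cell_factor = rng.lognormal(mean=0.0, sigma=0.2, size=n_cells)
    n_spiked = int(round(spiked_fraction * n_cells))
    spiked_cells = rng.choice(n_cells, size=n_spiked, replace=False)
    labels = pd.Series("control", index=cells, name="group")
    labels.iloc[spiked_cells] = "spiked"

    rate = np.outer(gene_rate, cell_factor)
    sig_idx = [genes.index(g) for g in signature]
    spike_mask = np.zeros((n_genes, n_cells), dtype=bool)
    spike_mask[np.ix_(sig_idx, spiked_cells)] = True
    rate = np.where(spike_mask, rate * math.exp(delta), rate)
    # gamma mixing gives NB-like overdispersion (shape 2 => variance ~ mu + mu^2/2)
    overdispersion = rng.gamma(shape=2.0, scale=0.5, size=(n_genes, n_cells))
    counts = rng.poisson(rate * overdispersion)
    return (
        pd.DataFrame(counts, index=genes, columns=cells),
        sorted(signature),
        labels,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write a simulated cohort as AIRR TSVs + VDJdb/HLA/metadata TSVs and a
    ground-truth JSON, all parseable by :mod:`tcrtrack.io`."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, table in cohort.blood.items():
        tio.write_clonotypes(table, outdir / f"{pid}_blood_reactive.tsv")
    for pid, table in cohort.til.items():
        tio.write_clonotypes(table, outdir / f"{pid}_til.tsv")
    tio.write_vdjdb(cohort.epitope_db, outdir / "epitope_db.tsv")
    tio.write_hla(cohort.hla.values(), outdir / "hla.tsv")
    tio.write_metadata(cohort.metadata.values(), outdir / "metadata.tsv")
    (outdir / "truth.json").write_text(cohort.truth.to_json())
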