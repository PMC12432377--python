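"""End-to-end orchestration: filter -> diversity -> cluster -> match -> report.

A single YAML config drives the run; outputs are plain TSVs plus a
machine-readable manifest (parameters and SHA-256 checksums of every input),
and identical config + inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import diversity as div
from . import io as tio
from . import matching
from .clustering import GliphParams, build_clusters
from .errors import ConfigError, TcrTrackError

logger = logging.getLogger(__name__)


@dataclass
class PatientInputs:
    patient_id: str
    reactive: Path
    til: Path


@dataclass
class RunConfig:
    patients: list[PatientInputs]
    output_dir: Path
    vdjdb: Optional[Path] = None
    hla: Optional[Path] = None
    metadata: Optional[Path] = None
    chain: str = "TRB"
    min_count: int = 10
    top_n: int = 10
    seed: int = 0
    use_cluster_extension: bool = True
    gliph: GliphParams = field(default_factory=GliphParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def _p(v):
            p = Path(v)
            return p if p.is_absolute() else base / p

        patients = [
            PatientInputs(
                patient_id=str(p["patient_id"]),
                reactive=_p(p["reactive"]),
                til=_p(p["til"]),
            )
            for p in raw.get("patients", [])
        ]
        gliph = GliphParams(**{
            **({k: v for k, v in raw.get("gliph", {}).items()}),
        }) if raw.get("gliph") else GliphParams()
        return cls(
            patients=patients,
            output_dir=_p(raw.get("output_dir", "tcrtrack_run")),
            vdjdb=_p(raw["vdjdb"]) if raw.get("vdjdb") else None,
            hla=_p(raw["hla"]) if raw.get("hla") else None,
            metadata=_p(raw["metadata"]) if raw.get("metadata") else None,
            chain=raw.get("chain", "TRB"),
            min_count=int(raw.get("min_count", 10)),
            top_n=int(raw.get("top_n", 10)),
            seed=int(raw.get("seed", 0)),
            use_cluster_extension=bool(raw.get("use_cluster_extension", True)),
            gliph=gliph,
            log_level=raw.get("log_level", "INFO"),
        )


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every problem with a config without executing anything."""
    problems: list[str] = []
    if not cfg.patients:
        problems.append("no patients configured")
    seen = set()
    for p in cfg.patients:
        if p.patient_id in seen:
            problems.append(f"duplicate patient_id {p.patient_id!r}")
        seen.add(p.patient_id)
        for role, path in (("reactive", p.reactive), ("til", p.til)):
            if not Path(path).exists():
                problems.append(f"{p.patient_id}: missing {role} file {path}")
    for role, path in (("vdjdb", cfg.vdjdb), ("hla", cfg.hla),
                       ("metadata", cfg.metadata)):
        if path is not None and not Path(path).exists():
            problems.append(f"missing {role} file {path}")
    if cfg.min_count < 1:
        problems.append(f"min_count must be >= 1, got {cfg.min_count}")
    if cfg.top_n < 1:
        problems.append(f"top_n must be >= 1, got {cfg.top_n}")
    if cfg.chain not in ("TRA", "TRB"):
        problems.append(f"chain must be TRA or TRB, got {cfg.chain!r}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stages: read + filter every repertoire; per-sample diversity summaries;
    cohort-wide specificity clustering (reference for motif enrichment =
    pooled TIL CDR3s of the *other* patients, minus all reactive CDR3s);
    per-patient exact / cluster-extended / pathogen match fractions; grouped
    cohort summary when metadata is available.
    """
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        reactive, til = {}, {}
        for p in cfg.patients:
            reactive[p.patient_id] = div.filter_clonotypes(
                tio.read_clonotypes(p.reactive, patient_id=p.patient_id,
                                    compartment="blood_reactive"),
                cfg.min_count,
            )
            til[p.patient_id] = div.filter_clonotypes(
                tio.read_clonotypes(p.til, patient_id=p.patient_id,
                                    compartment="til"),
                cfg.min_count,
            )
        epitope_db = tio.read_vdjdb(cfg.vdjdb) if cfg.vdjdb else None
        hla = tio.read_hla(cfg.hla) if cfg.hla else None
        metadata = tio.read_metadata(cfg.metadata) if cfg.metadata else None

        stage = "diversity"
        rows = []
        for pid in sorted(reactive):
            for label, table in (("blood_reactive", reactive[pid]),
                                 ("til", til[pid])):
                if table.n_clonotypes == 0:
                    logger.warning("%s/%s empty after filtering", pid, label)
                    continue
                s = div.summarize(table, cfg.top_n)
                rows.append({
                    "patient_id": pid, "compartment": label,
                    "n_unique_clonotypes": s.n_unique_clonotypes,
                    "n_unique_cdr3": s.n_unique_cdr3,
                    "shannon_H": s.shannon_H,
                    f"top_{cfg.top_n}_occupancy_pct": s.top_n_occupancy_pct,
                })
        pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)

        stage = "cluster"
        all_reactive = {pid: t.unique_cdr3() for pid, t in reactive.items()}
        all_til = {pid: t.unique_cdr3() for pid, t in til.items()}
        cluster_sets = {}
        if cfg.use_cluster_extension:
            reactive_union = set().union(*all_reactive.values())
            for pid in sorted(reactive):
                reference = sorted(
                    set().union(*(all_til[q] for q in all_til if q != pid), set())
                    - reactive_union
                )
                cluster_sets[pid] = build_clusters(
                    {f"reactive:{pid}": all_reactive[pid],
                     f"til:{pid}": all_til[pid]},
                    reference=reference,
                    params=cfg.gliph,
                )
            cluster_rows = []
            for pid, cs in sorted(cluster_sets.items()):
                for node in sorted(cs.nodes):
                    cluster_rows.append({
                        "patient_id": pid,
                        "cdr3_aa": node,
                        "cluster_id": cs.cluster_of[node],
                        "origins": ";".join(sorted(cs.origins[node])),
                    })
            pd.DataFrame(cluster_rows).to_csv(
                out / "clusters.tsv", sep="\t", index=False
            )

        stage = "match"
        reports = []
        for pid in sorted(reactive):
            if reactive[pid].n_clonotypes == 0:
                # no detectable blood response: reported missing, not zero
                logger.warning("%s: no blood-reactive clonotypes; skipped", pid)
                continue
            if til[pid].n_clonotypes == 0:
                logger.warning("%s: empty TIL table; skipped", pid)
                continue
            parts = [matching.exact_match_fraction(
                reactive[pid], til[pid], chain=cfg.chain)]
            if cfg.use_cluster_extension:
                parts.append(matching.cluster_extended_fraction(
                    reactive[pid], til[pid], cluster_sets[pid], chain=cfg.chain))
            if epitope_db is not None and hla is not None and pid in hla:
                parts.append(matching.pathogen_fraction(
                    til[pid], epitope_db, hla[pid], chain=cfg.chain))
            reports.append(matching.merge_reports(*parts))

        spec_rows = [{
            "patient_id": r.patient_id, "chain": r.chain,
            "n_til_clonotypes": r.n_til_clonotypes,
            "n_exact_matches": r.n_exact_matches,
            "n_extended_matches": r.n_extended_matches,
            "exact_fraction": r.exact_fraction,
            "extended_fraction": r.extended_fraction,
            "pathogen_fraction": r.pathogen_fraction,
        } for r in reports]
        pd.DataFrame(spec_rows).to_csv(out / "specificity.tsv", sep="\t",
                                       index=False)

        stage = "report"
        if metadata is not None and reports:
            summary = matching.cohort_report(reports, metadata)
            summary["per_patient"].to_csv(out / "per_patient.tsv", sep="\t",
                                          index=False)
            summary["by_lymph_node"].to_csv(out / "summary_by_lymph_node.tsv",
                                            sep="\t")
            summary["by_histology"].to_csv(out / "summary_by_histology.tsv",
                                           sep="\t")
            (out / "group_tests.json").write_text(
                json.dumps(summary["mannwhitney_p"], indent=2, sort_keys=True)
            )

        stage = "manifest"
        manifest = {
            "parameters": {
                "chain": cfg.chain, "min_count": cfg.min_count,
                "top_n": cfg.top_n, "seed": cfg.seed,
                "use_cluster_extension": cfg.use_cluster_extension,
                "gliph": {
                    "n_head": cfg.gliph.n_head, "n_tail": cfg.gliph.n_tail,
                    "k_set": sorted(cfg.gliph.k_set),
                    "min_fold": cfg.gliph.min_fold,
                    "max_p": cfg.gliph.max_p,
                    "min_occurrences": cfg.gliph.min_occurrences,
                },
            },
            "inputs": {
                str(p): _sha256(p)
                for p in sorted(
                    {pp.reactive for pp in cfg.patients}
                    | {pp.til for pp in cfg.patients}
                    | {x for x in (cfg.vdjdb, cfg.hla, cfg.metadata) if x}
                )
            },
            "status": "complete",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    except TcrTrackError as exc:
        (out / "manifest.json").write_text(json.dumps(
            {"status": "incomplete", "failed_stage": stage, "error": str(exc)},
            indent=2))
        raise TcrTrackError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
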