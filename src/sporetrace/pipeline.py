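"""End-to-end orchestration: validate -> rarefy -> enrich -> classify -> envo -> report.

A run consumes the TSV artifacts, applies every stage in the order of the
wet-lab workflow, and writes the reports plus a manifest (input digests,
seed, thresholds, rarefaction depth, package version) sufficient to
reproduce the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .abundance import choose_rarefaction_depth, rarefy, relative_abundance
from .classify import classify_source, summarize
from .enrichment import Thresholds, call_enrichment, enriched_otus
from .envo import DEFAULT_MIN_IDENTITY, build_profiles, prevalence_filter, read_hit_annotations
from .tables_io import (
    TableFormatError,
    read_count_table,
    read_sample_metadata,
    read_taxonomy,
    validate_tables,
    write_count_table,
    write_report,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    counts: Path
    metadata: Path
    out_dir: Path
    taxonomy: Path | None = None
    hits: Path | None = None
    seed: int = 0
    depth: int | None = None  # None: smallest library
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_identity: float = DEFAULT_MIN_IDENTITY

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        thr = Thresholds(
            baseline_max_fraction=raw.pop("baseline_max_fraction", 0.001),
            enriched_min_fraction=raw.pop("enriched_min_fraction", 0.01),
        )
        base = Path(path).parent
        def _p(key):
            return (base / raw[key]) if key in raw and raw[key] else None
        return cls(
            counts=_p("counts"),
            metadata=_p("metadata"),
            out_dir=Path(raw.get("out_dir", "sporetrace_out")),
            taxonomy=_p("taxonomy"),
            hits=_p("hits"),
            seed=int(raw.get("seed", 0)),
            depth=raw.get("depth"),
            thresholds=thr,
            min_identity=float(raw.get("min_identity", DEFAULT_MIN_IDENTITY)),
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result dict including the manifest path.

    Any validation failure aborts with :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.time()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    # -- validate ----------------------------------------------------------
    stage = "validate"
    try:
        for p in (config.counts, config.metadata):
            if p is None or not Path(p).exists():
                raise TableFormatError(f"missing input file: {p}")
        raw = read_count_table(config.counts)
        meta = read_sample_metadata(config.metadata)
        taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
        validate_tables(raw, meta, taxonomy)
    except TableFormatError as exc:
        raise StageError(stage, str(exc)) from exc
    log(f"validate: {len(raw.otu_ids)} OTUs x {len(raw.sample_ids)} samples")

    # -- rarefy ------------------------------------------------------------
    stage = "rarefy"
    try:
        depth = config.depth or choose_rarefaction_depth(raw)
        rarefied = rarefy(raw, depth, seed=config.seed)
    except TableFormatError as exc:
        raise StageError(stage, str(exc)) from exc
    write_count_table(rarefied, out / "rarefied_counts.tsv")
    log(f"rarefy: depth {depth}, seed {config.seed}")

    # -- enrich ------------------------------------------------------------
    stage = "enrich"
    try:
        rel = relative_abundance(rarefied)
        matrix = call_enrichment(rel, meta, config.thresholds)
    except TableFormatError as exc:
        raise StageError(stage, str(exc)) from exc
    matrix.to_frame().to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
    hits_set = enriched_otus(matrix)
    log(f"enrich: {len(hits_set)} OTUs enriched at >=1 station")

    # -- classify ----------------------------------------------------------
    stage = "classify"
    try:
        assignments = classify_source(matrix)
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc
    enriched_assignments = [a for a in assignments if a.otu_id in set(hits_set)]
    summary = summarize(assignments) if hits_set else None
    log(
        "classify: "
        + (str(summary.counts) if summary else "no enriched OTUs")
    )

    # -- envo (optional) ---------------------------------------------------
    profiles = None
    if config.hits:
        stage = "envo"
        try:
            annotations = read_hit_annotations(config.hits)
            all_profiles = build_profiles(annotations, config.min_identity)
            profiles = prevalence_filter(all_profiles, matrix)
        except (TableFormatError, ValueError) as exc:
            raise StageError(stage, str(exc)) from exc
        log(f"envo: {len(all_profiles)} profiles, {len(profiles)} prevalent")

    # -- report ------------------------------------------------------------
    stage = "report"
    try:
        paths = write_report(
            enriched_assignments, matrix, {}, profiles, out, taxonomy=taxonomy
        )
    except TableFormatError as exc:
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _digest(Path(p))}
            for name, p in (
                ("counts", config.counts),
                ("metadata", config.metadata),
                ("taxonomy", config.taxonomy),
                ("hits", config.hits),
            )
            if p
        },
        "seed": config.seed,
        "rarefaction_depth": depth,
        "thresholds": dataclasses.asdict(config.thresholds),
        "min_identity": config.min_identity,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "matrix": matrix,
        "assignments": assignments,
        "summary": summary,
        "profiles": profiles,
        "depth": depth,
        "paths": paths,
        "manifest": out / "manifest.json",
        "out_dir": out,
    }
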