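"""End-to-end pipeline: normalize -> sweep both directions -> curve ->
layout frames -> enrichment -> persistence, with a hashed artifact manifest.

Every stage output is a pure function of (inputs, config, seed), so a
rerun with an identical configuration produces byte-identical artifacts;
the manifest records a SHA-256 per file to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import expression as ex
from .sweep import (
    LatticeSequence,
    concept_count_curve,
    persistence_report,
    sequence_to_json,
    sweep as run_sweep,
    threshold_grid,
)
from .enrichment import enrich_concept, read_annotations, write_enrichment_csv
from .layout import export, layout_lattice, silhouette_positions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat pipeline configuration; serialized next to every run's outputs."""

    expression: str = ""  # raw expression TSV (required)
    groups: str | None = None  # replicate-group TSV, optional
    annotations: str | None = None  # gene->term TSV, optional
    out_dir: str = "kfca_out"
    dialect: str = "tsv"
    log_base: str = "e"
    pseudocount: float = 0.0
    directions: tuple[str, ...] = ("under", "over")
    max_points: int | None = None
    include_zero: bool = True
    layout_format: str = "dot"
    layout_all: bool = False  # one frame per threshold vs reference only
    universe: str = "all_genes"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "directions" in raw:
            raw["directions"] = tuple(raw["directions"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.expression:
            raise ValueError("config: 'expression' input path is required")
        for d in self.directions:
            if d not in ("under", "over"):
                raise ValueError(f"config: bad direction {d!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the artifact manifest (also written).

    Raises on the first failing stage, naming it; artifacts written by
    earlier stages are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path):
        artifacts.append(path)
        return path

    stage = "contextualization"
    try:
        t0 = _stage(stage)
        raw = ex.read_expression(config.expression, config.dialect)
        if config.groups:
            raw = ex.average_replicates(raw, ex.read_groups(config.groups))
        norm = ex.normalize_log(raw, config.log_base, config.pseudocount)
        ex.write_expression(norm, emit(out / "normalized.tsv"))
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        sequences: dict[str, LatticeSequence] = {}
        for direction in config.directions:
            stage = f"sweep-{direction}"
            t0 = _stage(stage)
            grid = threshold_grid(
                norm, direction, config.max_points, include_zero=config.include_zero
            )
            seq = run_sweep(norm, direction, grid)
            sequences[direction] = seq
            with open(emit(out / f"sequence_{direction}.json"), "w") as fh:
                json.dump(sequence_to_json(seq), fh, indent=1, sort_keys=True)
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "count-curve"
        t0 = _stage(stage)
        with open(emit(out / "curve.tsv"), "w") as fh:
            fh.write("direction\tthreshold\tconcepts\n")
            for direction, seq in sequences.items():
                for t, c in concept_count_curve(seq):
                    fh.write(f"{direction}\t{t!r}\t{c}\n")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "layout"
        t0 = _stage(stage)
        sil = silhouette_positions(norm.condition_ids)
        for direction, seq in sequences.items():
            if config.layout_all:
                frame_ts = list(seq.thresholds)
            else:
                frame_ts = [min(seq.thresholds, key=abs)]
            for idx, t in enumerate(frame_ts):
                lat = seq.lattices[t]
                name = f"frame_{direction}_{idx:03d}.{config.layout_format}"
                export(lat, layout_lattice(lat, sil), config.layout_format,
                       emit(out / name))
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        if config.annotations:
            stage = "enrichment"
            t0 = _stage(stage)
            ann = read_annotations(config.annotations)
            rows = []
            for direction, seq in sequences.items():
                t = min(seq.thresholds, key=abs)
                lat = seq.lattices[t]
                for i, c in enumerate(lat.concepts):
                    if not c.extent or not c.intent:
                        continue
                    for r in enrich_concept(
                        c, ann, config.universe, universe_genes=norm.gene_ids
                    ):
                        rows.append((t, f"{direction}:{i}", r))
            write_enrichment_csv(rows, emit(out / "enrichment.csv"))
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "persistence"
        t0 = _stage(stage)
        with open(emit(out / "persistence.tsv"), "w") as fh:
            fh.write("direction\tintent\tfirst\tlast\tspan\tn_thresholds\n")
            for direction, seq in sequences.items():
                for rec in persistence_report(seq):
                    first, last = rec.interval if rec.interval else ("", "")
                    fh.write(
                        f"{direction}\t{','.join(sorted(rec.intent))}\t{first!r}\t"
                        f"{last!r}\t{rec.span!r}\t{len(rec.present_at)}\n"
                    )
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as e:
        logger.error("pipeline failed at stage %r: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # provenance + manifest
    with open(emit(out / "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    manifest = {
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
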