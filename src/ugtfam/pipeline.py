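"""One-shot orchestration: mine -> filter -> extract -> classify -> profile.

`run_pipeline` executes the whole discovery workflow on one or more
protein FASTA files and writes machine-readable artifacts into an
output directory:

* ``candidates.tsv``   — every motif hit (record, pattern, 1-based start)
* ``boxes.fasta``      — the extracted 44-residue PSPG boxes
* ``tree.nwk``         — NJ tree with bootstrap supports (>= 3 boxes)
* ``assignments.tsv``  — group calls with evidence (needs references)
* ``profile.tsv``      — per-position consensus report
* ``predictions.tsv``  — sugar-donor calls
* ``summary.json``     — stage counts, parameters and seed
* ``run.log``          — plain, timestamp-free log (runs are expected to
  be byte-reproducible given the same config and seed)

Stage counts satisfy mined == kept + removed; the partial-length filter
is applied to mined candidates, mirroring a discovery workflow where
fragments are only recognised after the motif pulls them in.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import motif_mining, phylogeny, pspg_profile
from .io_formats import read_fasta, write_fasta, write_newick, ProteinRecord

__all__ = ["PipelineConfig", "PipelineSummary", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one pipeline run.

    ``reference_table`` is a mapping of sequence id -> group label, or a
    path to a two-column TSV of the same; without it the classification
    stage is skipped.  A single seed governs the bootstrap.
    """

    fasta: tuple[str, ...]
    output_dir: str
    patterns: tuple[str, ...] | None = None
    min_length: int = 250
    bootstrap_replicates: int = 1000
    seed: int = 0
    support_min: float = 60.0
    novel_min_size: int = 3
    reference_table: object | None = None

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat ``key = value`` config file; kwargs override."""
        values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs: dict = {}
        if "fasta" in values:
            kwargs["fasta"] = tuple(
                p.strip() for p in values.pop("fasta").split(",") if p.strip()
            )
        for key in ("min_length", "bootstrap_replicates", "seed", "novel_min_size"):
            if key in values:
                kwargs[key] = int(values.pop(key))
        if "support_min" in values:
            kwargs["support_min"] = float(values.pop("support_min"))
        for key in ("output_dir", "reference_table"):
            if key in values:
                kwargs[key] = values.pop(key)
        if "patterns" in values:
            kwargs["patterns"] = tuple(
                p.strip() for p in values.pop("patterns").split(",") if p.strip()
            )
        if values:
            raise ValueError(f"unknown config key(s): {sorted(values)}")
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineSummary:
    """Stage counts and artifact locations of one run."""

    seed: int
    parameters: dict
    input_records: int
    mined: int
    removed_partial: int
    kept: int
    boxes: int
    assignments_by_group: dict = field(default_factory=dict)
    donor_calls: dict = field(default_factory=dict)
    tree_built: bool = False
    notes: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _load_references(source) -> dict[str, str]:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return {str(k): str(v) for k, v in source.items()}
    frame = pd.read_csv(source, sep="\t", header=None, names=["id", "group"])
    return dict(zip(frame["id"].astype(str), frame["group"].astype(str)))


def run_pipeline(config: PipelineConfig) -> PipelineSummary:
    """Execute every stage in order and write all artifacts.

    Counts are internally consistent (mined == kept + removed) and the
    whole run, artifacts included, is reproducible from config + seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    written: list[Path] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    params = {
        "fasta": list(config.fasta),
        "patterns": list(config.patterns) if config.patterns else
            list(motif_mining.PATTERN_TEXTS.values()),
        "min_length": config.min_length,
        "bootstrap_replicates": config.bootstrap_replicates,
        "seed": config.seed,
        "support_min": config.support_min,
        "novel_min_size": config.novel_min_size,
    }
    log(f"parameters: {json.dumps(params, sort_keys=True)}")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for path in config.fasta:
        for record in read_fasta(path):
            if record.id in seen:
                raise ValueError(f"duplicate record id across inputs: {record.id!r}")
            seen.add(record.id)
            records.append(record)
    log(f"stage read: {len(records)} records from {len(config.fasta)} file(s)")

    if config.patterns:
        patterns = [
            motif_mining.parse_pattern(text, f"pattern-{i + 1}")
            for i, text in enumerate(config.patterns)
        ]
    else:
        patterns = motif_mining.default_patterns()

    result = motif_mining.mine(records, patterns)
    candidates = result.candidates
    log(f"stage mine: {len(candidates)} candidate(s)")
    result.to_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)
    written.append(out / "candidates.tsv")

    kept_records, removed_records = motif_mining.filter_partials(
        [entry.record for entry in candidates], config.min_length
    )
    kept_ids = {r.id for r in kept_records}
    log(
        f"stage filter: kept {len(kept_records)}, removed "
        f"{len(removed_records)} partial(s) (< {config.min_length} aa)"
    )

    summary = PipelineSummary(
        seed=config.seed,
        parameters=params,
        input_records=len(records),
        mined=len(candidates),
        removed_partial=len(removed_records),
        kept=len(kept_records),
        boxes=0,
    )

    boxes = []
    for entry in candidates:
        if entry.record.id not in kept_ids:
            continue
        hit = entry.best_hit(motif_mining.PSPG_SPAN)
        if hit is None:
            summary.notes.append(
                f"{entry.record.id}: no 44-residue hit; excluded from boxes"
            )
            continue
        boxes.append(motif_mining.extract_pspg(hit))
    summary.boxes = len(boxes)
    log(f"stage extract: {len(boxes)} PSPG box(es)")
    write_fasta(
        [ProteinRecord(b.record_id, b.residues) for b in boxes],
        out / "boxes.fasta",
    )
    written.append(out / "boxes.fasta")

    if boxes:
        profile = pspg_profile.build_profile(boxes)
        report = pspg_profile.check_consensus(profile)
        modal = profile.modal()
        merged = modal.merge(report, on="position", how="left")
        merged.to_csv(out / "profile.tsv", sep="\t", index=False)
        written.append(out / "profile.tsv")
        predictions = [pspg_profile.predict_donor(b) for b in boxes]
        pd.DataFrame(
            [(p.record_id, p.residue, p.call, p.confidence) for p in predictions],
            columns=["record_id", "residue44", "call", "confidence"],
        ).to_csv(out / "predictions.tsv", sep="\t", index=False)
        written.append(out / "predictions.tsv")
        summary.donor_calls = dict(
            sorted(Counter(p.call for p in predictions).items())
        )
        log(f"stage profile: donor calls {summary.donor_calls}")

    references = _load_references(config.reference_table)
    box_ids = {b.record_id for b in boxes}
    references = {k: v for k, v in references.items() if k in box_ids}

    if len(boxes) >= 3:
        alignment = phylogeny.Alignment.from_boxes(boxes)
        tree = phylogeny.bootstrap_support(
            alignment,
            n_replicates=config.bootstrap_replicates,
            seed=config.seed,
        )
        write_newick(tree, out / "tree.nwk")
        written.append(out / "tree.nwk")
        summary.tree_built = True
        log(
            f"stage tree: NJ + {config.bootstrap_replicates} bootstrap "
            "replicate(s)"
        )
        if references:
            assignments = phylogeny.assign_groups(
                tree,
                references,
                support_min=config.support_min,
                novel_min_size=config.novel_min_size,
            )
            pd.DataFrame(
                [
                    (
                        a.label,
                        a.group,
                        a.is_reference,
                        a.nearest_reference or "",
                        "" if a.patristic_distance is None
                        else f"{a.patristic_distance:.6g}",
                        "" if a.clade_support is None else f"{a.clade_support:.10g}",
                    )
                    for a in assignments
                ],
                columns=[
                    "query", "group", "is_reference", "nearest_reference",
                    "patristic_distance", "clade_support",
                ],
            ).to_csv(out / "assignments.tsv", sep="\t", index=False)
            written.append(out / "assignments.tsv")
            summary.assignments_by_group = dict(
                sorted(
                    Counter(
                        a.group for a in assignments if not a.is_reference
                    ).items()
                )
            )
            log(f"stage classify: {summary.assignments_by_group}")
        else:
            summary.notes.append("no usable references; classification skipped")
            log("stage classify: skipped (no references among boxes)")
    else:
        summary.notes.append("fewer than 3 boxes; tree and classification skipped")
        log("stage tree: skipped (fewer than 3 boxes)")

    # names only, so summaries are byte-identical across output dirs
    summary.artifacts = sorted(p.name for p in written)
    (out / "summary.json").write_text(summary.to_json() + "\n")
    log("stage summary: written")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
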