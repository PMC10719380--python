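"""File formats, configuration and run manifests.

Interchange dialect is TSV with '#'-prefixed header comments (producing
stage, config hash, column schema) followed by a normal column-header row.
Gene sets are read from GMT; the event catalog can additionally be
exported as GFF3 (1-based inclusive, one feature per segment, event id in
the attributes).  Malformed rows raise :class:`SchemaError` with the file
line number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .models import (
    CATEGORIES,
    ContrastResult,
    DifferentialCall,
    EventCounts,
    SchemaError,
    SimTruth,
    SpliceEvent,
    SubstrateSet,
    segments_from_str,
    segments_to_str,
)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Resolved run configuration; every field has a default.

    Serialises to YAML round-trippably; ``config_hash`` is embedded in every
    output header so files can be traced to the configuration that produced
    them.
    """

    seed: int = 0
    grid_size: int = 1001
    bf_threshold: float = 20.0
    min_info: int = 10
    epsilon: float = 0.0
    ks_magnitude_mode: str = "absolute"  # "absolute" | "signed"
    universe_mode: str = "testable_genes"
    ratio_orientation_treatment: str = "excluded_over_included"
    ratio_orientation_disease: str = "included_over_excluded"
    # synthetic-data conditions
    n_per_category: int = 300
    length_range: tuple[int, int] = (20, 200)
    frac_differential: float = 0.2
    effect_range: tuple[float, float] = (0.25, 0.6)
    frac_switch: float = 0.6
    mean_coverage: float = 100.0
    dispersion: float = 0.3
    n_replicates: int = 3
    coverage_distribution: str = "negative_binomial"
    out_dir: str = "spliceswitch_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(self.length_range)
        d["effect_range"] = list(self.effect_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}", str(path))
        for key in ("length_range", "effect_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        # out_dir is a location, not an analysis parameter: identical
        # configurations written to different directories hash identically
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TSV helpers

def _write_tsv(
    df: pd.DataFrame, path: str | Path, stage: str, config: PipelineConfig | None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        fh.write(f"# tool: spliceswitch {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash: {config.config_hash}\n")
        fh.write(f"# columns: {', '.join(df.columns)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path, required: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Read a commented TSV; returns the frame and the 1-based line number of
    the first data row (for error reporting)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", str(path))
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - parser failures vary
        raise SchemaError(f"unparseable TSV: {exc}", str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing columns {missing}; found {list(df.columns)}", str(path)
        )
    return df, n_comments + 2  # +1 for the header row, +1 for 1-based


def _row_line(first_data_line: int, idx: int) -> int:
    return first_data_line + idx


# ---------------------------------------------------------------------------
# Catalog

CATALOG_COLUMNS = [
    "event_id", "gene_id", "category", "chrom", "strand", "segments", "l_inc", "l_exc",
]


def write_catalog(
    events: Sequence[SpliceEvent], path: str | Path, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "gene_id": [e.gene_id for e in events],
            "category": [e.category for e in events],
            "chrom": [e.chrom for e in events],
            "strand": [e.strand for e in events],
            "segments": [segments_to_str(e.segments) for e in events],
            "l_inc": [e.l_inc for e in events],
            "l_exc": [e.l_exc for e in events],
        }
    )
    _write_tsv(df, path, "catalog", config)


def read_catalog(path: str | Path) -> list[SpliceEvent]:
    df, first = _read_tsv(path, CATALOG_COLUMNS)
    events = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = _row_line(first, idx)
        if row.event_id in seen:
            raise SchemaError(f"duplicate event_id {row.event_id!r}", str(path), line)
        seen.add(row.event_id)
        if row.category not in CATEGORIES:
            raise SchemaError(f"unknown category {row.category!r}", str(path), line)
        try:
            events.append(
                SpliceEvent(
                    event_id=row.event_id,
                    gene_id=row.gene_id,
                    category=row.category,
                    chrom=row.chrom,
                    strand=row.strand,
                    segments=segments_from_str(row.segments),
                    l_inc=int(row.l_inc),
                    l_exc=int(row.l_exc),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"bad catalog row: {exc}", str(path), line) from exc
    return events


def write_catalog_gff3(events: Sequence[SpliceEvent], path: str | Path) -> None:
    """Export the catalog as GFF3, one feature per segment (1-based inclusive)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in events:
            for i, (start, end) in enumerate(e.segments, start=1):
                attrs = (
                    f"ID={e.event_id}.seg{i};Parent={e.event_id};"
                    f"gene_id={e.gene_id};category={e.category}"
                )
                fh.write(
                    f"{e.chrom}\tspliceswitch\tsplice_segment\t{start}\t{end}"
                    f"\t.\t{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Counts

COUNTS_COLUMNS = ["event_id", "sample_id", "condition", "replicate", "n_inc", "n_exc"]


def write_counts(
    counts: Sequence[EventCounts], path: str | Path, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(
        {
            "event_id": [c.event_id for c in counts],
            "sample_id": [c.sample_id for c in counts],
            "condition": [c.condition for c in counts],
            "replicate": [c.replicate for c in counts],
            "n_inc": [c.n_inc for c in counts],
            "n_exc": [c.n_exc for c in counts],
        }
    )
    _write_tsv(df, path, "counts", config)


def read_counts(path: str | Path) -> list[EventCounts]:
    df, first = _read_tsv(path, COUNTS_COLUMNS)
    out = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = _row_line(first, idx)
        key = (row.event_id, row.sample_id)
        if key in seen:
            raise SchemaError(f"duplicate (event_id, sample_id) {key}", str(path), line)
        seen.add(key)
        try:
            out.append(
                EventCounts(
                    event_id=row.event_id,
                    sample_id=row.sample_id,
                    condition=row.condition,
                    replicate=int(row.replicate),
                    n_inc=int(row.n_inc),
                    n_exc=int(row.n_exc),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"bad counts row: {exc}", str(path), line) from exc
    return out


# ---------------------------------------------------------------------------
# Truth table

TRUTH_COLUMNS = [
    "event_id",
    "psi_by_condition",
    "is_differential_treatment",
    "is_differential_disease",
    "effect_treatment",
    "effect_disease",
    "substrate_of",
    "is_switch",
]


def write_truth(
    truth: Sequence[SimTruth], path: str | Path, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(
        {
            "event_id": [t.event_id for t in truth],
            "psi_by_condition": [
                ";".join(f"{c}={p:.10g}" for c, p in sorted(t.psi_by_condition.items()))
                for t in truth
            ],
            "is_differential_treatment": [int(t.is_differential_treatment) for t in truth],
            "is_differential_disease": [int(t.is_differential_disease) for t in truth],
            "effect_treatment": [f"{t.effect_treatment:.10g}" for t in truth],
            "effect_disease": [f"{t.effect_disease:.10g}" for t in truth],
            "substrate_of": [",".join(sorted(t.substrate_of)) for t in truth],
            "is_switch": [int(t.is_switch) for t in truth],
        }
    )
    _write_tsv(df, path, "truth", config)


def read_truth(path: str | Path) -> list[SimTruth]:
    df, first = _read_tsv(path, TRUTH_COLUMNS)
    out = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = _row_line(first, idx)
        try:
            psi = {}
            for chunk in row.psi_by_condition.split(";"):
                cond, _, val = chunk.partition("=")
                psi[cond] = float(val)
            subs = frozenset(
                s for s in (row.substrate_of or "").split(",") if s
            ) if isinstance(row.substrate_of, str) else frozenset()
            out.append(
                SimTruth(
                    event_id=row.event_id,
                    psi_by_condition=psi,
                    is_differential_treatment=bool(int(row.is_differential_treatment)),
                    is_differential_disease=bool(int(row.is_differential_disease)),
                    effect_treatment=float(row.effect_treatment),
                    effect_disease=float(row.effect_disease),
                    substrate_of=subs,
                    is_switch=bool(int(row.is_switch)),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"bad truth row: {exc}", str(path), line) from exc
    return out


# ---------------------------------------------------------------------------
# Contrast tables (differential_calling interchange format)

CONTRAST_COLUMNS = [
    "event_id",
    "gene_id",
    "category",
    "bf",
    "delta_psi_pooled",
    "replicate_delta_psis",
    "direction",
    "significant",
    "testable",
]


def write_contrast(
    contrast: ContrastResult, path: str | Path, config: PipelineConfig | None = None
) -> None:
    calls = contrast.calls
    df = pd.DataFrame(
        {
            "event_id": [c.event_id for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "category": [c.category for c in calls],
            "bf": [f"{c.bf:.10g}" for c in calls],
            "delta_psi_pooled": [f"{c.delta_psi_pooled:.10g}" for c in calls],
            "replicate_delta_psis": [
                ",".join(f"{d:.10g}" for d in c.replicate_delta_psis) for c in calls
            ],
            "direction": [c.direction for c in calls],
            "significant": [int(c.significant) for c in calls],
            "testable": [int(c.testable) for c in calls],
        }
    )
    _write_tsv(df, path, f"contrast:{contrast.contrast_label}", config)


def read_contrast(path: str | Path, contrast_label: str = "") -> ContrastResult:
    df, first = _read_tsv(path, CONTRAST_COLUMNS)
    if not contrast_label:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# stage: contrast:"):
                    contrast_label = line.split("contrast:", 1)[1].strip()
                    break
                if not line.startswith("#"):
                    break
    calls = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = _row_line(first, idx)
        try:
            reps = tuple(
                float(x)
                for x in (row.replicate_delta_psis or "").split(",")
                if x != ""
            ) if isinstance(row.replicate_delta_psis, str) else ()
            calls.append(
                DifferentialCall(
                    event_id=row.event_id,
                    gene_id=row.gene_id,
                    category=row.category,
                    bf=float(row.bf),
                    delta_psi_pooled=float(row.delta_psi_pooled),
                    replicate_delta_psis=reps,
                    direction=row.direction,
                    significant=bool(int(row.significant)),
                    testable=bool(int(row.testable)),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"bad contrast row: {exc}", str(path), line) from exc
    return ContrastResult(contrast_label=contrast_label, calls=calls)


# ---------------------------------------------------------------------------
# Gene sets (GMT)

def read_gene_sets(path: str | Path) -> list[SubstrateSet]:
    """Read GMT: one set per line — name, description, then gene ids."""
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", str(path))
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    "GMT line needs name, description and >= 1 gene", str(path), lineno
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise SchemaError(f"gene set {name!r} is empty", str(path), lineno)
            sets.append(
                SubstrateSet(set_name=name, gene_ids=frozenset(genes), description=desc)
            )
    return sets


def write_gene_sets(sets: Sequence[SubstrateSet], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_name, s.description, *sorted(s.gene_ids)]) + "\n")


# ---------------------------------------------------------------------------
# Manifests

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    config: PipelineConfig,
    inputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> None:
    """JSON run manifest: config, seed, input checksums, tool version."""
    manifest = {
        "stage": stage,
        "tool": "spliceswitch",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {obj!r}")
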