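"""Accession resolution: expand an accession into runs, files and metadata.

The INSDC archives (SRA/ENA/DDBJ) share a study → experiment → sample → run
hierarchy; downloadable sequence files attach at the run level.  GEO series
(GSE) and samples (GSM) link to SRA runs for their raw reads, BioProjects
(PRJNA) link to a study, and ENCODE accessions are dataset-centric with files
attached directly (no run level) — such records reuse :class:`RunRecord`
with themselves as the run id.

The archive is abstracted behind a small backend interface.  The shipped
:class:`FixtureMetadataBackend` reads a JSON metadata-tree dialect
(schema below, version 1) produced by :mod:`seqharvest.fixtures`; a live
backend implementing the same two methods can be swapped in without touching
resolution logic.

JSON metadata-tree schema (version 1)::

    {
      "schema_version": 1,
      "nodes": {
        "<ACCESSION>": {
          "level": "project|study|experiment|sample|run|submission|dataset",
          "attributes": {"organism": ..., "library_strategy": ..., ...},
          "children": ["<ACCESSION>", ...],     # container nodes
          "files": [                            # run / dataset nodes
            {"filename": str, "size_bytes": int, "md5": hex-or-null,
             "urls": [["local|http|ftp|fasp", "<address>"], ...]}
          ],
          "processed_files": [...]              # optional, series-level assets
        }, ...
      },
      "project_links": {"<PRJNA...>": "<study accession>", ...}
    }
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Protocol

import pandas as pd

from .grammar import AccessionID, classify

__all__ = [
    "FileRecord",
    "RunRecord",
    "MetadataTable",
    "ResolutionError",
    "MetadataBackend",
    "FixtureMetadataBackend",
    "resolve",
    "convert_project_to_study",
    "filter_by_format",
    "fetch_metadata_table",
    "write_metadata_table",
    "file_format",
    "validate_tree",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Stable column order of every metadata table.
METADATA_COLUMNS = (
    "run",
    "sample",
    "experiment",
    "study",
    "organism",
    "library_strategy",
    "layout",
    "instrument",
    "description",
)

_COMPRESSION_EXTS = {"gz", "bz2", "xz", "zst"}
_FORMAT_BY_EXT = {
    "fastq": "fastq",
    "fq": "fastq",
    "fasta": "fasta",
    "fa": "fasta",
    "bam": "bam",
    "vcf": "vcf",
}

SEQUENCE_FORMATS = ("bam", "vcf", "fasta", "fastq")


class ResolutionError(RuntimeError):
    """An accession could not be resolved by the backend."""

    def __init__(self, accession: str, reason: str):
        super().__init__(f"cannot resolve {accession}: {reason}")
        self.accession = accession
        self.reason = reason


def file_format(filename: str) -> str:
    """Derive the sequence-file format from the filename's extension chain.

    Compression suffixes are peeled first, so ``x.fastq.gz`` and ``x.fq.bz2``
    are both fastq; unrecognized extensions map to ``other``.
    """
    parts = filename.lower().split(".")
    while len(parts) > 1 and parts[-1] in _COMPRESSION_EXTS:
        parts.pop()
    return _FORMAT_BY_EXT.get(parts[-1], "other") if len(parts) > 1 else "other"


@dataclass(frozen=True)
class FileRecord:
    """One downloadable file: size, optional checksum and protocol URLs.

    ``size_bytes`` may be ``None`` for assets whose size the source does not
    declare (e.g. supplementary links); such files count zero toward planned
    totals and skip the size check at verification.
    """

    filename: str
    size_bytes: Optional[int]
    urls: tuple[tuple[str, str], ...]
    checksum: Optional[str] = None
    format: str = field(default="")

    def __post_init__(self) -> None:
        if not self.urls:
            raise ValueError(f"file {self.filename!r} has no URLs")
        if self.size_bytes is not None and self.size_bytes < 0:
            raise ValueError(f"file {self.filename!r} has negative size")
        object.__setattr__(self, "format", file_format(self.filename))


@dataclass(frozen=True)
class RunRecord:
    """A run (or ENCODE dataset) with its lineage, attributes and files."""

    run_id: AccessionID
    parent_ids: tuple[AccessionID, ...]
    attributes: dict[str, str]
    files: tuple[FileRecord, ...]
    #: accession the record was resolved under; drives the output directory
    root: str = ""


@dataclass
class MetadataTable:
    """Per-run sample/experimental-design table for one accession."""

    accession: AccessionID
    table: pd.DataFrame  # columns == METADATA_COLUMNS, one row per run


class MetadataBackend(Protocol):
    """Minimal archive surface the resolver needs."""

    def node(self, accession: str) -> Optional[dict]:
        """Metadata-tree node for an accession, or None when unknown."""
        ...

    def project_study(self, project: str) -> Optional[str]:
        """Study accession linked to a BioProject, or None."""
        ...


class FixtureMetadataBackend:
    """Backend over an in-memory or on-disk JSON metadata tree."""

    def __init__(self, tree: dict | str | Path):
        if not isinstance(tree, dict):
            tree = json.loads(Path(tree).read_text(encoding="utf-8"))
        errors = validate_tree(tree)
        if errors:
            raise ValueError("invalid metadata tree: " + "; ".join(errors[:5]))
        self._nodes: dict = tree["nodes"]
        self._project_links: dict = tree.get("project_links", {})

    def node(self, accession: str) -> Optional[dict]:
        return self._nodes.get(accession.upper())

    def project_study(self, project: str) -> Optional[str]:
        return self._project_links.get(project.upper())


def validate_tree(tree: dict) -> list[str]:
    """Validate a metadata tree against the documented schema; return problems."""
    errors: list[str] = []
    if tree.get("schema_version") != SCHEMA_VERSION:
        errors.append(f"schema_version must be {SCHEMA_VERSION}")
    nodes = tree.get("nodes")
    if not isinstance(nodes, dict):
        return errors + ["'nodes' mapping missing"]
    for acc, node in nodes.items():
        if classify(acc) is None:
            errors.append(f"node key {acc!r} is not a valid accession")
        if "level" not in node:
            errors.append(f"{acc}: missing level")
        for child in node.get("children", []):
            if child not in nodes:
                errors.append(f"{acc}: child {child} not in tree")
        for f in node.get("files", []) + node.get("processed_files", []):
            if "filename" not in f or "size_bytes" not in f:
                errors.append(f"{acc}: file entry missing filename/size_bytes")
            elif not isinstance(f["size_bytes"], int) or f["size_bytes"] < 0:
                errors.append(f"{acc}: {f['filename']} has bad size")
            if not f.get("urls"):
                errors.append(f"{acc}: {f.get('filename')} has no urls")
        if node.get("level") in ("run", "dataset") and not node.get("files"):
            errors.append(f"{acc}: terminal node without files")
    for prj, study in tree.get("project_links", {}).items():
        cls = classify(prj)
        if cls is None or cls.name != "BIOPROJECT":
            errors.append(f"project link key {prj!r} is not a BioProject")
        if study not in nodes:
            errors.append(f"project {prj} links to unknown study {study}")
    return errors


def _accession(text: str) -> AccessionID:
    cls = classify(text)
    if cls is None:
        raise ResolutionError(text, "not a valid accession")
    return AccessionID(text, cls)


def _file_record(raw: dict) -> FileRecord:
    return FileRecord(
        filename=raw["filename"],
        size_bytes=raw["size_bytes"],
        urls=tuple((p, a) for p, a in raw.get("urls", [])),
        checksum=raw.get("md5"),
    )


def convert_project_to_study(project: AccessionID, backend: MetadataBackend) -> AccessionID:
    """Map a BioProject accession to its linked sequencing study accession."""
    if project.accession_class.name != "BIOPROJECT":
        raise ValueError(f"{project.text} is not a BioProject accession")
    study = backend.project_study(project.text)
    if study is None:
        raise ResolutionError(project.text, "no study linked to this project")
    return _accession(study)


def resolve(accession: AccessionID | str, backend: MetadataBackend) -> list[RunRecord]:
    """Expand an accession into every run reachable beneath it.

    A run (or ENCODE dataset) accession resolves to itself; containers walk
    their children; BioProjects are first converted to their linked study.
    Output order is lexicographic by run id, so resolution is deterministic
    for a given backend snapshot.
    """
    if isinstance(accession, str):
        accession = _accession(accession)
    root_text = accession.text
    if accession.accession_class.name == "BIOPROJECT":
        accession = convert_project_to_study(accession, backend)

    start = backend.node(accession.text)
    if start is None:
        raise ResolutionError(accession.text, "unknown to the metadata backend")

    records: dict[str, RunRecord] = {}
    stack: list[tuple[str, tuple[AccessionID, ...]]] = [(accession.text, ())]
    visited: set[str] = set()
    while stack:
        acc_text, lineage = stack.pop()
        if acc_text in visited:
            continue
        visited.add(acc_text)
        node = backend.node(acc_text)
        if node is None:
            log.warning("dangling child %s while resolving %s", acc_text, root_text)
            continue
        acc_id = _accession(acc_text)
        if node.get("files"):
            records[acc_text] = RunRecord(
                run_id=acc_id,
                parent_ids=lineage,
                attributes=dict(node.get("attributes", {})),
                files=tuple(_file_record(f) for f in node["files"]),
                root=root_text,
            )
        for child in node.get("children", []):
            stack.append((child, lineage + (acc_id,)))
    return [records[k] for k in sorted(records)]


def filter_by_format(records: list[RunRecord], fmt: str) -> list[RunRecord]:
    """Restrict records to files of one sequence format.

    Records left with zero files are dropped; the input list is untouched.
    Only the four downloadable sequence formats are accepted.
    """
    if fmt not in SEQUENCE_FORMATS:
        raise ValueError(
            f"unsupported format {fmt!r}; expected one of {', '.join(SEQUENCE_FORMATS)}"
        )
    out = []
    for rec in records:
        kept = tuple(f for f in rec.files if f.format == fmt)
        if kept:
            out.append(replace(rec, files=kept))
    return out


def _lineage_by_level(rec: RunRecord) -> dict[str, str]:
    levels: dict[str, str] = {}
    for p in rec.parent_ids:
        levels.setdefault(p.hierarchy_level, p.text)
    return levels


def fetch_metadata_table(accession: AccessionID | str, backend: MetadataBackend) -> MetadataTable:
    """Build the per-run metadata table for an accession.

    One row per run, with the stable column set; values absent from the
    backend are rendered as "NA" so the column set never varies.
    """
    if isinstance(accession, str):
        accession = _accession(accession)
    records = resolve(accession, backend)
    rows = []
    for rec in records:
        lineage = _lineage_by_level(rec)
        attr = rec.attributes
        rows.append(
            {
                "run": rec.run_id.text,
                "sample": lineage.get("sample", attr.get("sample", "NA")),
                "experiment": lineage.get("experiment", attr.get("experiment", "NA")),
                "study": lineage.get("study", attr.get("study", "NA")),
                "organism": attr.get("organism", "NA"),
                "library_strategy": attr.get("library_strategy", "NA"),
                "layout": attr.get("layout", "NA"),
                "instrument": attr.get("instrument", "NA"),
                "description": attr.get("description", "NA"),
            }
        )
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).drop_duplicates(subset="run")
    return MetadataTable(accession=accession, table=df.reset_index(drop=True))


def write_metadata_table(table: MetadataTable, outdir: str | Path) -> Path:
    """Write a metadata table under ``<outdir>/<accession>/metadata.tsv``."""
    dest_dir = Path(outdir) / table.accession.text
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / "metadata.tsv"
    table.table.to_csv(dest, sep="\t", index=False)
    return dest
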