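"""Download planning: manifest construction, size aggregation, space gate.

Sequence files are customarily huge, so every transfer is planned before a
byte moves: resolved file records become a manifest of (accession, file,
destination) entries, the aggregate declared size is computed exactly in
bytes, and a disk-space gate compares it against the space available on the
filesystem holding the output directory.  When the requirement exceeds the
available space the pipeline halts without writing any payload, rather than
failing midway through a multi-hour transfer.

Layout convention: sequence files and metadata tables live in directories
named by the accession they were requested under; supplementary assets live
in directories named by the article's PMCID/URL id.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

from .resolver import FileRecord, RunRecord

__all__ = [
    "ManifestEntry",
    "DownloadManifest",
    "SpaceDecision",
    "build_manifest",
    "check_space",
    "layout_paths",
    "available_bytes_for",
]

log = logging.getLogger(__name__)

_GIB = 1024.0**3


def _gib(n: int) -> str:
    return f"{n / _GIB:.1f} GiB"


@dataclass(frozen=True)
class ManifestEntry:
    accession: str
    file: FileRecord
    destination: Path


@dataclass
class DownloadManifest:
    """Planned transfers; the byte total is recomputed, never cached."""

    entries: list[ManifestEntry]

    @property
    def total_bytes(self) -> int:
        return sum(e.file.size_bytes or 0 for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        """Serialize for --dry-run inspection."""
        return json.dumps(
            {
                "total_bytes": self.total_bytes,
                "entries": [
                    {
                        "accession": e.accession,
                        "filename": e.file.filename,
                        "size_bytes": e.file.size_bytes,
                        "checksum": e.file.checksum,
                        "format": e.file.format,
                        "urls": [list(u) for u in e.file.urls],
                        "destination": str(e.destination),
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class SpaceDecision:
    """Outcome of the pre-transfer disk-space gate."""

    required_bytes: int
    available_bytes: int
    margin_bytes: int
    verdict: str  # "proceed" | "halt"
    message: str


def build_manifest(records: list[RunRecord], outdir: str | Path) -> DownloadManifest:
    """Plan one manifest entry per resolved file.

    Destination is ``<outdir>/<accession>/<filename>`` where the accession is
    the one the run was resolved under (so a whole series lands in a single
    directory named after it).  A filename collision within one accession is
    disambiguated with a numeric suffix and logged.
    """
    outdir = Path(outdir)
    entries: list[ManifestEntry] = []
    taken: set[Path] = set()
    for rec in records:
        owner = rec.root or rec.run_id.text
        for f in rec.files:
            dest = outdir / owner / f.filename
            if dest in taken:
                stem, dot, ext = f.filename.partition(".")
                n = 1
                while dest in taken:
                    dest = outdir / owner / f"{stem}.{n}{dot}{ext}" if dot else outdir / owner / f"{stem}.{n}"
                    n += 1
                log.warning(
                    "duplicate filename %s under %s; renamed to %s",
                    f.filename, owner, dest.name,
                )
            taken.add(dest)
            entries.append(ManifestEntry(accession=owner, file=f, destination=dest))
    unsized = [e.file.filename for e in entries if e.file.size_bytes is None]
    if unsized:
        log.warning(
            "%d file(s) have no declared size and count 0 toward the total: %s",
            len(unsized), ", ".join(unsized[:10]),
        )
    return DownloadManifest(entries=entries)


def check_space(
    manifest: DownloadManifest, available_bytes: int, margin_bytes: int = 0
) -> SpaceDecision:
    """Compare the manifest's byte requirement against available disk space.

    Halts iff ``required + margin > available``.  Halting is a decision, not
    an exception; the pipeline turns it into a non-zero exit with zero files
    transferred.
    """
    if available_bytes < 0:
        raise ValueError("available_bytes must be non-negative")
    required = manifest.total_bytes
    if required + margin_bytes > available_bytes:
        verdict = "halt"
        message = (
            f"insufficient disk space: required {_gib(required)} "
            f"({required} bytes) exceeds available {_gib(available_bytes)} "
            f"({available_bytes} bytes); downloading halted"
        )
    else:
        verdict = "proceed"
        message = (
            f"space check passed: required {_gib(required)}, "
            f"available {_gib(available_bytes)}"
        )
    return SpaceDecision(
        required_bytes=required,
        available_bytes=available_bytes,
        margin_bytes=margin_bytes,
        verdict=verdict,
        message=message,
    )


def layout_paths(manifest: DownloadManifest, kind: str = "sequence") -> list[Path]:
    """Destination paths of a manifest under the per-owner directory layout.

    ``sequence`` and ``metadata`` outputs sit under a directory named by the
    accession; ``supplementary`` assets under a directory named by the
    article id (PMCID/URL).  The owner id is the entry's accession field in
    every case, so this simply materializes and checks the convention.
    """
    if kind not in ("sequence", "supplementary", "metadata"):
        raise ValueError(f"unknown layout kind {kind!r}")
    paths = []
    for e in manifest.entries:
        if e.destination.parent.name != e.accession:
            raise ValueError(
                f"entry {e.file.filename} not under its owner directory {e.accession}"
            )
        paths.append(e.destination)
    return paths


def available_bytes_for(path: str | Path) -> int:
    """Free bytes on the filesystem that holds ``path`` (or its nearest parent)."""
    p = Path(path)
    while not p.exists():
        parent = p.parent
        if parent == p:
            break
        p = parent
    return shutil.disk_usage(p).free
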