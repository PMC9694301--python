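"""Bounded-parallel, resumable, verified execution of a download manifest.

Transfers run on a thread pool of at most ``workers`` concurrent transfers
(default: logical cores − 1, floored at 1).  Each manifest entry picks one
URL by a fixed protocol preference — fasp > http > ftp > local — restricted
to protocols the backend actually speaks and not disabled by configuration.
Every completed file is verified against its declared size and, when the
archive declared one, its MD5 checksum; verification failures count as
failed attempts and are retried with exponential backoff.

Resumability: a destination that already exists and verifies is skipped; a
partial file is continued from its current length when the chosen backend
supports ranged transfers (first attempt only), otherwise restarted from
zero.  Re-running a finished manifest therefore transfers nothing, and
re-running an interrupted one converges to the same byte-identical tree as
an uninterrupted run.

The FASP (Aspera) protocol is represented by a stub backend that fails
gracefully: the wire protocol is proprietary, so entries whose only URL is
fasp report a clear "backend not installed" failure instead of hanging.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import urllib.error
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol
from urllib.parse import urlparse
from urllib.request import url2pathname

from .planner import DownloadManifest, ManifestEntry
from .resolver import FileRecord

__all__ = [
    "PROTOCOL_PREFERENCE",
    "WorkerConfig",
    "EntryReport",
    "DownloadReport",
    "BackendUnavailable",
    "TransferBackend",
    "LocalCopyBackend",
    "HttpBackend",
    "FtpBackend",
    "FaspStubBackend",
    "ProtocolRouter",
    "default_workers",
    "execute",
    "resume",
    "verify",
]

log = logging.getLogger(__name__)

#: Total, stable protocol preference for URL selection.
PROTOCOL_PREFERENCE = ("fasp", "http", "ftp", "local")


def default_workers(detected_cores: int) -> int:
    """Default worker count: one less than the detected cores, at least 1."""
    if detected_cores < 1:
        raise ValueError("detected_cores must be >= 1")
    return max(detected_cores - 1, 1)


@dataclass(frozen=True)
class WorkerConfig:
    """Transfer concurrency and retry policy."""

    workers: int = field(default_factory=lambda: default_workers(os.cpu_count() or 1))
    retries: int = 3
    retry_backoff: float = 1.0  # seconds; doubles per attempt
    disabled_protocols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.retries < 0:
            raise ValueError("retries must be >= 0")


class BackendUnavailable(RuntimeError):
    """The selected transfer backend cannot perform transfers."""


class TransferError(RuntimeError):
    """A single transfer attempt failed."""


class TransferBackend(Protocol):
    """A protocol-speaking transfer engine."""

    protocols: frozenset[str]

    def transfer(self, url: str, dest: Path, resume_from: int = 0) -> int:
        """Write the remote content to ``dest``; return bytes written.

        ``resume_from`` > 0 asks to append starting at that offset and is
        only passed when :meth:`supports_resume` said so for the protocol.
        """
        ...

    def supports_resume(self, protocol: str) -> bool: ...


def _local_source(url: str, root: Optional[Path]) -> Path:
    parsed = urlparse(url)
    if parsed.scheme == "file":
        return Path(url2pathname(parsed.path))
    p = Path(url)
    if not p.is_absolute() and root is not None:
        p = root / p
    return p


class LocalCopyBackend:
    """Copy files from a local store; the workhorse of offline runs and tests."""

    protocols = frozenset({"local"})

    def __init__(self, root: str | Path | None = None):
        self.root = Path(root) if root is not None else None

    def supports_resume(self, protocol: str) -> bool:
        return True

    def transfer(self, url: str, dest: Path, resume_from: int = 0) -> int:
        src = _local_source(url, self.root)
        if not src.is_file():
            raise TransferError(f"local source {src} does not exist")
        dest.parent.mkdir(parents=True, exist_ok=True)
        mode = "r+b" if resume_from else "wb"
        written = 0
        with open(src, "rb") as fin:
            fin.seek(resume_from)
            with open(dest, mode) as fout:
                fout.seek(resume_from)
                fout.truncate()
                while chunk := fin.read(1 << 20):
                    fout.write(chunk)
                    written += len(chunk)
        return written


class _UrllibBackend:
    """Shared urllib plumbing for the HTTP(S) and FTP backends."""

    protocols: frozenset[str] = frozenset()
    _ranged = False

    def __init__(self, timeout: float = 60.0):
        self.timeout = timeout

    def supports_resume(self, protocol: str) -> bool:
        return self._ranged

    def transfer(self, url: str, dest: Path, resume_from: int = 0) -> int:
        headers = {"User-Agent": "seqharvest/0.1"}
        if resume_from:
            headers["Range"] = f"bytes={resume_from}-"
        req = urllib.request.Request(url, headers=headers)
        dest.parent.mkdir(parents=True, exist_ok=True)
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                if resume_from and getattr(resp, "status", 200) != 206:
                    resume_from = 0  # server ignored the range; restart
                mode = "r+b" if resume_from else "wb"
                if resume_from and not dest.exists():
                    mode = "wb"
                    resume_from = 0
                written = 0
                with open(dest, mode) as fout:
                    fout.seek(resume_from)
                    fout.truncate()
                    while chunk := resp.read(1 << 20):
                        fout.write(chunk)
                        written += len(chunk)
                return written
        except (urllib.error.URLError, OSError, TimeoutError) as err:
            raise TransferError(f"transfer of {url} failed: {err}") from err


class HttpBackend(_UrllibBackend):
    protocols = frozenset({"http"})
    _ranged = True


class FtpBackend(_UrllibBackend):
    protocols = frozenset({"ftp"})
    _ranged = False


class FaspStubBackend:
    """Placeholder for the proprietary Aspera FASP protocol: always unavailable."""

    protocols = frozenset({"fasp"})

    def supports_resume(self, protocol: str) -> bool:
        return False

    def transfer(self, url: str, dest: Path, resume_from: int = 0) -> int:
        raise BackendUnavailable(
            "FASP/Aspera transfer backend is not installed; "
            "use an http/ftp/local URL instead"
        )


class ProtocolRouter:
    """Dispatch transfers to per-protocol backends under one interface."""

    def __init__(self, *backends: TransferBackend):
        self._by_protocol: dict[str, TransferBackend] = {}
        for b in backends:
            for p in b.protocols:
                self._by_protocol.setdefault(p, b)
        self.protocols = frozenset(self._by_protocol)

    def supports_resume(self, protocol: str) -> bool:
        b = self._by_protocol.get(protocol)
        return b is not None and b.supports_resume(protocol)

    def transfer(self, url: str, dest: Path, resume_from: int = 0) -> int:
        proto = _protocol_of(url)
        backend = self._by_protocol.get(proto)
        if backend is None:
            raise TransferError(f"no backend speaks {proto!r} for {url}")
        return backend.transfer(url, dest, resume_from)


def _protocol_of(url: str) -> str:
    scheme = urlparse(url).scheme.lower()
    if scheme in ("http", "https"):
        return "http"
    if scheme == "ftp":
        return "ftp"
    if scheme == "fasp":
        return "fasp"
    return "local"


@dataclass
class EntryReport:
    destination: Path
    accession: str
    filename: str
    outcome: str  # "completed" | "skipped_existing" | "failed"
    bytes_written: int = 0
    attempts: int = 0
    checksum_ok: Optional[bool] = None  # None == not_checked
    error: Optional[str] = None


@dataclass
class DownloadReport:
    entries: list[EntryReport]

    @property
    def success(self) -> bool:
        return not any(e.outcome == "failed" for e in self.entries)

    def count(self, outcome: str) -> int:
        return sum(1 for e in self.entries if e.outcome == outcome)

    @property
    def bytes_written(self) -> int:
        return sum(e.bytes_written for e in self.entries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "verdict": "success" if self.success else "failure",
                "completed": self.count("completed"),
                "skipped_existing": self.count("skipped_existing"),
                "failed": self.count("failed"),
                "bytes_written": self.bytes_written,
                "entries": [
                    {
                        "destination": str(e.destination),
                        "accession": e.accession,
                        "filename": e.filename,
                        "outcome": e.outcome,
                        "bytes_written": e.bytes_written,
                        "attempts": e.attempts,
                        "checksum_ok": e.checksum_ok,
                        "error": e.error,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )


def _verify_detail(path: Path, file: FileRecord) -> tuple[bool, Optional[bool]]:
    try:
        if not path.is_file():
            return False, None
        if file.size_bytes is not None and path.stat().st_size != file.size_bytes:
            return False, None
        if file.checksum is None:
            return True, None
        h = hashlib.md5()
        with open(path, "rb") as fh:
            while chunk := fh.read(1 << 20):
                h.update(chunk)
        ok = h.hexdigest().lower() == file.checksum.lower()
        return ok, ok
    except OSError:
        return False, None


def verify(path: str | Path, file: FileRecord) -> bool:
    """True iff the local file matches its declared size and checksum.

    With no declared checksum, size agreement alone passes (the report marks
    the checksum as not checked).  Unreadable files verify False.
    """
    ok, _ = _verify_detail(Path(path), file)
    return ok


def _select_url(
    file: FileRecord, backend: TransferBackend, config: WorkerConfig
) -> Optional[tuple[str, str]]:
    by_proto = {}
    for proto, addr in file.urls:
        by_proto.setdefault(proto, addr)
    for proto in PROTOCOL_PREFERENCE:
        if proto in config.disabled_protocols:
            continue
        if proto in by_proto and proto in backend.protocols:
            return proto, by_proto[proto]
    return None


def _process_entry(
    entry: ManifestEntry,
    config: WorkerConfig,
    backend: TransferBackend,
    skip_existing: bool,
) -> EntryReport:
    report = EntryReport(
        destination=entry.destination,
        accession=entry.accession,
        filename=entry.file.filename,
        outcome="failed",
    )
    dest = entry.destination
    if skip_existing:
        ok, chk = _verify_detail(dest, entry.file)
        if ok:
            report.outcome = "skipped_existing"
            report.checksum_ok = chk
            return report

    selected = _select_url(entry.file, backend, config)
    if selected is None:
        report.error = (
            f"no usable protocol among {[p for p, _ in entry.file.urls]} "
            f"(backend speaks {sorted(backend.protocols)})"
        )
        log.error("%s: %s", entry.file.filename, report.error)
        return report
    proto, url = selected

    for attempt in range(config.retries + 1):
        report.attempts = attempt + 1
        resume_from = 0
        if (
            attempt == 0
            and entry.file.size_bytes is not None
            and dest.is_file()
            and 0 < dest.stat().st_size < entry.file.size_bytes
            and backend.supports_resume(proto)
        ):
            resume_from = dest.stat().st_size
        try:
            report.bytes_written += backend.transfer(url, dest, resume_from)
            ok, chk = _verify_detail(dest, entry.file)
            report.checksum_ok = chk
            if ok:
                report.outcome = "completed"
                return report
            raise TransferError(
                f"verification failed for {dest} (size/checksum mismatch)"
            )
        except BackendUnavailable as err:
            report.error = str(err)
            log.error("%s: %s", entry.file.filename, err)
            return report  # retrying an absent backend is pointless
        except (TransferError, OSError) as err:
            report.error = str(err)
            log.warning(
                "%s attempt %d/%d failed: %s",
                entry.file.filename, attempt + 1, config.retries + 1, err,
            )
            if attempt < config.retries:
                time.sleep(config.retry_backoff * (2**attempt))
    return report


def execute(
    manifest: DownloadManifest,
    config: WorkerConfig | None = None,
    backend: TransferBackend | None = None,
    skip_existing: bool = False,
) -> DownloadReport:
    """Run every manifest entry through the worker pool and verify results.

    At most ``config.workers`` transfers are in flight at any instant.
    Entries are scheduled longest-file-first (stable tie-break on the
    destination path) to shorten the makespan tail.  A failed entry never
    stops the rest; the report lists each outcome.
    """
    config = config or WorkerConfig()
    backend = backend or ProtocolRouter(
        FaspStubBackend(), HttpBackend(), FtpBackend(), LocalCopyBackend()
    )
    ordered = sorted(
        manifest.entries, key=lambda e: (-(e.file.size_bytes or 0), str(e.destination))
    )
    if not ordered:
        return DownloadReport(entries=[])
    with ThreadPoolExecutor(max_workers=config.workers) as pool:
        reports = list(
            pool.map(
                lambda e: _process_entry(e, config, backend, skip_existing), ordered
            )
        )
    by_dest = {r.destination: r for r in reports}
    return DownloadReport(entries=[by_dest[e.destination] for e in manifest.entries])


def resume(
    manifest: DownloadManifest,
    config: WorkerConfig | None = None,
    backend: TransferBackend | None = None,
) -> DownloadReport:
    """Finish a previously interrupted :func:`execute`.

    Destinations that already verify are skipped; everything else is
    (re)transferred, so the final tree equals a fresh successful run.
    """
    return execute(manifest, config, backend, skip_existing=True)
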