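"""Parallel execution, verification, resume and protocol selection."""

import random
import threading

import pytest

from seqharvest import fixtures as fx
from seqharvest.downloader import (
    BackendUnavailable,
    FaspStubBackend,
    LocalCopyBackend,
    PROTOCOL_PREFERENCE,
    ProtocolRouter,
    WorkerConfig,
    _select_url,
    default_workers,
    execute,
    resume,
    verify,
)
from seqharvest.planner import build_manifest
from seqharvest.resolver import FileRecord, FixtureMetadataBackend, resolve

CFG = dict(retries=1, retry_backoff=0.0)


@pytest.fixture()
def manifest_and_root(tmp_path):
    """A resolvable 10-file store plus a manifest into a fresh outdir."""
    result = fx.make_store(
        fx.StoreSpec(seed=5, n_studies=1, runs_per_study=(10, 10)), tmp_path
    )
    be = FixtureMetadataBackend(result.tree)
    records = resolve(next(iter(result.series_map)), be)
    manifest = build_manifest(records, tmp_path / "out")
    return manifest, tmp_path


def _tree_bytes(root):
    return {
        str(p.relative_to(root)): p.read_bytes()
        for p in root.rglob("*")
        if p.is_file()
    }


class CountingBackend(LocalCopyBackend):
    """Local-copy backend that records the maximum concurrent transfers."""

    def __init__(self, root):
        super().__init__(root)
        self._lock = threading.Lock()
        self._inflight = 0
        self.max_inflight = 0
        self.calls = 0

    def transfer(self, url, dest, resume_from=0):
        with self._lock:
            self._inflight += 1
            self.calls += 1
            self.max_inflight = max(self.max_inflight, self._inflight)
        try:
            return super().transfer(url, dest, resume_from)
        finally:
            with self._lock:
                self._inflight -= 1


class FlakyBackend(LocalCopyBackend):
    """Fails the first ``n_failures`` transfer attempts, then behaves."""

    def __init__(self, root, n_failures):
        super().__init__(root)
        self._lock = threading.Lock()
        self.remaining = n_failures

    def transfer(self, url, dest, resume_from=0):
        with self._lock:
            if self.remaining > 0:
                self.remaining -= 1
                raise OSError("synthetic transient failure")
        return super().transfer(url, dest, resume_from)


class TestExecute:
    def test_all_files_byte_identical_to_store(self, manifest_and_root):
        manifest, root = manifest_and_root
        report = execute(manifest, WorkerConfig(workers=8, **CFG), LocalCopyBackend(root))
        assert report.success and report.count("completed") == 10
        for entry in manifest.entries:
            src = root / "store" / entry.file.filename.split("_")[0].split(".")[0] / entry.file.filename
            assert entry.destination.read_bytes() == src.read_bytes()

    def test_empty_manifest(self, tmp_path):
        from seqharvest.planner import DownloadManifest

        report = execute(DownloadManifest([]), WorkerConfig(workers=2, **CFG))
        assert report.success and report.entries == []

    def test_serial_and_parallel_trees_identical(self, tmp_path):
        result = fx.make_store(
            fx.StoreSpec(seed=6, n_studies=1, runs_per_study=(8, 8)), tmp_path
        )
        be = FixtureMetadataBackend(result.tree)
        records = resolve(next(iter(result.series_map)), be)
        out1, out8 = tmp_path / "serial", tmp_path / "parallel"
        execute(build_manifest(records, out1), WorkerConfig(workers=1, **CFG), LocalCopyBackend(tmp_path))
        execute(build_manifest(records, out8), WorkerConfig(workers=8, **CFG), LocalCopyBackend(tmp_path))
        assert _tree_bytes(out1) == _tree_bytes(out8)

    def test_concurrency_never_exceeds_worker_bound(self, tmp_path):
        result = fx.make_store(
            fx.StoreSpec(seed=8, n_studies=1, runs_per_study=(10, 10), files_per_run=2),
            tmp_path,
        )
        be = FixtureMetadataBackend(result.tree)
        records = resolve(next(iter(result.series_map)), be)
        for trial in range(5):
            backend = CountingBackend(tmp_path)
            out = tmp_path / f"out{trial}"
            report = execute(
                build_manifest(records, out), WorkerConfig(workers=3, **CFG), backend
            )
            assert report.success
            assert backend.max_inflight <= 3

    def test_failed_entry_does_not_stop_the_rest(self, manifest_and_root):
        manifest, root = manifest_and_root
        # exhaust retries for exactly one entry: retries=0 and one failure
        backend = FlakyBackend(root, n_failures=1)
        report = execute(manifest, WorkerConfig(workers=1, retries=0, retry_backoff=0), backend)
        assert report.count("failed") == 1
        assert report.count("completed") == 9
        assert not report.success

    def test_retries_recover_transient_failures(self, manifest_and_root):
        manifest, root = manifest_and_root
        backend = FlakyBackend(root, n_failures=3)
        report = execute(manifest, WorkerConfig(workers=2, retries=3, retry_backoff=0), backend)
        assert report.success
        assert max(e.attempts for e in report.entries) > 1

    def test_completed_bytes_match_declared_sizes(self, manifest_and_root):
        manifest, root = manifest_and_root
        report = execute(manifest, WorkerConfig(workers=4, **CFG), LocalCopyBackend(root))
        for entry, rep in zip(manifest.entries, report.entries):
            assert rep.outcome == "completed"
            assert rep.destination.stat().st_size == entry.file.size_bytes


class TestVerify:
    def test_intact_file_with_checksum(self, manifest_and_root):
        manifest, root = manifest_and_root
        execute(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        e = manifest.entries[0]
        assert verify(e.destination, e.file)

    def test_single_corrupt_byte_detected(self, manifest_and_root):
        manifest, root = manifest_and_root
        execute(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        e = manifest.entries[0]
        data = bytearray(e.destination.read_bytes())
        data[3] ^= 0x01
        e.destination.write_bytes(bytes(data))
        assert not verify(e.destination, e.file)

    def test_truncated_copy_detected(self, manifest_and_root):
        manifest, root = manifest_and_root
        execute(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        e = manifest.entries[0]
        e.destination.write_bytes(e.destination.read_bytes()[:-1])
        assert not verify(e.destination, e.file)

    def test_missing_file_fails_not_raises(self, tmp_path):
        f = FileRecord("x.fastq.gz", 10, (("local", "x"),))
        assert verify(tmp_path / "absent", f) is False

    def test_size_only_record_checksum_not_checked(self, tmp_path):
        p = tmp_path / "f.txt"
        p.write_bytes(b"12345")
        f = FileRecord("f.txt", 5, (("local", "f.txt"),), checksum=None)
        assert verify(p, f)


class TestResume:
    def _interrupted(self, manifest, root, k):
        """Simulate a kill after k completed files."""
        class StopAfter(LocalCopyBackend):
            def __init__(self, root, limit):
                super().__init__(root)
                self.limit = limit
                self._lock = threading.Lock()

            def transfer(self, url, dest, resume_from=0):
                with self._lock:
                    if self.limit <= 0:
                        raise OSError("process killed")
                    self.limit -= 1
                return super().transfer(url, dest, resume_from)

        execute(manifest, WorkerConfig(workers=1, retries=0, retry_backoff=0), StopAfter(root, k))

    @pytest.mark.parametrize("k", [0, 4, 10])
    def test_kill_after_k_then_resume_matches_uninterrupted(self, tmp_path, k):
        result = fx.make_store(
            fx.StoreSpec(seed=5, n_studies=1, runs_per_study=(10, 10)), tmp_path
        )
        be = FixtureMetadataBackend(result.tree)
        records = resolve(next(iter(result.series_map)), be)
        out_ref, out = tmp_path / "ref", tmp_path / "out"
        execute(build_manifest(records, out_ref), WorkerConfig(workers=2, **CFG), LocalCopyBackend(tmp_path))

        manifest = build_manifest(records, out)
        self._interrupted(manifest, tmp_path, k)
        report = resume(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(tmp_path))
        assert report.success
        assert report.count("skipped_existing") == k
        assert report.count("completed") == 10 - k
        assert _tree_bytes(out) == _tree_bytes(out_ref)

    def test_resume_after_success_is_idempotent(self, manifest_and_root):
        manifest, root = manifest_and_root
        execute(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        report = resume(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        assert report.count("skipped_existing") == len(manifest.entries)
        assert report.bytes_written == 0

    def test_corrupted_file_is_the_only_retransfer(self, manifest_and_root):
        manifest, root = manifest_and_root
        execute(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        victim = manifest.entries[4]
        data = bytearray(victim.destination.read_bytes())
        data[0] ^= 0xFF
        victim.destination.write_bytes(bytes(data))
        report = resume(manifest, WorkerConfig(workers=2, **CFG), LocalCopyBackend(root))
        retransferred = [e.filename for e in report.entries if e.outcome == "completed"]
        assert retransferred == [victim.file.filename]
        assert verify(victim.destination, victim.file)

    def test_partial_file_resumed_from_offset(self, manifest_and_root):
        manifest, root = manifest_and_root
        e = max(manifest.entries, key=lambda x: x.file.size_bytes)
        src = None
        for p in (root / "store").rglob(e.file.filename):
            src = p
        half = src.read_bytes()[: e.file.size_bytes // 2]
        e.destination.parent.mkdir(parents=True, exist_ok=True)
        e.destination.write_bytes(half)
        backend = CountingBackend(root)
        report = resume(manifest, WorkerConfig(workers=1, **CFG), backend)
        assert report.success
        rep = next(r for r in report.entries if r.filename == e.file.filename)
        # only the missing tail was transferred
        assert rep.bytes_written == e.file.size_bytes - len(half)


class TestProtocolSelection:
    def _file(self, urls):
        return FileRecord("x.fastq.gz", 1, tuple(urls))

    def test_preference_order_is_total_and_stable(self):
        urls = [
            ("local", "store/x"), ("ftp", "ftp://h/x"),
            ("http", "https://h/x"), ("fasp", "fasp://h/x"),
        ]
        backend = ProtocolRouter(FaspStubBackend(), LocalCopyBackend())
        # fasp outranks everything the backend speaks
        proto, _ = _select_url(self._file(urls), backend, WorkerConfig(workers=1))
        assert proto == "fasp"
        assert PROTOCOL_PREFERENCE == ("fasp", "http", "ftp", "local")

    def test_disabled_protocol_skipped(self):
        urls = [("fasp", "fasp://h/x"), ("local", "store/x")]
        backend = ProtocolRouter(FaspStubBackend(), LocalCopyBackend())
        proto, _ = _select_url(
            self._file(urls), backend, WorkerConfig(workers=1, disabled_protocols=("fasp",))
        )
        assert proto == "local"

    def test_fasp_stub_fails_gracefully(self, tmp_path):
        with pytest.raises(BackendUnavailable, match="not installed"):
            FaspStubBackend().transfer("fasp://h/x", tmp_path / "x")

    def test_fasp_only_entry_reports_failure_without_retry_storm(self, tmp_path):
        from seqharvest.planner import DownloadManifest, ManifestEntry

        entry = ManifestEntry(
            "GSE1",
            FileRecord("x.fastq.gz", 1, (("fasp", "fasp://h/x"),)),
            tmp_path / "GSE1" / "x.fastq.gz",
        )
        report = execute(
            DownloadManifest([entry]),
            WorkerConfig(workers=1, retries=3, retry_backoff=0),
            ProtocolRouter(FaspStubBackend(), LocalCopyBackend()),
        )
        rep = report.entries[0]
        assert rep.outcome == "failed" and rep.attempts == 1
        assert "not installed" in rep.error


class TestWorkerDefaults:
    @pytest.mark.parametrize("cores,expected", [(1, 1), (2, 1), (8, 7), (64, 63)])
    def test_cores_minus_one_floored_at_one(self, cores, expected):
        assert default_workers(cores) == expected

    def test_invalid_cores_rejected(self):
        with pytest.raises(ValueError):
            default_workers(0)

    def test_config_rejects_zero_workers(self):
        with pytest.raises(ValueError):
            WorkerConfig(workers=0)
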