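# seqharvest

**seqharvest** automates the end-to-end acquisition of published genomic and
transcriptomic sequence data.  Given research articles (PMCIDs, URLs) or bare
archive accession numbers, it:

1. **mines** article full text for accession numbers of every major archive
   family — SRA/ENA/DDBJ runs, experiments, samples and studies
   (SRR/ERR/DRR, SRX/ERX/DRX, SRS/ERS/DRS, SRP/ERP/DRP), SRA submissions
   (SRA), GEO series and samples (GSE/GSM), BioProjects (PRJNA), BioSamples
   (SAMN) and ENCODE records (ENCSR/ENCSB/ENCSD) — and writes a per-article
   summary table (`info.txt`: PubMed URL, Title, Abstract, Accessions, PMID);
2. **resolves** each accession through the study → experiment → sample → run
   hierarchy into concrete files with sizes, MD5 checksums and per-protocol
   download URLs, converting BioProjects to their linked study first;
3. **plans** the transfer: one manifest entry per file with a destination
   under a directory named by the accession, an exact byte total, and a
   disk-space gate that halts the run (non-zero exit, zero payload written)
   when the requirement exceeds the free space of the output filesystem;
4. **downloads** with a bounded pool of parallel workers (default: logical
   cores − 1), fixed protocol preference fasp > http > ftp > local,
   size/checksum verification of every file, retries with exponential
   backoff, and resumable re-runs that skip verified files and re-transfer
   corrupted or missing ones.

It can also retrieve *only* supplementary data tables attached to articles
(saved per PMCID), *only* per-accession metadata tables (run, sample,
experiment, study, organism, library strategy, layout, instrument,
description), or *only* processed data assets.

Who it is for: anyone who starts an analysis from published data — instead
of reading papers for accessions, converting identifiers by hand, guessing
whether the FASTQs fit on disk, and babysitting downloads, one command does
all four steps and is safe to re-run after an interruption.

Every stage runs offline against **fixture backends**: a directory of
article documents, a JSON metadata tree and a local file store, all
generated deterministically by `seqharvest.fixtures`.  A live HTTP retriever
and HTTP/FTP transfer backends ship for real use; the proprietary Aspera
FASP protocol is a stub interface that fails with a clear message.

## Worked example (offline, fixture backend)

Generate a small synthetic world — one article citing a GEO series and a
BioProject, both resolvable to three paired runs in a local store:

```python
from pathlib import Path
from seqharvest import fixtures as fx

root = Path("example")
store = fx.make_store(fx.StoreSpec(seed=42, n_studies=1, runs_per_study=(3, 3)), root)
fx.write_store(store, root)
pool = tuple(store.series_map) + tuple(store.project_map)
corpus = fx.make_corpus(fx.CorpusSpec(seed=42, n_articles=1,
                                      accessions_per_article=(2, 2),
                                      accession_pool=pool))
fx.write_corpus(corpus, root / "articles")
```

Then mine the article and download everything it cites:

```console
$ seqharvest -p PMC7000000 -s 0 -o out --fixture-root example --yes
wrote article summary table out/info.txt
space check passed: required 0.0 GiB, available 79.2 GiB
downloaded 6 file(s), skipped 0, failed 0
```

The article cited `PRJNA413434` and `GSE196530`; both resolve to the same
three runs, and each accession gets its own directory:

```console
$ find out -type f | sort
out/GSE196530/SRR10234053.fastq.gz
out/GSE196530/SRR10234054.fastq.gz
out/GSE196530/SRR10234055.fastq.gz
out/PRJNA413434/SRR10234053.fastq.gz
out/PRJNA413434/SRR10234054.fastq.gz
out/PRJNA413434/SRR10234055.fastq.gz
out/info.txt
out/report.json
```

"downloaded 6 file(s)" means six transfers completed and verified against
their declared sizes and MD5 checksums; `report.json` records the per-file
outcome (completed / skipped_existing / failed, bytes written, attempts).
Re-running the same command reports `downloaded 0 file(s), skipped 6` — a
finished manifest transfers nothing.

Other common invocations:

```bash
seqharvest -i GSE126379                  # one accession, live backends
seqharvest -i SRP200001 -t fastq -o /data  # FASTQ files only
seqharvest -p PMC6492329 -s 1            # only supplementary tables
seqharvest -i GSE126379 -s 0 -m 1        # only the metadata table
seqharvest -f 1                          # accessions from ACCESSIONS.txt
seqharvest -u                            # more usage examples
```

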