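# Methods

This note documents the models, rules and numerical choices behind
seqharvest: what each stage assumes, which parameters matter, what the
synthetic fixtures emulate, and where the design was genuinely open.

## Accession grammar

The unit of identification is the *accession*: a prefix naming an archive
family plus a constrained suffix.  The registry
(`seqharvest/data/accession_registry.json`) is data, not code, so suffix
rules can be adjusted without touching logic.  Families and suffix shapes:

| family (prefixes) | suffix | hierarchy level |
|---|---|---|
| INSDC runs/experiments/samples/studies (SRR/ERR/DRR, SRX/ERX/DRX, SRS/ERS/DRS, SRP/ERP/DRP), SRA submissions (SRA) | 5–9 decimal digits | run/experiment/sample/study/submission |
| GEO series/samples (GSE/GSM) | 1–9 digits | study/sample |
| BioProject (PRJNA) | 1–9 digits | project |
| BioSample (SAMN) | 1–12 digits | sample |
| ENCODE (ENCSR/ENCSB/ENCSD) | exactly 6 uppercase alphanumerics | dataset/sample |
| CXR | 1–9 digits | dataset |

Suffix bounds follow the shapes observed in the public registries.  The
documented prefix list contains 20 distinct families; ERR (ENA runs) is
included additionally, flagged `extension: true`, because an ENA family
with experiments, samples and studies but no runs would be an inconsistent
grammar — the flag keeps the documented core auditable.  CXR is not a known
INSDC/GEO/ENCODE prefix; it is retained with an assumed numeric suffix.

Free-text extraction requires a *maximal* match — no alphanumeric character
immediately before or after — which is what rejects the bare word "SRA" in
prose (no digit suffix), substrings of DOIs and catalogue codes, and
truncations like `GSE126379a`.  Matching is case-insensitive with uppercase
canonical output, because articles typeset identifiers inconsistently.
Classification tries longest prefixes first; since the registry is
prefix-free this is a determinism guarantee, not a disambiguation need.

## Article mining

Documents arrive through an injected retriever interface: a directory-backed
fixture retriever (used by every test) or a polite live HTTP retriever
(1 s delay, descriptive user agent, 3 retries; a PMCID maps to a full-text
URL through a configurable template).  HTML/XML is rendered to plain text
with `lxml`: scripts and styles stripped, whitespace collapsed, reading
order preserved.  Reference lists are deliberately *kept* in the mined text
— data-availability statements often sit next to them — and deduplication
absorbs the repeats this causes.  Anything that does not look like markup
is treated as a plain-text article verbatim.

The per-article summary (`info.txt`) is tab-delimited with fixed columns
(PubMed URL, Title, Abstract, Accessions, PMID); missing fields become
`"NA"`, embedded tabs/newlines are flattened to spaces so the table
round-trips byte-for-byte, and accessions join with `;` in extraction
order.

A supplementary asset is classified a *data table* when its filename
extension is one of xls/xlsx/csv/tsv/txt/ods or its link label matches
`/table/i`.  The archives never define "supplementary table"; this
heuristic captures data tables without grabbing figures or movies, and it
is a pure function of label + filename.

## Resolution

The archive is abstracted to two calls: `node(accession)` returning a
metadata-tree node and `project_study(project)` returning a BioProject's
linked study.  The shipped backend reads a versioned JSON dialect
(documented in `resolver.py`); resolution itself is a deterministic walk —
containers recurse into children, nodes with files become run records,
output sorted lexicographically by run id.  GEO series resolve through
their linked samples to SRA runs; GSM resolves to its runs only.  ENCODE
accessions are dataset-centric: files attach directly and the record is its
own run id, so one data model covers both worlds.  BioProjects convert to
their study first, which makes `resolve(PRJNA…)` and `resolve(SRP…)`
provably identical.

File formats derive from the filename's extension chain with compression
suffixes peeled first (`.fastq.gz`/`.fq.bz2` → fastq, `.fa`/`.fasta` →
fasta, `.bam`, `.vcf`); anything else is `other` and is excluded by any
format filter, which accepts exactly bam/vcf/fasta/fastq.

Metadata tables have a fixed nine-column set (run, sample, experiment,
study, organism, library strategy, layout, instrument, description).  The
exact field list is a design choice — archives expose far more — picked as
the minimal set that describes experimental design; absent values render
`"NA"` so the column set never varies.

## Planning and the space gate

All size arithmetic is in bytes; GiB appears only in messages (one
decimal).  The manifest's byte total is recomputed from entries on every
access — never cached — and each file's destination is
`<outdir>/<accession>/<filename>`, the accession being the one the run was
*requested* under, so a whole series lands in one directory.  Filename
collisions within an accession get a numeric suffix and a logged warning.
Files with no declared size count zero toward the total and are listed in a
warning: under-counting with an explicit warning beats refusing to run.

The gate halts iff `required + margin > available`, with margin defaulting
to 0 (a plain comparison) and the available figure measured with
`shutil.disk_usage` on the output filesystem, overridable by flag for
testing.  A halt is a decision, not an exception: the pipeline prints the
explanation, exits non-zero, and writes no payload.

## Transfer

Concurrency is a thread pool of `workers` transfers (default
`max(cores − 1, 1)`); threads are appropriate because transfers are
I/O-bound.  Entries are scheduled longest-file-first (stable tie-break on
destination) to shorten the makespan tail.  URL selection follows the fixed
preference fasp > http > ftp > local, intersected with what the backend
speaks and minus protocols disabled by configuration.  Shipped backends:
local copy (also serving `file://`), HTTP(S) with Range support, FTP, and a
FASP stub that fails immediately with "not installed" — the wire protocol
is proprietary, and an entry whose only URL is fasp reports that failure
without a retry storm.

Verification is size equality plus MD5 when declared; no declared checksum
means size alone passes and the report marks the checksum "not checked".
Failures retry up to 3 times with exponential backoff doubling from 1 s
(both configurable; tests use zero backoff).  Resume semantics: a
destination that verifies is skipped; a partial file continues from its
current length on the first attempt when the protocol supports ranges,
otherwise — and on every later attempt — it restarts from zero.
Correctness first: ranged continuation is an optimisation, and a wrong
prefix is caught by the checksum and repaired by the restart.

## Command-line surface

One input source per invocation (`-l` URLs, `-p` PMCIDs, `-i` accessions,
`-f` list file); the companions `-t`/`-s`/`-m`/`-n` require one.  List-file
modes map 1 → ACCESSIONS.txt, 2 → PMCIDS.txt, 3 → URLS.txt; entries whose
detected kind (accession / PMCID / URL) disagrees with the mode are still
used, with a warning naming both — tolerant reading costs nothing and
mislabeled lists are common.  `-s 1`, `-m 1` and `-n 1` are exclusive
retrieval modes: each fetches *only* its artifact (supplementary tables per
PMCID, metadata tables per accession, processed assets per accession).
"Processed data" (`-n`) is interpreted as the non-sequence assets attached
at series level in the metadata tree (e.g. processed count tables), since
no stricter definition exists.  With no mode flags the default action is
sequence-data download; `-s 0` simply states that default explicitly.

Dataset selection: candidates are presented with run counts, descriptions
and instrument; `--yes` (or a non-interactive stdin) selects all, otherwise
an interactive prompt accepts indices, ids or `all`.  Exit codes: 0 clean,
1 any per-source failure, 2 usage error, 3 space-gate halt.

## Synthetic fixtures: what they emulate and what they don't

The corpus generator emulates the one property of real articles that
matters for extraction: known accessions embedded in data-availability
prose among realistic confusers (gene symbols, antibody catalogue codes,
DOIs, bare archive names), with title/abstract/PMID markup and supplement
links.  Defaults are the standard testbed: 100 articles, 3–7 accessions
each drawn across every registered family, 60 distractor tokens per
article.  It does not emulate publisher-specific markup chaos, PDFs or
paywalls, so a perfect score here bounds parser behaviour on clean markup
only; the grammar's boundary rule is what carries over to messy text.

The store generator emulates archive structure, not scale: studies of 3–5
paired-end runs (10 where a scenario calls for it), one ~0.2–2 kB payload
file per run with exact declared sizes and MD5s, GEO series and BioProject
links, and local-protocol URLs.  Large-scale scenarios use size-only
entries — declared sizes with no payload — so a 297,527,566,336-byte
(277.1 GiB) manifest can be planned and gated on an ordinary machine
against a simulated 8,160,437,862-byte (7.6 GiB) disk.  It does not model
rate limits, partial-response servers or API quirks; transfer-failure
behaviour is exercised by instrumented backends that inject faults.

All generators are deterministic: same seed and spec, byte-identical
output.  Test and acceptance problem sizes (10–20 files, 50 concurrency
trials, 10 000 oracle tokens, 100 articles) were chosen so the complete
offline suite exercises every stage in a few seconds while keeping each
measurement's sample size meaningful.

## Known limitations

- No live metadata service ships: the live backend surface exists, but
  resolution against real archives requires providing a backend object;
  only retrieval and transfer have live implementations.
- No credential-gated archives (dbGaP/EGA), no mirror selection, no
  decompressed-size prediction, no PDF parsing.
- FASP is interface-only by design.
- `read_info_table` recovers accession cells through the grammar, so a
  hypothetical info.txt containing invalid accession strings would not
  round-trip them; files written by this package always do.
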