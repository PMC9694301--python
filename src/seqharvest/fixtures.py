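"""Deterministic synthetic fixtures: article corpora, metadata trees, file stores.

Everything downstream of the network is testable offline because this module
fabricates the two worlds the pipeline touches:

* **Corpora** — synthetic research articles (HTML) that embed known accession
  numbers inside data-availability prose, surrounded by distractor tokens of
  the kinds that defeat naive matchers: gene symbols, antibody catalogue
  numbers, DOIs, and the bare word "SRA".  The generator returns the exact
  embedded set per article, which is the ground truth for extraction tests.

* **Stores** — metadata trees in the resolver's JSON dialect (study →
  sample → run hierarchy, GEO series and BioProject links, per-file sizes,
  MD5 checksums and protocol URLs) together with an on-disk payload store the
  local-copy transfer backend serves.  Declared sizes and checksums always
  match the physical files; a ``size_only`` mode declares sizes without
  writing payload so disk-space-gate scenarios of hundreds of GiB need no
  real disk.

Identical seed and spec reproduce byte-identical output.  What these
fixtures deliberately do not model: archive API quirks, rate limits, or the
typographic chaos of real full-text HTML beyond ordinary markup.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .grammar import registry

__all__ = [
    "CorpusSpec",
    "ArticleFixture",
    "CorpusResult",
    "StoreSpec",
    "StoreResult",
    "make_corpus",
    "write_corpus",
    "make_store",
    "write_store",
]

# --- article corpus -------------------------------------------------------

_GENE_SYMBOLS = (
    "BRCA1", "TP53", "GAPDH", "ACTB", "MYC", "EGFR", "KRAS", "FOXP3",
    "IL6", "TNF", "STAT3", "SOX2", "PAX6", "RUNX1", "GATA3", "NOTCH1",
    "WNT5A", "SHH", "CDKN2A", "PTEN", "VEGFA", "HIF1A", "NFKB1", "CTNNB1",
)
_CATALOGUE_CODES = (
    "Cat#A1234", "ab45678", "sc-12345", "HPA00123", "MAB0005", "Cat#9987",
    "clone 4G10", "lot 22H11", "Cat#T8787",
)
_DOIS = (
    "doi:10.1038/s41586-020-1234-5", "doi:10.1126/science.abc1234",
    "doi:10.1093/nar/gkaa1100", "doi:10.1016/j.cell.2019.05.031",
)
_PLAIN_WORDS = (
    "sequencing", "libraries", "were", "prepared", "using", "standard",
    "protocols", "and", "aligned", "to", "the", "reference", "genome",
    "with", "default", "parameters", "replicates", "showed", "consistent",
    "expression", "profiles", "across", "conditions", "samples",
)
# Bare archive names must never be extracted: no digit suffix, so the
# grammar's boundary rule rejects them.
_ARCHIVE_WORDS = ("SRA", "GEO", "ENCODE", "DDBJ", "ENA")

_SUPPLEMENT_CATALOG = (
    ("Supplementary Table S1", "TableS1.xlsx", "table"),
    ("Supplementary Table S2", "TableS2.csv", "table"),
    ("Supplementary Data 1", "SupplementaryData1.tsv", "table"),
    ("Supplementary Figure 1", "SupplFig1.pdf", "other"),
    ("Supplementary Movie 1", "movie1.avi", "other"),
    ("Supplementary Methods", "methods.pdf", "other"),
)

_TITLE_TOPICS = (
    "single-cell transcriptomics of the developing cortex",
    "chromatin accessibility during stem-cell differentiation",
    "a map of liver cell populations at single-cell resolution",
    "transcriptional responses to hypoxia in tumour organoids",
    "regulatory variation across human immune cell types",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a synthetic article corpus.

    Defaults produce the standard extraction testbed: 100 articles, about
    five embedded accessions each drawn across every registered family, and
    at least 50 distractor tokens per article.
    """

    seed: int = 0
    n_articles: int = 100
    accessions_per_article: tuple[int, int] = (3, 7)
    distractor_density: int = 60
    supplement_labels: tuple[tuple[str, str, str], ...] = _SUPPLEMENT_CATALOG
    accession_pool: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class ArticleFixture:
    article_id: str  # synthetic PMCID
    title: str
    abstract: str
    pmid: str
    html: str
    accessions: tuple[str, ...]  # embedded, in order of appearance
    supplement_links: tuple[tuple[str, str, str], ...]  # (label, href, kind)


@dataclass(frozen=True)
class CorpusResult:
    spec: CorpusSpec
    articles: tuple[ArticleFixture, ...]

    @property
    def ground_truth(self) -> dict[str, tuple[str, ...]]:
        return {a.article_id: a.accessions for a in self.articles}


def _random_accession(rng: random.Random, cls) -> str:
    """Fabricate one syntactically valid exemplar of an accession family."""
    rule = cls.suffix_rule
    if "alphanumerics" in rule:
        alphabet = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        suffix = "".join(rng.choice(alphabet) for _ in range(6))
    else:
        lo, hi = {
            "1-9 decimal digits": (1, 9),
            "5-9 decimal digits": (5, 9),
            "1-12 decimal digits": (1, 12),
        }[rule]
        n = rng.randint(max(lo, 5), min(hi, 9))  # mid-length, realistic
        suffix = str(rng.randint(1, 9)) + "".join(
            str(rng.randint(0, 9)) for _ in range(n - 1)
        )
    return cls.prefix + suffix


def _distractor(rng: random.Random) -> str:
    bucket = rng.randrange(10)
    if bucket < 5:
        return rng.choice(_PLAIN_WORDS)
    if bucket < 7:
        return rng.choice(_GENE_SYMBOLS)
    if bucket == 7:
        return rng.choice(_CATALOGUE_CODES)
    if bucket == 8:
        return rng.choice(_DOIS)
    return rng.choice(_ARCHIVE_WORDS)


def _article_html(
    article_id: str,
    title: str,
    abstract: str,
    pmid: str,
    paragraphs: list[str],
    supplements: tuple[tuple[str, str, str], ...],
) -> str:
    supp_items = "\n".join(
        f'      <li><a href="supplements/{article_id}/{fname}">{label}</a></li>'
        for label, fname, _kind in supplements
    )
    body = "\n".join(f"    <p>{p}</p>" for p in paragraphs)
    return f"""<!DOCTYPE html>
<html>
<head>
  <title>{title}</title>
  <meta name="citation_pmid" content="{pmid}"/>
</head>
<body>
  <h1>{title}</h1>
  <div class="abstract"><h2>Abstract</h2><p>{abstract}</p></div>
  <div class="body">
{body}
  </div>
  <div class="supplementary-material">
    <h2>Supplementary material</h2>
    <ul>
{supp_items}
    </ul>
  </div>
  <div class="footer">
    <a href="https://pubmed.ncbi.nlm.nih.gov/{pmid}/">PubMed</a>
    <p>PMID: {pmid}</p>
  </div>
</body>
</html>
"""


def make_corpus(spec: CorpusSpec) -> CorpusResult:
    """Generate a deterministic synthetic article corpus with ground truth."""
    rng = random.Random(spec.seed)
    classes = registry()
    used: set[str] = set()
    articles: list[ArticleFixture] = []
    for i in range(spec.n_articles):
        article_id = f"PMC{7000000 + i}"
        pmid = str(30000000 + rng.randint(0, 9999999))
        title = _TITLE_TOPICS[i % len(_TITLE_TOPICS)].capitalize()
        abstract = (
            "We profiled "
            + " ".join(_distractor(rng) for _ in range(12))
            + " using high-throughput sequencing."
        )

        lo, hi = spec.accessions_per_article
        n_acc = rng.randint(lo, hi)
        if spec.accession_pool:
            pool = [a for a in spec.accession_pool if a not in used] or list(
                spec.accession_pool
            )
            embedded = []
            for _ in range(min(n_acc, len(pool))):
                pick = rng.choice(pool)
                pool.remove(pick)
                embedded.append(pick)
        else:
            embedded = []
            while len(embedded) < n_acc:
                acc = _random_accession(rng, rng.choice(classes))
                if acc not in used and acc not in embedded:
                    embedded.append(acc)
        used.update(embedded)

        # Distractor prose split across paragraphs, then a data-availability
        # paragraph that cites each embedded accession exactly once.
        tokens = [_distractor(rng) for _ in range(spec.distractor_density)]
        paragraphs = [
            " ".join(tokens[j : j + 20]) + "." for j in range(0, len(tokens), 20)
        ]
        citations = []
        for acc in embedded:
            style = rng.randrange(3)
            if style == 0:
                citations.append(f"deposited under accession {acc}")
            elif style == 1:
                citations.append(f"available from the archive ({acc})")
            else:
                citations.append(f"raw reads at {acc}")
        paragraphs.append(
            "Data availability: " + "; ".join(citations) + "." if citations
            else "Data availability: no new data were generated."
        )

        n_supp = rng.randint(1, len(spec.supplement_labels))
        supplements = tuple(spec.supplement_labels[:n_supp])

        html = _article_html(article_id, title, abstract, pmid, paragraphs, supplements)
        articles.append(
            ArticleFixture(
                article_id=article_id,
                title=title,
                abstract=abstract,
                pmid=pmid,
                html=html,
                accessions=tuple(embedded),
                supplement_links=supplements,
            )
        )
    return CorpusResult(spec=spec, articles=tuple(articles))


def write_corpus(result: CorpusResult, root: str | Path) -> Path:
    """Write articles (HTML), their supplement payloads and the truth table."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = random.Random(result.spec.seed ^ 0x5A17)
    for art in result.articles:
        (root / f"{art.article_id}.html").write_text(art.html, encoding="utf-8")
        supp_dir = root / "supplements" / art.article_id
        supp_dir.mkdir(parents=True, exist_ok=True)
        for label, fname, _kind in art.supplement_links:
            (supp_dir / fname).write_text(
                f"{label}\nvalue\t{rng.randint(0, 10**6)}\n", encoding="utf-8"
            )
    lines = ["article_id\tpmid\ttitle\taccessions"]
    for art in result.articles:
        lines.append(
            "\t".join(
                [art.article_id, art.pmid, art.title, ";".join(art.accessions)]
            )
        )
    (root / "ground_truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return root


# --- metadata tree + file store -------------------------------------------


@dataclass(frozen=True)
class StoreSpec:
    """Shape of a synthetic metadata tree and its payload store.

    Defaults describe a small desk-scale archive: one study of a handful of
    paired-end RNA-seq runs, each with one gzipped FASTQ of a few hundred
    bytes of payload, with a linked GEO series and BioProject.  ``size_only``
    declares sizes without payload (for space-gate scenarios);
    ``declared_total`` then forces the sizes to sum to an exact byte count.
    """

    seed: int = 0
    n_studies: int = 1
    runs_per_study: tuple[int, int] = (3, 5)
    files_per_run: int = 1
    file_formats: tuple[str, ...] = ("fastq",)
    size_range: tuple[int, int] = (200, 2000)
    protocols: tuple[str, ...] = ("local",)
    with_projects: bool = True
    with_geo_series: bool = True
    with_samples: bool = True
    processed_per_series: int = 1
    size_only: bool = False
    declared_total: Optional[int] = None


@dataclass(frozen=True)
class StoreResult:
    spec: StoreSpec
    tree: dict
    root: Optional[Path]  # payload directory, None in size_only mode
    run_files: dict[str, tuple[str, ...]] = field(default_factory=dict)
    project_map: dict[str, str] = field(default_factory=dict)
    series_map: dict[str, str] = field(default_factory=dict)  # GSE -> study

    @property
    def declared_bytes(self) -> int:
        return sum(
            f["size_bytes"]
            for node in self.tree["nodes"].values()
            for f in node.get("files", [])
        )


_ORGANISMS = ("Homo sapiens", "Mus musculus", "Danio rerio")
_STRATEGIES = ("RNA-Seq", "ATAC-Seq", "WGS", "ChIP-Seq")
_INSTRUMENTS = ("Illumina NovaSeq 6000", "Illumina HiSeq 2500", "NextSeq 500")
_EXT_BY_FORMAT = {"fastq": "fastq.gz", "bam": "bam", "vcf": "vcf.gz", "fasta": "fa.gz"}


def _payload(rng: random.Random, size: int) -> bytes:
    return rng.randbytes(size)


def make_store(spec: StoreSpec, root: str | Path | None = None) -> StoreResult:
    """Generate a metadata tree (and payload store unless ``size_only``).

    The tree conforms to the resolver's schema: studies contain samples which
    contain runs; every run's declared size and MD5 match the physical file;
    each study gets a BioProject link and, optionally, a GEO series whose
    children are the study's samples.  URLs advertise the requested
    protocols, pointing local/http/ftp addresses at the payload store.
    """
    if not spec.size_only and root is None:
        raise ValueError("a payload root is required unless size_only=True")
    rng = random.Random(spec.seed)
    store_root = None
    if not spec.size_only:
        store_root = Path(root) / "store"
        store_root.mkdir(parents=True, exist_ok=True)

    nodes: dict[str, dict] = {}
    project_map: dict[str, str] = {}
    series_map: dict[str, str] = {}
    run_files: dict[str, tuple[str, ...]] = {}

    # Pre-draw file sizes so declared_total can be hit exactly.
    n_runs_per_study = [
        rng.randint(*spec.runs_per_study) for _ in range(spec.n_studies)
    ]
    total_files = sum(n_runs_per_study) * spec.files_per_run
    sizes = [rng.randint(*spec.size_range) for _ in range(total_files)]
    if spec.declared_total is not None:
        scale = spec.declared_total / sum(sizes)
        sizes = [max(1, int(s * scale)) for s in sizes]
        sizes[-1] += spec.declared_total - sum(sizes)

    size_iter = iter(sizes)
    study_base = 200000 + rng.randint(0, 99999)
    run_base = 10000000 + rng.randint(0, 999999)
    sample_base = 5000000 + rng.randint(0, 999999)
    series_base = 100000 + rng.randint(0, 99999)
    project_base = 400000 + rng.randint(0, 99999)
    gsm_base = 3000000 + rng.randint(0, 999999)

    run_no = 0
    for s_idx in range(spec.n_studies):
        study = f"SRP{study_base + s_idx}"
        organism = rng.choice(_ORGANISMS)
        strategy = rng.choice(_STRATEGIES)
        instrument = rng.choice(_INSTRUMENTS)
        study_children: list[str] = []
        sample_ids: list[str] = []
        for r_idx in range(n_runs_per_study[s_idx]):
            run = f"SRR{run_base + run_no}"
            sample = f"SRS{sample_base + run_no}"
            gsm = f"GSM{gsm_base + run_no}"
            run_no += 1
            files = []
            fnames = []
            for f_idx in range(spec.files_per_run):
                fmt = spec.file_formats[f_idx % len(spec.file_formats)]
                ext = _EXT_BY_FORMAT[fmt]
                suffix = f"_{f_idx + 1}" if spec.files_per_run > 1 else ""
                fname = f"{run}{suffix}.{ext}"
                size = next(size_iter)
                checksum = None
                if store_root is not None:
                    data = _payload(rng, size)
                    fpath = store_root / run / fname
                    fpath.parent.mkdir(parents=True, exist_ok=True)
                    fpath.write_bytes(data)
                    checksum = hashlib.md5(data).hexdigest()
                urls = []
                rel = f"store/{run}/{fname}"
                for proto in spec.protocols:
                    if proto == "local":
                        urls.append(["local", rel])
                    elif proto == "http":
                        urls.append(["http", f"https://store.example.org/{rel}"])
                    elif proto == "ftp":
                        urls.append(["ftp", f"ftp://store.example.org/{rel}"])
                    elif proto == "fasp":
                        urls.append(["fasp", f"fasp://store.example.org/{rel}"])
                files.append(
                    {
                        "filename": fname,
                        "size_bytes": size,
                        "md5": checksum,
                        "urls": urls,
                    }
                )
                fnames.append(fname)
            run_files[run] = tuple(fnames)
            nodes[run] = {
                "level": "run",
                "attributes": {
                    "organism": organism,
                    "library_strategy": strategy,
                    "layout": rng.choice(("PAIRED", "SINGLE")),
                    "instrument": instrument,
                    "description": f"{strategy} run {run} of sample {sample}",
                },
                "files": files,
            }
            if spec.with_samples:
                nodes[sample] = {
                    "level": "sample",
                    "attributes": {"organism": organism},
                    "children": [run],
                }
                study_children.append(sample)
                sample_ids.append(sample)
                if spec.with_geo_series:
                    nodes[gsm] = {
                        "level": "sample",
                        "attributes": {"organism": organism},
                        "children": [run],
                    }
            else:
                study_children.append(run)
        nodes[study] = {
            "level": "study",
            "attributes": {
                "organism": organism,
                "library_strategy": strategy,
                "description": f"Synthetic study {study}",
            },
            "children": study_children,
        }
        if spec.with_projects:
            project = f"PRJNA{project_base + s_idx}"
            project_map[project] = study
        if spec.with_geo_series:
            series = f"GSE{series_base + s_idx}"
            gsm_children = [
                g for g in nodes if g.startswith("GSM") and g not in series_map
            ]
            # children of this series: the GSMs created for this study's runs
            gsm_children = gsm_children[-n_runs_per_study[s_idx]:]
            series_node: dict = {
                "level": "study",
                "attributes": {
                    "organism": organism,
                    "library_strategy": strategy,
                    "description": f"GEO series for {study}",
                },
                "children": gsm_children if spec.with_samples else study_children,
            }
            if spec.processed_per_series and store_root is not None:
                pfiles = []
                for p_idx in range(spec.processed_per_series):
                    pname = f"{series}_processed_{p_idx + 1}.txt"
                    data = (
                        f"gene\tcount\n" + "\n".join(
                            f"G{k}\t{rng.randint(0, 999)}" for k in range(10)
                        )
                    ).encode()
                    ppath = store_root / series / pname
                    ppath.parent.mkdir(parents=True, exist_ok=True)
                    ppath.write_bytes(data)
                    pfiles.append(
                        {
                            "filename": pname,
                            "size_bytes": len(data),
                            "md5": hashlib.md5(data).hexdigest(),
                            "urls": [["local", f"store/{series}/{pname}"]],
                        }
                    )
                series_node["processed_files"] = pfiles
            nodes[series] = series_node
            series_map[series] = study

    tree = {
        "schema_version": 1,
        "nodes": nodes,
        "project_links": project_map,
    }
    return StoreResult(
        spec=spec,
        tree=tree,
        root=Path(root) if root is not None else None,
        run_files=run_files,
        project_map=project_map,
        series_map=series_map,
    )


def write_store(result: StoreResult, root: str | Path | None = None) -> Path:
    """Write the metadata tree JSON next to the payload store."""
    base = Path(root) if root is not None else result.root
    if base is None:
        raise ValueError("no directory to write the metadata tree into")
    base.mkdir(parents=True, exist_ok=True)
    path = base / "metadata.json"
    path.write_text(json.dumps(result.tree, indent=1), encoding="utf-8")
    return path
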