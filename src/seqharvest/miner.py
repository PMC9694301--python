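"""Article mining: load documents, summarize them, and harvest links.

Data-availability statements in research articles are the usual place where
sequencing accessions are published, so the acquisition pipeline starts from
article identifiers (PMCIDs), article URLs, or local files.  This module
renders a document to plain text, extracts its bibliographic fields, mines
the text for accession numbers through :mod:`seqharvest.grammar`, and
collects hyperlinked assets so supplementary data tables can be downloaded.

Document retrieval is an injected interface.  Two retrievers ship:

* :class:`FixtureRetriever` serves documents from a local directory and is
  what every test uses — the pipeline is fully exercisable offline.
* :class:`HttpRetriever` fetches over HTTP(S) with a polite delay, a
  descriptive user agent and bounded retries, resolving a PMCID through a
  configurable URL template.

Text rendering strips ``<script>``/``<style>``, collapses whitespace and
preserves reading order.  Reference lists are kept in the mined text on
purpose: accessions are frequently cited in data-availability sections
adjacent to the references, and downstream deduplication absorbs repeats.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol
from urllib.parse import urljoin

import lxml.etree
import lxml.html

from .grammar import AccessionID, extract_accessions

__all__ = [
    "ArticleDocument",
    "ArticleSummary",
    "SupplementaryAsset",
    "ArticleLoadError",
    "DocumentRetriever",
    "FixtureRetriever",
    "HttpRetriever",
    "load_document",
    "summarize_article",
    "extract_supplementary_links",
    "write_info_table",
    "read_info_table",
]

log = logging.getLogger(__name__)

#: Column order of info.txt; the accession cell joins IDs with ";".
INFO_COLUMNS = ("PubMed URL", "Title", "Abstract", "Accessions", "PMID")

#: File extensions treated as data tables when classifying supplementary assets.
TABLE_EXTENSIONS = frozenset({"xls", "xlsx", "csv", "tsv", "txt", "ods"})

_TABLE_LABEL_RE = re.compile(r"table", re.IGNORECASE)

#: Template mapping a PMCID to its full-text address (PMC article path pattern).
DEFAULT_PMC_URL_TEMPLATE = "https://www.ncbi.nlm.nih.gov/pmc/articles/{pmcid}/"


class ArticleLoadError(RuntimeError):
    """A document could not be retrieved or was not usable full text."""

    def __init__(self, source: str, reason: str):
        super().__init__(f"failed to load article {source!r}: {reason}")
        self.source = source
        self.reason = reason


@dataclass
class ArticleDocument:
    """A loaded article: plain-text body plus whatever metadata the markup had."""

    source_id: str
    body_text: str
    title: Optional[str] = None
    abstract: Optional[str] = None
    pmid: Optional[str] = None
    pubmed_url: Optional[str] = None
    asset_links: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ArticleSummary:
    """One row of info.txt; missing fields hold the literal string "NA"."""

    pubmed_url: str
    title: str
    abstract: str
    accessions: list[AccessionID]
    pmid: str


@dataclass(frozen=True)
class SupplementaryAsset:
    """A hyperlinked supplementary item, classified as data table or other."""

    article_id: str
    label: str
    address: str
    kind: str  # "table" | "other"


class DocumentRetriever(Protocol):
    """Resolves a PMCID / URL / path to raw document content plus a base URL."""

    def fetch(self, source: str) -> tuple[str, str]:
        """Return ``(content, base_url)`` or raise :class:`ArticleLoadError`."""
        ...


class FixtureRetriever:
    """Serve article documents from a local directory.

    A PMCID or URL is looked up first through the optional ``aliases``
    mapping, then as ``<root>/<source>.html`` / ``.xml`` / ``.txt``, then as a
    literal path.  The returned base URL is the document's own ``file://``
    address so relative supplementary links resolve to absolute local
    addresses the download backends understand.
    """

    def __init__(self, root: str | Path, aliases: Optional[dict[str, str]] = None):
        self.root = Path(root)
        self.aliases = dict(aliases or {})

    def _candidate_paths(self, source: str):
        if source in self.aliases:
            yield self.root / self.aliases[source]
        safe = re.sub(r"[^A-Za-z0-9._-]+", "_", source).strip("_")
        for ext in ("", ".html", ".xml", ".txt"):
            yield self.root / f"{safe}{ext}"
        yield Path(source)

    def fetch(self, source: str) -> tuple[str, str]:
        for path in self._candidate_paths(source):
            if path.is_file():
                return path.read_text(encoding="utf-8"), path.resolve().as_uri()
        raise ArticleLoadError(source, f"no fixture document under {self.root}")


class HttpRetriever:
    """Fetch full-text documents over HTTP(S) with retries and a polite delay."""

    def __init__(
        self,
        pmc_url_template: str = DEFAULT_PMC_URL_TEMPLATE,
        delay_seconds: float = 1.0,
        retries: int = 3,
        user_agent: str = "seqharvest/0.1 (sequence-data acquisition)",
    ):
        self.pmc_url_template = pmc_url_template
        self.delay_seconds = delay_seconds
        self.retries = retries
        self.user_agent = user_agent
        self._last_request = 0.0

    def _url_for(self, source: str) -> str:
        if re.fullmatch(r"PMC\d+", source, re.IGNORECASE):
            return self.pmc_url_template.format(pmcid=source.upper())
        return source

    def fetch(self, source: str) -> tuple[str, str]:
        url = self._url_for(source)
        last_err: Exception | None = None
        for attempt in range(self.retries + 1):
            wait = self.delay_seconds - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                req = urllib.request.Request(url, headers={"User-Agent": self.user_agent})
                with urllib.request.urlopen(req) as resp:
                    charset = resp.headers.get_content_charset() or "utf-8"
                    return resp.read().decode(charset, errors="replace"), resp.geturl()
            except (urllib.error.URLError, OSError) as err:
                last_err = err
                log.warning("fetch %s failed (attempt %d): %s", url, attempt + 1, err)
        raise ArticleLoadError(source, str(last_err))


def _looks_like_markup(content: str) -> bool:
    head = content.lstrip()[:200].lower()
    return head.startswith("<") and (
        "<html" in head or "<!doctype" in head or "<article" in head or "<?xml" in head
    )


def _text_of(el) -> str:
    return re.sub(r"\s+", " ", " ".join(el.itertext())).strip()


def _parse_markup(content: str, base_url: str, source: str) -> ArticleDocument:
    try:
        tree = lxml.html.fromstring(content)
    except lxml.etree.ParserError as err:
        raise ArticleLoadError(source, f"unparseable markup: {err}")

    for bad in tree.iter("script", "style"):
        parent = bad.getparent()
        if parent is not None:
            parent.remove(bad)

    title = None
    for xp in ("//h1", "//title", "//*[local-name()='article-title']"):
        nodes = tree.xpath(xp)
        if nodes and _text_of(nodes[0]):
            title = _text_of(nodes[0])
            break

    abstract = None
    nodes = tree.xpath(
        "//*[local-name()='abstract']"
        " | //*[contains(concat(' ', normalize-space(@class), ' '), ' abstract ')]"
        " | //*[@id='abstract']"
    )
    if nodes:
        abstract = _text_of(nodes[0])
        # Drop a leading "Abstract" heading if the markup nested one.
        abstract = re.sub(r"^abstract\s*:?\s*", "", abstract, flags=re.IGNORECASE)

    pmid = None
    metas = tree.xpath("//meta[@name='citation_pmid']/@content")
    if metas:
        pmid = metas[0].strip()
    else:
        m = re.search(r"\bPMID:?\s*(\d{1,10})\b", content)
        if m:
            pmid = m.group(1)

    pubmed_url = None
    links = tree.xpath("//a[@href]")
    for a in links:
        href = a.get("href", "")
        if "pubmed" in href.lower():
            pubmed_url = urljoin(base_url, href)
            break
    if pubmed_url is None and pmid:
        pubmed_url = f"https://pubmed.ncbi.nlm.nih.gov/{pmid}/"

    assets: list[tuple[str, str]] = []
    for a in links:
        href = a.get("href", "").strip()
        if not href or href.startswith(("#", "mailto:", "javascript:")):
            continue
        label = _text_of(a) or href.rsplit("/", 1)[-1]
        assets.append((label, urljoin(base_url, href)))

    body_text = _text_of(tree)
    if not body_text:
        raise ArticleLoadError(source, "document rendered to empty text")
    return ArticleDocument(
        source_id=source,
        body_text=body_text,
        title=title,
        abstract=abstract,
        pmid=pmid,
        pubmed_url=pubmed_url,
        asset_links=assets,
    )


def load_document(source: str, retriever: DocumentRetriever) -> ArticleDocument:
    """Load and parse one article document.

    HTML/XML content is rendered to plain text with title, abstract, PMID and
    hyperlink assets pulled from the markup; anything else is treated as a
    plain-text article whose body is the file content verbatim.  Retrieval or
    parse failures raise :class:`ArticleLoadError` naming the source; callers
    processing several sources catch it and continue.
    """
    if not source:
        raise ArticleLoadError(source, "empty source identifier")
    content, base_url = retriever.fetch(source)
    if _looks_like_markup(content):
        return _parse_markup(content, base_url, source)
    if not content.strip():
        raise ArticleLoadError(source, "document rendered to empty text")
    return ArticleDocument(source_id=source, body_text=content)


_WS_RE = re.compile(r"[\t\r\n]+")


def _cell(value: Optional[str]) -> str:
    """Serialize a field for the tab-delimited summary; missing -> "NA"."""
    if value is None or value == "":
        return "NA"
    return _WS_RE.sub(" ", value)


def summarize_article(doc: ArticleDocument) -> ArticleSummary:
    """Build the info.txt row for a document; accessions are mined from its body."""
    return ArticleSummary(
        pubmed_url=_cell(doc.pubmed_url),
        title=_cell(doc.title),
        abstract=_cell(doc.abstract),
        accessions=extract_accessions(doc.body_text),
        pmid=_cell(doc.pmid),
    )


def classify_asset_kind(label: str, address: str) -> str:
    """"table" when the filename extension or the link label says data table."""
    filename = address.rsplit("/", 1)[-1].split("?", 1)[0]
    ext = filename.rsplit(".", 1)[-1].lower() if "." in filename else ""
    if ext in TABLE_EXTENSIONS or _TABLE_LABEL_RE.search(label):
        return "table"
    return "other"


def extract_supplementary_links(doc: ArticleDocument) -> list[SupplementaryAsset]:
    """Deduplicated supplementary assets of a document, classified table/other."""
    seen: set[str] = set()
    out: list[SupplementaryAsset] = []
    for label, address in doc.asset_links:
        if address in seen:
            continue
        seen.add(address)
        out.append(
            SupplementaryAsset(
                article_id=doc.source_id,
                label=label,
                address=address,
                kind=classify_asset_kind(label, address),
            )
        )
    return out


def write_info_table(summaries: list[ArticleSummary], path: str | Path) -> Path:
    """Write the article summary table (``info.txt``).

    Tab-delimited, one row per article, header row with the five fields in
    fixed order; the accession cell joins IDs with ";" preserving extraction
    order.  The file is written atomically: nothing is left behind on error.
    """
    path = Path(path)
    lines = ["\t".join(INFO_COLUMNS)]
    for s in summaries:
        acc = ";".join(a.text for a in s.accessions)
        lines.append("\t".join([s.pubmed_url, s.title, s.abstract, acc, s.pmid]))
    payload = "\n".join(lines) + "\n"
    tmp = path.with_name(path.name + ".tmp")
    try:
        tmp.write_text(payload, encoding="utf-8")
        tmp.replace(path)
    except OSError:
        tmp.unlink(missing_ok=True)
        raise
    return path


def read_info_table(path: str | Path) -> list[ArticleSummary]:
    """Parse an info.txt back into summaries (inverse of :func:`write_info_table`)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != INFO_COLUMNS:
        raise ValueError(f"{path} is not an info.txt summary table")
    out = []
    for line in lines[1:]:
        url, title, abstract, acc_cell, pmid = line.split("\t")
        accs = extract_accessions(acc_cell.replace(";", " "))
        out.append(ArticleSummary(url, title, abstract, accs, pmid))
    return out
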