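"""Accession-identifier grammar: classification, validation and free-text extraction.

Public sequence archives assign stable accession numbers at several levels of
a shared hierarchy: BioProjects (PRJNA), INSDC studies/experiments/samples/runs
(SRP/SRX/SRS/SRR and the ENA/DDBJ mirrors ERP.../DRP...), SRA submissions
(SRA), GEO series and samples (GSE/GSM), BioSamples (SAMN) and ENCODE portal
records (ENCSR/ENCSB/ENCSD).  Articles cite these identifiers in free prose,
so the grammar here has to do two jobs: decide whether an isolated token is a
well-formed accession of a known family, and pull every such token out of
arbitrary running text without picking up gene symbols, catalogue numbers or
the bare word "SRA".

The registry of families is data, not code: ``data/accession_registry.json``
ships with the package and records, per family, the literal prefix, the
allowed suffix shape, and where the family sits in the
project/study/experiment/sample/run hierarchy.  Matching is case-insensitive;
canonical form is uppercase.  A token matches only when it is flanked by
non-alphanumeric context (so ``xGSE12`` and ``GSE126379a`` never match), and
the longest registered prefix wins when prefixes could compete.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "AccessionClass",
    "AccessionID",
    "registry",
    "classify",
    "validate",
    "extract_accessions",
]


@dataclass(frozen=True)
class AccessionClass:
    """One accession family: prefix, suffix shape and hierarchy level."""

    name: str
    prefix: str
    suffix_regex: str
    suffix_rule: str
    hierarchy_level: str
    extension: bool = False
    _pattern: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pat = re.compile(
            re.escape(self.prefix) + "(?:" + self.suffix_regex + ")",
            re.IGNORECASE,
        )
        object.__setattr__(self, "_pattern", pat)

    def matches(self, token: str) -> bool:
        """Whole-token match, case-insensitive."""
        return bool(self._pattern.fullmatch(token))


@dataclass(frozen=True)
class AccessionID:
    """A validated accession in canonical (uppercase) form."""

    text: str
    accession_class: AccessionClass

    def __post_init__(self) -> None:
        canonical = self.text.upper()
        if not self.accession_class.matches(canonical):
            raise ValueError(
                f"{self.text!r} is not a valid {self.accession_class.name} accession"
            )
        object.__setattr__(self, "text", canonical)

    @property
    def hierarchy_level(self) -> str:
        return self.accession_class.hierarchy_level

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def _load_registry() -> tuple[AccessionClass, ...]:
    raw = resources.files("seqharvest.data").joinpath("accession_registry.json")
    data = json.loads(raw.read_text(encoding="utf-8"))
    classes = tuple(
        AccessionClass(
            name=c["name"],
            prefix=c["prefix"],
            suffix_regex=c["suffix_regex"],
            suffix_rule=c["suffix_rule"],
            hierarchy_level=c["level"],
            extension=c["extension"],
        )
        for c in data["classes"]
    )
    prefixes = [c.prefix for c in classes]
    if len(set(prefixes)) != len(prefixes):
        raise RuntimeError("accession registry contains duplicate prefixes")
    for p in prefixes:
        for q in prefixes:
            if p != q and q.startswith(p):
                raise RuntimeError(f"registry prefix {p!r} is a prefix of {q!r}")
    return classes


_REGISTRY: tuple[AccessionClass, ...] = _load_registry()

# Longest prefix first so e.g. PRJNA/ENCSR families are tried before
# shorter prefixes; deterministic tie-break on the prefix itself.
_BY_PREFIX_LENGTH: tuple[AccessionClass, ...] = tuple(
    sorted(_REGISTRY, key=lambda c: (-len(c.prefix), c.prefix))
)

# One scanner for extraction: any family, flanked by non-alphanumerics.
_EXTRACT_RE = re.compile(
    r"(?<![A-Za-z0-9])(?:"
    + "|".join(
        re.escape(c.prefix) + "(?:" + c.suffix_regex + ")" for c in _BY_PREFIX_LENGTH
    )
    + r")(?![A-Za-z0-9])",
    re.IGNORECASE,
)


def registry() -> list[AccessionClass]:
    """Return the full fixed set of supported accession families.

    The list includes every documented prefix family once (ERP appears a
    single time) plus families flagged ``extension=True`` that were added for
    archive-family symmetry (ERR, the ENA run family).
    """
    return list(_REGISTRY)


def classify(token: str) -> Optional[AccessionClass]:
    """Return the accession family a whole token belongs to, or ``None``.

    Matching is case-insensitive and requires the entire token to be a valid
    accession; unknown or malformed tokens yield ``None``, never an exception.
    """
    if not token:
        return None
    for cls in _BY_PREFIX_LENGTH:
        if cls.matches(token):
            return cls
    return None


def validate(token: str) -> bool:
    """True iff ``token`` is a well-formed accession of a registered family."""
    return classify(token) is not None


def extract_accessions(text: str) -> list[AccessionID]:
    """Extract every accession cited in free text, in first-occurrence order.

    A match must be maximal: it may not be immediately preceded or followed by
    an alphanumeric character, so substrings of longer identifiers (DOIs,
    catalogue codes, gene names with numeric suffixes) are never reported.
    Duplicates are removed keeping the first occurrence; output is canonical
    uppercase.
    """
    seen: set[str] = set()
    out: list[AccessionID] = []
    for m in _EXTRACT_RE.finditer(text):
        token = m.group(0).upper()
        if token in seen:
            continue
        cls = classify(token)
        if cls is None:  # pragma: no cover - scanner and classify share patterns
            continue
        seen.add(token)
        out.append(AccessionID(token, cls))
    return out
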