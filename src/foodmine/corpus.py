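"""Bibliographic corpus access.

A corpus is an ordered collection of :class:`BibEntry` records retrieved for a
single food search term. Two readers produce the same type: the JSON-lines
fixture dialect (one entry object per line, the default for offline work) and
PubMed efetch XML. Live retrieval through the Entrez E-utilities is available
behind an explicit ``source="pubmed"`` flag and is never touched by the test
suite or default builds.
"""

from __future__ import annotations

import json
import re
import time
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "BibEntry",
    "Corpus",
    "ParseError",
    "parse_entry",
    "parse_pubmed_xml",
    "read_jsonl",
    "write_jsonl",
    "search",
]

_WS = re.compile(r"\s+")


class ParseError(ValueError):
    """A bibliographic record could not be parsed; names the offending record."""


def _norm_text(text: str | None) -> str:
    """Collapse internal whitespace and trim. Unicode is preserved."""
    if not text:
        return ""
    return _WS.sub(" ", text).strip()


def _dedup(terms: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for t in terms:
        t = _norm_text(t)
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return out


@dataclass
class BibEntry:
    """One bibliographic record (PMID-like accession, title, abstract, MeSH).

    ``mesh_terms`` are deduplicated with case preserved; a missing abstract is
    the empty string, never an error. ``has_full_text_link`` mirrors whether
    the source listed any full-text link; such entries are kept in the corpus
    and excluded only downstream, at the retrieval-funnel stage.
    """

    entry_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    has_full_text_link: bool = False
    year: int | None = None
    food_query: str = ""

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ParseError("bibliographic record is missing an entry_id")
        self.entry_id = str(self.entry_id)
        self.title = _norm_text(self.title)
        self.abstract = _norm_text(self.abstract)
        self.mesh_terms = _dedup(self.mesh_terms)

    def to_dict(self) -> dict:
        d = {
            "entry_id": self.entry_id,
            "title": self.title,
            "abstract": self.abstract,
            "mesh_terms": list(self.mesh_terms),
            "has_full_text_link": self.has_full_text_link,
            "food_query": self.food_query,
        }
        if self.year is not None:
            d["year"] = self.year
        return d


@dataclass
class Corpus:
    query: str
    entries: list[BibEntry] = field(default_factory=list)
    retrieved_at: str = "fixture"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[BibEntry]:
        return iter(self.entries)


def parse_entry(raw: str | dict, lineno: int | None = None) -> BibEntry:
    """Parse one fixture-dialect record (a JSON object or its text) to a BibEntry."""
    where = f" at line {lineno}" if lineno is not None else ""
    if isinstance(raw, str):
        try:
            raw = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON record{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"record{where} is not an object")
    if not raw.get("entry_id"):
        raise ParseError(f"record{where} is missing entry_id")
    return BibEntry(
        entry_id=raw["entry_id"],
        title=raw.get("title", ""),
        abstract=raw.get("abstract", ""),
        mesh_terms=raw.get("mesh_terms", []),
        has_full_text_link=bool(raw.get("has_full_text_link", False)),
        year=raw.get("year"),
        food_query=raw.get("food_query", ""),
    )


def parse_pubmed_xml(text: str, food_query: str = "") -> list[BibEntry]:
    """Parse a PubMed efetch XML document into BibEntry records."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed PubMed XML: {exc}") from exc
    entries = []
    for art in root.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid:
            raise ParseError("PubmedArticle without a PMID")
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (node.text or "") for node in art.findall(".//AbstractText")
        )
        mesh = [
            node.text or ""
            for node in art.findall(".//MeshHeading/DescriptorName")
        ]
        year_text = art.findtext(".//PubDate/Year")
        entries.append(
            BibEntry(
                entry_id=pmid,
                title=title,
                abstract=abstract,
                mesh_terms=mesh,
                year=int(year_text) if year_text else None,
                food_query=food_query,
            )
        )
    return entries


def read_jsonl(path: str | Path, query: str = "") -> Corpus:
    """Read a JSON-lines fixture into a Corpus, deterministically."""
    path = Path(path)
    entries = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            entries.append(parse_entry(line, lineno=lineno))
    return Corpus(query=query or (entries[0].food_query if entries else ""), entries=entries)


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus, one entry per line, with stable key order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for entry in corpus.entries:
            fh.write(json.dumps(entry.to_dict(), sort_keys=True, ensure_ascii=False))
            fh.write("\n")


def search(query: str, source: str, *, retmax: int = 100_000,
           email: str | None = None, api_key: str | None = None) -> Corpus:
    """Retrieve all entries matching ``query`` from ``source``.

    ``source`` is either ``"fixture:<path>"`` (a JSON-lines file, read
    deterministically) or ``"pubmed"`` (live Entrez E-utilities; pages through
    results at <=3 requests/s without an API key, with exponential backoff).
    """
    if not query:
        raise ValueError("query must be non-empty")
    if source.startswith("fixture:"):
        return read_jsonl(source[len("fixture:"):], query=query)
    if source == "pubmed":
        return _search_pubmed(query, retmax=retmax, email=email, api_key=api_key)
    raise ValueError(f"unknown corpus source {source!r}; use 'pubmed' or 'fixture:PATH'")


def _search_pubmed(query: str, retmax: int, email: str | None,
                   api_key: str | None) -> Corpus:  # pragma: no cover - network
    from Bio import Entrez  # lazy: live mode only

    Entrez.email = email or "foodmine@example.org"
    if api_key:
        Entrez.api_key = api_key
    with Entrez.esearch(db="pubmed", term=query, retmax=retmax) as handle:
        result = Entrez.read(handle)
    ids = list(result["IdList"])
    entries: list[BibEntry] = []
    delay = 1.0 / 3  # NCBI courtesy limit without a key
    for start in range(0, len(ids), 200):
        chunk = ids[start:start + 200]
        for attempt in range(5):
            try:
                with Entrez.efetch(db="pubmed", id=",".join(chunk),
                                   rettype="xml", retmode="text") as handle:
                    entries.extend(parse_pubmed_xml(handle.read(), food_query=query))
                break
            except OSError:
                if attempt == 4:
                    raise
                time.sleep(delay * 2 ** attempt)
        time.sleep(delay)
    return Corpus(query=query, entries=entries,
                  retrieved_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()))
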