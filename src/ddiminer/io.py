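"""Readers and writers for three MEDLINE record dialects.

Supported dialects:

* **PubMed XML** — ``<PubmedArticleSet>`` documents as exported by PubMed;
  substances come from ``ChemicalList/Chemical/NameOfSubstance`` and MeSH
  headings from ``MeshHeadingList`` with major-topic flags preserved.
* **nbib** — the tagged plain-text MEDLINE export (4-character tag, ``- ``,
  value; continuation lines indented).  ``MH`` lines split descriptor from
  qualifiers on ``/`` with a leading ``*`` marking the major topic; substance
  names are taken from ``RN`` registry-number lines by stripping the registry
  token and the enclosing parentheses.
* **jsonl** — one JSON object per line with keys ``pmid``, ``title``,
  ``abstract``, ``mesh_headings``, ``substances``; the fixture interchange
  format of this package (schema in the README).

Every reader keeps the contract: records out + reported record-level errors
= article blocks in the input.  Pass an ``errors`` list to collect
:class:`ParseIssue` entries and keep going; with ``errors=None`` a
record-level problem raises.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass
from typing import IO, Iterable

from lxml import etree

from .records import DuplicatePmidError, MedlineRecord, MeshHeading

__all__ = [
    "ParseError",
    "ParseIssue",
    "read_pubmed_xml",
    "write_pubmed_xml",
    "read_nbib",
    "write_nbib",
    "read_jsonl",
    "write_jsonl",
    "DIALECTS",
]


class ParseError(ValueError):
    """Input is structurally unusable (malformed XML, stray continuation)."""


@dataclass(frozen=True)
class ParseIssue:
    """A record-level problem that did not abort parsing."""

    location: str  # e.g. "article 3" or "line 17"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.location}: {self.message}"


def _report(errors: list[ParseIssue] | None, issue: ParseIssue) -> None:
    if errors is None:
        raise ParseError(str(issue))
    errors.append(issue)


# ---------------------------------------------------------------------------
# PubMed XML


def read_pubmed_xml(
    stream: IO[bytes] | bytes, errors: list[ParseIssue] | None = None
) -> list[MedlineRecord]:
    """Parse a PubMed XML article set into records."""
    data = stream if isinstance(stream, bytes) else stream.read()
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(
            f"malformed XML at line {exc.lineno}, column {exc.position[1]}: "
            f"{exc.msg}"
        ) from exc

    records: list[MedlineRecord] = []
    for i, art in enumerate(root.iter("PubmedArticle"), start=1):
        pmid = art.findtext(".//MedlineCitation/PMID") or art.findtext(".//PMID")
        if not pmid or not pmid.strip():
            _report(errors, ParseIssue(f"article {i}", "article without PMID"))
            continue
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            t.strip()
            for t in (
                el.text or "" for el in art.iterfind(".//Abstract/AbstractText")
            )
            if t.strip()
        )
        headings = []
        for mh in art.iterfind(".//MeshHeadingList/MeshHeading"):
            desc_el = mh.find("DescriptorName")
            if desc_el is None or not (desc_el.text or "").strip():
                continue
            quals = [
                q.text.strip()
                for q in mh.iterfind("QualifierName")
                if (q.text or "").strip()
            ]
            is_major = desc_el.get("MajorTopicYN", "N") == "Y" or any(
                q.get("MajorTopicYN", "N") == "Y"
                for q in mh.iterfind("QualifierName")
            )
            headings.append(
                MeshHeading(desc_el.text.strip(), tuple(quals), is_major)
            )
        substances = [
            el.text.strip()
            for el in art.iterfind(".//ChemicalList/Chemical/NameOfSubstance")
            if (el.text or "").strip()
        ]
        records.append(
            MedlineRecord(
                pmid=pmid.strip(),
                title=title,
                abstract=abstract,
                mesh_headings=headings,
                substances=substances,
            )
        )
    return records


def write_pubmed_xml(stream: IO[bytes], records: Iterable[MedlineRecord]) -> None:
    """Serialize records as a PubMed XML article set."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        if rec.substances:
            chems = etree.SubElement(cit, "ChemicalList")
            for name in rec.substances:
                chem = etree.SubElement(chems, "Chemical")
                etree.SubElement(chem, "RegistryNumber").text = "0"
                etree.SubElement(chem, "NameOfSubstance").text = name
        if rec.mesh_headings:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for h in rec.mesh_headings:
                mh = etree.SubElement(mhl, "MeshHeading")
                d = etree.SubElement(mh, "DescriptorName")
                d.text = h.descriptor
                d.set("MajorTopicYN", "Y" if h.is_major else "N")
                for q in h.qualifiers:
                    qel = etree.SubElement(mh, "QualifierName")
                    qel.text = q
                    qel.set("MajorTopicYN", "N")
    stream.write(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# nbib tagged text


def _substance_from_rn(value: str) -> str:
    """Strip the registry token from an RN value, keeping the name.

    ``"0 (Aspirin)"`` -> ``"Aspirin"``; ``"EC 1.14.14.1 (Cytochrome P-450
    CYP2C9)"`` -> ``"Cytochrome P-450 CYP2C9"``.  A value without a
    parenthesized name is returned as-is (it is then just a registry number
    with no substance name and gets dropped by the caller if empty).
    """
    open_idx = value.find(" (")
    if open_idx >= 0 and value.rstrip().endswith(")"):
        return value[open_idx + 2 : value.rstrip().rfind(")")].strip()
    return value.strip()


def _parse_mh(value: str) -> MeshHeading:
    is_major = value.lstrip().startswith("*")
    parts = [p.lstrip("*").strip() for p in value.strip().split("/")]
    descriptor, qualifiers = parts[0], tuple(p for p in parts[1:] if p)
    return MeshHeading(descriptor, qualifiers, is_major)


def read_nbib(
    stream: IO[str] | str, errors: list[ParseIssue] | None = None
) -> list[MedlineRecord]:
    """Parse MEDLINE nbib tagged text into records.

    Records are separated by blank lines.  A continuation line (leading
    whitespace) before any tag is a structural error.
    """
    text = stream if isinstance(stream, str) else stream.read()
    records: list[MedlineRecord] = []
    fields: list[tuple[str, str]] = []
    block_start = 1

    def flush(end_line: int) -> None:
        nonlocal fields
        if not fields:
            return
        rec_fields, fields = fields, []
        pmid = next((v for t, v in rec_fields if t == "PMID"), "").strip()
        if not pmid:
            _report(
                errors,
                ParseIssue(f"line {block_start}", "record block without PMID"),
            )
            return
        title = next((v for t, v in rec_fields if t == "TI"), "")
        abstract = next((v for t, v in rec_fields if t == "AB"), "")
        headings = [_parse_mh(v) for t, v in rec_fields if t == "MH"]
        substances = []
        for t, v in rec_fields:
            if t == "RN":
                name = _substance_from_rn(v)
                if name:
                    substances.append(name)
        records.append(
            MedlineRecord(pmid, title, abstract, headings, substances)
        )

    lineno = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            flush(lineno)
            block_start = lineno + 1
            continue
        if line[:1].isspace():
            if not fields:
                raise ParseError(
                    f"line {lineno}: continuation line before any tag"
                )
            tag, value = fields[-1]
            fields[-1] = (tag, value + " " + line.strip())
            continue
        if len(line) < 6 or line[4:6] != "- ":
            raise ParseError(f"line {lineno}: not a tagged nbib line: {line!r}")
        fields.append((line[:4].strip(), line[6:]))
    flush(lineno if text.strip() else 0)
    return records


def write_nbib(stream: IO[str], records: Iterable[MedlineRecord]) -> None:
    """Serialize records as MEDLINE nbib tagged text."""
    blocks = []
    for rec in records:
        lines = [f"PMID- {rec.pmid}"]
        if rec.title:
            lines.append(f"TI  - {rec.title}")
        if rec.abstract:
            lines.append(f"AB  - {rec.abstract}")
        for h in rec.mesh_headings:
            star = "*" if h.is_major else ""
            lines.append(f"MH  - {star}{'/'.join([h.descriptor, *h.qualifiers])}")
        for s in rec.substances:
            lines.append(f"RN  - 0 ({s})")
        blocks.append("\n".join(lines))
    stream.write("\n\n".join(blocks) + ("\n" if blocks else ""))


# ---------------------------------------------------------------------------
# JSON lines fixture dialect


def read_jsonl(
    stream: IO[str] | str, errors: list[ParseIssue] | None = None
) -> list[MedlineRecord]:
    """Parse the one-object-per-line fixture dialect.

    A duplicate PMID is always an error naming the PMID (it would silently
    corrupt downstream counting).
    """
    text = stream if isinstance(stream, str) else stream.read()
    records: list[MedlineRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"line {lineno}: invalid JSON: {exc.msg}") from exc
        pmid = str(obj.get("pmid", "")).strip()
        if not pmid:
            _report(errors, ParseIssue(f"line {lineno}", "record without pmid"))
            continue
        if pmid in seen:
            raise DuplicatePmidError(pmid)
        seen.add(pmid)
        headings = [
            MeshHeading(
                h["descriptor"],
                tuple(h.get("qualifiers", ())),
                bool(h.get("is_major", False)),
            )
            for h in obj.get("mesh_headings", [])
        ]
        records.append(
            MedlineRecord(
                pmid=pmid,
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                mesh_headings=headings,
                substances=list(obj.get("substances", [])),
            )
        )
    return records


def write_jsonl(stream: IO[str], records: Iterable[MedlineRecord]) -> None:
    """Serialize records, one JSON object per line (UTF-8, no ASCII escaping)."""
    for rec in records:
        obj = {
            "pmid": rec.pmid,
            "title": rec.title,
            "abstract": rec.abstract,
            "mesh_headings": [
                {
                    "descriptor": h.descriptor,
                    "qualifiers": list(h.qualifiers),
                    "is_major": h.is_major,
                }
                for h in rec.mesh_headings
            ],
            "substances": list(rec.substances),
        }
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")


def _read_xml_path(path, errors=None):
    with open(path, "rb") as fh:
        return read_pubmed_xml(fh, errors)


def _write_xml_path(path, records):
    with open(path, "wb") as fh:
        write_pubmed_xml(fh, records)


def _make_text_io(reader, writer):
    def read(path, errors=None):
        with open(path, "r", encoding="utf-8") as fh:
            return reader(fh, errors)

    def write(path, records):
        with open(path, "w", encoding="utf-8") as fh:
            writer(fh, records)

    return read, write


#: dialect name -> (read_path, write_path) helpers operating on file paths
DIALECTS = {
    "pubmed_xml": (_read_xml_path, _write_xml_path),
    "nbib": _make_text_io(read_nbib, write_nbib),
    "jsonl": _make_text_io(read_jsonl, write_jsonl),
}
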