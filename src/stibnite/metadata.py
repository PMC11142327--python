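"""Model-level metadata: provenance URIs, creators, timestamps, notes.

Metadata statements look like ``model model_source "http://..."`` or
``model creator1.givenName "John"`` and are only legal inside an
explicit ``model name() ... end`` block.  On export they become the
standard SBML ``<notes>`` body and an RDF ``<annotation>`` using
BioModels qualifier conventions:

========================  =====================================
keyword                   RDF term
========================  =====================================
model_source              bqmodel:is
publication               bqmodel:isDescribedBy
biological_system         bqbiol:is
taxon                     bqbiol:hasTaxon
created / modified        dcterms:created / dcterms:modified (W3CDTF)
creatorN.*                dcterms:creator vCard entries
notes                     XHTML notes body
========================  =====================================

The keyword names come from the language; their RDF qualifiers are a
fixed convention of this package (the language itself does not pin
them down).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Tuple
from urllib.parse import urlparse

from lxml import etree

from .diagnostics import DiagnosticSink, SourceLocation
from .syntax import MetadataStmt

SCALAR_KEYWORDS = ("model_source", "publication", "biological_system",
                   "taxon", "created", "modified", "notes")
CREATOR_FIELDS = ("givenName", "familyName", "organization", "email")
_URI_KEYWORDS = {"model_source", "publication", "biological_system", "taxon"}
_TIME_KEYWORDS = {"created", "modified"}
_CREATOR_RE = re.compile(r"^creator(\d+)$")


@dataclass
class CreatorRecord:
    index: int
    givenName: Optional[str] = None
    familyName: Optional[str] = None
    organization: Optional[str] = None
    email: Optional[str] = None

    def is_empty(self) -> bool:
        return all(getattr(self, f) is None for f in CREATOR_FIELDS)


@dataclass
class MetadataRecord:
    model_source: Optional[str] = None
    publication: Optional[str] = None
    biological_system: Optional[str] = None
    taxon: Optional[str] = None
    created: Optional[str] = None
    modified: Optional[str] = None
    creators: List[CreatorRecord] = field(default_factory=list)
    notes: Optional[str] = None

    def is_empty(self) -> bool:
        return (all(getattr(self, k) is None for k in SCALAR_KEYWORDS)
                and not self.creators)


def _valid_timestamp(value: str) -> bool:
    try:
        datetime.fromisoformat(value.replace("Z", "+00:00"))
        return True
    except ValueError:
        return False


def build_metadata(statements: List[Tuple[MetadataStmt, bool]],
                   sink: DiagnosticSink) -> MetadataRecord:
    """Fold metadata statements into a record.

    Each item pairs the statement with whether it appeared inside a
    named ``model name() ... end`` block; statements outside one are a
    bracketing error.
    """
    rec = MetadataRecord()
    creators: Dict[int, CreatorRecord] = {}
    for stmt, in_block in statements:
        if not in_block:
            sink.error("metadata statements must appear inside a "
                       "'model name() ... end' block", stmt.loc)
            continue
        kw = stmt.keyword
        if "." in kw:
            head, fld = kw.split(".", 1)
            m = _CREATOR_RE.match(head)
            if not m or fld not in CREATOR_FIELDS:
                sink.error(f"unknown metadata keyword '{kw}'", stmt.loc)
                continue
            idx = int(m.group(1))
            if idx < 1:
                sink.error("creator indices are 1-based", stmt.loc)
                continue
            creators.setdefault(idx, CreatorRecord(idx))
            setattr(creators[idx], fld, stmt.value)
            continue
        if kw not in SCALAR_KEYWORDS:
            sink.error(f"unknown metadata keyword '{kw}'", stmt.loc)
            continue
        value = stmt.value
        if kw in _TIME_KEYWORDS and not _valid_timestamp(value):
            sink.error(f"'{kw}' timestamp is not ISO-8601: {value!r}",
                       stmt.loc)
            continue
        if kw in _URI_KEYWORDS and not urlparse(value).scheme:
            sink.error(f"'{kw}' requires an absolute URI, got {value!r}",
                       stmt.loc)
            continue
        if getattr(rec, kw) is not None:
            sink.warn(f"metadata keyword '{kw}' set twice; last value wins",
                      stmt.loc)
        setattr(rec, kw, value)
    if creators:
        indices = sorted(creators)
        if indices != list(range(1, len(indices) + 1)):
            missing = sorted(set(range(1, max(indices) + 1)) - set(indices))
            sink.error("creator indices must be contiguous from 1; "
                       f"missing creator{missing[0]}")
        rec.creators = [creators[i] for i in indices]
    return rec


def unparse_metadata(rec: MetadataRecord) -> List[str]:
    """Canonical metadata statements, one per line."""
    out: List[str] = []
    for kw in ("model_source", "publication", "biological_system", "taxon",
               "created", "modified"):
        v = getattr(rec, kw)
        if v is not None:
            out.append(f'model {kw} "{v}"')
    for c in rec.creators:
        for fld in CREATOR_FIELDS:
            v = getattr(c, fld)
            if v is not None:
                out.append(f'model creator{c.index}.{fld} "{v}"')
    if rec.notes is not None:
        out.append(f'model notes "{rec.notes}"')
    return out


# --------------------------------------------------------------------------
# SBML annotation serialization
# --------------------------------------------------------------------------

NS = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "dcterms": "http://purl.org/dc/terms/",
    "vCard4": "http://www.w3.org/2006/vcard/ns#",
    "bqbiol": "http://biomodels.net/biology-qualifiers/",
    "bqmodel": "http://biomodels.net/model-qualifiers/",
}
XHTML_NS = "http://www.w3.org/1999/xhtml"

_QUALIFIERS = (  # keyword, namespace prefix, RDF term
    ("model_source", "bqmodel", "is"),
    ("publication", "bqmodel", "isDescribedBy"),
    ("biological_system", "bqbiol", "is"),
    ("taxon", "bqbiol", "hasTaxon"),
)


def _q(prefix: str, tag: str) -> str:
    return f"{{{NS[prefix]}}}{tag}"


def notes_element(rec: MetadataRecord, sbml_ns: str) -> Optional[etree._Element]:
    """The SBML ``<notes>`` element with an XHTML body, or None."""
    if rec.notes is None:
        return None
    notes = etree.Element(f"{{{sbml_ns}}}notes")
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body",
                            nsmap={None: XHTML_NS})
    p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
    p.text = rec.notes
    return notes


def annotation_element(rec: MetadataRecord, metaid: str,
                       sbml_ns: str) -> Optional[etree._Element]:
    """The RDF ``<annotation>`` element, or None when nothing to say."""
    has_rdf = (rec.creators or rec.created or rec.modified
               or any(getattr(rec, kw) for kw, _, _ in _QUALIFIERS))
    if not has_rdf:
        return None
    ann = etree.Element(f"{{{sbml_ns}}}annotation")
    rdf = etree.SubElement(ann, _q("rdf", "RDF"), nsmap=NS)
    desc = etree.SubElement(rdf, _q("rdf", "Description"))
    desc.set(_q("rdf", "about"), f"#{metaid}")
    if rec.creators:
        creator = etree.SubElement(desc, _q("dcterms", "creator"))
        bag = etree.SubElement(creator, _q("rdf", "Bag"))
        for c in rec.creators:
            li = etree.SubElement(bag, _q("rdf", "li"))
            li.set(_q("rdf", "parseType"), "Resource")
            if c.givenName is not None or c.familyName is not None:
                has_name = etree.SubElement(li, _q("vCard4", "hasName"))
                has_name.set(_q("rdf", "parseType"), "Resource")
                if c.familyName is not None:
                    el = etree.SubElement(has_name, _q("vCard4", "family-name"))
                    el.text = c.familyName
                if c.givenName is not None:
                    el = etree.SubElement(has_name, _q("vCard4", "given-name"))
                    el.text = c.givenName
            if c.email is not None:
                el = etree.SubElement(li, _q("vCard4", "hasEmail"))
                el.text = c.email
            if c.organization is not None:
                el = etree.SubElement(li, _q("vCard4", "organization-name"))
                el.text = c.organization
    for kw, attr in (("created", "created"), ("modified", "modified")):
        v = getattr(rec, kw)
        if v is not None:
            term = etree.SubElement(desc, _q("dcterms", attr))
            term.set(_q("rdf", "parseType"), "Resource")
            w3 = etree.SubElement(term, _q("dcterms", "W3CDTF"))
            w3.text = v
    for kw, prefix, term in _QUALIFIERS:
        v = getattr(rec, kw)
        if v is not None:
            el = etree.SubElement(desc, _q(prefix, term))
            bag = etree.SubElement(el, _q("rdf", "Bag"))
            li = etree.SubElement(bag, _q("rdf", "li"))
            li.set(_q("rdf", "resource"), v)
    return ann


def parse_annotation(notes: Optional[etree._Element],
                     annotation: Optional[etree._Element]) -> MetadataRecord:
    """Inverse of the two emitters above, for the fragments they produce."""
    rec = MetadataRecord()
    if notes is not None:
        texts = [t.strip() for t in notes.itertext() if t.strip()]
        if texts:
            rec.notes = " ".join(texts)
    if annotation is None:
        return rec
    desc = annotation.find(f".//{_q('rdf', 'Description')}")
    if desc is None:
        return rec
    for li in desc.findall(f"./{_q('dcterms', 'creator')}/"
                           f"{_q('rdf', 'Bag')}/{_q('rdf', 'li')}"):
        c = CreatorRecord(index=len(rec.creators) + 1)
        fam = li.find(f"./{_q('vCard4', 'hasName')}/{_q('vCard4', 'family-name')}")
        giv = li.find(f"./{_q('vCard4', 'hasName')}/{_q('vCard4', 'given-name')}")
        email = li.find(f"./{_q('vCard4', 'hasEmail')}")
        org = li.find(f"./{_q('vCard4', 'organization-name')}")
        c.familyName = fam.text if fam is not None else None
        c.givenName = giv.text if giv is not None else None
        c.email = email.text if email is not None else None
        c.organization = org.text if org is not None else None
        if not c.is_empty():
            rec.creators.append(c)
    for kw in ("created", "modified"):
        w3 = desc.find(f"./{_q('dcterms', kw)}/{_q('dcterms', 'W3CDTF')}")
        if w3 is not None and w3.text:
            setattr(rec, kw, w3.text.strip())
    for kw, prefix, term in _QUALIFIERS:
        li = desc.find(f"./{_q(prefix, term)}/{_q('rdf', 'Bag')}/"
                       f"{_q('rdf', 'li')}")
        if li is not None:
            setattr(rec, kw, li.get(_q("rdf", "resource")))
    return rec
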