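"""Domain model for archive entries and cross-reference annotations.

An archive entry (``EmdbEntry``) is the unit the pipeline works on: an
EMD-accessioned cryo-EM map with its citation stub, the PDB models fitted
into it, and the macromolecules/ligands making up the imaged sample.  An
``Annotation`` is one computed or depositor-provided cross-reference to an
external resource, carried with its provenance so conflicting sources stay
distinguishable downstream.

The entry-header dialect read and written here is a deliberately small
subset of the archive's metadata schema: only the fields the annotators
consume are modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

#: External resources an annotation may point at.
RESOURCES: tuple[str, ...] = (
    "EMPIAR",
    "PDB",
    "PubMed",
    "PMC",
    "DOI",
    "ISSN",
    "ORCiD",
    "UniProt",
    "ComplexPortal",
    "ChEMBL",
    "ChEBI",
    "DrugBank",
    "PDBeKB",
    "AlphaFoldDB",
    "Rfam",
    "GO",
    "InterPro",
    "Pfam",
    "CATH",
    "SCOP",
    "SCOP2",
    "SCOP2B",
)

#: Citation-identifier resources (excluded from the similarity neighborhood).
CITATION_RESOURCES: frozenset[str] = frozenset(
    {"PubMed", "PMC", "DOI", "ISSN", "ORCiD"}
)

#: Domain/function resources annotated at sequence level from SIFTS features.
FEATURE_RESOURCES: tuple[str, ...] = (
    "GO",
    "InterPro",
    "Pfam",
    "CATH",
    "SCOP",
    "SCOP2",
    "SCOP2B",
)

#: Recorded origins of an annotation.
PROVENANCES: tuple[str, ...] = (
    "AUTHOR",
    "PDBe",
    "UNIPROT",
    "EUROPEPMC",
    "CCD",
    "SIFTS",
    "AFDB",
    "CPX",
    "EMICSS",
)

LEVELS: tuple[str, ...] = ("entry", "sample", "sequence")
SAMPLE_KINDS: tuple[str, ...] = ("protein", "rna", "ligand", "other")
GO_CATEGORIES: tuple[str, ...] = (
    "molecular_function",
    "biological_process",
    "cellular_component",
)

_ENTRY_ID_RE = re.compile(r"^EMD-\d{4,5}$")
_PDB_ID_RE = re.compile(r"^\d[a-z0-9]{3}$")
_HET_RE = re.compile(r"^[A-Z0-9]{1,5}$")
_ORCID_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[0-9X]$")
_SEQ_RE = re.compile(r"^[A-Z]+$")


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class HeaderParseError(ValueError):
    """An entry header file is not well-formed in the expected dialect."""


class EntryId(str):
    """Archive accession of the form EMD-NNNN or EMD-NNNNN (uppercase)."""

    def __new__(cls, value: str) -> "EntryId":
        value = str(value).upper()
        if not _ENTRY_ID_RE.match(value):
            raise ValidationError(f"invalid entry id {value!r}: expected EMD-NNNN[N]")
        return super().__new__(cls, value)


def _check_pdb_id(pdb_id: str) -> str:
    pdb_id = pdb_id.lower()
    if not _PDB_ID_RE.match(pdb_id):
        raise ValidationError(
            f"invalid PDB id {pdb_id!r}: expected 4 characters, first a digit"
        )
    return pdb_id


@dataclass
class CitationStub:
    """Depositor-provided citation skeleton: the PubMed ID (the only key used
    for citation enrichment), an optional DOI, and the ordered author list
    with optional ORCiD identifiers."""

    pubmed_id: Optional[str] = None
    doi: Optional[str] = None
    authors: list[tuple[str, Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pubmed_id is not None:
            if not self.pubmed_id or not self.pubmed_id.isdigit():
                raise ValidationError(f"pubmed_id must be digits, got {self.pubmed_id!r}")
        for name, orcid in self.authors:
            if orcid is not None and not _ORCID_RE.match(orcid):
                raise ValidationError(f"invalid ORCiD {orcid!r} for author {name!r}")


@dataclass
class SampleComponent:
    """One macromolecule or ligand in the imaged sample."""

    sample_id: int
    kind: str
    name: str
    sequence: Optional[str] = None
    ncbi_taxid: Optional[int] = None
    het_code: Optional[str] = None
    copies: int = 1

    def __post_init__(self) -> None:
        if self.sample_id < 1:
            raise ValidationError("sample_id must be a positive integer")
        if self.kind not in SAMPLE_KINDS:
            raise ValidationError(f"unknown sample kind {self.kind!r}")
        if self.copies < 1:
            raise ValidationError("copies must be a positive integer")
        if self.het_code is not None:
            if self.kind != "ligand":
                raise ValidationError("het_code is only valid on ligand samples")
            if not _HET_RE.match(self.het_code):
                raise ValidationError(f"invalid HET code {self.het_code!r}")
        if self.sequence is not None:
            if self.kind not in ("protein", "rna"):
                raise ValidationError("sequence is only valid on protein/rna samples")
            if not _SEQ_RE.match(self.sequence):
                raise ValidationError("sequence must be uppercase one-letter residues")
        if self.ncbi_taxid is not None and self.ncbi_taxid < 1:
            raise ValidationError("ncbi_taxid must be a positive integer")


@dataclass
class Annotation:
    """One cross-reference at entry, sample or sequence level.

    ``score`` is only meaningful for Complex Portal mappings (a Jaccard
    overlap in the retained band (0.5, 1.0]); ``residue_range`` is only
    meaningful for sequence-level annotations and is expressed 1-based
    inclusive on the author-provided sequence.  ``extra`` is a free-form
    string map for resource-specific payload (feature names, GO categories,
    molecular weights, author ordering ...).
    """

    entry_id: EntryId
    level: str
    resource: str
    accession: str
    provenance: str
    sample_id: Optional[int] = None
    score: Optional[float] = None
    residue_range: Optional[tuple[int, int]] = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entry_id = EntryId(self.entry_id)
        if self.level not in LEVELS:
            raise ValidationError(f"unknown annotation level {self.level!r}")
        if self.resource not in RESOURCES:
            raise ValidationError(f"unknown resource {self.resource!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if self.level == "entry":
            if self.sample_id is not None:
                raise ValidationError("entry-level annotations carry no sample_id")
        else:
            if self.sample_id is None or self.sample_id < 1:
                raise ValidationError(
                    f"{self.level}-level annotation requires a positive sample_id"
                )
        if self.score is not None:
            if self.resource != "ComplexPortal":
                raise ValidationError("score is only valid on ComplexPortal annotations")
            if not (0.5 < self.score <= 1.0):
                raise ValidationError(
                    f"ComplexPortal score must be in (0.5, 1.0], got {self.score}"
                )
        if self.residue_range is not None:
            if self.level != "sequence":
                raise ValidationError("residue_range is only valid at sequence level")
            start, end = self.residue_range
            if not (1 <= start <= end):
                raise ValidationError(f"invalid residue range {self.residue_range}")
            self.residue_range = (int(start), int(end))
        if not all(
            isinstance(k, str) and isinstance(v, str) for k, v in self.extra.items()
        ):
            raise ValidationError("extra must map strings to strings")

    def sort_key(self) -> tuple:
        """Canonical deterministic ordering used by every writer."""
        return (
            str(self.entry_id),
            LEVELS.index(self.level),
            self.sample_id or 0,
            RESOURCES.index(self.resource),
            self.accession,
            self.residue_range or (0, 0),
        )


@dataclass
class EmdbEntry:
    """One archive entry with its depositor-supplied metadata."""

    id: EntryId
    title: str = ""
    fitted_pdb_ids: list[str] = field(default_factory=list)
    citation: CitationStub = field(default_factory=CitationStub)
    samples: list[SampleComponent] = field(default_factory=list)
    depositor_xrefs: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.id = EntryId(self.id)
        self.fitted_pdb_ids = [_check_pdb_id(p) for p in self.fitted_pdb_ids]
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate sample_id in entry {self.id}")
        for xref in self.depositor_xrefs:
            if xref.provenance != "AUTHOR":
                raise ValidationError("depositor cross-references must be AUTHOR")
            if xref.entry_id != self.id:
                raise ValidationError("depositor cross-reference entry_id mismatch")
            if xref.sample_id is not None and xref.sample_id not in set(ids):
                raise ValidationError(
                    f"depositor cross-reference points at unknown sample "
                    f"{xref.sample_id} in entry {self.id}"
                )

    def sample(self, sample_id: int) -> SampleComponent:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Entry-header dialect: parse and serialize


def parse_entry_header(header_text: str) -> EmdbEntry:
    """Parse one entry-header document into an :class:`EmdbEntry`.

    Raises :class:`HeaderParseError` (naming the line) on malformed XML and
    :class:`ValidationError` when the document violates a domain invariant.
    """
    try:
        root = etree.fromstring(header_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise HeaderParseError(f"malformed header XML: {exc}") from exc
    if root.tag != "entry":
        raise ValidationError(f"expected root element 'entry', got {root.tag!r}")
    entry_id = root.get("id")
    if entry_id is None:
        raise ValidationError("entry element lacks an id attribute")
    entry_id = EntryId(entry_id)

    title = ""
    citation = CitationStub()
    pdb_ids: list[str] = []
    samples: list[SampleComponent] = []
    xrefs: list[Annotation] = []

    for child in root:
        if child.tag == "title":
            title = child.text or ""
        elif child.tag == "citation":
            authors = []
            pubmed_id = doi = None
            for c in child:
                if c.tag == "pubmed_id":
                    pubmed_id = (c.text or "").strip() or None
                elif c.tag == "doi":
                    doi = (c.text or "").strip() or None
                elif c.tag == "author":
                    authors.append(((c.text or "").strip(), c.get("orcid")))
            citation = CitationStub(pubmed_id=pubmed_id, doi=doi, authors=authors)
        elif child.tag == "pdb_ref":
            pdb_ids.append((child.text or "").strip())
        elif child.tag == "sample":
            try:
                sample_id = int(child.get("id", ""))
            except ValueError:
                raise ValidationError(
                    f"sample id {child.get('id')!r} is not an integer"
                ) from None
            name = ""
            sequence = taxid = het = None
            for c in child:
                if c.tag == "name":
                    name = (c.text or "").strip()
                elif c.tag == "sequence":
                    sequence = "".join((c.text or "").split()) or None
                elif c.tag == "taxid":
                    taxid = int((c.text or "").strip())
                elif c.tag == "het":
                    het = (c.text or "").strip() or None
            samples.append(
                SampleComponent(
                    sample_id=sample_id,
                    kind=child.get("kind", "other"),
                    name=name,
                    sequence=sequence,
                    ncbi_taxid=taxid,
                    het_code=het,
                    copies=int(child.get("copies", "1")),
                )
            )
        elif child.tag == "xref":
            sid = child.get("sample_id")
            xrefs.append(
                Annotation(
                    entry_id=entry_id,
                    level="entry" if sid is None else "sample",
                    resource=child.get("resource", ""),
                    accession=child.get("accession", ""),
                    provenance="AUTHOR",
                    sample_id=None if sid is None else int(sid),
                )
            )
        else:
            raise ValidationError(f"unexpected header element {child.tag!r}")

    return EmdbEntry(
        id=entry_id,
        title=title,
        fitted_pdb_ids=pdb_ids,
        citation=citation,
        samples=samples,
        depositor_xrefs=xrefs,
    )


def serialize_entry_header(entry: EmdbEntry) -> str:
    """Serialize an entry back to header text; inverse of
    :func:`parse_entry_header` field-for-field."""
    root = etree.Element("entry", id=str(entry.id))
    etree.SubElement(root, "title").text = entry.title
    cit = etree.SubElement(root, "citation")
    if entry.citation.pubmed_id is not None:
        etree.SubElement(cit, "pubmed_id").text = entry.citation.pubmed_id
    if entry.citation.doi is not None:
        etree.SubElement(cit, "doi").text = entry.citation.doi
    for name, orcid in entry.citation.authors:
        a = etree.SubElement(cit, "author")
        a.text = name
        if orcid is not None:
            a.set("orcid", orcid)
    for pdb_id in entry.fitted_pdb_ids:
        etree.SubElement(root, "pdb_ref").text = pdb_id
    for s in entry.samples:
        el = etree.SubElement(
            root, "sample", id=str(s.sample_id), kind=s.kind, copies=str(s.copies)
        )
        etree.SubElement(el, "name").text = s.name
        if s.sequence is not None:
            etree.SubElement(el, "sequence").text = s.sequence
        if s.ncbi_taxid is not None:
            etree.SubElement(el, "taxid").text = str(s.ncbi_taxid)
        if s.het_code is not None:
            etree.SubElement(el, "het").text = s.het_code
    for xref in entry.depositor_xrefs:
        el = etree.SubElement(
            root, "xref", resource=xref.resource, accession=xref.accession
        )
        if xref.sample_id is not None:
            el.set("sample_id", str(xref.sample_id))
    return etree.tostring(root, pretty_print=True, encoding="unicode")
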