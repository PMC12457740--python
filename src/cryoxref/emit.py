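"""Writers for the pipeline's public outputs: per-resource TSV files,
per-entry XML documents, and release statistics.

The 22 annotation resources are grouped into exactly 19 TSV files: the
four citation identifiers (PubMed, PMC, DOI, ISSN) collapse into one row
per publication in the ``emdb_pubmed`` file, ORCiD gets its own per-author
file, and every other resource maps to one file of its own.  Per-entry XML
documents carry the schema version, the annotation date, the release
version of every resource consulted, and per-annotation provenance; every
document is validated against the bundled XSD before it is returned, and
:func:`parse_entry_xml` inverts :func:`write_entry_xml` exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .model import (
    Annotation,
    EntryId,
    FEATURE_RESOURCES,
    RESOURCES,
    ValidationError,
)

SCHEMA_VERSION = "1.0"

#: TSV file stem for each resource; the four citation-identifier resources
#: share the pubmed file, giving 19 files for 22 resources.
FILE_FOR_RESOURCE: dict[str, str] = {
    "EMPIAR": "emdb_empiar",
    "PDB": "emdb_pdb",
    "PubMed": "emdb_pubmed",
    "PMC": "emdb_pubmed",
    "DOI": "emdb_pubmed",
    "ISSN": "emdb_pubmed",
    "ORCiD": "emdb_orcid",
    "UniProt": "emdb_uniprot",
    "ComplexPortal": "emdb_complex_portal",
    "ChEMBL": "emdb_chembl",
    "ChEBI": "emdb_chebi",
    "DrugBank": "emdb_drugbank",
    "PDBeKB": "emdb_pdbekb",
    "AlphaFoldDB": "emdb_alphafold",
    "Rfam": "emdb_rfam",
    "GO": "emdb_go",
    "InterPro": "emdb_interpro",
    "Pfam": "emdb_pfam",
    "CATH": "emdb_cath",
    "SCOP": "emdb_scop",
    "SCOP2": "emdb_scop2",
    "SCOP2B": "emdb_scop2b",
}

#: The stable file inventory, independent of archive content.
TSV_FILE_STEMS: tuple[str, ...] = tuple(
    dict.fromkeys(FILE_FOR_RESOURCE[r] for r in RESOURCES)
)

_COMMON = ("emdb_id", "accession", "provenance")
_DOMAIN_COLS = _COMMON + ("sample_id", "start", "end", "name")

TSV_COLUMNS: dict[str, tuple[str, ...]] = {
    "emdb_empiar": _COMMON,
    "emdb_pdb": _COMMON + ("mw_da", "copies", "overall_mw_da"),
    "emdb_pubmed": (
        "emdb_id",
        "accession",
        "provenance",
        "pmc_id",
        "pmc_provenance",
        "doi",
        "doi_provenance",
        "issn",
        "issn_provenance",
    ),
    "emdb_orcid": _COMMON + ("author_name", "author_order"),
    "emdb_uniprot": _COMMON + ("sample_id",),
    "emdb_complex_portal": _COMMON + ("score", "shared_members"),
    "emdb_chembl": _COMMON + ("sample_id",),
    "emdb_chebi": _COMMON + ("sample_id",),
    "emdb_drugbank": _COMMON + ("sample_id",),
    "emdb_pdbekb": _COMMON + ("sample_id",),
    "emdb_alphafold": _COMMON + ("sample_id",),
    "emdb_rfam": _COMMON + ("sample_id",),
    "emdb_go": _DOMAIN_COLS + ("go_category",),
    "emdb_interpro": _DOMAIN_COLS,
    "emdb_pfam": _DOMAIN_COLS,
    "emdb_cath": _DOMAIN_COLS,
    "emdb_scop": _DOMAIN_COLS,
    "emdb_scop2": _DOMAIN_COLS,
    "emdb_scop2b": _DOMAIN_COLS,
}


class EmitError(ValueError):
    """An output document cannot be produced or fails schema validation."""


def _fmt_score(score: float) -> str:
    return repr(score)


def _tsv_row(stem: str, ann: Annotation) -> list[str]:
    row = [str(ann.entry_id), ann.accession, ann.provenance]
    if stem == "emdb_pdb":
        row += [ann.extra.get("mw_da", ""), ann.extra.get("copies", ""),
                ann.extra.get("overall_mw_da", "")]
    elif stem == "emdb_orcid":
        row += [ann.extra.get("author_name", ""), ann.extra.get("author_order", "")]
    elif stem == "emdb_complex_portal":
        row += ["" if ann.score is None else _fmt_score(ann.score),
                ann.extra.get("shared_members", "")]
    elif stem in ("emdb_uniprot", "emdb_chembl", "emdb_chebi", "emdb_drugbank",
                  "emdb_pdbekb", "emdb_alphafold", "emdb_rfam"):
        row += ["" if ann.sample_id is None else str(ann.sample_id)]
    elif stem in {f"emdb_{r.lower()}" for r in FEATURE_RESOURCES}:
        start, end = ann.residue_range or ("", "")
        row += ["" if ann.sample_id is None else str(ann.sample_id),
                str(start), str(end), ann.extra.get("name", "")]
        if stem == "emdb_go":
            row += [ann.extra.get("go_category", "")]
    return row


def write_resource_tsvs(
    annotations: Iterable[Annotation], outdir: str | Path
) -> list[Path]:
    """Write the full archive annotation set as exactly 19 per-resource TSV
    files under ``outdir`` (UTF-8, LF endings, header row, rows sorted by
    entry id then accession).  Files for resources with no annotations are
    still written, header-only, so the inventory is stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    by_stem: dict[str, list[Annotation]] = {stem: [] for stem in TSV_FILE_STEMS}
    citation: dict[tuple[str, str], dict[str, Annotation]] = {}
    for ann in sorted(annotations, key=Annotation.sort_key):
        stem = FILE_FOR_RESOURCE.get(ann.resource)
        if stem is None:
            raise EmitError(f"no TSV grouping for resource {ann.resource!r}")
        if stem == "emdb_pubmed":
            # one row per (entry, publication); PMC/DOI/ISSN become columns
            citation.setdefault((str(ann.entry_id), ann.resource), {})
            citation[(str(ann.entry_id), ann.resource)][ann.accession] = ann
        else:
            by_stem[stem].append(ann)

    # regroup citation identifiers: one row per entry, keyed by PubMed id
    pubmed_rows: dict[str, dict[str, Annotation]] = {}
    for (entry_id, resource), accs in citation.items():
        slot = pubmed_rows.setdefault(entry_id, {})
        for ann in accs.values():
            slot[resource] = ann

    paths = []
    for stem in TSV_FILE_STEMS:
        by_stem[stem].sort(
            key=lambda a: (str(a.entry_id), a.accession, a.sample_id or 0,
                           a.residue_range or (0, 0))
        )
        path = outdir / f"{stem}.tsv"
        lines = ["\t".join(TSV_COLUMNS[stem])]
        if stem == "emdb_pubmed":
            for entry_id in sorted(pubmed_rows):
                slot = pubmed_rows[entry_id]
                pubmed = slot.get("PubMed")
                row = [
                    entry_id,
                    pubmed.accession if pubmed else "",
                    pubmed.provenance if pubmed else "",
                ]
                for resource in ("PMC", "DOI", "ISSN"):
                    ann = slot.get(resource)
                    row += [ann.accession if ann else "", ann.provenance if ann else ""]
                lines.append("\t".join(row))
        else:
            for ann in by_stem[stem]:
                lines.append("\t".join(_tsv_row(stem, ann)))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# per-entry XML


def _schema() -> etree.XMLSchema:
    text = (_ilr.files("cryoxref") / "data" / "emicss_schema.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode("utf-8")))


_SCHEMA_CACHE: Optional[etree.XMLSchema] = None


def _get_schema() -> etree.XMLSchema:
    global _SCHEMA_CACHE
    if _SCHEMA_CACHE is None:
        _SCHEMA_CACHE = _schema()
    return _SCHEMA_CACHE


def write_entry_xml(
    entry_id: EntryId | str,
    annotations: Iterable[Annotation],
    versions: dict[str, str],
    date: str,
) -> str:
    """Serialize one entry's annotation set as a schema-valid XML document.

    ``date`` is the ISO-8601 annotation date, injected by the caller so
    regeneration is byte-reproducible.  Resource blocks appear in canonical
    resource order and carry the resource's snapshot release version where
    one is known.
    """
    entry_id = EntryId(entry_id)
    annotations = sorted(annotations, key=Annotation.sort_key)
    for ann in annotations:
        if ann.entry_id != entry_id:
            raise EmitError(
                f"annotation for {ann.entry_id} passed to document {entry_id}"
            )

    root = etree.Element(
        "emicss",
        emdb_id=str(entry_id),
        schema_version=SCHEMA_VERSION,
        date=date,
    )
    for resource in RESOURCES:
        group = [a for a in annotations if a.resource == resource]
        if not group:
            continue
        block = etree.SubElement(root, "resource", name=resource)
        if resource in versions:
            block.set("version", versions[resource])
        for ann in group:
            el = etree.SubElement(
                block,
                "annotation",
                level=ann.level,
                accession=ann.accession,
                provenance=ann.provenance,
            )
            if ann.sample_id is not None:
                el.set("sample_id", str(ann.sample_id))
            if ann.score is not None:
                el.set("score", _fmt_score(ann.score))
            if ann.residue_range is not None:
                el.set("start", str(ann.residue_range[0]))
                el.set("end", str(ann.residue_range[1]))
            for key in sorted(ann.extra):
                etree.SubElement(el, "extra", key=key, value=ann.extra[key])

    schema = _get_schema()
    if not schema.validate(root):
        raise EmitError(f"generated document invalid: {schema.error_log.last_error}")
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def parse_entry_xml(
    text: str,
) -> tuple[EntryId, list[Annotation], dict[str, str], str]:
    """Parse and validate a per-entry XML document; exact inverse of
    :func:`write_entry_xml` (versions are recovered for the resources
    present in the document)."""
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise EmitError(f"malformed entry XML: {exc}") from exc
    schema = _get_schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise EmitError(f"schema violation: {err}")

    entry_id = EntryId(root.get("emdb_id"))
    date = root.get("date")
    versions: dict[str, str] = {}
    annotations: list[Annotation] = []
    for block in root:
        resource = block.get("name")
        if block.get("version") is not None:
            versions[resource] = block.get("version")
        for el in block:
            extra = {e.get("key"): e.get("value") for e in el}
            sid = el.get("sample_id")
            score = el.get("score")
            start, end = el.get("start"), el.get("end")
            annotations.append(
                Annotation(
                    entry_id=entry_id,
                    level=el.get("level"),
                    resource=resource,
                    accession=el.get("accession"),
                    provenance=el.get("provenance"),
                    sample_id=None if sid is None else int(sid),
                    score=None if score is None else float(score),
                    residue_range=None
                    if start is None
                    else (int(start), int(end)),
                    extra=extra,
                )
            )
    annotations.sort(key=Annotation.sort_key)
    return entry_id, annotations, versions, date


# ---------------------------------------------------------------------------
# release statistics


@dataclass
class ReleaseStats:
    """Per-resource counts of distinct entries with at least one mapping."""

    counts: dict[str, int]
    total_entries: int
    release_date: str

    def __post_init__(self) -> None:
        for resource, count in self.counts.items():
            if resource not in RESOURCES:
                raise ValidationError(f"unknown resource {resource!r} in stats")
            if count > self.total_entries:
                raise ValidationError(
                    f"{resource} count {count} exceeds total {self.total_entries}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "release_date": self.release_date,
                "total_entries": self.total_entries,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def release_stats(
    annotations: Iterable[Annotation],
    total_entries: int,
    date: Optional[str] = None,
) -> ReleaseStats:
    """Count, for each resource, the distinct entries holding at least one
    annotation of that resource."""
    entries_by_resource: dict[str, set[str]] = {r: set() for r in RESOURCES}
    for ann in annotations:
        entries_by_resource[ann.resource].add(str(ann.entry_id))
    return ReleaseStats(
        counts={r: len(entries_by_resource[r]) for r in RESOURCES},
        total_entries=total_entries,
        release_date=date or _dt.date.today().isoformat(),
    )
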