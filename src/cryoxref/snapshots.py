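"""Readers for the local snapshot tables standing in for external resources.

Each snapshot file opens with a ``#version=<text>`` comment capturing the
release of the resource it was taken from, followed by a tab-separated
header row and data rows (the AlphaFold accession list is a headerless CSV
and the reference proteins a FASTA, both still version-prefixed).  All
record invariants are enforced at load time so the annotators can trust
the in-memory tables.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .model import FEATURE_RESOURCES, GO_CATEGORIES, ValidationError, _check_pdb_id

log = logging.getLogger(__name__)


class SnapshotError(ValueError):
    """A snapshot file is malformed; the message names file and line."""


@dataclass(frozen=True)
class ChainUniprotRecord:
    """SIFTS-style mapping of one PDB chain to a UniProt accession, with the
    entity name used for fuzzy matching and the chain sequence (given in
    UniProt numbering starting at 1)."""

    pdb_id: str
    chain_id: str
    uniprot_acc: str
    entity_name: str
    ncbi_taxid: int
    pdb_sequence: str


@dataclass(frozen=True)
class AssemblyRecord:
    pdb_id: str
    assembly_mw_da: float
    copies: int


@dataclass(frozen=True)
class ComplexRecord:
    complex_acc: str
    members: frozenset[str]


@dataclass(frozen=True)
class CitationRecord:
    pubmed_id: str
    pmc_id: Optional[str]
    doi: Optional[str]
    issn: Optional[str]
    author_orcids: tuple[Optional[str], ...]


@dataclass(frozen=True)
class CcdRecord:
    het_code: str
    chembl_id: Optional[str]
    chebi_id: Optional[str]
    drugbank_id: Optional[str]


@dataclass(frozen=True)
class FeatureRecord:
    uniprot_acc: str
    resource: str
    accession: str
    name: str
    go_category: Optional[str]
    start: int
    end: int


@dataclass(frozen=True)
class ReferenceProtein:
    accession: str
    ncbi_taxid: int
    sequence: str


@dataclass
class ResourceSnapshot:
    """The loaded bundle of external mapping tables, indexed by natural key."""

    versions: dict[str, str] = field(default_factory=dict)
    empiar_map: list[tuple[str, str]] = field(default_factory=list)
    chains_by_pdb: dict[str, list[ChainUniprotRecord]] = field(default_factory=dict)
    assemblies: dict[str, AssemblyRecord] = field(default_factory=dict)
    complexes: list[ComplexRecord] = field(default_factory=list)
    afdb_accessions: frozenset[str] = frozenset()
    reference_proteins: list[ReferenceProtein] = field(default_factory=list)
    citations: dict[str, CitationRecord] = field(default_factory=dict)
    ccd: dict[str, CcdRecord] = field(default_factory=dict)
    rfam: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    features_by_acc: dict[str, list[FeatureRecord]] = field(default_factory=dict)

    def resource_versions(self) -> dict[str, str]:
        """Map each annotation resource to the release version of the
        snapshot file its mappings were derived from."""
        source = {
            "EMPIAR": "empiar",
            "PDB": "assemblies",
            "PubMed": "citations",
            "PMC": "citations",
            "DOI": "citations",
            "ISSN": "citations",
            "ORCiD": "citations",
            "UniProt": "sifts_chains",
            "ComplexPortal": "complexes",
            "ChEMBL": "ccd",
            "ChEBI": "ccd",
            "DrugBank": "ccd",
            "PDBeKB": "sifts_chains",
            "AlphaFoldDB": "afdb",
            "Rfam": "rfam",
        }
        for res in FEATURE_RESOURCES:
            source[res] = "features"
        return {
            res: self.versions[f]
            for res, f in source.items()
            if f in self.versions
        }


# ---------------------------------------------------------------------------
# low-level file helpers

MANDATORY_FILES = (
    "empiar.tsv",
    "sifts_chains.tsv",
    "assemblies.tsv",
    "complexes.tsv",
    "afdb.csv",
    "swissprot.fasta",
    "citations.tsv",
    "ccd.tsv",
    "rfam.tsv",
    "features.tsv",
)


def _read_versioned(path: Path) -> tuple[str, list[tuple[int, str]]]:
    """Return the version string and the (line_number, text) data lines."""
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#version="):
        raise SnapshotError(f"{path.name}:1: missing mandatory '#version=' header")
    version = lines[0][len("#version="):].strip()
    if not version:
        raise SnapshotError(f"{path.name}:1: empty version string")
    data = [
        (i + 1, line)
        for i, line in enumerate(lines)
        if i > 0 and line.strip() and not line.startswith("#")
    ]
    return version, data


def _read_table(path: Path, columns: tuple[str, ...]) -> tuple[str, list[tuple[int, list[str]]]]:
    """Read a versioned TSV with a fixed header; yield split data rows."""
    version, data = _read_versioned(path)
    if not data:
        raise SnapshotError(f"{path.name}: missing header row")
    first_no, header = data[0]
    if tuple(header.split("\t")) != columns:
        raise SnapshotError(
            f"{path.name}:{first_no}: expected columns {list(columns)}, got "
            f"{header.split(chr(9))}"
        )
    rows = []
    for no, line in data[1:]:
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise SnapshotError(
                f"{path.name}:{no}: expected {len(columns)} fields, got {len(fields)}"
            )
        rows.append((no, fields))
    return version, rows


def _opt(value: str) -> Optional[str]:
    return value if value else None


# ---------------------------------------------------------------------------
# per-file loaders


def _load_empiar(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("empiar_id", "emdb_id"))
    snap.versions["empiar"] = version
    seen = set()
    for no, (empiar_id, emdb_id) in rows:
        key = (empiar_id, emdb_id)
        if key in seen:
            raise SnapshotError(f"{path.name}:{no}: duplicate mapping {key}")
        seen.add(key)
        snap.empiar_map.append(key)


def _load_sifts_chains(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(
        path, ("pdb_id", "chain", "uniprot_acc", "entity_name", "taxid", "sequence")
    )
    snap.versions["sifts_chains"] = version
    seen = set()
    for no, (pdb_id, chain, acc, name, taxid, seq) in rows:
        try:
            pdb_id = _check_pdb_id(pdb_id)
            if not seq:
                raise ValidationError("empty pdb_sequence")
            rec = ChainUniprotRecord(
                pdb_id=pdb_id,
                chain_id=chain,
                uniprot_acc=acc,
                entity_name=name,
                ncbi_taxid=int(taxid),
                pdb_sequence=seq,
            )
        except (ValidationError, ValueError) as exc:
            raise SnapshotError(f"{path.name}:{no}: {exc}") from exc
        if (pdb_id, chain) in seen:
            raise SnapshotError(f"{path.name}:{no}: duplicate chain {pdb_id}/{chain}")
        seen.add((pdb_id, chain))
        snap.chains_by_pdb.setdefault(pdb_id, []).append(rec)


def _load_assemblies(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("pdb_id", "mw_da", "copies"))
    snap.versions["assemblies"] = version
    for no, (pdb_id, mw, copies) in rows:
        try:
            pdb_id = _check_pdb_id(pdb_id)
            rec = AssemblyRecord(pdb_id=pdb_id, assembly_mw_da=float(mw), copies=int(copies))
            if rec.assembly_mw_da <= 0 or rec.copies < 1:
                raise ValidationError("mw_da must be > 0 and copies >= 1")
        except (ValidationError, ValueError) as exc:
            raise SnapshotError(f"{path.name}:{no}: {exc}") from exc
        if pdb_id in snap.assemblies:
            raise SnapshotError(f"{path.name}:{no}: duplicate assembly for {pdb_id}")
        snap.assemblies[pdb_id] = rec


def _load_complexes(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("complex_acc", "members"))
    snap.versions["complexes"] = version
    seen = set()
    for no, (acc, members) in rows:
        member_set = frozenset(members.split())
        if not member_set:
            raise SnapshotError(f"{path.name}:{no}: complex {acc} has no members")
        if acc in seen:
            raise SnapshotError(f"{path.name}:{no}: duplicate complex {acc}")
        seen.add(acc)
        snap.complexes.append(ComplexRecord(complex_acc=acc, members=member_set))


def _load_afdb(path: Path, snap: ResourceSnapshot) -> None:
    version, data = _read_versioned(path)
    snap.versions["afdb"] = version
    accs = set()
    for no, line in data:
        acc = line.split(",")[0].strip()
        if not acc:
            raise SnapshotError(f"{path.name}:{no}: empty accession")
        accs.add(acc)
    snap.afdb_accessions = frozenset(accs)


def _load_swissprot(path: Path, snap: ResourceSnapshot) -> None:
    version, data = _read_versioned(path)
    snap.versions["swissprot"] = version
    fasta_text = "\n".join(line for _, line in data)
    seen = set()
    for record in SeqIO.parse(io.StringIO(fasta_text), "fasta"):
        taxid = None
        for token in record.description.split():
            if token.startswith("taxid="):
                taxid = int(token[len("taxid="):])
        if taxid is None:
            raise SnapshotError(f"{path.name}: record {record.id} lacks taxid=")
        if record.id in seen:
            raise SnapshotError(f"{path.name}: duplicate accession {record.id}")
        seen.add(record.id)
        snap.reference_proteins.append(
            ReferenceProtein(accession=record.id, ncbi_taxid=taxid, sequence=str(record.seq))
        )


def _load_citations(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("pubmed_id", "pmc_id", "doi", "issn", "orcids"))
    snap.versions["citations"] = version
    for no, (pubmed_id, pmc, doi, issn, orcids) in rows:
        if not pubmed_id.isdigit():
            raise SnapshotError(f"{path.name}:{no}: pubmed_id must be digits")
        if pubmed_id in snap.citations:
            raise SnapshotError(f"{path.name}:{no}: duplicate pubmed_id {pubmed_id}")
        author_orcids = tuple(
            _opt(tok) for tok in orcids.split(";")
        ) if orcids else ()
        snap.citations[pubmed_id] = CitationRecord(
            pubmed_id=pubmed_id,
            pmc_id=_opt(pmc),
            doi=_opt(doi),
            issn=_opt(issn),
            author_orcids=author_orcids,
        )


def _load_ccd(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("het", "chembl", "chebi", "drugbank"))
    snap.versions["ccd"] = version
    for no, (het, chembl, chebi, drugbank) in rows:
        rec = CcdRecord(
            het_code=het,
            chembl_id=_opt(chembl),
            chebi_id=_opt(chebi),
            drugbank_id=_opt(drugbank),
        )
        if not (rec.chembl_id or rec.chebi_id or rec.drugbank_id):
            raise SnapshotError(f"{path.name}:{no}: {het} carries no target identifier")
        if het in snap.ccd:
            raise SnapshotError(f"{path.name}:{no}: duplicate HET code {het}")
        snap.ccd[het] = rec


def _load_rfam(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(path, ("pdb_id", "sample_id", "rfam_acc"))
    snap.versions["rfam"] = version
    seen = set()
    for no, (pdb_id, sample_id, rfam_acc) in rows:
        try:
            key = (_check_pdb_id(pdb_id), int(sample_id))
        except (ValidationError, ValueError) as exc:
            raise SnapshotError(f"{path.name}:{no}: {exc}") from exc
        if (key, rfam_acc) in seen:
            raise SnapshotError(f"{path.name}:{no}: duplicate row {key} -> {rfam_acc}")
        seen.add((key, rfam_acc))
        snap.rfam.setdefault(key, []).append(rfam_acc)


def _load_features(path: Path, snap: ResourceSnapshot) -> None:
    version, rows = _read_table(
        path, ("uniprot_acc", "resource", "accession", "name", "go_category", "start", "end")
    )
    snap.versions["features"] = version
    for no, (acc, resource, feat_acc, name, go_cat, start, end) in rows:
        try:
            if resource not in FEATURE_RESOURCES:
                raise ValidationError(f"unknown feature resource {resource!r}")
            go_category = _opt(go_cat)
            if (go_category is not None) != (resource == "GO"):
                raise ValidationError("go_category present iff resource is GO")
            if go_category is not None and go_category not in GO_CATEGORIES:
                raise ValidationError(f"unknown GO category {go_category!r}")
            rec = FeatureRecord(
                uniprot_acc=acc,
                resource=resource,
                accession=feat_acc,
                name=name,
                go_category=go_category,
                start=int(start),
                end=int(end),
            )
            if not (1 <= rec.start <= rec.end):
                raise ValidationError(f"invalid feature range {rec.start}..{rec.end}")
        except (ValidationError, ValueError) as exc:
            raise SnapshotError(f"{path.name}:{no}: {exc}") from exc
        snap.features_by_acc.setdefault(acc, []).append(rec)


_LOADERS = {
    "empiar.tsv": _load_empiar,
    "sifts_chains.tsv": _load_sifts_chains,
    "assemblies.tsv": _load_assemblies,
    "complexes.tsv": _load_complexes,
    "afdb.csv": _load_afdb,
    "swissprot.fasta": _load_swissprot,
    "citations.tsv": _load_citations,
    "ccd.tsv": _load_ccd,
    "rfam.tsv": _load_rfam,
    "features.tsv": _load_features,
}


def load_snapshot(directory: str | Path) -> ResourceSnapshot:
    """Load every snapshot table found in ``directory``.

    Missing files yield empty tables plus a logged warning; malformed rows,
    duplicate natural keys and absent version headers raise
    :class:`SnapshotError` naming the file and line.
    """
    directory = Path(directory)
    snap = ResourceSnapshot()
    for filename, loader in _LOADERS.items():
        path = directory / filename
        if not path.exists():
            log.warning("snapshot file %s missing; table left empty", filename)
            continue
        loader(path, snap)
    return snap
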