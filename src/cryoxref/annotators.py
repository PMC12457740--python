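"""Per-resource annotation collection and provenance reconciliation.

Each ``map_*`` function implements the collection protocol for one external
resource; :func:`annotate_entry` orchestrates them in dependency order
(UniProt identification first, since complexes, AlphaFold models, PDBe-KB
pages and sequence features all key on UniProt accessions) and then
reconciles the computed annotations against the depositor-provided ones.
The reconciliation rule is fixed: where depositor metadata and an external
source disagree, the depositor value is trusted and the conflict is
recorded rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

from . import align
from .model import Annotation, EmdbEntry, EntryId
from .snapshots import ChainUniprotRecord, ComplexRecord, ResourceSnapshot

log = logging.getLogger(__name__)


class Conflict(NamedTuple):
    """One depositor-vs-external disagreement, logged, never resolved away."""

    entry_id: str
    resource: str
    author_value: str
    external_value: str


@dataclass(frozen=True)
class MatchParams:
    """Tunable matching parameters shared by the mappers."""

    sw_match: float = align.DEFAULT_MATCH
    sw_mismatch: float = align.DEFAULT_MISMATCH
    sw_gap: float = align.DEFAULT_GAP
    fuzzy_threshold: float = align.DEFAULT_FUZZY_THRESHOLD
    complex_min_score: float = 0.5  # strictly-greater-than filter


@dataclass(frozen=True)
class ComplexMapping:
    """A retained Complex Portal match for one entry."""

    entry_id: EntryId
    complex_acc: str
    score: float
    shared_members: frozenset[str]


# ---------------------------------------------------------------------------
# set overlap


def jaccard_score(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| of two accession sets.

    Raises ``ValueError`` when both sets are empty (the ratio is undefined).
    """
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(set(a) & set(b)) / len(set(a) | set(b))


def map_complexes(
    entry_id: EntryId | str,
    entry_uniprot_set: set[str] | frozenset[str],
    complex_table: Iterable[ComplexRecord],
    min_score: float = 0.5,
) -> list[ComplexMapping]:
    """Score the entry's UniProt set against every known complex.

    Only candidates scoring strictly above ``min_score`` are retained (a
    score of exactly the threshold is rejected); all retained complexes are
    listed, sorted by score descending then accession ascending.  A score
    of 1.0 marks an exact member-set match.
    """
    if not entry_uniprot_set:
        raise ValueError("entry UniProt set must be non-empty")
    entry_id = EntryId(entry_id)
    entry_set = frozenset(entry_uniprot_set)
    mappings = []
    for record in complex_table:
        score = jaccard_score(entry_set, record.members)
        if score > min_score:
            mappings.append(
                ComplexMapping(
                    entry_id=entry_id,
                    complex_acc=record.complex_acc,
                    score=score,
                    shared_members=entry_set & record.members,
                )
            )
    mappings.sort(key=lambda m: (-m.score, m.complex_acc))
    return mappings


# ---------------------------------------------------------------------------
# per-resource mappers


def build_empiar_lookup(empiar_map: Iterable[tuple[str, str]]) -> dict[str, list[str]]:
    """One pass over the archive-wide EMPIAR↔EMDB mapping: EMDB id → raw
    EMPIAR ids (unknown EMDB ids are filtered later, at use)."""
    lookup: dict[str, list[str]] = {}
    for empiar_id, emdb_id in empiar_map:
        lookup.setdefault(emdb_id, []).append(empiar_id)
    return lookup


def map_empiar(
    entries: Iterable[EmdbEntry], empiar_map: Iterable[tuple[str, str]]
) -> list[Annotation]:
    """Entry-level EMPIAR annotations for the whole archive at once."""
    known = {str(e.id) for e in entries}
    lookup = build_empiar_lookup(empiar_map)
    annotations = []
    for emdb_id, empiar_ids in lookup.items():
        if emdb_id not in known:
            log.warning("EMPIAR mapping to unknown entry %s skipped", emdb_id)
            continue
        for empiar_id in empiar_ids:
            annotations.append(
                Annotation(
                    entry_id=EntryId(emdb_id),
                    level="entry",
                    resource="EMPIAR",
                    accession=empiar_id,
                    provenance="EMICSS",
                )
            )
    return annotations


def _author_uniprot(entry: EmdbEntry, sample_id: int) -> Optional[Annotation]:
    for xref in entry.depositor_xrefs:
        if xref.resource == "UniProt" and xref.sample_id == sample_id:
            return xref
    return None


def map_uniprot(
    entry: EmdbEntry,
    snapshot: ResourceSnapshot,
    params: MatchParams = MatchParams(),
) -> list[Annotation]:
    """Identify the UniProt accession of each protein sample.

    Three routes, in order of trust: (1) a depositor-provided UniProt
    cross-reference is kept as-is; (2) with fitted PDB models, the sample
    name is fuzzy-matched against the models' entity names and the matched
    chain's accession taken; (3) with an author-provided sequence, an exact
    full-coverage search against the reference proteins (same taxonomy)
    assigns the accession.  The sequence route also runs when the name
    match misses.  Samples failing every route get no UniProt annotation.
    """
    annotations = []
    chains: list[ChainUniprotRecord] = []
    for pdb_id in entry.fitted_pdb_ids:
        chains.extend(snapshot.chains_by_pdb.get(pdb_id, []))
    for sample in entry.samples:
        if sample.kind != "protein":
            continue
        author = _author_uniprot(entry, sample.sample_id)
        if author is not None:
            annotations.append(author)
            continue
        hit: Optional[Annotation] = None
        if chains:
            matched = align.fuzzy_name_match(
                sample.name,
                [c.entity_name for c in chains],
                threshold=params.fuzzy_threshold,
            )
            if matched is not None:
                chain = chains[matched[0]]
                hit = Annotation(
                    entry_id=entry.id,
                    level="sample",
                    sample_id=sample.sample_id,
                    resource="UniProt",
                    accession=chain.uniprot_acc,
                    provenance="PDBe",
                    extra={"pdb_id": chain.pdb_id, "chain_id": chain.chain_id},
                )
        if hit is None and sample.sequence and sample.ncbi_taxid is not None:
            acc = align.sequence_search(
                sample.sequence, sample.ncbi_taxid, snapshot.reference_proteins
            )
            if acc is not None:
                hit = Annotation(
                    entry_id=entry.id,
                    level="sample",
                    sample_id=sample.sample_id,
                    resource="UniProt",
                    accession=acc,
                    provenance="UNIPROT",
                )
        if hit is not None:
            annotations.append(hit)
        else:
            log.info(
                "no UniProt identification for %s sample %d (%s)",
                entry.id,
                sample.sample_id,
                sample.name,
            )
    return annotations


def _fmt_mw(value: float) -> str:
    return format(value, ".10g")


def map_assembly(entry: EmdbEntry, snapshot: ResourceSnapshot) -> list[Annotation]:
    """Entry-level PDB annotations carrying assembly molecular weight and
    copy counts, plus the overall sample weight as the sum over fitted
    models (attached to the first PDB annotation with a ``derived=sum``
    marker, since summing per-model assemblies can over- or under-count)."""
    annotations = []
    total = 0.0
    any_mw = False
    for pdb_id in sorted(entry.fitted_pdb_ids):
        extra: dict[str, str] = {}
        record = snapshot.assemblies.get(pdb_id)
        if record is not None:
            extra["mw_da"] = _fmt_mw(record.assembly_mw_da)
            extra["copies"] = str(record.copies)
            total += record.assembly_mw_da
            any_mw = True
        else:
            log.info("fitted model %s of %s absent from assembly table", pdb_id, entry.id)
        annotations.append(
            Annotation(
                entry_id=entry.id,
                level="entry",
                resource="PDB",
                accession=pdb_id,
                provenance="PDBe",
                extra=extra,
            )
        )
    if annotations and any_mw:
        annotations[0].extra["overall_mw_da"] = _fmt_mw(total)
        annotations[0].extra["derived"] = "sum"
    return annotations


def map_afdb(
    uniprot_annotations: Iterable[Annotation], afdb_accessions: frozenset[str]
) -> list[Annotation]:
    """Sample-level AlphaFold DB models (AF-<acc>-F1) for every identified
    UniProt accession present in the AlphaFold accession list."""
    annotations = []
    for ann in uniprot_annotations:
        if ann.accession in afdb_accessions:
            annotations.append(
                Annotation(
                    entry_id=ann.entry_id,
                    level="sample",
                    sample_id=ann.sample_id,
                    resource="AlphaFoldDB",
                    accession=f"AF-{ann.accession}-F1",
                    provenance="AFDB",
                )
            )
    return annotations


def depositor_citation_annotations(entry: EmdbEntry) -> list[Annotation]:
    """Depositor-side citation annotations: the PubMed ID, an optional DOI,
    and per-author ORCiDs, all AUTHOR provenance.  Without a PubMed ID no
    citation annotations exist at all (the PubMed ID is the only citation
    key and is solely author-provided)."""
    cit = entry.citation
    if cit.pubmed_id is None:
        return []
    annotations = [
        Annotation(
            entry_id=entry.id,
            level="entry",
            resource="PubMed",
            accession=cit.pubmed_id,
            provenance="AUTHOR",
        )
    ]
    if cit.doi is not None:
        annotations.append(
            Annotation(
                entry_id=entry.id,
                level="entry",
                resource="DOI",
                accession=cit.doi,
                provenance="AUTHOR",
            )
        )
    for order, (name, orcid) in enumerate(cit.authors):
        if orcid is not None:
            annotations.append(
                Annotation(
                    entry_id=entry.id,
                    level="entry",
                    resource="ORCiD",
                    accession=orcid,
                    provenance="AUTHOR",
                    extra={"author_name": name, "author_order": str(order)},
                )
            )
    return annotations


def map_citation(entry: EmdbEntry, citations) -> list[Annotation]:
    """Citation enrichment from the citation table, keyed by the depositor's
    PubMed ID: PMC, DOI, ISSN and per-author ORCiD annotations with
    EUROPEPMC provenance.  Depositor-provided fields win later, in
    :func:`reconcile`."""
    cit = entry.citation
    if cit.pubmed_id is None:
        return []
    record = citations.get(cit.pubmed_id)
    if record is None:
        log.info("PubMed %s of %s not found in citation table", cit.pubmed_id, entry.id)
        return []
    annotations = []
    for resource, value in (
        ("PMC", record.pmc_id),
        ("DOI", record.doi),
        ("ISSN", record.issn),
    ):
        if value is not None:
            annotations.append(
                Annotation(
                    entry_id=entry.id,
                    level="entry",
                    resource=resource,
                    accession=value,
                    provenance="EUROPEPMC",
                )
            )
    for order, orcid in enumerate(record.author_orcids):
        if orcid is None:
            continue
        name = cit.authors[order][0] if order < len(cit.authors) else ""
        annotations.append(
            Annotation(
                entry_id=entry.id,
                level="entry",
                resource="ORCiD",
                accession=orcid,
                provenance="EUROPEPMC",
                extra={"author_name": name, "author_order": str(order)},
            )
        )
    return annotations


def map_ligands(entry: EmdbEntry, ccd) -> list[Annotation]:
    """ChEMBL/ChEBI/DrugBank identifiers for each ligand sample, keyed by
    its HET code in the chemical-component dictionary table."""
    annotations = []
    for sample in entry.samples:
        if sample.kind != "ligand" or sample.het_code is None:
            continue
        record = ccd.get(sample.het_code)
        if record is None:
            log.info("HET %s of %s absent from CCD table", sample.het_code, entry.id)
            continue
        for resource, value in (
            ("ChEMBL", record.chembl_id),
            ("ChEBI", record.chebi_id),
            ("DrugBank", record.drugbank_id),
        ):
            if value is not None:
                annotations.append(
                    Annotation(
                        entry_id=entry.id,
                        level="sample",
                        sample_id=sample.sample_id,
                        resource=resource,
                        accession=value,
                        provenance="CCD",
                    )
                )
    return annotations


def map_rfam(entry: EmdbEntry, rfam) -> list[Annotation]:
    """Rfam families for RNA samples, looked up by (fitted PDB id,
    sample id) so multiple RNAs fitted into one model disambiguate."""
    annotations = []
    for sample in entry.samples:
        if sample.kind != "rna":
            continue
        for pdb_id in entry.fitted_pdb_ids:
            for rfam_acc in rfam.get((pdb_id, sample.sample_id), []):
                annotations.append(
                    Annotation(
                        entry_id=entry.id,
                        level="sample",
                        sample_id=sample.sample_id,
                        resource="Rfam",
                        accession=rfam_acc,
                        provenance="PDBe",
                    )
                )
    return annotations


def _chain_for(
    entry: EmdbEntry, snapshot: ResourceSnapshot, ann: Annotation
) -> Optional[ChainUniprotRecord]:
    """The fitted chain backing a sample's UniProt annotation: the one the
    name match picked where recorded, else the first chain (by PDB id and
    chain id) carrying the same accession."""
    if "pdb_id" in ann.extra and "chain_id" in ann.extra:
        for chain in snapshot.chains_by_pdb.get(ann.extra["pdb_id"], []):
            if chain.chain_id == ann.extra["chain_id"]:
                return chain
    candidates = [
        chain
        for pdb_id in entry.fitted_pdb_ids
        for chain in snapshot.chains_by_pdb.get(pdb_id, [])
        if chain.uniprot_acc == ann.accession
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c.pdb_id, c.chain_id))


def map_sequence_features(
    entry: EmdbEntry,
    snapshot: ResourceSnapshot,
    uniprot_annotations: Iterable[Annotation],
    params: MatchParams = MatchParams(),
) -> list[Annotation]:
    """Sequence-level GO/InterPro/Pfam/CATH/SCOP/SCOP2/SCOP2B annotations
    restricted to the structurally represented region.

    The author-provided sample sequence is locally aligned against the
    fitted chain's sequence (given in UniProt numbering); a feature is
    emitted only when its UniProt interval overlaps at least one
    identically matched residue, and its residue range is reported on the
    author sequence over the overlapped positions.
    """
    annotations = []
    for ann in uniprot_annotations:
        if ann.sample_id is None:
            continue
        sample = entry.sample(ann.sample_id)
        if sample.sequence is None:
            continue
        chain = _chain_for(entry, snapshot, ann)
        if chain is None:
            continue
        result = align.smith_waterman(
            sample.sequence,
            chain.pdb_sequence,
            match=params.sw_match,
            mismatch=params.sw_mismatch,
            gap=params.sw_gap,
        )
        if not result.matched_pairs:
            continue
        for feature in snapshot.features_by_acc.get(ann.accession, []):
            query_hits = [
                q for q, t in result.matched_pairs if feature.start <= t <= feature.end
            ]
            if not query_hits:
                continue
            extra = {"name": feature.name}
            if feature.go_category is not None:
                extra["go_category"] = feature.go_category
            annotations.append(
                Annotation(
                    entry_id=entry.id,
                    level="sequence",
                    sample_id=sample.sample_id,
                    resource=feature.resource,
                    accession=feature.accession,
                    provenance="SIFTS",
                    residue_range=(min(query_hits), max(query_hits)),
                    extra=extra,
                )
            )
    return annotations


def map_pdbekb(uniprot_annotations: Iterable[Annotation]) -> list[Annotation]:
    """A PDBe-KB aggregated-views link for every UniProt-identified sample
    (PDBe-KB pages are keyed by UniProt accession)."""
    return [
        Annotation(
            entry_id=ann.entry_id,
            level="sample",
            sample_id=ann.sample_id,
            resource="PDBeKB",
            accession=ann.accession,
            provenance="PDBe",
        )
        for ann in uniprot_annotations
    ]


# ---------------------------------------------------------------------------
# provenance reconciliation

#: Resources where one value per (level, sample) key is meaningful.
SINGLE_VALUED = frozenset({"PubMed", "PMC", "DOI", "ISSN", "UniProt"})


def _reconcile_key(ann: Annotation) -> tuple:
    key = (ann.level, ann.sample_id, ann.resource)
    if ann.resource == "ORCiD":
        # per-author precedence: the depositor's ORCiD for an author beats
        # the citation table's ORCiD for that same author position
        key += (ann.extra.get("author_order", ""),)
    return key


def reconcile(
    depositor: Iterable[Annotation], computed: Iterable[Annotation]
) -> tuple[list[Annotation], list[Conflict]]:
    """Merge computed annotations under depositor precedence.

    Keys held by the depositor keep the depositor value; a differing
    external value for the same key (single-valued resources and per-author
    ORCiDs) is dropped and recorded as a :class:`Conflict`.  Multi-valued
    resources are unioned by accession, with duplicates collapsing onto the
    AUTHOR copy.
    """
    depositor = list(depositor)
    computed = list(computed)
    merged: list[Annotation] = list(depositor)
    conflicts: list[Conflict] = []
    dep_by_key: dict[tuple, list[Annotation]] = {}
    for ann in depositor:
        dep_by_key.setdefault(_reconcile_key(ann), []).append(ann)

    for ann in computed:
        key = _reconcile_key(ann)
        holders = dep_by_key.get(key)
        if holders is None:
            merged.append(ann)
            continue
        accessions = {h.accession for h in holders}
        if ann.accession in accessions:
            continue  # identical value both sides: keep the AUTHOR copy only
        if ann.resource in SINGLE_VALUED or ann.resource == "ORCiD":
            conflicts.append(
                Conflict(
                    entry_id=str(ann.entry_id),
                    resource=ann.resource,
                    author_value=";".join(sorted(accessions)),
                    external_value=ann.accession,
                )
            )
            log.warning(
                "conflict in %s %s: depositor %s vs external %s",
                ann.entry_id,
                ann.resource,
                sorted(accessions),
                ann.accession,
            )
        else:
            merged.append(ann)

    # drop exact duplicates within the merged set, keeping first occurrence
    seen: set[tuple] = set()
    unique: list[Annotation] = []
    for ann in merged:
        ident = (_reconcile_key(ann), ann.accession, ann.residue_range)
        if ident in seen:
            continue
        seen.add(ident)
        unique.append(ann)
    unique.sort(key=Annotation.sort_key)
    return unique, conflicts


# ---------------------------------------------------------------------------
# orchestration


def annotate_entry(
    entry: EmdbEntry,
    snapshot: ResourceSnapshot,
    params: MatchParams = MatchParams(),
    empiar_lookup: Optional[dict[str, list[str]]] = None,
) -> tuple[list[Annotation], list[Conflict]]:
    """Collect the complete annotation set for one entry.

    Mappers run in dependency order; UniProt identification feeds the
    Complex Portal, AlphaFold, PDBe-KB and sequence-feature steps.  The
    result is deterministic for fixed inputs and sorted canonically.
    """
    if empiar_lookup is None:
        empiar_lookup = build_empiar_lookup(snapshot.empiar_map)

    computed: list[Annotation] = []
    for empiar_id in empiar_lookup.get(str(entry.id), []):
        computed.append(
            Annotation(
                entry_id=entry.id,
                level="entry",
                resource="EMPIAR",
                accession=empiar_id,
                provenance="EMICSS",
            )
        )

    uniprot = map_uniprot(entry, snapshot, params)
    computed.extend(uniprot)
    computed.extend(map_assembly(entry, snapshot))

    entry_set = frozenset(ann.accession for ann in uniprot)
    if entry_set:
        for mapping in map_complexes(
            entry.id, entry_set, snapshot.complexes, min_score=params.complex_min_score
        ):
            computed.append(
                Annotation(
                    entry_id=entry.id,
                    level="entry",
                    resource="ComplexPortal",
                    accession=mapping.complex_acc,
                    provenance="CPX",
                    score=mapping.score,
                    extra={"shared_members": " ".join(sorted(mapping.shared_members))},
                )
            )

    computed.extend(map_afdb(uniprot, snapshot.afdb_accessions))
    computed.extend(map_pdbekb(uniprot))
    computed.extend(map_citation(entry, snapshot.citations))
    computed.extend(map_ligands(entry, snapshot.ccd))
    computed.extend(map_rfam(entry, snapshot.rfam))
    computed.extend(map_sequence_features(entry, snapshot, uniprot, params))

    depositor = list(entry.depositor_xrefs) + depositor_citation_annotations(entry)
    return reconcile(depositor, computed)
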