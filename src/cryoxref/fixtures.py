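"""Seeded synthetic-archive generator with planted ground truth.

The generator emits a mutually consistent set of entry headers and
resource-snapshot tables in which every cross-reference reachable by the
documented mapper rules is known in advance.  It emulates the structural
features the pipeline cares about — map-only entries, author-provided
versus derivable identifiers, partial structural coverage of a sequence,
shared ligands/domains across entries — with synthetic accessions of
realistic shape.  It does not emulate the real archive's resource-coverage
statistics or sequence composition biases.

Corruption knobs plant controlled imperfections: ``name_typo_rate``
introduces single-edit typos into chain entity names (exercising the fuzzy
matcher), ``conflict_rate`` plants depositor-vs-external DOI disagreements
(exercising provenance reconciliation).  With both at zero, pipeline
output equals the planted ground truth exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import (
    Annotation,
    CitationStub,
    EmdbEntry,
    EntryId,
    FEATURE_RESOURCES,
    SampleComponent,
    serialize_entry_header,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
TAXIDS = (9606, 10090, 562, 4932, 2697049)

_NAME_BASES = (
    "ATP synthase",
    "DNA-directed polymerase",
    "ribosomal protein large",
    "spike glycoprotein trimer",
    "heat shock chaperone",
    "elongation factor complex",
    "cytochrome oxidase chain",
    "proteasome regulatory particle",
    "photosystem core antenna",
    "nucleocapsid phosphoprotein",
    "tubulin folding cofactor",
    "replication terminator protein",
)

# HET codes and their chemical-component dictionary target identifiers
_CCD = {
    "ATP": ("CHEMBL14249", "CHEBI:15422", "DB00171"),
    "GTP": ("CHEMBL283807", "CHEBI:15996", None),
    "NAD": (None, "CHEBI:15846", "DB14128"),
    "HEM": ("CHEMBL190", "CHEBI:24479", "DB03404"),
    "ZN": (None, "CHEBI:29105", "DB14487"),
    "MG": (None, "CHEBI:18420", None),
    "ADP": ("CHEMBL14830", "CHEBI:16761", None),
    "FAD": (None, "CHEBI:16238", "DB03147"),
}
_HET_MISSING = "XXX"  # deliberately absent from the CCD table

_RFAM_POOL = tuple(f"RF{n:05d}" for n in range(1, 11))


@dataclass
class FixtureConfig:
    """Shape of the synthetic archive.

    Defaults describe a small but structurally complete archive: a little
    under half the entries are map-only (no fitted model), most protein
    samples carry an author sequence, and samples average two per entry.
    """

    n_entries: int = 20
    fraction_map_only: float = 0.4
    fraction_with_sequence: float = 0.7
    mean_samples_per_entry: float = 2.0
    seed: int = 0
    name_typo_rate: float = 0.0
    conflict_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be positive")
        for name in ("fraction_map_only", "fraction_with_sequence",
                     "name_typo_rate", "conflict_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.mean_samples_per_entry <= 0:
            raise ValueError("mean_samples_per_entry must be positive")


#: Planted link: (entry_id, level, sample_id or None, resource, accession).
PlantedLink = tuple[str, str, Optional[int], str, str]
#: Planted conflict: (entry_id, resource, author_value, external_value).
PlantedConflict = tuple[str, str, str, str]


@dataclass
class GroundTruth:
    planted: set[PlantedLink] = field(default_factory=set)
    conflicts: set[PlantedConflict] = field(default_factory=set)


class _Tables:
    """Accumulators for the snapshot files, written once at the end."""

    def __init__(self) -> None:
        self.empiar: list[tuple[str, str]] = []
        self.sifts: list[tuple[str, str, str, str, int, str]] = []
        self.assemblies: list[tuple[str, int, int]] = []
        self.complexes: list[tuple[str, frozenset[str]]] = []
        self.afdb: list[str] = []
        self.fasta: list[tuple[str, int, str]] = []
        self.citations: list[tuple[str, str, str, str, list[Optional[str]]]] = []
        self.rfam: list[tuple[str, int, str]] = []
        self.features: list[tuple[str, str, str, str, str, int, int]] = []


def _typo(rng: random.Random, text: str) -> str:
    """One random single-character edit (substitute, delete or insert)."""
    pos = rng.randrange(len(text))
    op = rng.choice("sdi")
    letter = rng.choice("abcdefghijklmnopqrstuvwxyz")
    if op == "s":
        return text[:pos] + letter + text[pos + 1:]
    if op == "d":
        return text[:pos] + text[pos + 1:]
    return text[:pos] + letter + text[pos:]


class _Generator:
    def __init__(self, config: FixtureConfig) -> None:
        self.cfg = config
        self.rng = random.Random(config.seed)
        self.tables = _Tables()
        self.gt = GroundTruth()
        self.entries: list[EmdbEntry] = []
        self._acc_counter = 0
        self._name_counter = 0
        self._pdb_ids: set[str] = set()
        self._cpx_counter = 0
        self._pubmed_counter = 30_000_000
        self._empiar_counter = 10_000
        self._orcid_counter = 0

    # -- id factories -------------------------------------------------------

    def _uniprot_acc(self) -> str:
        self._acc_counter += 1
        return f"P{self._acc_counter:05d}"

    def _decoy_acc(self) -> str:
        self._acc_counter += 1
        return f"Q{self._acc_counter:05d}"

    def _protein_name(self) -> str:
        self._name_counter += 1
        base = _NAME_BASES[self._name_counter % len(_NAME_BASES)]
        return f"{base} subunit {self._name_counter}"

    def _pdb_id(self) -> str:
        while True:
            candidate = self.rng.choice("123456789") + "".join(
                self.rng.choice("abcdefghijklmnopqrstuvwxyz0123456789")
                for _ in range(3)
            )
            if candidate not in self._pdb_ids:
                self._pdb_ids.add(candidate)
                return candidate

    def _orcid(self) -> str:
        self._orcid_counter += 1
        return f"0000-0002-{self._orcid_counter % 10000:04d}-{self._orcid_counter % 1000:03d}{self.rng.choice('0123456789X')}"

    def _sequence(self, length: int) -> str:
        return "".join(self.rng.choice(AA) for _ in range(length))

    # -- per-resource planting ----------------------------------------------

    def _plant(self, entry_id: str, level: str, sample_id: Optional[int],
               resource: str, accession: str) -> None:
        self.gt.planted.add((entry_id, level, sample_id, resource, accession))

    def _gen_features(self, acc: str, full_len: int, matched_len: int,
                      entry_id: str, sample_id: int, annotated: bool,
                      rich: bool) -> None:
        """Write features for one accession; plant those whose interval
        touches the structurally matched prefix of an annotated sample."""
        rng = self.rng
        if rich:
            resources = list(FEATURE_RESOURCES)
        else:
            resources = [rng.choice(FEATURE_RESOURCES)
                         for _ in range(rng.randrange(2, 5))]
        for resource in resources:
            k = rng.randrange(1, 13)
            if resource == "GO":
                feat_acc = f"GO:{46000 + k:07d}"
                category = ("molecular_function", "biological_process",
                            "cellular_component")[k % 3]
            else:
                prefix = {"InterPro": "IPR", "Pfam": "PF"}.get(resource)
                if prefix == "IPR":
                    feat_acc = f"IPR{k:06d}"
                elif prefix == "PF":
                    feat_acc = f"PF{k:05d}"
                elif resource == "CATH":
                    feat_acc = f"1.10.8.{k}"
                elif resource == "SCOP":
                    feat_acc = f"{50000 + k}"
                elif resource == "SCOP2":
                    feat_acc = f"SF{k:06d}"
                else:
                    feat_acc = f"SCB{k:06d}"
                category = ""
            if rich:
                start = rng.randrange(1, max(2, matched_len // 2))
            else:
                start = rng.randrange(1, full_len)
            end = min(full_len, start + rng.randrange(10, 80))
            name = f"{resource} term {k}"
            self.tables.features.append(
                (acc, resource, feat_acc, name, category, start, end)
            )
            if annotated and matched_len > 0 and start <= matched_len:
                self._plant(entry_id, "sequence", sample_id, resource, feat_acc)

    def _gen_citation(self, entry_id: str, rich: bool) -> CitationStub:
        rng, cfg = self.rng, self.cfg
        if not rich and rng.random() >= 0.85:
            return CitationStub()  # no PubMed id: no citation annotations
        self._pubmed_counter += 1
        pubmed_id = str(self._pubmed_counter)
        self._plant(entry_id, "entry", None, "PubMed", pubmed_id)

        n_authors = rng.randrange(1, 4)
        authors: list[tuple[str, Optional[str]]] = []
        table_orcids: list[Optional[str]] = []
        for a in range(n_authors):
            name = f"Author {self._pubmed_counter}-{a}"
            author_orcid = self._orcid() if (rich and a == 0) or rng.random() < 0.4 else None
            if author_orcid is not None:
                table_orcid = author_orcid if rng.random() < 0.5 else None
                planted = author_orcid
            else:
                table_orcid = self._orcid() if rng.random() < 0.7 else None
                planted = table_orcid
            authors.append((name, author_orcid))
            table_orcids.append(table_orcid)
            if planted is not None:
                self._plant(entry_id, "entry", None, "ORCiD", planted)

        true_doi = f"10.1000/syn.{self._pubmed_counter}"
        author_doi = true_doi if (rich or rng.random() < 0.5) else None
        in_table = rich or rng.random() < 0.9
        if not in_table:
            # lookup miss: only the depositor-side fields are annotated
            self.gt.planted -= {
                (entry_id, "entry", None, "ORCiD", o)
                for o in table_orcids
                if o is not None and (entry_id, "entry", None, "ORCiD", o)
                in self.gt.planted
            }
            # re-plant only author-held ORCiDs
            for (name, author_orcid) in authors:
                if author_orcid is not None:
                    self._plant(entry_id, "entry", None, "ORCiD", author_orcid)
            if author_doi is not None:
                self._plant(entry_id, "entry", None, "DOI", author_doi)
            return CitationStub(pubmed_id=pubmed_id, doi=author_doi, authors=authors)

        table_doi = true_doi
        if author_doi is not None and rng.random() < cfg.conflict_rate:
            table_doi = f"10.1000/alt.{self._pubmed_counter}"
            self.gt.conflicts.add((entry_id, "DOI", author_doi, table_doi))
        pmc = f"PMC{self._pubmed_counter}" if rich or rng.random() < 0.9 else ""
        issn = f"{rng.randrange(1000, 9999)}-{rng.randrange(1000, 9999)}" \
            if rich or rng.random() < 0.8 else ""
        self.tables.citations.append(
            (pubmed_id, pmc, table_doi, issn, table_orcids)
        )
        self._plant(entry_id, "entry", None, "DOI",
                    author_doi if author_doi is not None else table_doi)
        if pmc:
            self._plant(entry_id, "entry", None, "PMC", pmc)
        if issn:
            self._plant(entry_id, "entry", None, "ISSN", issn)
        return CitationStub(pubmed_id=pubmed_id, doi=author_doi, authors=authors)

    # -- entry construction -------------------------------------------------

    def _gen_entry(self, index: int, map_only: bool, rich: bool) -> None:
        rng, cfg = self.rng, self.cfg
        entry_id = EntryId(f"EMD-{10001 + index:05d}")
        eid = str(entry_id)
        pdb_ids: list[str] = []
        if not map_only:
            pdb_ids = [self._pdb_id()]
            if not rich and rng.random() < 0.2:
                pdb_ids.append(self._pdb_id())

        if rich:
            kinds = ["protein", "protein", "ligand", "rna"]
        else:
            n_samples = max(1, min(5, round(rng.gauss(cfg.mean_samples_per_entry, 1.0))))
            kinds = [
                rng.choices(("protein", "ligand", "rna"), weights=(70, 15, 15))[0]
                for _ in range(n_samples)
            ]

        samples: list[SampleComponent] = []
        xrefs: list[Annotation] = []
        annotated_accs: list[str] = []
        chain_letters = iter("ABCDEFGHIJKLMNOP")
        ligand_pool = list(_CCD) + [_HET_MISSING]

        for sample_id, kind in enumerate(kinds, start=1):
            if kind == "protein":
                name = self._protein_name()
                acc = self._uniprot_acc()
                taxid = rng.choice(TAXIDS)
                full_seq = self._sequence(rng.randrange(60, 200))
                has_seq = rich or rng.random() < cfg.fraction_with_sequence
                if has_seq:
                    if rich or rng.random() < 0.5:
                        author_seq = full_seq
                    else:
                        author_seq = full_seq[: max(30, 2 * len(full_seq) // 3)]
                else:
                    author_seq = None

                annotated = False
                matched_len = 0
                if not map_only:
                    # PDB route (or author xref): chain record always written
                    entity_name = name
                    if cfg.name_typo_rate > 0 and rng.random() < cfg.name_typo_rate:
                        entity_name = _typo(rng, name)
                    self.tables.sifts.append(
                        (pdb_ids[0], next(chain_letters), acc, entity_name,
                         taxid, full_seq)
                    )
                    if not rich and rng.random() < 0.25:
                        xrefs.append(Annotation(
                            entry_id=entry_id, level="sample", sample_id=sample_id,
                            resource="UniProt", accession=acc, provenance="AUTHOR",
                        ))
                    annotated = True
                    matched_len = len(author_seq) if author_seq else 0
                elif author_seq is not None:
                    # sequence route against the reference set
                    self.tables.fasta.append((acc, taxid, full_seq))
                    if rng.random() < 0.5:
                        self.tables.fasta.append((self._decoy_acc(), taxid + 1, full_seq))
                    annotated = True
                elif rng.random() < 0.3:
                    xrefs.append(Annotation(
                        entry_id=entry_id, level="sample", sample_id=sample_id,
                        resource="UniProt", accession=acc, provenance="AUTHOR",
                    ))
                    annotated = True

                if annotated:
                    annotated_accs.append(acc)
                    self._plant(eid, "sample", sample_id, "UniProt", acc)
                    self._plant(eid, "sample", sample_id, "PDBeKB", acc)
                    if rich or rng.random() < 0.7:
                        self.tables.afdb.append(acc)
                        self._plant(eid, "sample", sample_id, "AlphaFoldDB",
                                    f"AF-{acc}-F1")
                self._gen_features(acc, len(full_seq), matched_len, eid,
                                   sample_id, annotated and not map_only and
                                   author_seq is not None, rich)
                samples.append(SampleComponent(
                    sample_id=sample_id, kind="protein", name=name,
                    sequence=author_seq, ncbi_taxid=taxid,
                    copies=rng.randrange(1, 5),
                ))
            elif kind == "ligand":
                het = "ATP" if rich else rng.choice(ligand_pool)
                samples.append(SampleComponent(
                    sample_id=sample_id, kind="ligand",
                    name=f"ligand {het} molecule", het_code=het,
                    copies=rng.randrange(1, 9),
                ))
                record = _CCD.get(het)
                if record is not None:
                    for resource, value in zip(("ChEMBL", "ChEBI", "DrugBank"), record):
                        if value is not None:
                            self._plant(eid, "sample", sample_id, resource, value)
            else:  # rna
                samples.append(SampleComponent(
                    sample_id=sample_id, kind="rna",
                    name=f"ribosomal RNA component {index}-{sample_id}",
                    sequence="".join(rng.choice("ACGU") for _ in range(rng.randrange(30, 80)))
                    if rng.random() < 0.3 else None,
                    copies=1,
                ))
                if pdb_ids and (rich or rng.random() < 0.8):
                    rfam_acc = rng.choice(_RFAM_POOL)
                    self.tables.rfam.append((pdb_ids[0], sample_id, rfam_acc))
                    self._plant(eid, "sample", sample_id, "Rfam", rfam_acc)

        # fitted-model assemblies
        for pdb_id in pdb_ids:
            self._plant(eid, "entry", None, "PDB", pdb_id)
            if rich or rng.random() < 0.9:
                self.tables.assemblies.append(
                    (pdb_id, rng.randrange(20_000, 500_000), rng.randrange(1, 5))
                )

        # complexes: exact match planted, low-scoring decoys never retained
        acc_set = frozenset(annotated_accs)
        if len(acc_set) >= 2 and (rich or rng.random() < 0.6):
            self._cpx_counter += 1
            cpx = f"CPX-{self._cpx_counter:03d}"
            self.tables.complexes.append((cpx, acc_set))
            self._plant(eid, "entry", None, "ComplexPortal", cpx)
        if acc_set and rng.random() < 0.4:
            self._cpx_counter += 1
            decoy_members = frozenset(
                [sorted(acc_set)[0]] + [self._decoy_acc() for _ in range(3)]
            )
            self.tables.complexes.append(
                (f"CPX-{self._cpx_counter:03d}", decoy_members)
            )

        # raw-image archive link(s)
        if rich or rng.random() < 0.5:
            n_links = 2 if (not rich and rng.random() < 0.15) else 1
            for _ in range(n_links):
                self._empiar_counter += 1
                empiar_id = f"EMPIAR-{self._empiar_counter:05d}"
                self.tables.empiar.append((empiar_id, eid))
                self._plant(eid, "entry", None, "EMPIAR", empiar_id)

        citation = self._gen_citation(eid, rich)
        self.entries.append(EmdbEntry(
            id=entry_id,
            title=f"Synthetic reconstruction {index + 1}",
            fitted_pdb_ids=pdb_ids,
            citation=citation,
            samples=samples,
            depositor_xrefs=xrefs,
        ))

    # -- top level ----------------------------------------------------------

    def run(self) -> None:
        n, cfg = self.cfg.n_entries, self.cfg
        k = round(n * cfg.fraction_map_only)
        if k >= n:
            map_only = set(range(n))
        elif k <= n - 1:
            map_only = set(self.rng.sample(sorted(range(1, n)), k))
        for index in range(n):
            self._gen_entry(index, map_only=index in map_only,
                            rich=index == 0 and index not in map_only)

        # background reference proteins that must never be hit
        for _ in range(3):
            self.tables.fasta.append(
                (self._decoy_acc(), self.rng.choice(TAXIDS), self._sequence(80))
            )


# ---------------------------------------------------------------------------
# disk output


def _write(path: Path, version: str, header: Optional[str],
           rows: list[str]) -> None:
    lines = [f"#version={version}"]
    if header is not None:
        lines.append(header)
    lines.extend(rows)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def generate_archive(
    config: FixtureConfig, out_dir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    """Generate a synthetic archive under ``out_dir``.

    Writes ``archive/`` (one header file per entry), ``snapshot/`` (all ten
    resource tables) and ``ground_truth.tsv`` / ``planted_conflicts.tsv``.
    Deterministic: the same config yields byte-identical output.
    """
    out_dir = Path(out_dir)
    archive_dir = out_dir / "archive"
    snapshot_dir = out_dir / "snapshot"
    archive_dir.mkdir(parents=True, exist_ok=True)
    snapshot_dir.mkdir(parents=True, exist_ok=True)

    gen = _Generator(config)
    gen.run()
    t = gen.tables

    for entry in gen.entries:
        (archive_dir / f"{entry.id}.xml").write_text(
            serialize_entry_header(entry), encoding="utf-8", newline="\n"
        )

    _write(snapshot_dir / "empiar.tsv", "empiar-2025.3", "empiar_id\temdb_id",
           [f"{a}\t{b}" for a, b in t.empiar])
    _write(snapshot_dir / "sifts_chains.tsv", "sifts-2025.38",
           "pdb_id\tchain\tuniprot_acc\tentity_name\ttaxid\tsequence",
           ["\t".join(map(str, row)) for row in t.sifts])
    _write(snapshot_dir / "assemblies.tsv", "pdbe-assemblies-2025.09",
           "pdb_id\tmw_da\tcopies",
           [f"{p}\t{m}\t{c}" for p, m, c in t.assemblies])
    _write(snapshot_dir / "complexes.tsv", "complexportal-2025.2",
           "complex_acc\tmembers",
           [f"{acc}\t{' '.join(sorted(members))}" for acc, members in t.complexes])
    _write(snapshot_dir / "afdb.csv", "afdb-v4", None, list(t.afdb))
    _write(snapshot_dir / "swissprot.fasta", "uniprot-2025_04", None,
           [f">{acc} taxid={taxid}\n{seq}" for acc, taxid, seq in t.fasta])
    _write(snapshot_dir / "citations.tsv", "europepmc-2025.09",
           "pubmed_id\tpmc_id\tdoi\tissn\torcids",
           [f"{p}\t{pmc}\t{doi}\t{issn}\t" + ";".join(o or "" for o in orcids)
            for p, pmc, doi, issn, orcids in t.citations])
    _write(snapshot_dir / "ccd.tsv", "ccd-2025.09", "het\tchembl\tchebi\tdrugbank",
           [f"{het}\t{c[0] or ''}\t{c[1] or ''}\t{c[2] or ''}"
            for het, c in _CCD.items()])
    _write(snapshot_dir / "rfam.tsv", "rfam-14.10", "pdb_id\tsample_id\trfam_acc",
           [f"{p}\t{s}\t{r}" for p, s, r in t.rfam])
    _write(snapshot_dir / "features.tsv", "sifts-features-2025.38",
           "uniprot_acc\tresource\taccession\tname\tgo_category\tstart\tend",
           ["\t".join(map(str, row)) for row in t.features])

    _write_ground_truth(out_dir, gen.gt)
    return archive_dir, snapshot_dir, gen.gt


def _write_ground_truth(out_dir: Path, gt: GroundTruth) -> None:
    rows = ["entry_id\tlevel\tsample_id\tresource\taccession"]
    for entry_id, level, sample_id, resource, accession in sorted(
        gt.planted, key=lambda p: (p[0], p[1], p[2] or 0, p[3], p[4])
    ):
        rows.append(
            f"{entry_id}\t{level}\t{'' if sample_id is None else sample_id}"
            f"\t{resource}\t{accession}"
        )
    (out_dir / "ground_truth.tsv").write_text(
        "\n".join(rows) + "\n", encoding="utf-8", newline="\n"
    )
    rows = ["entry_id\tresource\tauthor_value\texternal_value"]
    for conflict in sorted(gt.conflicts):
        rows.append("\t".join(conflict))
    (out_dir / "planted_conflicts.tsv").write_text(
        "\n".join(rows) + "\n", encoding="utf-8", newline="\n"
    )


def load_ground_truth(out_dir: str | Path) -> GroundTruth:
    """Re-read a previously written ground truth."""
    out_dir = Path(out_dir)
    gt = GroundTruth()
    lines = (out_dir / "ground_truth.tsv").read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        entry_id, level, sample_id, resource, accession = line.split("\t")
        gt.planted.add(
            (entry_id, level, int(sample_id) if sample_id else None,
             resource, accession)
        )
    conflict_path = out_dir / "planted_conflicts.tsv"
    if conflict_path.exists():
        for line in conflict_path.read_text(encoding="utf-8").splitlines()[1:]:
            entry_id, resource, author, external = line.split("\t")
            gt.conflicts.add((entry_id, resource, author, external))
    return gt
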