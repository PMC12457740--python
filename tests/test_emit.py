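"""Output writers: TSV inventory, XML schema round-trips, release stats."""

from __future__ import annotations

import pytest

from cryoxref.emit import (
    EmitError,
    TSV_FILE_STEMS,
    parse_entry_xml,
    release_stats,
    write_entry_xml,
    write_resource_tsvs,
)
from cryoxref.model import Annotation, RESOURCES, ValidationError


def ann(**kwargs) -> Annotation:
    base = dict(entry_id="EMD-10001", level="entry", provenance="AUTHOR")
    base.update(kwargs)
    return Annotation(**base)


class TestResourceTsvs:
    def test_empty_archive_still_writes_nineteen_files(self, tmp_path):
        paths = write_resource_tsvs([], tmp_path)
        assert len(paths) == 19
        for path in paths:
            header, = path.read_text().splitlines()
            assert header.split("\t")[:3] == ["emdb_id", "accession", "provenance"]

    def test_file_inventory_is_stable(self):
        assert len(TSV_FILE_STEMS) == 19
        assert len(set(TSV_FILE_STEMS)) == 19

    def test_single_annotation_single_row(self, tmp_path):
        write_resource_tsvs(
            [ann(resource="EMPIAR", accession="EMPIAR-10001", provenance="EMICSS")],
            tmp_path,
        )
        lines = (tmp_path / "emdb_empiar.tsv").read_text().splitlines()
        assert lines[1] == "EMD-10001\tEMPIAR-10001\tEMICSS"

    def test_citation_identifiers_share_one_row_per_publication(self, tmp_path):
        write_resource_tsvs(
            [
                ann(resource="PubMed", accession="123"),
                ann(resource="DOI", accession="10.1/x"),
                ann(resource="ISSN", accession="1234-5678", provenance="EUROPEPMC"),
            ],
            tmp_path,
        )
        lines = (tmp_path / "emdb_pubmed.tsv").read_text().splitlines()
        assert len(lines) == 2
        row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row["accession"] == "123"
        assert row["doi"] == "10.1/x" and row["doi_provenance"] == "AUTHOR"
        assert row["issn_provenance"] == "EUROPEPMC"
        assert row["pmc_id"] == ""

    def test_every_noncitation_annotation_maps_to_one_row(self, small_result, tmp_path):
        annotations = small_result.all_annotations
        write_resource_tsvs(annotations, tmp_path)
        citation = {"PubMed", "PMC", "DOI", "ISSN"}
        n_rows = sum(
            len((tmp_path / f"{stem}.tsv").read_text().splitlines()) - 1
            for stem in TSV_FILE_STEMS
            if stem != "emdb_pubmed"
        )
        assert n_rows == sum(1 for a in annotations if a.resource not in citation)

    def test_rows_sorted_by_entry_then_accession(self, small_result, tmp_path):
        write_resource_tsvs(small_result.all_annotations, tmp_path)
        for stem in TSV_FILE_STEMS:
            rows = (tmp_path / f"{stem}.tsv").read_text().splitlines()[1:]
            keys = [(r.split("\t")[0], r.split("\t")[1]) for r in rows]
            assert keys == sorted(keys)


class TestEntryXml:
    VERSIONS = {"UniProt": "sifts-2025.38"}

    def test_empty_annotation_set_is_minimal_valid_document(self):
        text = write_entry_xml("EMD-10001", [], {}, "2025-09-05")
        entry_id, annotations, versions, date = parse_entry_xml(text)
        assert entry_id == "EMD-10001"
        assert annotations == [] and versions == {} and date == "2025-09-05"

    def test_uniprot_annotation_carries_provenance_and_version(self):
        uniprot = ann(level="sample", sample_id=1, resource="UniProt",
                      accession="P12345", provenance="PDBe")
        text = write_entry_xml("EMD-10001", [uniprot], self.VERSIONS, "2025-09-05")
        assert 'provenance="PDBe"' in text
        assert 'version="sifts-2025.38"' in text
        _, annotations, versions, _ = parse_entry_xml(text)
        assert annotations == [uniprot]
        assert versions == self.VERSIONS

    def test_round_trip_over_generated_archive(self, small_result, small_snapshot):
        versions = small_snapshot.resource_versions()
        for entry in small_result.entries:
            annotations = small_result.annotations_by_entry[str(entry.id)]
            text = write_entry_xml(entry.id, annotations, versions, "2025-09-05")
            entry_id, parsed, _, date = parse_entry_xml(text)
            assert entry_id == entry.id and date == "2025-09-05"
            assert parsed == sorted(annotations, key=Annotation.sort_key)

    def test_regeneration_is_byte_identical(self, small_result):
        annotations = small_result.all_annotations[:5]
        args = ("EMD-10001", [a for a in annotations if str(a.entry_id) == "EMD-10001"],
                self.VERSIONS, "2025-09-05")
        assert write_entry_xml(*args) == write_entry_xml(*args)

    def test_truncated_document_rejected(self):
        text = write_entry_xml("EMD-10001", [], {}, "2025-09-05")
        with pytest.raises(EmitError):
            parse_entry_xml(text[: len(text) // 2])

    def test_unknown_provenance_token_rejected_by_schema(self):
        text = write_entry_xml(
            "EMD-10001",
            [ann(level="sample", sample_id=1, resource="UniProt", accession="P1")],
            {},
            "2025-09-05",
        )
        with pytest.raises(EmitError, match="provenance|Schema|schema"):
            parse_entry_xml(text.replace('provenance="AUTHOR"', 'provenance="GUESS"'))

    def test_foreign_annotation_rejected(self):
        with pytest.raises(EmitError):
            write_entry_xml("EMD-10002", [ann(resource="DOI", accession="x")],
                            {}, "2025-09-05")


class TestReleaseStats:
    def test_distinct_entry_counting(self):
        annotations = [
            ann(level="sample", sample_id=1, resource="UniProt", accession="P1",
                provenance="PDBe"),
            ann(entry_id="EMD-10002", level="sample", sample_id=1,
                resource="UniProt", accession="P2", provenance="PDBe"),
        ]
        stats = release_stats(annotations, total_entries=3, date="2025-09-05")
        assert stats.counts["UniProt"] == 2
        assert stats.counts["Rfam"] == 0
        assert stats.total_entries == 3

    def test_entry_with_many_terms_counts_once(self):
        annotations = [
            ann(level="sequence", sample_id=1, resource="GO",
                accession=f"GO:000000{i}", provenance="SIFTS",
                residue_range=(1, 5))
            for i in range(1, 6)
        ]
        stats = release_stats(annotations, total_entries=1)
        assert stats.counts["GO"] == 1

    def test_counts_never_exceed_total(self, small_result):
        stats = small_result.stats
        assert set(stats.counts) == set(RESOURCES)
        assert all(c <= stats.total_entries for c in stats.counts.values())

    def test_count_above_total_rejected(self):
        with pytest.raises(ValidationError):
            release_stats([ann(resource="DOI", accession="x")], total_entries=0)
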