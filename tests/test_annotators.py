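"""Per-resource mappers and provenance reconciliation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from cryoxref.annotators import (
    annotate_entry,
    depositor_citation_annotations,
    jaccard_score,
    map_afdb,
    map_assembly,
    map_citation,
    map_complexes,
    map_empiar,
    map_ligands,
    map_rfam,
    map_sequence_features,
    map_uniprot,
    reconcile,
)
from cryoxref.model import Annotation, CitationStub, EmdbEntry, EntryId, SampleComponent
from cryoxref.snapshots import (
    AssemblyRecord,
    CcdRecord,
    ChainUniprotRecord,
    CitationRecord,
    ComplexRecord,
    FeatureRecord,
    ReferenceProtein,
    ResourceSnapshot,
)

EID = EntryId("EMD-10001")


def ann(**kwargs) -> Annotation:
    base = dict(entry_id=EID, level="entry", provenance="AUTHOR")
    base.update(kwargs)
    return Annotation(**base)


class TestJaccard:
    def test_exact_match_scores_one(self):
        assert jaccard_score({"P1", "P2", "P3"}, {"P1", "P2", "P3"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert jaccard_score({"P1", "P2"}, {"P3", "P4"}) == 0.0

    def test_half_overlap(self):
        assert jaccard_score({"P1", "P2", "P3"}, {"P2", "P3", "P4"}) == 0.5

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            jaccard_score(set(), set())

    @given(
        a=st.frozensets(st.sampled_from("abcdefgh"), min_size=0, max_size=8),
        b=st.frozensets(st.sampled_from("abcdefgh"), min_size=1, max_size=8),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_bounds_symmetry_identity_laws(self, a, b):
        score = jaccard_score(a, b)
        assert 0.0 <= score <= 1.0
        assert score == jaccard_score(b, a)
        assert (score == 1.0) == (set(a) == set(b))
        assert (score == 0.0) == (not set(a) & set(b))


class TestMapComplexes:
    def test_exact_member_set_scores_one(self):
        table = [ComplexRecord("CPX-1", frozenset({"P1", "P2", "P3"}))]
        (mapping,) = map_complexes(EID, {"P1", "P2", "P3"}, table)
        assert mapping.score == 1.0
        assert mapping.shared_members == frozenset({"P1", "P2", "P3"})

    def test_strictly_above_half_filter(self):
        # candidates scoring 0.25, 0.5 and 0.75: only 0.75 is retained
        entry = {"P1", "P2", "P3"}
        table = [
            ComplexRecord("CPX-a", frozenset({"P1", "Q1"})),
            ComplexRecord("CPX-b", frozenset({"P1", "P2", "P3", "Q1", "Q2", "Q3"})),
            ComplexRecord("CPX-c", frozenset({"P1", "P2", "P3", "Q1"})),
        ]
        scores = [jaccard_score(entry, c.members) for c in table]
        assert scores == [0.25, 0.5, 0.75]
        retained = map_complexes(EID, entry, table)
        assert [m.score for m in retained] == [0.75]

    def test_all_retained_sorted_by_score_then_accession(self):
        entry = {"P1", "P2", "P3", "P4"}
        table = [
            ComplexRecord("CPX-z", frozenset({"P1", "P2", "P3"})),  # 0.75
            ComplexRecord("CPX-m", frozenset(entry)),  # 1.0
            ComplexRecord("CPX-a", frozenset({"P2", "P3", "P4"})),  # 0.75
        ]
        retained = map_complexes(EID, entry, table)
        assert [(m.complex_acc, m.score) for m in retained] == [
            ("CPX-m", 1.0), ("CPX-a", 0.75), ("CPX-z", 0.75),
        ]

    def test_all_candidates_below_threshold_yield_nothing(self):
        table = [ComplexRecord("CPX-1", frozenset({"P1", "Q1", "Q2", "Q3"}))]
        assert map_complexes(EID, {"P1", "P2"}, table) == []

    def test_empty_entry_set_raises(self):
        with pytest.raises(ValueError):
            map_complexes(EID, set(), [])


class TestMapEmpiar:
    def _entry(self, eid="EMD-10001"):
        return EmdbEntry(id=EntryId(eid))

    def test_single_mapping(self):
        annotations = map_empiar([self._entry()], [("EMPIAR-10001", "EMD-10001")])
        assert [(a.resource, a.accession) for a in annotations] == [
            ("EMPIAR", "EMPIAR-10001")
        ]

    def test_empty_mapping(self):
        assert map_empiar([self._entry()], []) == []

    def test_two_image_sets_for_one_entry(self):
        annotations = map_empiar(
            [self._entry()],
            [("EMPIAR-1", "EMD-10001"), ("EMPIAR-2", "EMD-10001")],
        )
        assert len(annotations) == 2

    def test_unknown_entry_skipped(self):
        assert map_empiar([self._entry()], [("EMPIAR-1", "EMD-99999")]) == []


def _protein_entry(**kwargs) -> EmdbEntry:
    defaults = dict(
        id=EID,
        fitted_pdb_ids=["6w6v"],
        samples=[
            SampleComponent(sample_id=1, kind="protein", name="ATP synthase subunit 1",
                            sequence="MKVLAAGITT", ncbi_taxid=9606)
        ],
    )
    defaults.update(kwargs)
    return EmdbEntry(**defaults)


def _chain(acc="P11111", name="ATP synthase subunit 1", seq="MKVLAAGITT"):
    return ChainUniprotRecord(
        pdb_id="6w6v", chain_id="A", uniprot_acc=acc,
        entity_name=name, ncbi_taxid=9606, pdb_sequence=seq,
    )


class TestMapUniprot:
    def test_author_xref_beats_derived_accession(self):
        entry = _protein_entry(depositor_xrefs=[
            ann(level="sample", sample_id=1, resource="UniProt", accession="P99999")
        ])
        snap = ResourceSnapshot(chains_by_pdb={"6w6v": [_chain(acc="P11111")]})
        (result,) = map_uniprot(entry, snap)
        assert result.accession == "P99999" and result.provenance == "AUTHOR"

    def test_name_match_takes_chain_accession(self):
        snap = ResourceSnapshot(chains_by_pdb={"6w6v": [_chain()]})
        (result,) = map_uniprot(_protein_entry(), snap)
        assert result.accession == "P11111" and result.provenance == "PDBe"

    def test_map_only_entry_uses_sequence_route(self):
        entry = _protein_entry(fitted_pdb_ids=[])
        snap = ResourceSnapshot(
            reference_proteins=[ReferenceProtein("P22222", 9606, "MKVLAAGITT")]
        )
        (result,) = map_uniprot(entry, snap)
        assert result.accession == "P22222" and result.provenance == "UNIPROT"

    def test_sequence_route_after_fuzzy_miss(self):
        # fitted model present but its entity name is unrelated: fall
        # through to the sequence search
        snap = ResourceSnapshot(
            chains_by_pdb={"6w6v": [_chain(name="completely different protein")]},
            reference_proteins=[ReferenceProtein("P22222", 9606, "MKVLAAGITT")],
        )
        (result,) = map_uniprot(_protein_entry(), snap)
        assert result.accession == "P22222" and result.provenance == "UNIPROT"

    def test_no_route_yields_nothing(self):
        entry = EmdbEntry(id=EID, samples=[
            SampleComponent(sample_id=1, kind="protein", name="orphan protein")
        ])
        assert map_uniprot(entry, ResourceSnapshot()) == []


class TestMapAssembly:
    def test_single_model_weight_and_copies(self):
        snap = ResourceSnapshot(assemblies={"6w6v": AssemblyRecord("6w6v", 150000.0, 2)})
        (result,) = map_assembly(_protein_entry(), snap)
        assert result.extra["mw_da"] == "150000"
        assert result.extra["copies"] == "2"
        assert result.extra["overall_mw_da"] == "150000"

    def test_two_models_sum_to_overall_weight(self):
        entry = _protein_entry(fitted_pdb_ids=["6w6v", "7abc"])
        snap = ResourceSnapshot(assemblies={
            "6w6v": AssemblyRecord("6w6v", 100000.0, 1),
            "7abc": AssemblyRecord("7abc", 50000.0, 1),
        })
        results = map_assembly(entry, snap)
        assert len(results) == 2
        assert results[0].extra["overall_mw_da"] == "150000"
        assert results[0].extra["derived"] == "sum"

    def test_model_absent_from_table_still_annotated(self):
        (result,) = map_assembly(_protein_entry(), ResourceSnapshot())
        assert result.accession == "6w6v" and "mw_da" not in result.extra

    def test_no_fitted_models_no_annotations(self):
        assert map_assembly(EmdbEntry(id=EID), ResourceSnapshot()) == []


class TestMapAfdb:
    UNIPROT = [ann(level="sample", sample_id=1, resource="UniProt",
                   accession="P12345", provenance="UNIPROT")]

    def test_listed_accession_gets_model_link(self):
        (result,) = map_afdb(self.UNIPROT, frozenset({"P12345"}))
        assert result.accession == "AF-P12345-F1" and result.provenance == "AFDB"

    def test_unlisted_accession_gets_nothing(self):
        assert map_afdb(self.UNIPROT, frozenset({"P99999"})) == []


class TestMapCitation:
    RECORD = CitationRecord("123", "PMC77", "10.1/y", "1234-5678", ("0000-0001-2345-6789",))

    def test_enrichment_from_table(self):
        entry = EmdbEntry(id=EID, citation=CitationStub(pubmed_id="123"))
        results = map_citation(entry, {"123": self.RECORD})
        by_resource = {a.resource: a for a in results}
        assert by_resource["DOI"].accession == "10.1/y"
        assert by_resource["PMC"].accession == "PMC77"
        assert by_resource["ISSN"].accession == "1234-5678"
        assert all(a.provenance == "EUROPEPMC" for a in results)

    def test_depositor_doi_wins_over_table_doi(self):
        entry = EmdbEntry(
            id=EID, citation=CitationStub(pubmed_id="123", doi="10.1/x")
        )
        merged, conflicts = reconcile(
            depositor_citation_annotations(entry),
            map_citation(entry, {"123": self.RECORD}),
        )
        (doi,) = [a for a in merged if a.resource == "DOI"]
        assert doi.accession == "10.1/x" and doi.provenance == "AUTHOR"
        assert [(c.resource, c.author_value, c.external_value) for c in conflicts] == [
            ("DOI", "10.1/x", "10.1/y")
        ]

    def test_no_pubmed_id_no_citation_annotations(self):
        entry = EmdbEntry(id=EID, citation=CitationStub(doi="10.1/x"))
        assert map_citation(entry, {"123": self.RECORD}) == []
        assert depositor_citation_annotations(entry) == []

    def test_pubmed_id_missing_from_table(self):
        entry = EmdbEntry(id=EID, citation=CitationStub(pubmed_id="999"))
        assert map_citation(entry, {"123": self.RECORD}) == []


class TestMapLigands:
    CCD = {"ATP": CcdRecord("ATP", "CHEMBL14249", "CHEBI:15422", "DB00171"),
           "MG": CcdRecord("MG", None, "CHEBI:18420", None)}

    def _entry(self, het):
        return EmdbEntry(id=EID, samples=[
            SampleComponent(sample_id=1, kind="ligand", name="ligand", het_code=het)
        ])

    def test_full_record_yields_three_annotations(self):
        results = map_ligands(self._entry("ATP"), self.CCD)
        assert {a.resource for a in results} == {"ChEMBL", "ChEBI", "DrugBank"}
        assert all(a.provenance == "CCD" for a in results)

    def test_partial_record_yields_only_present_ids(self):
        (result,) = map_ligands(self._entry("MG"), self.CCD)
        assert result.resource == "ChEBI"

    def test_unknown_het_code_ignored(self):
        assert map_ligands(self._entry("XXX"), self.CCD) == []

    def test_protein_sample_ignored(self):
        entry = EmdbEntry(id=EID, samples=[
            SampleComponent(sample_id=1, kind="protein", name="not a ligand")
        ])
        assert map_ligands(entry, self.CCD) == []


class TestMapRfam:
    def _entry(self):
        return EmdbEntry(id=EID, fitted_pdb_ids=["6w6v"], samples=[
            SampleComponent(sample_id=1, kind="rna", name="rRNA one"),
            SampleComponent(sample_id=2, kind="rna", name="rRNA two"),
        ])

    def test_sample_id_disambiguates_multiple_rnas(self):
        table = {("6w6v", 1): ["RF00001"], ("6w6v", 2): ["RF00002"]}
        results = map_rfam(self._entry(), table)
        assert {(a.sample_id, a.accession) for a in results} == {
            (1, "RF00001"), (2, "RF00002")
        }

    def test_rna_without_table_row_gets_nothing(self):
        assert map_rfam(self._entry(), {}) == []

    def test_map_only_entry_gets_nothing(self):
        entry = EmdbEntry(id=EID, samples=[
            SampleComponent(sample_id=1, kind="rna", name="rRNA one")
        ])
        assert map_rfam(entry, {("6w6v", 1): ["RF00001"]}) == []


class TestSequenceFeatures:
    def _snapshot(self, features):
        return ResourceSnapshot(
            chains_by_pdb={"6w6v": [_chain(seq="MKVLAAGITTWWQQ")]},
            features_by_acc={"P11111": features},
        )

    def _uniprot(self):
        return [ann(level="sample", sample_id=1, resource="UniProt",
                    accession="P11111", provenance="PDBe",
                    extra={"pdb_id": "6w6v", "chain_id": "A"})]

    def test_feature_inside_aligned_region_annotated(self):
        # author sequence covers residues 1-10 of the 14-residue chain
        snap = self._snapshot([FeatureRecord("P11111", "Pfam", "PF00001",
                                             "domain", None, 2, 8)])
        (result,) = map_sequence_features(_protein_entry(), snap, self._uniprot())
        assert result.accession == "PF00001"
        assert result.residue_range == (2, 8)
        assert result.provenance == "SIFTS"

    def test_feature_outside_aligned_region_dropped(self):
        snap = self._snapshot([FeatureRecord("P11111", "Pfam", "PF00001",
                                             "domain", None, 11, 14)])
        assert map_sequence_features(_protein_entry(), snap, self._uniprot()) == []

    def test_go_category_carried_in_extra(self):
        snap = self._snapshot([FeatureRecord("P11111", "GO", "GO:0046039",
                                             "GTP metabolic process",
                                             "biological_process", 1, 6)])
        (result,) = map_sequence_features(_protein_entry(), snap, self._uniprot())
        assert result.extra["go_category"] == "biological_process"

    def test_partial_overlap_clipped_to_matched_residues(self):
        snap = self._snapshot([FeatureRecord("P11111", "Pfam", "PF00001",
                                             "domain", None, 7, 14)])
        (result,) = map_sequence_features(_protein_entry(), snap, self._uniprot())
        assert result.residue_range == (7, 10)


class TestReconcile:
    def test_author_doi_kept_over_external(self):
        dep = [ann(resource="DOI", accession="10.1/x")]
        ext = [ann(resource="DOI", accession="10.1/y", provenance="EUROPEPMC")]
        merged, conflicts = reconcile(dep, ext)
        assert [(a.accession, a.provenance) for a in merged] == [("10.1/x", "AUTHOR")]
        assert len(conflicts) == 1

    def test_disjoint_keys_union(self):
        dep = [ann(resource="DOI", accession="10.1/x")]
        ext = [ann(resource="ISSN", accession="1234-5678", provenance="EUROPEPMC")]
        merged, conflicts = reconcile(dep, ext)
        assert len(merged) == 2 and conflicts == []

    def test_identical_accession_collapses_to_author_copy(self):
        dep = [ann(level="sample", sample_id=1, resource="UniProt", accession="P1")]
        ext = [ann(level="sample", sample_id=1, resource="UniProt", accession="P1",
                   provenance="PDBe")]
        merged, conflicts = reconcile(dep, ext)
        assert [(a.accession, a.provenance) for a in merged] == [("P1", "AUTHOR")]
        assert conflicts == []

    def test_multivalued_resources_union(self):
        dep = [ann(resource="EMPIAR", accession="EMPIAR-1")]
        ext = [ann(resource="EMPIAR", accession="EMPIAR-2", provenance="EMICSS")]
        merged, _ = reconcile(dep, ext)
        assert {a.accession for a in merged} == {"EMPIAR-1", "EMPIAR-2"}

    @given(data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_depositor_always_wins_under_fuzzed_conflicts(self, data):
        """For every key the depositor holds, the merged value equals the
        depositor value, whatever the external side claims."""
        resources = ["DOI", "ISSN", "PMC", "PubMed"]
        dep, ext = [], []
        for resource in data.draw(st.sets(st.sampled_from(resources))):
            dep.append(ann(resource=resource,
                           accession=data.draw(st.sampled_from(["v1", "v2", "v3"]))))
        for resource in data.draw(st.sets(st.sampled_from(resources))):
            ext.append(ann(resource=resource, provenance="EUROPEPMC",
                           accession=data.draw(st.sampled_from(["v1", "v2", "v3"]))))
        merged, conflicts = reconcile(dep, ext)
        merged_by_resource = {a.resource: a for a in merged}
        for d in dep:
            assert merged_by_resource[d.resource].accession == d.accession
            assert merged_by_resource[d.resource].provenance == "AUTHOR"
        # single-valued resources never carry two values
        assert len(merged) == len({(a.level, a.sample_id, a.resource) for a in merged})


class TestAnnotateEntry:
    def test_empty_entry_yields_only_depositor_side(self):
        entry = EmdbEntry(id=EID)
        annotations, conflicts = annotate_entry(entry, ResourceSnapshot())
        assert annotations == [] and conflicts == []

    def test_map_only_entry_with_sequence_still_annotated(self):
        """Entries without fitted models reach UniProt, AlphaFold and
        PDBe-KB through the sequence route."""
        entry = _protein_entry(fitted_pdb_ids=[])
        snap = ResourceSnapshot(
            reference_proteins=[ReferenceProtein("P22222", 9606, "MKVLAAGITT")],
            afdb_accessions=frozenset({"P22222"}),
        )
        annotations, _ = annotate_entry(entry, snap)
        resources = {a.resource for a in annotations}
        assert resources == {"UniProt", "AlphaFoldDB", "PDBeKB"}

    def test_deterministic_for_fixed_inputs(self, small_archive, small_snapshot):
        from cryoxref.pipeline import read_archive
        entry = read_archive(small_archive.archive_dir)[0]
        first, _ = annotate_entry(entry, small_snapshot)
        second, _ = annotate_entry(entry, small_snapshot)
        assert first == second
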