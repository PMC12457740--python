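"""Restrict sequence annotations to the structurally represented region.

The author-provided sample sequence is locally aligned (Smith–Waterman)
against the fitted chain's sequence.  A GO/Pfam/... feature is annotated
only when its interval overlaps a matched residue, so terms describing
parts of the protein absent from the structure are dropped."""

from cryoxref import smith_waterman
from cryoxref.annotators import map_sequence_features
from cryoxref.model import Annotation, EmdbEntry, SampleComponent
from cryoxref.snapshots import ChainUniprotRecord, FeatureRecord, ResourceSnapshot

author_seq = "MKVLAAGITT"          # residues 1-10 of the full protein
chain_seq = "MKVLAAGITTWWQQ"       # the fitted model covers residues 1-14

result = smith_waterman(author_seq, chain_seq)
print(f"alignment score {result.score}, matched residues "
      f"{result.query_range} -> {result.target_range}")

entry = EmdbEntry(
    id="EMD-10001",
    fitted_pdb_ids=["6w6v"],
    samples=[SampleComponent(sample_id=1, kind="protein", name="demo protein",
                             sequence=author_seq, ncbi_taxid=9606)],
)
snapshot = ResourceSnapshot(
    chains_by_pdb={"6w6v": [ChainUniprotRecord("6w6v", "A", "P11111",
                                               "demo protein", 9606, chain_seq)]},
    features_by_acc={"P11111": [
        FeatureRecord("P11111", "Pfam", "PF00001", "N-terminal domain", None, 2, 8),
        FeatureRecord("P11111", "GO", "GO:0046039", "GTP metabolic process",
                      "biological_process", 1, 6),
        FeatureRecord("P11111", "Pfam", "PF00099", "C-terminal domain", None, 11, 14),
    ]},
)
uniprot = [Annotation(entry_id="EMD-10001", level="sample", sample_id=1,
                      resource="UniProt", accession="P11111", provenance="PDBe",
                      extra={"pdb_id": "6w6v", "chain_id": "A"})]

print("\nfeatures kept (interval overlaps a matched residue):")
for ann in map_sequence_features(entry, snapshot, uniprot):
    print(f"  {ann.resource}:{ann.accession}  residues {ann.residue_range}  "
          f"{ann.extra.get('name')}")
print("\nPF00099 (residues 11-14) lies outside the matched region: dropped.")
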