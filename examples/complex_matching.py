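"""Match an entry's protein set against curated complexes.

The entry's UniProt accessions (A) are compared to each complex's member
set (B) by the Jaccard index |A∩B|/|A∪B|.  A score of 1.0 is an exact
match; only complexes scoring strictly above 0.5 are retained, and all of
them are listed, best first."""

from cryoxref import EntryId, map_complexes
from cryoxref.snapshots import ComplexRecord

entry_set = {"P00001", "P00002", "P00003"}
complexes = [
    ComplexRecord("CPX-101", frozenset({"P00001", "P00002", "P00003"})),   # 1.0
    ComplexRecord("CPX-102", frozenset({"P00001", "P00002", "P00003", "P00004"})),  # 0.75
    ComplexRecord("CPX-103", frozenset({"P00001", "P00002", "P00009", "P00010"})),  # 1/3
]

print(f"entry UniProt set: {sorted(entry_set)}\n")
for mapping in map_complexes(EntryId("EMD-10001"), entry_set, complexes):
    print(f"{mapping.complex_acc}  score={mapping.score:.2f}  "
          f"shared={sorted(mapping.shared_members)}")
print("\nCPX-103 (score 0.33) was rejected by the strict >0.5 filter.")
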