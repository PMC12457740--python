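"""Rank entries by annotation-neighborhood overlap.

Entries and their biological annotations form a bipartite graph; the
similarity of two entries is the Jaccard coefficient of their annotation
neighborhoods.  Citation identifiers are excluded so shared journals or
authors do not make unrelated structures look similar."""

import tempfile
from pathlib import Path

from cryoxref import FixtureConfig, generate_archive, run_annotation, build_graph
from cryoxref.similarity import similar_entries

root = Path(tempfile.mkdtemp())
archive_dir, snapshot_dir, _ = generate_archive(
    FixtureConfig(n_entries=20, seed=3), root
)
result = run_annotation(archive_dir, snapshot_dir, root / "out", date="2025-09-05")
graph = build_graph(result.all_annotations)

query = str(result.entries[0].id)
print(f"entries similar to {query}:")
for record in similar_entries(query, graph, top_k=5):
    shared = sorted(f"{r}:{a}" for r, a in record.shared)
    print(f"  {record.entry_b}  coefficient={record.coefficient:.3f}  "
          f"shared={shared[:3]}{'...' if len(shared) > 3 else ''}")
print("\ncoefficient = |shared annotations| / |union of both neighborhoods|")
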