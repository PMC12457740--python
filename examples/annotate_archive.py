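"""Run the full annotation pipeline over a small synthetic archive.

Generates a 10-entry archive with planted cross-references, annotates it
against the accompanying snapshot tables, and prints the release
statistics.  Each count is the number of distinct entries that gained at
least one cross-reference to that resource."""

import tempfile
from pathlib import Path

from cryoxref import FixtureConfig, generate_archive, run_annotation

root = Path(tempfile.mkdtemp())
archive_dir, snapshot_dir, gt = generate_archive(
    FixtureConfig(n_entries=10, seed=7), root
)
result = run_annotation(archive_dir, snapshot_dir, root / "out", date="2025-09-05")

print(f"entries annotated : {len(result.entries)}")
print(f"annotations       : {len(result.all_annotations)}")
print(f"planted links     : {len(gt.planted)} (all recovered: "
      f"{len(result.all_annotations) == len(gt.planted)})")
print("\nper-resource distinct-entry counts (nonzero):")
for resource, count in sorted(result.stats.counts.items()):
    if count:
        print(f"  {resource:14s} {count}")
print(f"\noutputs: 19 TSV files and {len(result.entries)} XML documents "
      f"under {root / 'out'}")
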