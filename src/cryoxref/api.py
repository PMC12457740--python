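"""The three query modes over a completed annotation run.

Mirrors the query surface of the production system: per-entry annotations,
entries similar to a given entry, and per-release statistics.  All three
read the files a previous :func:`cryoxref.pipeline.run_annotation` wrote.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import emit, similarity
from .model import Annotation, EntryId

__all__ = ["entry_annotations", "similar_entries", "release_statistics"]


def entry_annotations(out_dir: str | Path, entry_id: str) -> list[Annotation]:
    """The annotation set of one entry, read back from its XML document."""
    path = Path(out_dir) / "xml" / f"{EntryId(entry_id)}.xml"
    if not path.exists():
        raise KeyError(f"no annotation document for {entry_id} under {out_dir}")
    _, annotations, _, _ = emit.parse_entry_xml(path.read_text(encoding="utf-8"))
    return annotations


def similar_entries(
    out_dir: str | Path,
    entry_id: str,
    min_coefficient: float = similarity.DEFAULT_MIN_COEFFICIENT,
    top_k: int = similarity.DEFAULT_TOP_K,
) -> list[similarity.SimilarityRecord]:
    """Entries ranked by annotation-neighborhood overlap with ``entry_id``,
    rebuilt from the per-entry XML documents of a previous run."""
    xml_dir = Path(out_dir) / "xml"
    annotations: list[Annotation] = []
    for path in sorted(xml_dir.glob("*.xml")):
        _, anns, _, _ = emit.parse_entry_xml(path.read_text(encoding="utf-8"))
        annotations.extend(anns)
    graph = similarity.build_graph(annotations)
    return similarity.similar_entries(
        entry_id, graph, min_coefficient=min_coefficient, top_k=top_k
    )


def release_statistics(out_dir: str | Path) -> dict:
    """The per-resource distinct-entry counts of a previous run."""
    path = Path(out_dir) / "stats.json"
    if not path.exists():
        raise FileNotFoundError(f"no stats.json under {out_dir}; run annotate first")
    return json.loads(path.read_text(encoding="utf-8"))
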