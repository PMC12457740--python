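"""End-to-end orchestration: read an archive of entry headers, load the
resource snapshot, annotate every entry, and write the public outputs
(per-resource TSVs, per-entry XML, release statistics, conflict log)."""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import emit
from .annotators import (
    Conflict,
    MatchParams,
    annotate_entry,
    build_empiar_lookup,
)
from .model import Annotation, EmdbEntry, parse_entry_header
from .snapshots import ResourceSnapshot, load_snapshot

log = logging.getLogger(__name__)


@dataclass
class ArchiveResult:
    """Everything one annotation run produced, in memory."""

    entries: list[EmdbEntry]
    annotations_by_entry: dict[str, list[Annotation]]
    conflicts: list[Conflict]
    snapshot: ResourceSnapshot
    stats: emit.ReleaseStats

    @property
    def all_annotations(self) -> list[Annotation]:
        flat: list[Annotation] = []
        for entry in self.entries:
            flat.extend(self.annotations_by_entry[str(entry.id)])
        return flat


def read_archive(archive_dir: str | Path) -> list[EmdbEntry]:
    """Parse every ``*.xml`` entry header under ``archive_dir``, sorted by
    file name so runs are deterministic."""
    entries = []
    for path in sorted(Path(archive_dir).glob("*.xml")):
        entries.append(parse_entry_header(path.read_text(encoding="utf-8")))
    return entries


def annotate_archive(
    entries: list[EmdbEntry],
    snapshot: ResourceSnapshot,
    params: MatchParams = MatchParams(),
    date: Optional[str] = None,
) -> ArchiveResult:
    """Annotate a list of entries against a loaded snapshot."""
    date = date or _dt.date.today().isoformat()
    empiar_lookup = build_empiar_lookup(snapshot.empiar_map)
    known = {str(e.id) for e in entries}
    for emdb_id in empiar_lookup:
        if emdb_id not in known:
            log.warning("EMPIAR mapping to unknown entry %s skipped", emdb_id)

    by_entry: dict[str, list[Annotation]] = {}
    conflicts: list[Conflict] = []
    for entry in entries:
        annotations, entry_conflicts = annotate_entry(
            entry, snapshot, params=params, empiar_lookup=empiar_lookup
        )
        by_entry[str(entry.id)] = annotations
        conflicts.extend(entry_conflicts)

    flat = [ann for entry in entries for ann in by_entry[str(entry.id)]]
    stats = emit.release_stats(flat, total_entries=len(entries), date=date)
    return ArchiveResult(
        entries=entries,
        annotations_by_entry=by_entry,
        conflicts=conflicts,
        snapshot=snapshot,
        stats=stats,
    )


def run_annotation(
    archive_dir: str | Path,
    snapshot_dir: str | Path,
    out_dir: str | Path,
    params: MatchParams = MatchParams(),
    date: Optional[str] = None,
) -> ArchiveResult:
    """The full pipeline: read, annotate, and write all outputs.

    Output layout under ``out_dir``: ``tsv/`` (the 19 per-resource files),
    ``xml/`` (one document per entry), ``stats.json`` and
    ``conflicts.tsv``.  ``date`` fixes the annotation date so regeneration
    is byte-identical.
    """
    out_dir = Path(out_dir)
    date = date or _dt.date.today().isoformat()
    entries = read_archive(archive_dir)
    snapshot = load_snapshot(snapshot_dir)
    result = annotate_archive(entries, snapshot, params=params, date=date)

    emit.write_resource_tsvs(result.all_annotations, out_dir / "tsv")

    xml_dir = out_dir / "xml"
    xml_dir.mkdir(parents=True, exist_ok=True)
    versions = snapshot.resource_versions()
    for entry in entries:
        text = emit.write_entry_xml(
            entry.id, result.annotations_by_entry[str(entry.id)], versions, date
        )
        (xml_dir / f"{entry.id}.xml").write_text(text, encoding="utf-8", newline="\n")

    (out_dir / "stats.json").write_text(
        result.stats.to_json() + "\n", encoding="utf-8", newline="\n"
    )
    conflict_lines = ["entry_id\tresource\tauthor_value\texternal_value"]
    for c in sorted(result.conflicts):
        conflict_lines.append("\t".join(c))
    (out_dir / "conflicts.tsv").write_text(
        "\n".join(conflict_lines) + "\n", encoding="utf-8", newline="\n"
    )
    return result
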