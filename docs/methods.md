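# Methods

`cryoxref` is an offline re-implementation of an added-value annotation
engine for a cryo-EM archive: it computes cross-references between archive
entries (EMD accessions) and external biological resources, records the
provenance of every link, and derives entry-similarity rankings and
release statistics from the result. The live web services the production
pipeline consults are replaced by local snapshot tables, which makes every
step deterministic and testable.

## The annotation model

An entry carries depositor-supplied metadata: a citation stub (PubMed ID,
optional DOI, authors with optional ORCiDs), fitted PDB model identifiers,
and sample components (proteins, RNAs, ligands) with optional sequences,
taxonomy identifiers and HET codes. Annotation proceeds in four steps:
harvest the snapshot tables, collect candidate cross-references per entry,
reconcile them against depositor-provided values, and emit TSV/XML
outputs. Cross-references live at three levels:

- **entry** — EMPIAR image sets, fitted PDB models (with assembly
  molecular weight and copy number), citation identifiers, Complex Portal
  complexes;
- **sample** — UniProt, AlphaFold DB, PDBe-KB, ChEMBL/ChEBI/DrugBank (via
  the chemical-component dictionary), Rfam;
- **sequence** — GO, InterPro, Pfam, CATH, SCOP, SCOP2, SCOP2B terms
  restricted to the residue range actually represented by the structure.

That is 22 resource types in total. The provenance vocabulary
distinguishes depositor-supplied values (`AUTHOR`) from each derivation
route (`PDBe`, `UNIPROT`, `EUROPEPMC`, `CCD`, `SIFTS`, `AFDB`, `CPX`,
`EMICSS`).

### UniProt identification

Protein samples are identified in order of trust:

1. a depositor-provided UniProt cross-reference is kept verbatim;
2. if the entry has fitted models, the sample name is fuzzy-matched
   against the models' chain entity names and the matched chain's SIFTS
   accession is used;
3. if the sample has an author-provided sequence, it is searched against
   the reference protein set; a hit requires 100% query coverage with
   zero mismatches *and* an identical NCBI taxonomy identifier.

Route 3 also runs when route 2 finds no acceptable name match, so
map-only entries (no fitted model — a substantial part of any cryo-EM
archive) can still be annotated, and through UniProt also reach AlphaFold
DB, PDBe-KB and the sequence-feature resources.

The fuzzy matcher canonicalizes names (case-fold, strip punctuation,
collapse whitespace) and scores normalized Levenshtein similarity
`1 − d/max(|a|,|b|)` (edit distance via edlib), accepting matches at
≥ 0.8 by default. This tolerates a single-character typo in any name
longer than ten characters while rejecting unrelated names. The sequence
search is an exact substring scan; with full coverage and full identity
required, this is equivalent to (and stricter than any parameterization
of) a heuristic protein search, and it removes dependence on an external
binary and database version. Ties are resolved to the lexicographically
smallest accession.

### Complex matching

The entry's identified UniProt set A is scored against every curated
complex's member set B with the Jaccard index |A∩B|/|A∪B|. A score of
1.0 is an exact match; candidates scoring strictly above 0.5 are all
retained (a candidate at exactly 0.5 is rejected), sorted by score then
accession. Only the full entry set is scored: the entry dialect carries
no per-sample complex grouping, and enumerating arbitrary subsets would
be exponential without changing what the score means. Stoichiometry is
ignored; matching is on identifier sets.

### Sequence-feature restriction

For a UniProt-identified sample with an author sequence and a fitted
chain, the author sequence is aligned to the chain sequence with
Smith–Waterman (linear gap penalty; defaults match +2, mismatch −1,
gap −2, all configurable). The aligner is implemented directly because
the restriction step needs the identically matched residue pairs of one
optimal traceback, not only a score; ties are broken deterministically
(earliest best cell in row-major order; diagonal over vertical over
horizontal moves). A feature interval in UniProt numbering is annotated
only when it overlaps at least one matched residue, and its residue range
is reported on the author sequence, clipped to the overlapped positions.
Chain sequences are taken to be in UniProt numbering starting at 1;
residue-level renumbering with insertion codes is out of scope. The exact
feature sets retained are insensitive to the scoring scheme whenever the
author sequence is a contiguous region of the chain sequence, which is
the dominant real-world case.

### Provenance reconciliation

Depositor-provided data is trusted: where the depositor and an external
source both supply a value for the same key (level, sample, resource),
the depositor value is kept and the disagreement is logged as a conflict
(`conflicts.tsv`), never silently resolved. Single-valued keys are the
citation identifiers and per-sample UniProt; ORCiDs are reconciled per
author position, so a depositor ORCiD beats the citation table's ORCiD
for the same author while other authors' identifiers still merge.
Multi-valued resources union by accession, with exact duplicates
collapsing onto the depositor copy. Citation enrichment is keyed solely
by the depositor's PubMed ID; without one, no citation annotations are
produced.

## Outputs

- **19 TSV files**, one per resource group: the four citation identifiers
  (PubMed, PMC, DOI, ISSN) share one row per publication; ORCiD has its
  own per-author file; the remaining 18 resources one file each. Every
  file has a header with common columns (emdb_id, accession, provenance)
  plus resource-specific ones (score and shared members for complexes;
  sample_id, residue range and term name for sequence features; GO
  category; molecular weight and copies for PDB). Files are written even
  when empty so the inventory is stable.
- **Per-entry XML** validated against the bundled XSD
  (`src/cryoxref/data/emicss_schema.xsd`, schema version 1.0), carrying
  the annotation date and the snapshot release version of every resource
  consulted. The date is injectable, so regeneration is byte-identical;
  `parse_entry_xml` is the exact inverse of `write_entry_xml`.
- **Release statistics**: per resource, the number of distinct entries
  with at least one mapping, plus the total entries processed.

## Entry similarity

Entries and their biological annotations form a bipartite graph; the
similarity of two entries is the Jaccard coefficient of their annotation
neighborhoods, computed in process over two-hop neighbors (no graph
database needed at this scale). Citation-identifier resources are
excluded from the neighborhood so shared journals or author lists do not
drive similarity. Defaults: minimum coefficient 0, top 10 results; ties
rank by entry id.

## The synthetic archive generator

`cryoxref.fixtures` generates a mutually consistent archive and snapshot
directory with planted ground truth. Defaults: 20 entries, 40% map-only,
70% of protein samples with an author sequence, two samples per entry on
average — a small archive that still exercises every mapper route, with
one entry planted across all 22 resources. Accessions have realistic
shapes (P#####, CPX-###, EMPIAR-#####, CHEMBL###, CHEBI:###, DB#####,
RF#####, GO:#######, PF#####, IPR######) so format handling is
exercised; protein sequences are uniform over the 20 amino-acid letters,
lengths 60–200, with author sequences either complete or a two-thirds
prefix so the feature-restriction step has both kept and dropped
intervals. Domain, GO and ligand accessions are drawn from shared pools
so entries overlap in the similarity graph; UniProt accessions are
globally unique so complex decoys (score ≤ 0.25 by construction) can
never cross-match another entry.

Two corruption knobs exist: `name_typo_rate` applies single-character
edits to chain entity names (the fuzzy matcher must still recover every
planted link), and `conflict_rate` plants depositor-vs-external DOI
disagreements that must surface in the conflict log with the depositor
value winning.

What the generator does **not** emulate: the real archive's resource
coverage distributions, realistic protein families or homology (sequences
are random, so the exact-substring search has no near-miss decoys beyond
the planted wrong-taxonomy ones), SIFTS numbering offsets, or obsolete or
merged accessions. Passing the recovery suite therefore demonstrates that
the mapping rules are implemented faithfully, not that the thresholds are
tuned for real archive noise.

## Numerical and design choices

- Alignment tie-breaks and all output orderings are fixed, so two runs
  over the same inputs are byte-identical; annotation sort order is
  (entry, level, sample, resource, accession).
- The Jaccard index is undefined for two empty sets and raises rather
  than returning a default.
- The overall sample molecular weight is the sum of assembly weights over
  fitted models, emitted with a `derived=sum` marker: when models overlap
  or cover the map only partly, the sum can over- or under-count, so the
  value is marked as derived rather than measured.
- Complex Portal links are attached at entry level: a complex spans
  several sample components, so no single sample id applies.
- Snapshot files carry a mandatory `#version=` first line; versions
  propagate into the XML per resource. Malformed rows, duplicate natural
  keys and missing version headers are load-time errors naming file and
  line; missing whole files degrade to empty tables with a warning.

## Known limitations

Header parsing covers the small dialect defined here, not the full
archive metadata schema. Sub-complex matching beyond the full entry set
is not attempted. The citation table is a flat stand-in for a live
literature API; fields it lacks simply produce no annotation. Entry
similarity is recomputed from the emitted XML rather than served from a
persistent graph store.
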