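"""Matching kernels: Smith–Waterman local alignment, fuzzy name matching,
and the exact full-coverage sequence search against a reference set.

The local aligner is implemented directly (linear gap penalty) because the
sequence-feature restriction downstream needs the set of identically
matched residue pairs from one optimal traceback, not just a score.  The
fuzzy matcher is normalized Levenshtein similarity on canonicalized names,
with the edit distance computed by edlib.  The sequence search accepts a
reference hit only at 100% query coverage with zero mismatches and an
identical NCBI taxonomy identifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .snapshots import ReferenceProtein

#: Default local-alignment scoring scheme (linear gap penalty).
DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0

#: Default minimum normalized name similarity accepted by the fuzzy matcher.
DEFAULT_FUZZY_THRESHOLD = 0.8


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment.

    ``matched_pairs`` holds the 1-based (query_pos, target_pos) pairs where
    the chosen optimal alignment places identical residues opposite each
    other.  Ranges are 1-based inclusive; both are ``None`` when the best
    local score is zero (nothing aligns).
    """

    score: float
    query_range: Optional[tuple[int, int]]
    target_range: Optional[tuple[int, int]]
    matched_pairs: frozenset[tuple[int, int]]


_EMPTY = AlignmentResult(0.0, None, None, frozenset())


def smith_waterman(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> AlignmentResult:
    """Optimal local alignment of ``a`` against ``b`` with linear gaps.

    Ties are resolved deterministically: the best-scoring cell earliest in
    row-major order is chosen, and the traceback prefers diagonal over
    vertical over horizontal moves.
    """
    if match <= 0:
        raise ValueError("match score must be positive")
    if mismatch > 0 or gap > 0:
        raise ValueError("mismatch and gap penalties must be <= 0")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return _EMPTY

    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            best = diag
            up = prev[j] + gap
            if up > best:
                best = up
            left = row[j - 1] + gap
            if left > best:
                best = left
            row[j] = best if best > 0 else 0.0

    flat = int(np.argmax(H))
    i, j = divmod(flat, m + 1)
    score = float(H[i, j])
    if score == 0.0:
        return _EMPTY

    end_q, end_t = i, j
    pairs = []
    while H[i, j] > 0:
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
            if a[i - 1] == b[j - 1]:
                pairs.append((i, j))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return AlignmentResult(
        score=score,
        query_range=(i + 1, end_q),
        target_range=(j + 1, end_t),
        matched_pairs=frozenset(pairs),
    )


_CANON_RE = re.compile(r"[^0-9a-z]+")


def canonicalize_name(name: str) -> str:
    """Case-fold, replace punctuation with spaces, collapse whitespace."""
    return " ".join(_CANON_RE.sub(" ", name.casefold()).split())


def name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity of two canonicalized names, in
    [0, 1]; exactly 1.0 iff the canonical forms are equal."""
    ca, cb = canonicalize_name(a), canonicalize_name(b)
    if ca == cb:
        return 1.0
    longest = max(len(ca), len(cb))
    if longest == 0:
        return 1.0
    distance = edlib.align(ca, cb, task="distance")["editDistance"]
    return 1.0 - distance / longest


def fuzzy_name_match(
    query: str,
    candidates: Sequence[str],
    threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> Optional[tuple[int, float]]:
    """Best fuzzy match of ``query`` among ``candidates``.

    Returns ``(index, similarity)`` for the most similar candidate with
    similarity >= threshold (ties broken by lowest index), or ``None``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    best: Optional[tuple[int, float]] = None
    for idx, candidate in enumerate(candidates):
        sim = name_similarity(query, candidate)
        if best is None or sim > best[1]:
            best = (idx, sim)
    if best is None or best[1] < threshold:
        return None
    return best


def sequence_search(
    query: str,
    taxid: int,
    reference_db: Iterable[ReferenceProtein],
) -> Optional[str]:
    """Search reference proteins for an exact full-coverage hit.

    A reference matches only when the entire query occurs within its
    sequence without mismatches (100% coverage, 100% identity) and its
    taxonomy identifier equals ``taxid``.  Among multiple hits the
    lexicographically smallest accession is returned.
    """
    if not query:
        raise ValueError("query sequence must be non-empty")
    hits = [
        ref.accession
        for ref in reference_db
        if ref.ncbi_taxid == taxid and query in ref.sequence
    ]
    return min(hits) if hits else None
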