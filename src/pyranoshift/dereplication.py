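"""Local reference-collection search, conflict detection, and swap diagnostics.

A dereplication query asks whether a "new" compound's ¹³C shift list already
matches a known structure.  Matching here is *label-free*: literature
assignments are exactly what is under suspicion, so two shift lists are
compared as multisets of ppm values under an optimal one-to-one matching with
a tolerance cap — maximizing the number of matched peaks, then minimizing the
total absolute difference (an exact dynamic program on the sorted lists).

Two auditing passes build on the same matcher:

* ``find_conflicts`` — pairs of entries where identical data carry distinct
  structures (class 1), or the same compound name carries divergent data
  (class 2);
* ``detect_swapped_assignments`` — label-aware: carbon pairs (classically
  C-8a/C-9a) whose transposition in one data set clearly improves agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .shift_data import CompoundEntry, ValidationError, format_subtype

__all__ = [
    "DEFAULT_SEARCH_TOLERANCE",
    "MatchResult",
    "SearchHit",
    "ReferenceCollection",
    "match_shift_sets",
    "search_by_shifts",
    "ConflictPair",
    "find_conflicts",
    "SwapFinding",
    "detect_swapped_assignments",
]

DEFAULT_SEARCH_TOLERANCE = 0.5  # ppm; literature matches show sub-1-ppm agreement
DEFAULT_NEAR_TOL = 1.0  # ppm, conflict detection
DEFAULT_MIN_OVERLAP = 0.9


@dataclass(frozen=True)
class MatchResult:
    """Optimal tolerance-capped one-to-one matching of two shift multisets."""

    n_matched: int
    total_abs_diff: float
    pairs: tuple[tuple[float, float], ...]
    unmatched_query: tuple[float, ...]

    @property
    def mean_abs_diff(self) -> float:
        return self.total_abs_diff / self.n_matched if self.n_matched else 0.0


def match_shift_sets(
    query: Sequence[float], reference: Sequence[float], tolerance: float
) -> MatchResult:
    """Exact 1-D dynamic program over the sorted value lists.

    Objective is lexicographic: maximize the number of |q − r| ≤ tolerance
    pairs, then minimize Σ|q − r| over matched pairs.  For values on a line
    an optimal matching can always be taken order-preserving, so the DP over
    (query index, reference index) is exact.
    """
    if tolerance <= 0:
        raise ValidationError("matching tolerance must be positive")
    q = sorted(float(v) for v in query)
    r = sorted(float(v) for v in reference)
    n, m = len(q), len(r)
    NEG = (-1, 0.0)
    # dp[i][j]: best (n_matched, -total_diff) using q[:i], r[:j]
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1=skip q, 2=skip r, 3=match
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best, bmove = NEG, 0
            if i > 0 and dp[i - 1][j] > best:
                best, bmove = dp[i - 1][j], 1
            if j > 0 and dp[i][j - 1] > best:
                best, bmove = dp[i][j - 1], 2
            if i > 0 and j > 0:
                d = abs(q[i - 1] - r[j - 1])
                if d <= tolerance:
                    prev = dp[i - 1][j - 1]
                    cand = (prev[0] + 1, prev[1] - d)
                    if cand > best:
                        best, bmove = cand, 3
            dp[i][j] = best
            move[i][j] = bmove
    pairs = []
    matched_q = set()
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 3:
            pairs.append((q[i - 1], r[j - 1]))
            matched_q.add(i - 1)
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    unmatched = tuple(q[k] for k in range(n) if k not in matched_q)
    n_matched, neg_diff = dp[n][m]
    return MatchResult(n_matched, -neg_diff, tuple(pairs), unmatched)


@dataclass(frozen=True)
class SearchHit:
    entry_id: str
    n_matched: int
    n_query: int
    mean_abs_diff: float
    unmatched_query: tuple[float, ...]

    @property
    def fraction_matched(self) -> float:
        return self.n_matched / self.n_query if self.n_query else 0.0


class ReferenceCollection:
    """In-memory reference collection with a sorted-shift index per entry."""

    def __init__(self, entries: Iterable[CompoundEntry]):
        self.entries: list[CompoundEntry] = list(entries)
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("reference collection ids must be unique")
        self._index: dict[str, tuple[float, ...]] = {
            e.id: tuple(sorted(e.shift_values)) for e in self.entries
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def shifts_of(self, entry_id: str) -> tuple[float, ...]:
        return self._index[entry_id]

    def get(self, entry_id: str) -> CompoundEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)


def search_by_shifts(
    query: Sequence[float],
    collection: ReferenceCollection,
    tolerance: float = DEFAULT_SEARCH_TOLERANCE,
    min_matched: float = 0.0,
) -> list[SearchHit]:
    """Rank collection entries against a query shift list.

    Hits matching fewer than ``min_matched`` (a fraction of the query size)
    are dropped.  Ranking: n_matched descending, mean |diff| ascending, id.
    An empty collection yields an empty result, not an error.
    """
    if len(query) == 0:
        raise ValidationError("query shift list must be nonempty")
    hits = []
    for entry in collection:
        res = match_shift_sets(query, collection.shifts_of(entry.id), tolerance)
        hit = SearchHit(
            entry_id=entry.id,
            n_matched=res.n_matched,
            n_query=len(query),
            mean_abs_diff=res.mean_abs_diff,
            unmatched_query=res.unmatched_query,
        )
        if hit.fraction_matched >= min_matched:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.n_matched, h.mean_abs_diff, h.entry_id))
    return hits


@dataclass(frozen=True)
class ConflictPair:
    """A suspicious entry pair found while auditing a collection."""

    id_a: str
    id_b: str
    kind: str  # identical_data_distinct_structures | same_structure_divergent_data
    overlap: float
    mean_abs_diff: float


def _spectra_match(
    collection: ReferenceCollection,
    a: CompoundEntry,
    b: CompoundEntry,
    near_tol: float,
    min_overlap: float,
) -> tuple[bool, float, float]:
    res = match_shift_sets(collection.shifts_of(a.id), collection.shifts_of(b.id), near_tol)
    denom = min(len(a.shifts), len(b.shifts))
    overlap = res.n_matched / denom if denom else 0.0
    ok = overlap >= min_overlap and res.mean_abs_diff <= near_tol
    return ok, overlap, res.mean_abs_diff


def _same_structure(a: CompoundEntry, b: CompoundEntry) -> bool:
    if a.name and b.name and a.name.strip().casefold() == b.name.strip().casefold():
        return True
    return False


def find_conflicts(
    collection: ReferenceCollection,
    near_tol: float = DEFAULT_NEAR_TOL,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> tuple[list[ConflictPair], list[ConflictPair]]:
    """Audit a collection for the two literature failure modes.

    Class 1: shift multisets match (≥ min_overlap of the smaller entry, mean
    |diff| ≤ near_tol) but the entries describe different structures.
    Class 2: entries share a compound name but their data fail that same
    test.  Symmetric in entry order; no self-pairs.
    """
    class1, class2 = [], []
    entries = collection.entries
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            ok, overlap, mean_diff = _spectra_match(collection, a, b, near_tol, min_overlap)
            same = _same_structure(a, b)
            if ok and not same:
                class1.append(
                    ConflictPair(a.id, b.id, "identical_data_distinct_structures", overlap, mean_diff)
                )
            elif same and not ok:
                class2.append(
                    ConflictPair(a.id, b.id, "same_structure_divergent_data", overlap, mean_diff)
                )
    return class1, class2


@dataclass(frozen=True)
class SwapFinding:
    label_x: str
    label_y: str
    gain: float  # ppm improvement in Σ|δ_a − δ_b| over {x, y} after transposition


def detect_swapped_assignments(
    a: CompoundEntry,
    b: CompoundEntry,
    candidate_labels: Sequence[str] | None = None,
    gain_tol: float = 1.0,
) -> list[SwapFinding]:
    """Find label pairs whose transposition in ``b`` improves agreement.

    Only single-pair exchanges are searched (the narrated failure mode, e.g.
    reversed C-8a/C-9a assignments), keeping the scan O(n²).  Pairs whose
    exchange reduces Σ|δ_a − δ_b| over the two labels by at least ``gain_tol``
    are reported best-gain first.  Labels missing from either entry are
    skipped with a warning.
    """
    a_map = {k: v[0] for k, v in a.shift_map().items()}
    b_map = {k: v[0] for k, v in b.shift_map().items()}
    if candidate_labels is None:
        labels = sorted(set(a_map) & set(b_map))
    else:
        labels = []
        for lab in candidate_labels:
            if lab in a_map and lab in b_map:
                labels.append(lab)
            else:
                warnings.warn(f"swap-candidate label {lab!r} missing from an entry; skipped")
    findings = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            x, y = labels[i], labels[j]
            direct = abs(a_map[x] - b_map[x]) + abs(a_map[y] - b_map[y])
            swapped = abs(a_map[x] - b_map[y]) + abs(a_map[y] - b_map[x])
            gain = direct - swapped
            if gain >= gain_tol:
                findings.append(SwapFinding(x, y, gain))
    findings.sort(key=lambda f: (-f.gain, f.label_x, f.label_y))
    return findings
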