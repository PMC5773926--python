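"""Structural queries: prune, filter, refine, rank.

The full-length query pipeline:

1. *prune* — for each reference r, bound the candidate set to fragments
   whose indexed distance to r lies in
   ``[rmsd(q, r) - d_q - eps, rmsd(q, r) + d_q + eps]`` and intersect
   across references (the triangle inequality guarantees no true match
   is lost; ``eps`` absorbs float32 storage rounding);
2. drop candidates from excluded PDB codes;
3. drop candidates whose sequence fails the regex (anchored full-string
   match) — sequence filtering runs after pruning, before refinement;
4. *refine* — keep candidates with exact ``rmsd(q, f) <= d_q``;
5. sort ascending by RMSD, ties by fragment id;
6. apply the result limit, if any.

The result is guaranteed identical (membership and order) to a
brute-force scan over the whole database.

Masked (gapped) queries bypass the index entirely: the tables hold
full-length RMSDs and their triangle-inequality bounds say nothing
about the masked metric, so a linear scan over the masked atoms is the
only correct route.  It is still fast — the kernel is vectorised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, InvalidRegexError, UsageError
from .fragment_store import Fragment, FragmentDatabase
from .geometry import qcp_rmsd, qcp_rmsd_many
from .index import STORAGE_EPSILON, RmsdIndex, range_candidates

__all__ = [
    "StructuralQuery",
    "Match",
    "QueryResult",
    "query",
    "query_masked",
    "apply_limit",
    "query_auto_widen",
]

_REFINE_CHUNK = 512  # candidates refined per vectorised block in first-N mode


@dataclass(frozen=True)
class Match:
    """A database fragment matched to a query, with its exact RMSD."""

    fragment_id: int
    pdb_code: str
    chain: str
    start_residue: tuple[int, str]
    rmsd: float


@dataclass
class QueryResult:
    """Matches plus the threshold that produced them."""

    matches: list[Match]
    threshold: float
    under_target: bool = False


@dataclass
class StructuralQuery:
    """A query fragment with threshold, mask and filters.

    ``query_fragment`` may be a :class:`Fragment` or a bare (4L, 3)
    coordinate array (then ``sequence_constraint`` still applies to the
    candidates, not the query).  ``mask`` selects residue positions
    (0-based) of the query that participate in the distance; ``limit``
    is ``(mode, N)`` with mode ``"best"`` or ``"first"``;
    ``auto_widen`` is ``(target_count, step, ceiling)`` in Å.
    """

    query_fragment: Fragment | np.ndarray
    threshold: float = 1.0
    mask: frozenset[int] | None = None
    sequence_constraint: str | None = None
    excluded_pdb_codes: frozenset[str] = field(default_factory=frozenset)
    limit: tuple[str, int] | None = None
    auto_widen: tuple[int, float, float] | None = None

    def __post_init__(self):
        if self.threshold < 0:
            raise UsageError(f"threshold must be >= 0, got {self.threshold}")
        if self.mask is not None:
            self.mask = frozenset(int(p) for p in self.mask)
            if len(self.mask) < 3:
                raise UsageError(
                    f"mask must select >= 3 residues, got {len(self.mask)}"
                )
            if min(self.mask) < 0:
                raise UsageError("mask positions must be >= 0")
        if self.limit is not None:
            mode, n = self.limit
            if mode not in ("best", "first"):
                raise UsageError(f"limit mode must be 'best' or 'first', got {mode!r}")
            if n < 1:
                raise UsageError(f"limit count must be >= 1, got {n}")
        self.excluded_pdb_codes = frozenset(
            c.upper() for c in self.excluded_pdb_codes
        )

    @property
    def coords(self) -> np.ndarray:
        if isinstance(self.query_fragment, Fragment):
            return self.query_fragment.coords
        return np.asarray(self.query_fragment, dtype=np.float64)

    def query_length(self) -> int:
        c = self.coords
        if c.shape[0] % 4:
            raise DataError(
                f"query coordinate count {c.shape[0]} is not a multiple of 4"
            )
        return c.shape[0] // 4


def _compile_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise InvalidRegexError(pattern, str(exc)) from exc


def _mask_atom_rows(mask: frozenset[int], length: int) -> np.ndarray:
    positions = sorted(mask)
    if positions[-1] >= length:
        raise UsageError(
            f"mask position {positions[-1]} out of range for length {length}"
        )
    rows = []
    for p in positions:
        rows.extend(range(4 * p, 4 * p + 4))
    return np.asarray(rows, dtype=np.intp)


def _passes_filters(
    frag: Fragment,
    excluded: frozenset[str],
    regex: re.Pattern | None,
) -> bool:
    if frag.pdb_code.upper() in excluded:
        return False
    if regex is not None and regex.fullmatch(frag.sequence) is None:
        return False
    return True


def _finalize(matches: list[Match]) -> list[Match]:
    matches.sort(key=lambda m: (m.rmsd, m.fragment_id))
    return matches


def _make_match(frag: Fragment, rmsd: float) -> Match:
    return Match(
        fragment_id=frag.fragment_id,
        pdb_code=frag.pdb_code,
        chain=frag.chain,
        start_residue=frag.start_residue,
        rmsd=float(rmsd),
    )


def query(
    db: FragmentDatabase, index: RmsdIndex, sq: StructuralQuery
) -> list[Match]:
    """Full-length query: prune against the index, then refine exactly.

    Returns matches sorted ascending by RMSD (ties by fragment id),
    identical to a brute-force scan.
    """
    if sq.mask is not None:
        raise UsageError("masked queries use query_masked (the index does not apply)")
    if sq.query_length() != db.fragment_length:
        raise DataError(
            f"query length {sq.query_length()} != "
            f"database fragment length {db.fragment_length}"
        )
    index.check_compatible(db)
    regex = (
        _compile_regex(sq.sequence_constraint)
        if sq.sequence_constraint is not None
        else None
    )

    q = sq.coords
    d_q = sq.threshold

    candidates: np.ndarray | None = None
    for j in range(index.n_references):
        d = qcp_rmsd(q, index.reference_coords[j])
        lo = max(0.0, d - d_q) - STORAGE_EPSILON
        hi = d + d_q + STORAGE_EPSILON
        ids = range_candidates(index, j, lo, hi)
        candidates = (
            np.sort(ids) if candidates is None else np.intersect1d(candidates, ids)
        )
        if candidates.size == 0:
            return []

    surviving = [
        db.fragments[int(i)]
        for i in candidates
        if _passes_filters(db.fragments[int(i)], sq.excluded_pdb_codes, regex)
    ]
    return _refine(db, q, surviving, d_q, sq.limit, None)


def query_masked(db: FragmentDatabase, sq: StructuralQuery) -> list[Match]:
    """Masked (gapped) query: linear scan with the distance restricted to
    the masked residues' backbone atoms."""
    if sq.mask is None:
        raise UsageError("query_masked requires a mask; use query otherwise")
    if sq.query_length() != db.fragment_length:
        raise DataError(
            f"query length {sq.query_length()} != "
            f"database fragment length {db.fragment_length}"
        )
    regex = (
        _compile_regex(sq.sequence_constraint)
        if sq.sequence_constraint is not None
        else None
    )
    rows = _mask_atom_rows(sq.mask, db.fragment_length)
    q = sq.coords[rows]
    surviving = [
        f
        for f in db.fragments
        if _passes_filters(f, sq.excluded_pdb_codes, regex)
    ]
    return _refine(db, q, surviving, sq.threshold, sq.limit, rows)


def _refine(
    db: FragmentDatabase,
    q: np.ndarray,
    candidates: list[Fragment],
    d_q: float,
    limit: tuple[str, int] | None,
    mask_rows: np.ndarray | None,
) -> list[Match]:
    """Exact refinement over candidates in fragment-id order.

    In first-N mode the scan stops as soon as N candidates pass, which
    by id-ordering reproduces a sequential "first found" semantics
    regardless of any internal vectorisation/parallelism.
    """
    candidates = sorted(candidates, key=lambda f: f.fragment_id)
    first_n = limit[1] if limit is not None and limit[0] == "first" else None

    matches: list[Match] = []
    for start in range(0, len(candidates), _REFINE_CHUNK):
        chunk = candidates[start : start + _REFINE_CHUNK]
        ids = [f.fragment_id for f in chunk]
        coords = db.coords_matrix[ids]
        if mask_rows is not None:
            coords = coords[:, mask_rows, :]
        rmsds = qcp_rmsd_many(q, coords)
        for f, r in zip(chunk, rmsds):
            if r <= d_q:
                matches.append(_make_match(f, r))
                if first_n is not None and len(matches) >= first_n:
                    return _finalize(matches)
    matches = _finalize(matches)
    if limit is not None and limit[0] == "best":
        matches = matches[: limit[1]]
    return matches


def apply_limit(matches: list[Match], mode: str, n: int) -> list[Match]:
    """Truncate a sorted match list.

    ``best`` keeps the N smallest RMSDs.  ``first`` keeps the N matches
    that a sequential fragment-id-order refinement scan would have found
    first, then re-sorts them by RMSD.
    """
    if n < 1:
        raise UsageError(f"limit count must be >= 1, got {n}")
    if mode == "best":
        return list(matches[:n])
    if mode == "first":
        by_id = sorted(matches, key=lambda m: m.fragment_id)[:n]
        return _finalize(by_id)
    raise UsageError(f"limit mode must be 'best' or 'first', got {mode!r}")


def query_auto_widen(
    db: FragmentDatabase, index: RmsdIndex, sq: StructuralQuery
) -> QueryResult:
    """Re-run the query at increasing thresholds until ``target`` matches.

    Widens by ``step`` up to ``ceiling``; each iteration equals a fresh
    query at that threshold (thresholds only grow, so match sets are
    nested).  If the ceiling is reached short of the target, the result
    is flagged ``under_target`` — not an error.
    """
    if sq.auto_widen is None:
        raise UsageError("query_auto_widen requires auto_widen parameters")
    target, step, ceiling = sq.auto_widen
    if target < 1:
        raise UsageError(f"auto-widen target must be >= 1, got {target}")
    if step <= 0:
        raise UsageError(f"auto-widen step must be > 0, got {step}")
    if ceiling < sq.threshold:
        raise UsageError(
            f"auto-widen ceiling {ceiling} is below the initial threshold "
            f"{sq.threshold}"
        )

    threshold = sq.threshold
    while True:
        attempt = replace(sq, threshold=threshold, auto_widen=None)
        matches = (
            query_masked(db, attempt) if sq.mask is not None else query(db, index, attempt)
        )
        if len(matches) >= target:
            return QueryResult(matches=matches, threshold=threshold)
        if threshold + step > ceiling:
            return QueryResult(
                matches=matches, threshold=threshold, under_target=True
            )
        threshold += step
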