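"""Reference fragments and precomputed RMSD tables.

For each *reference* fragment r, the index stores the superposition
RMSD from r to every database fragment, sorted ascending.  Because the
RMSD is a metric, any fragment f matching a query q within threshold
d_q must satisfy

    rmsd(f, r) in [rmsd(q, r) - d_q, rmsd(q, r) + d_q]

so a binary-search range query on each table prunes the search space
before any query-time RMSD is computed.  Distances are stored as
float32; callers widen the interval by a small epsilon to make storage
rounding harmless (pruning must never lose a true match).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BadMagicError,
    DataError,
    TruncatedStreamError,
    UsageError,
    VersionMismatchError,
)
from .fragment_store import Fragment, FragmentDatabase, _read_exact
from .geometry import qcp_rmsd_many

__all__ = [
    "ReferenceSet",
    "RmsdIndex",
    "select_references",
    "build_index",
    "range_candidates",
    "write_index",
    "read_index",
    "STORAGE_EPSILON",
]

# outward widening applied to pruning intervals to absorb float32 rounding
STORAGE_EPSILON = 1e-4

INDEX_MAGIC = b"FRGX"
INDEX_VERSION = 1


@dataclass
class ReferenceSet:
    """Ordered reference fragments plus how they were chosen."""

    references: list[Fragment]
    selection_method: str = "given"  # given | random | far-apart
    seed: int | None = None

    def __post_init__(self):
        if not self.references:
            raise UsageError("at least one reference fragment is required")
        lengths = {f.length for f in self.references}
        if len(lengths) != 1:
            raise DataError(f"references have mixed lengths: {sorted(lengths)}")


@dataclass
class RmsdIndex:
    """Per-reference sorted (distance, fragment_id) tables.

    ``distances[j]`` is sorted ascending; ``ids[j]`` carries the
    corresponding fragment ids.  ``db_hash`` binds the index to the
    database it was built from.
    """

    fragment_length: int
    db_hash: str
    reference_ids: list[int]  # -1 when the reference is not a db fragment
    reference_coords: list[np.ndarray] = field(repr=False)
    distances: list[np.ndarray] = field(repr=False)  # float32, sorted
    ids: list[np.ndarray] = field(repr=False)  # int64, parallel to distances

    @property
    def n_references(self) -> int:
        return len(self.distances)

    def check_compatible(self, db: FragmentDatabase) -> None:
        from .errors import IndexMismatchError

        if self.fragment_length != db.fragment_length:
            raise IndexMismatchError(
                f"index length {self.fragment_length} != "
                f"database length {db.fragment_length}"
            )
        if self.db_hash != db.content_hash():
            raise IndexMismatchError(
                "index was built from a different database (content hash mismatch)"
            )


def select_references(db: FragmentDatabase, seed: int) -> ReferenceSet:
    """Far-apart reference heuristic.

    Pick one fragment uniformly at random (seeded), then take the
    fragment furthest from it and the fragment at the (lower) median of
    the same distance list.  Ties resolve to the lowest fragment id.
    Deterministic given (db, seed).
    """
    n = len(db.fragments)
    if n < 3:
        raise UsageError(f"reference selection needs >= 3 fragments, got {n}")
    rng = np.random.default_rng(seed)
    i = int(rng.integers(n))
    f_i = db.fragments[i]

    d = qcp_rmsd_many(f_i.coords, db.coords_matrix)

    d_max = d.max()
    j = int(np.flatnonzero(d == d_max).min())  # lowest id on ties

    order = np.argsort(d, kind="stable")  # stable => id order within ties
    med_pos = (n - 1) // 2  # lower median
    d_med = d[order[med_pos]]
    k = int(np.flatnonzero(d == d_med).min())

    return ReferenceSet(
        references=[f_i, db.fragments[j], db.fragments[k]],
        selection_method="far-apart",
        seed=seed,
    )


def build_index(db: FragmentDatabase, refs: ReferenceSet) -> RmsdIndex:
    """Compute, sort and store each reference's distances to all fragments."""
    if refs.references[0].length != db.fragment_length:
        raise DataError(
            f"reference length {refs.references[0].length} != "
            f"database fragment length {db.fragment_length}"
        )
    coords = db.coords_matrix
    distances, ids, ref_ids = [], [], []
    for ref in refs.references:
        d = qcp_rmsd_many(ref.coords, coords).astype(np.float32)
        order = np.argsort(d, kind="stable")
        distances.append(d[order])
        ids.append(order.astype(np.int64))
        # record provenance when the reference is itself a db fragment
        rid = ref.fragment_id
        is_db = (
            0 <= rid < len(db.fragments)
            and db.fragments[rid] is ref
        )
        ref_ids.append(rid if is_db else -1)
    return RmsdIndex(
        fragment_length=db.fragment_length,
        db_hash=db.content_hash(),
        reference_ids=ref_ids,
        reference_coords=[ref.coords.copy() for ref in refs.references],
        distances=distances,
        ids=ids,
    )


def range_candidates(
    index: RmsdIndex, ref_ordinal: int, d_inf: float, d_sup: float
) -> np.ndarray:
    """Fragment ids whose stored distance to reference ``ref_ordinal``
    lies in the closed interval [d_inf, d_sup].  O(log n + k)."""
    if not 0 <= ref_ordinal < index.n_references:
        raise UsageError(
            f"reference ordinal {ref_ordinal} out of range "
            f"(index has {index.n_references} references)"
        )
    if d_inf > d_sup:
        raise UsageError(f"empty interval: d_inf {d_inf} > d_sup {d_sup}")
    table = index.distances[ref_ordinal]
    lo = int(np.searchsorted(table, d_inf, side="left"))
    hi = int(np.searchsorted(table, d_sup, side="right"))
    return index.ids[ref_ordinal][lo:hi]


# ---------------------------------------------------------------------------
# Persistence: magic "FRGX", version u16, fragment length u32,
# n_refs u32, n_frags u64, db hash (64 hex bytes); per reference:
# reference id i64, coords 4*L*3 float32, then distances float32[n] and
# ids int64[n].

_IDX_HEADER = struct.Struct("<4sHIIQ64s")


def write_index(index: RmsdIndex, sink) -> None:
    from pathlib import Path

    own = isinstance(sink, (str, Path))
    fh = open(sink, "wb") if own else sink
    try:
        n = len(index.distances[0]) if index.distances else 0
        fh.write(
            _IDX_HEADER.pack(
                INDEX_MAGIC,
                INDEX_VERSION,
                index.fragment_length,
                index.n_references,
                n,
                index.db_hash.encode("ascii"),
            )
        )
        for j in range(index.n_references):
            fh.write(struct.pack("<q", index.reference_ids[j]))
            fh.write(
                np.ascontiguousarray(
                    index.reference_coords[j], dtype=np.float32
                ).tobytes()
            )
            fh.write(np.ascontiguousarray(index.distances[j]).tobytes())
            fh.write(np.ascontiguousarray(index.ids[j]).tobytes())
    finally:
        if own:
            fh.close()


def read_index(source) -> RmsdIndex:
    from pathlib import Path

    own = isinstance(source, (str, Path))
    fh = open(source, "rb") if own else source
    try:
        head = _read_exact(fh, _IDX_HEADER.size, "index header")
        magic, version, length, n_refs, n, db_hash = _IDX_HEADER.unpack(head)
        if magic != INDEX_MAGIC:
            raise BadMagicError(f"bad magic {magic!r}; not an index stream")
        if version != INDEX_VERSION:
            raise VersionMismatchError(
                f"unsupported index format version {version} "
                f"(supported: {INDEX_VERSION})"
            )
        ref_ids, ref_coords, distances, ids = [], [], [], []
        for j in range(n_refs):
            buf = _read_exact(fh, 8, f"reference {j} id", ordinal=j)
            (rid,) = struct.unpack("<q", buf)
            ref_ids.append(rid)
            nc = 4 * length * 3
            buf = _read_exact(fh, nc * 4, f"reference {j} coords", ordinal=j)
            ref_coords.append(
                np.frombuffer(buf, dtype="<f4").astype(np.float64).reshape(-1, 3)
            )
            buf = _read_exact(fh, n * 4, f"reference {j} distances", ordinal=j)
            distances.append(np.frombuffer(buf, dtype="<f4").copy())
            buf = _read_exact(fh, n * 8, f"reference {j} ids", ordinal=j)
            ids.append(np.frombuffer(buf, dtype="<i8").copy())
        return RmsdIndex(
            fragment_length=length,
            db_hash=db_hash.decode("ascii"),
            reference_ids=ref_ids,
            reference_coords=ref_coords,
            distances=distances,
            ids=ids,
        )
    finally:
        if own:
            fh.close()
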