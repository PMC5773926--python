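"""One-versus-many backbone RMSD ranking.

Usable without any database or index: point it at a query fragment and
a pool (loose PDB files or a binary database) and get every pool member
ranked by superposition RMSD.  Shares the QCP kernel and mask semantics
with the query engine.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import DataError, IncompatibleFragmentsError, PdbParseError, UsageError
from .fragment_store import (
    Fragment,
    FragmentDatabase,
    parse_pdb_file,
    read_binary,
)
from .geometry import qcp_rmsd_many

__all__ = ["rank_one_vs_many", "rank_from_files", "fragment_from_pdb_file"]


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, Fragment):
        return obj.coords
    return np.asarray(obj, dtype=np.float64)


def _masked(coords: np.ndarray, mask_rows: np.ndarray | None) -> np.ndarray:
    return coords if mask_rows is None else coords[mask_rows]


def _mask_rows(mask, length: int) -> np.ndarray | None:
    if mask is None:
        return None
    positions = sorted(int(p) for p in mask)
    if len(positions) < 3:
        raise UsageError(f"mask must select >= 3 residues, got {len(positions)}")
    if positions[0] < 0 or positions[-1] >= length:
        raise UsageError(f"mask positions out of range for length {length}")
    rows = []
    for p in positions:
        rows.extend(range(4 * p, 4 * p + 4))
    return np.asarray(rows, dtype=np.intp)


def rank_one_vs_many(
    query, pool, mask=None
) -> list[tuple[int, float]]:
    """RMSD of ``query`` against every pool member, sorted ascending.

    ``query`` and pool members are :class:`Fragment` objects or (4L, 3)
    coordinate arrays.  ``mask`` selects query residue positions
    (0-based); pool members must have the same masked atom count.
    Returns (pool ordinal, rmsd) pairs; ties break on ordinal.
    """
    qc = _coords_of(query)
    if qc.shape[0] % 4:
        raise DataError(f"query atom count {qc.shape[0]} is not a multiple of 4")
    rows = _mask_rows(mask, qc.shape[0] // 4)
    qm = _masked(qc, rows)

    if len(pool) == 0:
        return []
    coords = []
    for ordinal, member in enumerate(pool):
        c = _masked(_coords_of(member), rows)
        if c.shape != qm.shape:
            raise IncompatibleFragmentsError(
                f"pool member {ordinal} has {c.shape[0]} (masked) atoms, "
                f"query has {qm.shape[0]}"
            )
        coords.append(c)
    rmsds = qcp_rmsd_many(qm, np.stack(coords))
    order = np.lexsort((np.arange(len(rmsds)), rmsds))
    return [(int(i), float(rmsds[i])) for i in order]


def fragment_from_pdb_file(path) -> Fragment:
    """Read a PDB file as a single fragment (first chain, all residues)."""
    rec = parse_pdb_file(path)
    if not rec.chains:
        raise PdbParseError(f"no backbone residues in {path}")
    chain_id, residues = rec.chains[0]
    return Fragment(
        fragment_id=0, pdb_code=rec.pdb_code, chain=chain_id, residues=residues
    )


def _load_pool(pool_source) -> tuple[list[Fragment], list[str]]:
    """Pool from a directory of PDB files (sorted by name), a list of
    paths, or a binary database path/object."""
    if isinstance(pool_source, FragmentDatabase):
        db = pool_source
        return db.fragments, [
            f"{f.pdb_code}:{f.chain}:{f.start_residue[0]}" for f in db.fragments
        ]
    p = Path(pool_source) if isinstance(pool_source, (str, Path)) else None
    if p is not None and p.is_dir():
        paths = sorted(p.glob("*.pdb"))
        frags = [fragment_from_pdb_file(fp) for fp in paths]
        return frags, [fp.name for fp in paths]
    if p is not None and p.is_file():
        db = read_binary(p)
        return db.fragments, [
            f"{f.pdb_code}:{f.chain}:{f.start_residue[0]}" for f in db.fragments
        ]
    if isinstance(pool_source, (list, tuple)):
        frags = [fragment_from_pdb_file(fp) for fp in pool_source]
        return frags, [str(fp) for fp in pool_source]
    raise UsageError(f"cannot interpret pool source {pool_source!r}")


def rank_from_files(query_pdb, pool_source, mask=None, sink=None) -> list[dict]:
    """Parse the inputs, rank, and optionally write a TSV.

    ``pool_source`` is a directory of PDB files, a list of PDB paths, a
    binary database path, or a :class:`FragmentDatabase`.  Returns rows
    of ``{ordinal, provenance, rmsd}``; when ``sink`` is given, also
    writes tab-separated ``rank, ordinal, provenance, rmsd``.
    """
    query = fragment_from_pdb_file(query_pdb)
    pool, provenance = _load_pool(pool_source)
    ranked = rank_one_vs_many(query, pool, mask=mask)
    rows = [
        {"ordinal": i, "provenance": provenance[i], "rmsd": r} for i, r in ranked
    ]
    if sink is not None:
        own = isinstance(sink, (str, Path))
        fh = open(sink, "w") if own else sink
        try:
            fh.write("rank\tordinal\tprovenance\trmsd\n")
            for rank, row in enumerate(rows, start=1):
                fh.write(
                    f"{rank}\t{row['ordinal']}\t{row['provenance']}\t"
                    f"{row['rmsd']:.6f}\n"
                )
        finally:
            if own:
                fh.close()
    return rows
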