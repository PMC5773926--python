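"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's query path: brute
force scans use their own RMSD loop (Kabsch where affordable), their
own filtering and their own sort, so agreement with the engine is a
genuine dual-route check.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from fragpick.fragment_store import database_from_fragments, extract_fragments
from fragpick.fixtures import make_decoy_pool, make_helix_chain
from fragpick.geometry import kabsch_rmsd, qcp_rmsd_many


@pytest.fixture(scope="session")
def helix_record():
    return make_helix_chain(30, seed=11, jitter=0.05)


@pytest.fixture(scope="session")
def helix_db(helix_record):
    return extract_fragments([helix_record], 9)


@pytest.fixture(scope="session")
def base_fragment(helix_db):
    return helix_db.fragments[0]


@pytest.fixture(scope="session")
def decoy_db(base_fragment):
    """300 decoys at mixed noise levels, varied sequences and PDB codes."""
    rng = np.random.default_rng(42)
    sigmas = rng.uniform(0.05, 2.5, size=300)
    decoys = make_decoy_pool(
        base_fragment, 300, sigmas, seed=43, vary_sequence=True
    )
    return database_from_fragments(decoys)


@pytest.fixture(scope="session")
def decoy_index(decoy_db):
    from fragpick.index import build_index, select_references

    return build_index(decoy_db, select_references(decoy_db, seed=7))


def brute_force_matches(
    db,
    query_coords: np.ndarray,
    threshold: float,
    mask_rows: np.ndarray | None = None,
    excluded: frozenset[str] = frozenset(),
    regex: str | None = None,
    use_kabsch: bool = False,
):
    """Independent linear-scan oracle.

    Returns [(fragment_id, rmsd), ...] sorted by (rmsd, id).  With
    ``use_kabsch`` the distances come from the SVD implementation, making
    the oracle fully independent of the QCP kernel.
    """
    pat = re.compile(regex) if regex is not None else None
    q = query_coords if mask_rows is None else query_coords[mask_rows]
    out = []
    if use_kabsch:
        for f in db.fragments:
            if f.pdb_code.upper() in excluded:
                continue
            if pat is not None and pat.fullmatch(f.sequence) is None:
                continue
            c = f.coords if mask_rows is None else f.coords[mask_rows]
            r = kabsch_rmsd(q, c)
            if r <= threshold:
                out.append((f.fragment_id, r))
    else:
        coords = db.coords_matrix
        if mask_rows is not None:
            coords = coords[:, mask_rows, :]
        rmsds = qcp_rmsd_many(q, coords)
        for f, r in zip(db.fragments, rmsds):
            if f.pdb_code.upper() in excluded:
                continue
            if pat is not None and pat.fullmatch(f.sequence) is None:
                continue
            if r <= threshold:
                out.append((f.fragment_id, float(r)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def mask_rows_for(mask, length: int) -> np.ndarray:
    rows = []
    for p in sorted(mask):
        assert 0 <= p < length
        rows.extend(range(4 * p, 4 * p + 4))
    return np.asarray(rows, dtype=np.intp)
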