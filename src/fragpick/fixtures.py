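"""Deterministic synthetic structures for tests, demos and benchmarks.

Backbones are grown atom-by-atom from ideal internal coordinates
(bond lengths N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231 Å, standard
angles) with helical torsions, so peptide-bond continuity holds by
construction.  Everything is reproducible from (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .errors import UsageError
from .fragment_store import (
    BackboneResidue,
    Fragment,
    PdbRecord,
    record_to_pdb,
)

__all__ = [
    "make_helix_chain",
    "make_break_chain",
    "make_decoy_pool",
    "record_to_pdb",
]

# ideal backbone internal coordinates
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5
_PHI = -57.0
_PSI = -47.0
_OMEGA = 180.0

_CYCLE = "ACDEFGHIKLMNPQRSTVWY"


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a new atom from three predecessors and internal coords
    (natural extension of reference frame)."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _helix_backbone(n_residues: int) -> np.ndarray:
    """(n, 4, 3) ideal helical backbone, atoms N, CA, C, O."""
    n_atoms = []
    ca_atoms = []
    c_atoms = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    n_atoms.append(n0)
    ca_atoms.append(ca0)
    c_atoms.append(c0)
    for _ in range(1, n_residues):
        nn = _place_atom(n_atoms[-1], ca_atoms[-1], c_atoms[-1], _B_C_N, _A_CA_C_N, _PSI)
        nca = _place_atom(ca_atoms[-1], c_atoms[-1], nn, _B_N_CA, _A_C_N_CA, _OMEGA)
        nc = _place_atom(c_atoms[-1], nn, nca, _B_CA_C, _A_N_CA_C, _PHI)
        n_atoms.append(nn)
        ca_atoms.append(nca)
        c_atoms.append(nc)
    out = np.empty((n_residues, 4, 3))
    for i in range(n_residues):
        out[i, 0] = n_atoms[i]
        out[i, 1] = ca_atoms[i]
        out[i, 2] = c_atoms[i]
        # carbonyl O in the peptide plane, opposite the next N
        out[i, 3] = _place_atom(
            n_atoms[i], ca_atoms[i], c_atoms[i], _B_C_O, _A_CA_C_O, _PSI + 180.0
        )
    return out


def _residues_from_coords(
    coords: np.ndarray,
    chain_id: str,
    sequence: str,
    start_number: int = 1,
) -> list[BackboneResidue]:
    return [
        BackboneResidue(
            amino_acid=sequence[i],
            atoms=coords[i],
            residue_id=(chain_id, start_number + i, " "),
        )
        for i in range(coords.shape[0])
    ]


def _resolve_sequence(n: int, sequence: str | None) -> str:
    if sequence is None:
        return "".join(_CYCLE[i % len(_CYCLE)] for i in range(n))
    if len(sequence) != n:
        raise UsageError(
            f"sequence length {len(sequence)} != residue count {n}"
        )
    return sequence


def make_helix_chain(
    n_residues: int,
    chain_id: str = "A",
    seed: int = 0,
    jitter: float = 0.0,
    sequence: str | None = None,
    pdb_code: str = "HLX1",
) -> PdbRecord:
    """Ideal helical chain, optionally with Gaussian coordinate jitter.

    With ``jitter <= 0.1`` Å the continuity check passes by
    construction.  Sequence defaults to cycling through the 20 letters.
    """
    if n_residues < 3:
        raise UsageError(f"need >= 3 residues, got {n_residues}")
    coords = _helix_backbone(n_residues)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    seq = _resolve_sequence(n_residues, sequence)
    residues = _residues_from_coords(coords, chain_id, seq)
    return PdbRecord(
        pdb_code=pdb_code, path="<synthetic>", chains=[(chain_id, residues)]
    )


def make_break_chain(
    run_lengths: list[int],
    gap: float = 5.0,
    chain_id: str = "A",
    seed: int = 0,
    jitter: float = 0.0,
    sequence: str | None = None,
    pdb_code: str = "BRK1",
) -> PdbRecord:
    """Chain made of helical runs separated by a controlled C-N gap.

    Each run is displaced along the previous C->N direction so the
    distance between the last C of run k and the first N of run k+1 is
    exactly ``gap`` Å.  Residue numbering is continuous across runs
    (numbering is deliberately untrustworthy for continuity).
    """
    if not run_lengths or any(m < 1 for m in run_lengths):
        raise UsageError(f"run lengths must be positive, got {run_lengths}")
    total = sum(run_lengths)
    coords = _helix_backbone(total)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    start = 0
    shift = np.zeros(3)
    shifted = coords.copy()
    for m in run_lengths[:-1]:
        prev_c = shifted[start + m - 1, 2]
        next_n = coords[start + m, 0] + shift
        v = next_n - prev_c
        d0 = np.linalg.norm(v)
        shift = shift + (gap - d0) * (v / d0)
        shifted[start + m :] = coords[start + m :] + shift
        start += m
    seq = _resolve_sequence(total, sequence)
    residues = _residues_from_coords(shifted, chain_id, seq)
    return PdbRecord(
        pdb_code=pdb_code, path="<synthetic>", chains=[(chain_id, residues)]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_decoy_pool(
    base: Fragment,
    n: int,
    sigma,
    seed: int = 0,
    vary_sequence: bool = False,
    pdb_code_prefix: str = "D",
) -> list[Fragment]:
    """``n`` jittered, rigidly moved copies of ``base``.

    ``sigma`` is the per-coordinate Gaussian noise (scalar, or one value
    per decoy for a controlled distance spread); the subsequent random
    rigid motion leaves the superposition RMSD untouched, so the
    expected RMSD to ``base`` scales with sigma.  PDB codes cycle
    ``<prefix>000 .. <prefix>999`` so exclusion filters have something
    to bite on; ``vary_sequence`` draws random sequences for regex
    filters.
    """
    if n < 0:
        raise UsageError(f"decoy count must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=np.float64), (n,))
    length = base.length
    base_coords = base.coords.reshape(length, 4, 3)
    decoys: list[Fragment] = []
    for i in range(n):
        coords = base_coords + rng.normal(scale=max(sigmas[i], 0), size=base_coords.shape)
        rot = _random_rotation(rng)
        t = rng.uniform(-50, 50, size=3)
        coords = coords @ rot.T + t
        if vary_sequence:
            seq = "".join(rng.choice(list(_CYCLE), size=length))
        else:
            seq = base.sequence
        residues = [
            BackboneResidue(
                amino_acid=seq[j],
                atoms=coords[j],
                residue_id=("A", j + 1, " "),
            )
            for j in range(length)
        ]
        decoys.append(
            Fragment(
                fragment_id=i,
                pdb_code=f"{pdb_code_prefix}{i % 1000:03d}",
                chain="A",
                residues=residues,
            )
        )
    return decoys
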