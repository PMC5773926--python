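"""Fragment extraction, representation and persistence.

A *fragment* is a fixed-length window of consecutive, peptide-bonded
residues from a single protein chain, represented by its 4-atom
backbone (N, CA, C, O) plus sequence and provenance.  A
:class:`FragmentDatabase` holds every such window of one length
extracted from a set of PDB files, and can be persisted to a compact
binary format that is much faster to reload than re-parsing PDB text.

PDB files are parsed with Biopython.  Cleanup rules (this package has
no external structure-preparation dependency):

* first model only in multi-model files;
* standard amino acids plus MSE (mapped to ``M``); other het residues
  are skipped;
* residues missing any of the 4 backbone atoms are skipped;
* for alternate locations, altloc ``' '`` or ``'A'`` is kept;
* residues i, i+1 are continuous iff ``|C_i - N_{i+1}| <= 2.0`` Å —
  author numbering is never trusted for continuity.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    BadMagicError,
    DataError,
    PdbParseError,
    TruncatedStreamError,
    UsageError,
    VersionMismatchError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneResidue",
    "Fragment",
    "FragmentDatabase",
    "PdbRecord",
    "parse_pdb_file",
    "extract_fragments",
    "database_from_fragments",
    "write_binary",
    "read_binary",
    "fragment_to_pdb",
    "record_to_pdb",
    "get_random_fragments",
    "BACKBONE_ATOMS",
    "CONTINUITY_CUTOFF",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
ATOM_CONVENTION = "N,CA,C,O"
CONTINUITY_CUTOFF = 2.0  # Å between C(i) and N(i+1); peptide bond ~1.33 Å

MAGIC = b"FRGR"
FORMAT_VERSION = 1
_ATOM_CONVENTION_TAG = 0  # 0 = N,CA,C,O

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, modelled as MET
}
AA1TO3 = {one: three for three, one in AA3TO1.items() if three != "MSE"}
AA1TO3["X"] = "UNK"
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class BackboneResidue:
    """One residue reduced to its 4 backbone atoms.

    ``atoms`` is a (4, 3) float array ordered N, CA, C, O (Å);
    ``residue_id`` is (chain id, residue sequence number, insertion code).
    """

    amino_acid: str
    atoms: np.ndarray
    residue_id: tuple[str, int, str]

    def __post_init__(self):
        arr = np.asarray(self.atoms, dtype=np.float64)
        if arr.shape != (4, 3):
            raise DataError(f"backbone residue needs (4, 3) atoms, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DataError("backbone residue has non-finite coordinates")
        if self.amino_acid not in VALID_AA:
            raise DataError(f"invalid one-letter amino acid {self.amino_acid!r}")
        object.__setattr__(self, "atoms", arr)


@dataclass
class Fragment:
    """A window of L consecutive residues from one chain."""

    fragment_id: int
    pdb_code: str
    chain: str
    residues: list[BackboneResidue]
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def start_residue(self) -> tuple[int, str]:
        """(sequence number, insertion code) of the first residue."""
        _, num, icode = self.residues[0].residue_id
        return (num, icode)

    @property
    def coords(self) -> np.ndarray:
        """(4L, 3) backbone coordinates, residue-major, atom order N,CA,C,O."""
        if self._coords is None:
            self._coords = np.concatenate([r.atoms for r in self.residues])
        return self._coords


@dataclass
class PdbRecord:
    """A parsed structure reduced to backbone residues per chain."""

    pdb_code: str
    path: str
    chains: list[tuple[str, list[BackboneResidue]]]


@dataclass
class FragmentDatabase:
    """All fragments of one length, with provenance manifest."""

    fragment_length: int
    fragments: list[Fragment]
    source_manifest: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    _coords_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.params:
            self.params = {
                "length": self.fragment_length,
                "atom_convention": ATOM_CONVENTION,
                "continuity_cutoff": CONTINUITY_CUTOFF,
            }

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def coords_matrix(self) -> np.ndarray:
        """(n, 4L, 3) stack of all fragment coordinates (cached)."""
        if self._coords_matrix is None:
            if self.fragments:
                self._coords_matrix = np.stack([f.coords for f in self.fragments])
            else:
                self._coords_matrix = np.empty(
                    (0, 4 * self.fragment_length, 3), dtype=np.float64
                )
        return self._coords_matrix

    @property
    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]

    def content_hash(self) -> str:
        """SHA-256 over the canonical fragment payload (manifest excluded,
        so the hash is stable across file relocations)."""
        h = hashlib.sha256()
        h.update(struct.pack("<IQ", self.fragment_length, len(self.fragments)))
        for f in self.fragments:
            h.update(_pack_fragment(f, self.fragment_length))
        return h.hexdigest()

    def fragment_by_location(
        self, pdb_code: str, chain: str, start: int, icode: str = " "
    ) -> Fragment:
        """Look up a fragment by provenance handle."""
        code = pdb_code.upper()
        for f in self.fragments:
            if (
                f.pdb_code == code
                and f.chain == chain
                and f.start_residue == (start, icode)
            ):
                return f
        raise DataError(
            f"no fragment at {pdb_code}:{chain}:{start}{icode.strip()}"
        )


# ---------------------------------------------------------------------------
# PDB parsing

def _pdb_code_from(path: Path, header_code: str | None) -> str:
    if header_code and len(header_code.strip()) == 4:
        return header_code.strip().upper()
    return path.stem[:4].upper().ljust(4, "_")


def _pick_atom(residue, name: str):
    """Return the Atom for ``name`` honouring the altloc policy, or None."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        for alt in (" ", "A"):
            if atom.disordered_has_id(alt):
                return atom.disordered_get(alt)
        return None
    return atom


def parse_pdb_file(path, pdb_code: str | None = None) -> PdbRecord:
    """Parse a PDB file into backbone residues per chain.

    Applies the cleanup rules in the module docstring.  The PDB code is
    taken from the HEADER record when present, else from the file stem.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted types
        raise PdbParseError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise PdbParseError(f"no models in {path}")
    model = models[0]  # first MODEL only

    code = pdb_code or _pdb_code_from(path, structure.header.get("idcode"))
    code = code.upper()[:4].ljust(4, "_")

    chains: list[tuple[str, list[BackboneResidue]]] = []
    for chain in model:
        residues: list[BackboneResidue] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            resname = res.get_resname().strip()
            if resname not in AA3TO1:
                continue
            if hetflag not in (" ", "H_MSE"):
                continue
            atoms = [_pick_atom(res, name) for name in BACKBONE_ATOMS]
            if any(a is None for a in atoms):
                continue
            coords = np.array([a.coord for a in atoms], dtype=np.float64)
            residues.append(
                BackboneResidue(
                    amino_acid=AA3TO1[resname],
                    atoms=coords,
                    residue_id=(chain.id, int(resseq), icode),
                )
            )
        if residues:
            chains.append((chain.id, residues))
    return PdbRecord(pdb_code=code, path=str(path), chains=chains)


# ---------------------------------------------------------------------------
# Extraction

def _continuity_runs(residues: list[BackboneResidue]) -> list[list[BackboneResidue]]:
    """Split a chain into maximal runs of peptide-bonded residues."""
    runs: list[list[BackboneResidue]] = []
    current: list[BackboneResidue] = []
    for res in residues:
        if current:
            c_prev = current[-1].atoms[2]  # C
            n_here = res.atoms[0]  # N
            if np.linalg.norm(n_here - c_prev) > CONTINUITY_CUTOFF:
                runs.append(current)
                current = []
        current.append(res)
    if current:
        runs.append(current)
    return runs


def extract_fragments(records: list[PdbRecord], length: int) -> FragmentDatabase:
    """Slide a window of ``length`` residues over every continuity run.

    Fragments are emitted in deterministic order: record order, then
    chain order, then window start.  Windows never span a chain break.
    """
    if length < 3:
        raise UsageError(f"fragment length must be >= 3, got {length}")
    if not records:
        raise UsageError("at least one input structure is required")

    fragments: list[Fragment] = []
    manifest: list[dict] = []
    for rec in records:
        before = len(fragments)
        for chain_id, residues in rec.chains:
            for run in _continuity_runs(residues):
                for start in range(len(run) - length + 1):
                    window = run[start : start + length]
                    fragments.append(
                        Fragment(
                            fragment_id=len(fragments),
                            pdb_code=rec.pdb_code,
                            chain=chain_id,
                            residues=window,
                        )
                    )
        contributed = len(fragments) - before
        manifest.append(
            {
                "pdb_code": rec.pdb_code,
                "path": rec.path,
                "chain_count": len(rec.chains),
                "fragment_count": contributed,
            }
        )
        if contributed == 0:
            warnings.warn(
                f"structure {rec.pdb_code} ({rec.path}) contributed no fragments "
                f"at length {length}",
                stacklevel=2,
            )
    logger.info("extracted %d fragments of length %d", len(fragments), length)
    return FragmentDatabase(
        fragment_length=length, fragments=fragments, source_manifest=manifest
    )


def database_from_fragments(
    fragments: list[Fragment], length: int | None = None
) -> FragmentDatabase:
    """Build a database from ready-made fragments, renumbering ids 0..n-1."""
    if length is None:
        if not fragments:
            raise UsageError("length required for an empty fragment list")
        length = fragments[0].length
    renumbered = []
    for i, f in enumerate(fragments):
        if f.length != length:
            raise DataError(
                f"fragment {i} has length {f.length}, database length is {length}"
            )
        renumbered.append(
            Fragment(
                fragment_id=i,
                pdb_code=f.pdb_code,
                chain=f.chain,
                residues=f.residues,
            )
        )
    return FragmentDatabase(fragment_length=length, fragments=renumbered)


# ---------------------------------------------------------------------------
# Binary format
#
# Little-endian.  Header: magic "FRGR", version u16, atom-convention u8,
# fragment length u32, fragment count u64, metadata length u32 + UTF-8
# JSON (manifest + creation params).  Per fragment: pdb_code 4 bytes,
# chain 1 byte, L x (resseq i32 + icode u8), sequence L bytes,
# coordinates 4*L*3 float32.  Per-residue numbering is stored (not just
# the window start) so insertion-coded and gap-numbered fragments
# round-trip losslessly.

_HEADER = struct.Struct("<4sHBIQ")


def _pack_fragment(f: Fragment, length: int) -> bytes:
    parts = [
        f.pdb_code.encode("ascii")[:4].ljust(4, b"_"),
        f.chain.encode("ascii")[:1].ljust(1, b" "),
    ]
    for r in f.residues:
        _, num, icode = r.residue_id
        parts.append(struct.pack("<iB", num, ord(icode[:1] or " ")))
    parts.append(f.sequence.encode("ascii"))
    coords = np.ascontiguousarray(f.coords, dtype=np.float32)
    parts.append(coords.tobytes())
    return b"".join(parts)


def _fragment_nbytes(length: int) -> int:
    return 4 + 1 + 5 * length + length + 12 * length * 4


def write_binary(db: FragmentDatabase, sink) -> None:
    """Serialize a database to ``sink`` (path or binary file object)."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "wb") if own else sink
    try:
        meta = json.dumps(
            {"source_manifest": db.source_manifest, "params": db.params}
        ).encode("utf-8")
        fh.write(
            _HEADER.pack(
                MAGIC,
                FORMAT_VERSION,
                _ATOM_CONVENTION_TAG,
                db.fragment_length,
                len(db.fragments),
            )
        )
        fh.write(struct.pack("<I", len(meta)))
        fh.write(meta)
        for f in db.fragments:
            fh.write(_pack_fragment(f, db.fragment_length))
    finally:
        if own:
            fh.close()


def _read_exact(fh, n: int, what: str, ordinal: int | None = None) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise TruncatedStreamError(
            f"stream truncated while reading {what} "
            f"(wanted {n} bytes, got {len(buf)})",
            ordinal=ordinal,
        )
    return buf


def read_binary(source) -> FragmentDatabase:
    """Deserialize a database written by :func:`write_binary`."""
    own = isinstance(source, (str, Path))
    fh = open(source, "rb") if own else source
    try:
        head = _read_exact(fh, _HEADER.size, "header")
        magic, version, conv, length, count = _HEADER.unpack(head)
        if magic != MAGIC:
            raise BadMagicError(
                f"bad magic {magic!r}; not a fragment database stream"
            )
        if version != FORMAT_VERSION:
            raise VersionMismatchError(
                f"unsupported database format version {version} "
                f"(supported: {FORMAT_VERSION})"
            )
        if conv != _ATOM_CONVENTION_TAG:
            raise VersionMismatchError(f"unsupported atom convention tag {conv}")
        (meta_len,) = struct.unpack("<I", _read_exact(fh, 4, "metadata length"))
        meta = json.loads(_read_exact(fh, meta_len, "metadata").decode("utf-8"))

        frag_size = _fragment_nbytes(length)
        fragments: list[Fragment] = []
        for i in range(count):
            buf = _read_exact(fh, frag_size, f"fragment {i}", ordinal=i)
            off = 0
            pdb_code = buf[off : off + 4].decode("ascii")
            off += 4
            chain = buf[off : off + 1].decode("ascii")
            off += 1
            rids = []
            for _ in range(length):
                num, ic = struct.unpack_from("<iB", buf, off)
                rids.append((num, chr(ic)))
                off += 5
            seq = buf[off : off + length].decode("ascii")
            off += length
            coords = np.frombuffer(
                buf, dtype="<f4", count=12 * length, offset=off
            ).reshape(4 * length, 3).astype(np.float64)
            residues = [
                BackboneResidue(
                    amino_acid=seq[j],
                    atoms=coords[4 * j : 4 * j + 4],
                    residue_id=(chain, rids[j][0], rids[j][1]),
                )
                for j in range(length)
            ]
            fragments.append(
                Fragment(
                    fragment_id=i, pdb_code=pdb_code, chain=chain, residues=residues
                )
            )
        return FragmentDatabase(
            fragment_length=length,
            fragments=fragments,
            source_manifest=meta.get("source_manifest", []),
            params=meta.get("params", {}),
        )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# PDB output

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _atom_records(residues, chain: str, serial_start: int = 1):
    serial = serial_start
    out = []
    for r in residues:
        _, num, icode = r.residue_id
        resname = AA1TO3[r.amino_acid]
        for name, xyz in zip(BACKBONE_ATOMS, r.atoms):
            out.append(
                _ATOM_FMT.format(
                    serial=serial,
                    name=f" {name}" if len(name) < 4 else name,
                    altloc=" ",
                    resname=resname,
                    chain=chain,
                    resseq=num,
                    icode=icode,
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    occ=1.00,
                    b=0.00,
                    element=name[0],
                )
            )
            serial += 1
    return out, serial


def fragment_to_pdb(f: Fragment, sink) -> None:
    """Write a fragment as standard ATOM records + TER + END."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        records, serial = _atom_records(f.residues, f.chain)
        fh.writelines(records)
        last = f.residues[-1]
        _, num, icode = last.residue_id
        fh.write(
            f"TER   {serial:>5d}      {AA1TO3[last.amino_acid]:>3s} "
            f"{f.chain:1s}{num:>4d}{icode:1s}\n"
        )
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def record_to_pdb(rec: PdbRecord, sink, omit: set | None = None) -> None:
    """Write a parsed record back to PDB text.

    ``omit`` is a set of (chain_id, resseq, atom_name) triples to drop —
    used by fixtures to fabricate missing-atom structures.
    """
    omit = omit or set()
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        serial = 1
        for chain_id, residues in rec.chains:
            for r in residues:
                _, num, icode = r.residue_id
                resname = AA1TO3[r.amino_acid]
                for name, xyz in zip(BACKBONE_ATOMS, r.atoms):
                    if (chain_id, num, name) in omit:
                        continue
                    fh.write(
                        _ATOM_FMT.format(
                            serial=serial,
                            name=f" {name}" if len(name) < 4 else name,
                            altloc=" ",
                            resname=resname,
                            chain=chain_id,
                            resseq=num,
                            icode=icode,
                            x=xyz[0],
                            y=xyz[1],
                            z=xyz[2],
                            occ=1.00,
                            b=0.00,
                            element=name[0],
                        )
                    )
                    serial += 1
            if residues:
                last = residues[-1]
                _, num, icode = last.residue_id
                fh.write(
                    f"TER   {serial:>5d}      {AA1TO3[last.amino_acid]:>3s} "
                    f"{chain_id:1s}{num:>4d}{icode:1s}\n"
                )
                serial += 1
        fh.write("END\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------

def get_random_fragments(db: FragmentDatabase, n: int, seed: int) -> list[Fragment]:
    """Sample ``n`` distinct fragments uniformly without replacement."""
    if n < 0:
        raise UsageError(f"sample size must be >= 0, got {n}")
    if n > len(db.fragments):
        raise UsageError(
            f"cannot sample {n} fragments from a database of {len(db.fragments)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(db.fragments), size=n, replace=False)
    return [db.fragments[int(i)] for i in idx]
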