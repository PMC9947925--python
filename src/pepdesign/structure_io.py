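"""PDB backbone I/O and 3-state secondary-structure assignment.

Only backbone atoms (N, CA, C, O) are retained; residues missing any of the
four are dropped at parse time and counted. HETATM records, waters and
non-canonical residues are excluded. Secondary structure is assigned from
backbone dihedrals with a dependency-free phi/psi binning scheme followed by
a run-length smoothing pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .constants import ONE_TO_THREE, THREE_TO_ONE

logger = logging.getLogger(__name__)

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for unreadable or empty structures."""


@dataclass
class BackboneResidue:
    """One residue reduced to its four backbone atoms.

    Coordinates are in Angstrom; ``res_seq`` keeps author numbering; ``ss``
    is one of H/E/L once assigned, "-" before assignment.
    """

    chain_id: str
    res_seq: int
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    ss: str = "-"

    def backbone_coords(self) -> np.ndarray:
        """4x3 array in N, CA, C, O order."""
        return np.stack([self.n, self.ca, self.c, self.o])

    def copy(self) -> "BackboneResidue":
        return replace(
            self, n=self.n.copy(), ca=self.ca.copy(),
            c=self.c.copy(), o=self.o.copy(),
        )


@dataclass
class ProteinStructure:
    """Ordered multichain backbone model."""

    chains: dict[str, list[BackboneResidue]]
    source_id: str = ""
    resolution: float | None = None
    dropped_residues: int = 0

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def all_residues(self) -> list[BackboneResidue]:
        return [r for ch in self.chains.values() for r in ch]


def _geometry_ok(res: BackboneResidue) -> bool:
    # CA-N and CA-C bond distances must be physically plausible.
    d_n = float(np.linalg.norm(res.ca - res.n))
    d_c = float(np.linalg.norm(res.ca - res.c))
    return 0.5 < d_n < 2.5 and 0.5 < d_c < 2.5


def read_pdb(path: str | Path, source_id: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a backbone-only :class:`ProteinStructure`.

    Keeps canonical amino acids with all four backbone atoms present and
    plausible CA-N / CA-C bond lengths. Altloc collisions are resolved to the
    highest-occupancy conformer (ties: first listed, Bio.PDB's behaviour);
    duplicated (chain, res_seq) positions keep the first occurrence.

    Raises
    ------
    StructureError
        If the file cannot be parsed or no residue survives filtering.
    """
    path = Path(path)
    if not path.is_file():
        raise StructureError(f"no such PDB file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(source_id or path.stem, str(path))
    except Exception as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    resolution = None
    header = getattr(structure, "header", None) or {}
    if header.get("resolution") is not None:
        resolution = float(header["resolution"])

    chains: dict[str, list[BackboneResidue]] = {}
    dropped = 0
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no model in PDB file {path}")

    for chain in model:
        seen: set[int] = set()
        residues: list[BackboneResidue] = []
        for res in chain:
            hetflag, res_seq, _icode = res.get_id()
            if hetflag != " ":
                continue  # HETATM / water
            if res.get_resname() not in THREE_TO_ONE:
                dropped += 1
                continue
            if res_seq in seen:
                continue  # insertion-code collision: first occurrence kept
            coords = {}
            for name in _BACKBONE_ATOMS:
                if name in res:
                    coords[name] = np.asarray(res[name].get_coord(), dtype=np.float64)
            if len(coords) < 4:
                dropped += 1
                continue
            bb = BackboneResidue(
                chain_id=chain.id, res_seq=res_seq,
                aa=THREE_TO_ONE[res.get_resname()],
                n=coords["N"], ca=coords["CA"], c=coords["C"], o=coords["O"],
            )
            if not _geometry_ok(bb):
                dropped += 1
                continue
            seen.add(res_seq)
            residues.append(bb)
        if residues:
            residues.sort(key=lambda r: r.res_seq)
            chains[chain.id] = residues

    if not chains:
        raise StructureError(f"no backbone-complete canonical residues in {path}")
    if dropped:
        logger.info("read_pdb(%s): dropped %d incomplete/non-canonical residues",
                    path.name, dropped)
    return ProteinStructure(chains=chains, source_id=source_id or path.stem,
                            resolution=resolution, dropped_residues=dropped)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def phi_psi(chain: list[BackboneResidue]) -> list[tuple[float | None, float | None]]:
    """Backbone (phi, psi) per residue; None at chain termini."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(chain):
        phi = psi = None
        if i > 0:
            phi = _dihedral(chain[i - 1].c, res.n, res.ca, res.c)
        if i < len(chain) - 1:
            psi = _dihedral(res.n, res.ca, res.c, chain[i + 1].n)
        out.append((phi, psi))
    return out


def _bin_ss(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "L"
    if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
        return "H"
    if -170.0 < phi < -50.0 and (90.0 < psi < 180.0 or -180.0 < psi < -170.0):
        return "E"
    return "L"


def _smooth(labels: list[str]) -> list[str]:
    """Demote H/E runs shorter than 3 residues to L."""
    out = list(labels)
    i = 0
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        if out[i] in "HE" and j - i < 3:
            for k in range(i, j):
                out[k] = "L"
        i = j
    return out


def assign_secondary_structure(s: ProteinStructure) -> ProteinStructure:
    """Label every residue H, E or L from backbone dihedrals (in place).

    Chain-terminal residues (undefined phi or psi) are L; H/E runs shorter
    than 3 are smoothed to L. Pure function of coordinates within each chain.
    """
    for chain in s.chains.values():
        raw = [_bin_ss(phi, psi) for phi, psi in phi_psi(chain)]
        for res, label in zip(chain, _smooth(raw)):
            res.ss = label
    return s


_ATOM_FMT = ("ATOM  {serial:5d} {name:^4s}{alt:1s}{resname:3s} {chain:1s}"
             "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {element:>2s}\n")


def write_pdb(s: ProteinStructure, path: str | Path) -> Path:
    """Write backbone ATOM records (N, CA, C, O) for all chains."""
    path = Path(path)
    serial = 1
    with open(path, "w") as fh:
        for chain_id, residues in s.chains.items():
            for res in residues:
                resname = ONE_TO_THREE[res.aa]
                for name, coord in zip(_BACKBONE_ATOMS,
                                       (res.n, res.ca, res.c, res.o)):
                    fh.write(_ATOM_FMT.format(
                        serial=serial, name=name, alt=" ", resname=resname,
                        chain=chain_id, resseq=res.res_seq, icode=" ",
                        x=coord[0], y=coord[1], z=coord[2], occ=1.0, b=0.0,
                        element=name[0]))
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")
    return path


def write_designed_pdb(record, seq: str, path: str | Path) -> Path:
    """Write a peptide-site complex with the peptide renamed to ``seq``.

    The peptide backbone coordinates are untouched; only residue names
    change. Round-trips through :func:`read_pdb`.
    """
    from .extraction import ComplexRecord  # local import to avoid a cycle

    assert isinstance(record, ComplexRecord)
    if len(seq) != len(record.peptide):
        raise ValueError(
            f"sequence length {len(seq)} != peptide length {len(record.peptide)}")
    peptide = [replace(r.copy(), aa=a) for r, a in zip(record.peptide, seq)]
    chains: dict[str, list[BackboneResidue]] = {}
    for res in record.site:
        chains.setdefault(res.chain_id, []).append(res)
    pep_chain = record.peptide[0].chain_id
    # The peptide goes on its own chain; remap on collision with site chains.
    if pep_chain in chains:
        pep_chain = next(c for c in "pqrstuvwxyz" if c not in chains)
        peptide = [replace(r, chain_id=pep_chain) for r in peptide]
    chains[pep_chain] = peptide
    return write_pdb(ProteinStructure(chains=chains, source_id=record.source_id), path)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    """Write (header, sequence) pairs as FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (header, sequence) pairs."""
    out: list[tuple[str, str]] = []
    header, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(parts)))
                header, parts = line[1:], []
            elif line:
                parts.append(line)
    if header is not None:
        out.append((header, "".join(parts)))
    return out
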