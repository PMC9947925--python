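"""Synthetic peptide-pocket complexes with a planted geometry-to-sequence
mapping.

The generator builds 6-residue peptides with idealized backbone geometry
(canonical phi/psi, standard bond lengths) posed against a procedurally
constructed pocket: an arc of residues wrapped around the peptide axis at
contact distance. Every record satisfies the extraction-module invariants
by construction.

The planted mapping makes the design problem exactly solvable: each
peptide position's target amino acid is a deterministic function of
observable features — the identity of the nearest binding-site residue and
the binned CA-CA contact distance — so a correctly wired model can learn
it and a brute-force rule reader (:func:`planted_rule`) can verify it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import (AA_ALPHABET, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA,
                        ANGLE_N_CA_C, BOND_CA_C, BOND_C_N, BOND_C_O, BOND_N_CA,
                        INDEX_TO_AA, AA_TO_INDEX, N_AA, OMEGA, PEPTIDE_LEN,
                        SITE_MAX, SITE_MIN)
from .extraction import ComplexRecord
from .structure_io import BackboneResidue

# Canonical backbone dihedrals per 3-state secondary-structure type.
SS_DIHEDRALS: dict[str, tuple[float, float]] = {
    "H": (-57.0, -47.0),    # alpha helix
    "E": (-120.0, 130.0),   # beta strand
    "L": (-150.0, 60.0),    # irregular / loop
}

# Distance bins (Angstrom) of the planted mapping.
RULE_BINS = (5.5, 7.0)


@dataclass
class ToySpec:
    """Study conditions for one synthetic dataset."""

    n_complexes: int = 50
    site_range: tuple[int, int] = (SITE_MIN, SITE_MAX)
    peptide_ss: str = "H"
    noise: float = 0.0          # Gaussian coordinate jitter, Angstrom
    seed: int = 0
    radius_range: tuple[float, float] = (4.6, 7.5)

    def validate(self) -> None:
        lo, hi = self.site_range
        if not (SITE_MIN <= lo <= hi <= SITE_MAX):
            raise ValueError(f"site_range {self.site_range} outside "
                             f"[{SITE_MIN}, {SITE_MAX}]")
        if self.peptide_ss not in SS_DIHEDRALS:
            raise ValueError(f"unknown peptide ss type {self.peptide_ss!r}")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as requested."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.cos(tor) * np.sin(ang),
                        bond * np.sin(tor) * np.sin(ang)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_backbone(n_res: int, phi: float, psi: float,
                         chain_id: str = "A", start_seq: int = 1,
                         sequence: str | None = None,
                         ) -> list[BackboneResidue]:
    """Idealized backbone chain from constant (phi, psi), trans omega."""
    seq = sequence or "G" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length mismatch")
    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    c_xyz = [ca_xyz[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        n_next = _place_atom(n_xyz[-1], ca_xyz[-1], c_xyz[-1],
                             BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(ca_xyz[-1], c_xyz[-1], n_next,
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place_atom(c_xyz[-1], n_next, ca_next,
                             BOND_CA_C, ANGLE_N_CA_C, phi)
        n_xyz.append(n_next)
        ca_xyz.append(ca_next)
        c_xyz.append(c_next)
    residues = []
    for i in range(n_res):
        # Carbonyl O: in the peptide plane, anti to the next amide N.
        o = _place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                        BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        residues.append(BackboneResidue(
            chain_id=chain_id, res_seq=start_seq + i, aa=seq[i],
            n=n_xyz[i], ca=ca_xyz[i], c=c_xyz[i], o=o))
    return residues


def _rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


_SITE_TEMPLATE = build_ideal_backbone(1, *SS_DIHEDRALS["L"])[0]


def _pocket_residue(ca_target: np.ndarray, orientation: np.ndarray,
                    chain_id: str, res_seq: int, aa: str, ss: str
                    ) -> BackboneResidue:
    """Rigidly posed copy of a single-residue backbone template."""
    t = _SITE_TEMPLATE
    shift = ca_target - orientation @ t.ca
    res = BackboneResidue(
        chain_id=chain_id, res_seq=res_seq, aa=aa,
        n=orientation @ t.n + shift, ca=ca_target.copy(),
        c=orientation @ t.c + shift, o=orientation @ t.o + shift, ss=ss)
    return res


def generate_toy_complex(spec: ToySpec,
                         rng: np.random.Generator | None = None,
                         index: int = 0) -> ComplexRecord:
    """One synthetic complex; deterministic given (spec.seed, index)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng((spec.seed, index))
    phi, psi = SS_DIHEDRALS[spec.peptide_ss]
    peptide = build_ideal_backbone(PEPTIDE_LEN, phi, psi, chain_id="A",
                                   start_seq=1)
    pep_ca = np.stack([r.ca for r in peptide])
    center = pep_ca.mean(axis=0)
    axis = pep_ca[-1] - pep_ca[0]
    extent = np.linalg.norm(axis)
    axis /= extent
    # Orthonormal frame around the peptide axis.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    lo, hi = spec.site_range
    site_size = int(rng.integers(lo, hi + 1))
    theta0 = rng.uniform(0.0, 2 * np.pi)
    arc_span = rng.uniform(1.5 * np.pi, 2.2 * np.pi)
    site = []
    for i in range(site_size):
        frac = i / max(site_size - 1, 1)
        theta = theta0 + frac * arc_span
        radius = rng.uniform(*spec.radius_range)
        along = (frac - 0.5) * (extent + 4.0)
        ca = (center + along * axis
              + radius * (np.cos(theta) * u + np.sin(theta) * v))
        orientation = _rotation_from_axis_angle(
            rng.normal(size=3) + 1e-3, rng.uniform(0, 2 * np.pi))
        aa = INDEX_TO_AA[int(rng.integers(1, N_AA + 1))]
        ss = "HEL"[int(rng.integers(0, 3))]
        site.append(_pocket_residue(ca, orientation, "B", i + 1, aa, ss))

    if spec.noise > 0:
        # redraw peptide jitter until the CA-CA band survives
        clean = np.stack([r.backbone_coords() for r in peptide])
        for _attempt in range(100):
            jittered = clean + rng.normal(scale=spec.noise, size=clean.shape)
            gaps = np.linalg.norm(np.diff(jittered[:, 1, :], axis=0), axis=1)
            if np.all(gaps < 4.2) and np.all(gaps > 3.2):
                break
        else:
            raise RuntimeError("noise level incompatible with chain geometry")
        for res, xyz in zip(peptide, jittered):
            res.n, res.ca, res.c, res.o = xyz[0], xyz[1], xyz[2], xyz[3]
        for res in site:
            for atom in ("n", "ca", "c", "o"):
                setattr(res, atom,
                        getattr(res, atom) + rng.normal(scale=spec.noise,
                                                        size=3))

    record = ComplexRecord(peptide=peptide, site=site,
                           oligomeric_label=int(rng.integers(0, 2)),
                           source_id=f"toy{spec.seed:04d}_{index:05d}",
                           ligand_chain="A", start_res_seq=1)
    for res, aa in zip(record.peptide, planted_rule(record)):
        res.aa = aa
        res.ss = spec.peptide_ss
    record.validate()
    return record


def planted_rule(record: ComplexRecord) -> str:
    """The documented geometry-to-sequence rule (brute-force readable).

    For peptide position i: find the nearest site residue by CA-CA
    distance; with a = its amino-acid index (1-20) and b the distance bin
    (0: d < 5.5 A, 1: d < 7.0 A, 2: otherwise), the target index is
    ``((a - 1 + b) mod 20) + 1``.
    """
    site_ca = np.stack([r.ca for r in record.site])
    site_aa = [r.aa for r in record.site]
    out = []
    for res in record.peptide:
        d = np.linalg.norm(site_ca - res.ca, axis=1)
        j = int(d.argmin())
        a = AA_TO_INDEX[site_aa[j]]
        b = 0 if d[j] < RULE_BINS[0] else (1 if d[j] < RULE_BINS[1] else 2)
        out.append(INDEX_TO_AA[((a - 1 + b) % N_AA) + 1])
    return "".join(out)


def planted_mapping_dataset(spec: ToySpec
                            ) -> list[tuple[ComplexRecord, str]]:
    """(record, target) pairs; the native peptide sequence IS the target."""
    spec.validate()
    out = []
    for i in range(spec.n_complexes):
        record = generate_toy_complex(spec, index=i)
        out.append((record, record.peptide_sequence()))
    return out


def write_toy_dataset(spec: ToySpec, outdir: str | Path
                      ) -> tuple[Path, Path, Path]:
    """Materialize a dataset: complex PDBs, targets TSV, tensor store."""
    import pandas as pd

    from .featurize import featurize_complex, save_tensors
    from .structure_io import write_designed_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = planted_mapping_dataset(spec)
    rows = []
    for i, (record, target) in enumerate(dataset):
        pdb_path = outdir / f"{record.source_id}.pdb"
        write_designed_pdb(record, target, pdb_path)
        rows.append((record.source_id, pdb_path.name, target,
                     record.oligomeric_label, len(record.site)))
    targets_path = outdir / "targets.tsv"
    pd.DataFrame(rows, columns=["source_id", "pdb", "target", "oligo",
                                "site_size"]).to_csv(
        targets_path, sep="\t", index=False)
    from .structure_io import write_fasta
    write_fasta([(r.source_id, t) for (r, t) in dataset],
                outdir / "natives.fasta")
    h5_path = outdir / "tensors.h5"
    save_tensors(h5_path, [(featurize_complex(r), t) for r, t in dataset])
    return outdir, targets_path, h5_path
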