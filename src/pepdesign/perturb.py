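"""Bounded backbone perturbation of peptide fragments.

Emulates the "near-native but not exact" regime a designed or modelled
backbone occupies: the peptide is stripped to poly-glycine and displaced by
a small rigid-body move plus per-atom Gaussian noise, rescaled so the
coordinate RMSD to the native pose equals a uniformly drawn target bounded
by ``max_rmsd`` (default 1.07 A). RMSD is computed WITHOUT superposition:
the peptide's placement relative to the binding site is part of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import CA_CA_MAX, CA_CA_MIN
from .extraction import ComplexRecord
from .structure_io import BackboneResidue

DEFAULT_MAX_RMSD = 1.07  # Angstrom


@dataclass
class PerturbationSpec:
    max_rmsd: float = DEFAULT_MAX_RMSD
    seed: int = 0
    max_rotation_deg: float = 10.0
    max_translation: float = 1.0
    noise_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.max_rmsd <= 0:
            raise ValueError(f"max_rmsd must be positive, got {self.max_rmsd}")


def compute_rmsd(a: list[BackboneResidue] | np.ndarray,
                 b: list[BackboneResidue] | np.ndarray) -> float:
    """Coordinate RMSD over backbone atoms (N, CA, C, O), no superposition."""
    xa = _coords(a)
    xb = _coords(b)
    if xa.shape != xb.shape:
        raise ValueError(f"backbone shape mismatch: {xa.shape} vs {xb.shape}")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=-1))))


def _coords(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.reshape(-1, 3)
    return np.concatenate([r.backbone_coords() for r in x])


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def perturb_coords(coords: np.ndarray, spec: PerturbationSpec,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Perturb an (n_atoms, 3) coordinate array to a drawn target RMSD.

    The displacement field is a random rigid-body move (rotation about the
    centroid <= max_rotation_deg, translation <= max_translation) plus
    per-atom Gaussian noise; because RMSD is linear in a uniform scaling of
    the displacement field, the field is rescaled exactly onto a target RMSD
    drawn uniformly in (0, max_rmsd]. Draws that break the consecutive
    CA-CA distance band are rejected and redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    flat = coords.reshape(-1, 3)
    n_res = flat.shape[0] // 4
    for _attempt in range(200):
        target = rng.uniform(0.0, spec.max_rmsd)
        if target == 0.0:  # open interval (0, max_rmsd]
            target = spec.max_rmsd
        angle = np.radians(rng.uniform(-spec.max_rotation_deg,
                                       spec.max_rotation_deg))
        axis = rng.normal(size=3)
        shift = rng.uniform(-1.0, 1.0, size=3)
        shift *= spec.max_translation / max(np.linalg.norm(shift), 1e-12)
        centroid = flat.mean(axis=0)
        rigid = (flat - centroid) @ _rotation_matrix(axis, angle).T + centroid + shift
        displacement = (rigid - flat) + rng.normal(scale=spec.noise_sigma,
                                                   size=flat.shape)
        base = float(np.sqrt(np.mean(np.sum(displacement ** 2, axis=-1))))
        if base < 1e-9:
            continue
        moved = flat + displacement * (target / base)
        cas = moved.reshape(n_res, 4, 3)[:, 1, :]
        gaps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        if n_res < 2 or (np.all(gaps > CA_CA_MIN) and np.all(gaps < CA_CA_MAX)):
            return moved.reshape(coords.shape)
    raise RuntimeError("could not draw a geometry-preserving perturbation")


def perturb_peptide(peptide: list[BackboneResidue], spec: PerturbationSpec,
                    rng: np.random.Generator | None = None,
                    ) -> list[BackboneResidue]:
    """Perturbed copy of a peptide backbone; RMSD to input <= spec.max_rmsd."""
    coords = np.stack([r.backbone_coords() for r in peptide])
    moved = perturb_coords(coords, spec, rng=rng)
    out = []
    for res, xyz in zip(peptide, moved):
        out.append(replace(res.copy(), n=xyz[0], ca=xyz[1], c=xyz[2], o=xyz[3]))
    return out


def strip_to_glycine(record: ComplexRecord) -> ComplexRecord:
    """All-glycine copy of the peptide; coordinates and site untouched."""
    out = record.copy()
    for res in out.peptide:
        res.aa = "G"
    return out


def perturb_complex(record: ComplexRecord, spec: PerturbationSpec,
                    rng: np.random.Generator | None = None,
                    to_glycine: bool = True) -> ComplexRecord:
    """Glycine-stripped, backbone-perturbed copy of a complex."""
    out = strip_to_glycine(record) if to_glycine else record.copy()
    out.peptide = perturb_peptide(out.peptide, spec, rng=rng)
    return out
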