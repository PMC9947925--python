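"""Fixed-shape model inputs from a peptide-site complex.

Five tensors per complex:

1. ``inter_maps``  (48, 6, 2)  N(site)-N(peptide) and O-O distance maps,
   stacked in the depth dimension; rows beyond the true site size are zero.
2. ``site_aa``     (48,)       amino-acid indices of site residues (pad 0).
3. ``site_ss``     (48,)       3-state secondary structure (pad 0).
4. ``intra_maps``  (6, 6, 2)   peptide-internal N-N and O-O maps.
5. ``oligo``       scalar      0 = homo-, 1 = hetero-oligomeric interface.

All features are backbone geometry plus site sequence: the peptide's own
amino-acid identities never enter, so a glycine-stripped backbone featurizes
identically to the native one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .constants import AA_TO_INDEX, PEPTIDE_LEN, SITE_MAX, SS_TO_INDEX
from .extraction import ComplexRecord


@dataclass
class FeatureTensors:
    inter_maps: np.ndarray  # (48, 6, 2), float32, Angstrom
    site_aa: np.ndarray     # (48,), int64
    site_ss: np.ndarray     # (48,), int64
    intra_maps: np.ndarray  # (6, 6, 2), float32, Angstrom
    oligo: int
    site_size: int
    provenance: str = ""

    def validate(self) -> None:
        assert self.inter_maps.shape == (SITE_MAX, PEPTIDE_LEN, 2)
        assert self.site_aa.shape == (SITE_MAX,)
        assert self.site_ss.shape == (SITE_MAX,)
        assert self.intra_maps.shape == (PEPTIDE_LEN, PEPTIDE_LEN, 2)
        assert self.oligo in (0, 1)
        n = self.site_size
        assert np.all(self.inter_maps[n:] == 0)
        assert np.all(self.site_aa[n:] == 0) and np.all(self.site_aa[:n] > 0)
        assert np.all(self.site_ss[n:] == 0) and np.all(self.site_ss[:n] > 0)


def inter_distance_maps(record: ComplexRecord) -> np.ndarray:
    """(48, 6, 2) site-peptide distance maps: channel 0 N-N, channel 1 O-O."""
    out = np.zeros((SITE_MAX, PEPTIDE_LEN, 2), dtype=np.float32)
    pep_n = np.stack([r.n for r in record.peptide])
    pep_o = np.stack([r.o for r in record.peptide])
    site_n = np.stack([r.n for r in record.site])
    site_o = np.stack([r.o for r in record.site])
    k = len(record.site)
    out[:k, :, 0] = np.linalg.norm(site_n[:, None, :] - pep_n[None, :, :], axis=-1)
    out[:k, :, 1] = np.linalg.norm(site_o[:, None, :] - pep_o[None, :, :], axis=-1)
    return out


def intra_distance_maps(peptide) -> np.ndarray:
    """(6, 6, 2) peptide-internal maps; symmetric per channel, zero diagonal."""
    n = np.stack([r.n for r in peptide])
    o = np.stack([r.o for r in peptide])
    out = np.zeros((PEPTIDE_LEN, PEPTIDE_LEN, 2), dtype=np.float32)
    out[:, :, 0] = np.linalg.norm(n[:, None, :] - n[None, :, :], axis=-1)
    out[:, :, 1] = np.linalg.norm(o[:, None, :] - o[None, :, :], axis=-1)
    return out


def encode_site(record: ComplexRecord) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded site sequence and secondary structure, zero-padded."""
    aa = np.zeros(SITE_MAX, dtype=np.int64)
    ss = np.zeros(SITE_MAX, dtype=np.int64)
    for i, res in enumerate(record.site):
        if res.aa not in AA_TO_INDEX:
            raise ValueError(f"unknown residue code {res.aa!r} at site position "
                             f"{i} ({res.chain_id}{res.res_seq})")
        aa[i] = AA_TO_INDEX[res.aa]
        ss[i] = SS_TO_INDEX.get(res.ss, SS_TO_INDEX["L"])
    return aa, ss


def featurize_complex(record: ComplexRecord) -> FeatureTensors:
    """Compose the five model inputs for one complex (deterministic)."""
    record.validate()
    aa, ss = encode_site(record)
    ft = FeatureTensors(
        inter_maps=inter_distance_maps(record),
        site_aa=aa, site_ss=ss,
        intra_maps=intra_distance_maps(record.peptide),
        oligo=int(record.oligomeric_label),
        site_size=len(record.site),
        provenance=record.provenance,
    )
    ft.validate()
    return ft


# ---------------------------------------------------------------------------
# HDF5 tensor store: one group per complex, datasets input1..input5.

def save_tensors(path: str | Path, items: list[tuple[FeatureTensors, str | None]],
                 ) -> Path:
    """Write (tensors, optional target sequence) pairs to an HDF5 store."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for i, (ft, target) in enumerate(items):
            grp = fh.create_group(f"complex_{i:05d}")
            grp.create_dataset("input1", data=ft.inter_maps)
            grp.create_dataset("input2", data=ft.site_aa)
            grp.create_dataset("input3", data=ft.site_ss)
            grp.create_dataset("input4", data=ft.intra_maps)
            grp.create_dataset("input5", data=np.int64(ft.oligo))
            grp.attrs["site_size"] = ft.site_size
            grp.attrs["provenance"] = ft.provenance
            if target is not None:
                grp.attrs["target"] = target
    return path


def load_tensors(path: str | Path) -> list[tuple[FeatureTensors, str | None]]:
    """Read a tensor store written by :func:`save_tensors` (group order)."""
    out: list[tuple[FeatureTensors, str | None]] = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            grp = fh[name]
            ft = FeatureTensors(
                inter_maps=np.asarray(grp["input1"], dtype=np.float32),
                site_aa=np.asarray(grp["input2"], dtype=np.int64),
                site_ss=np.asarray(grp["input3"], dtype=np.int64),
                intra_maps=np.asarray(grp["input4"], dtype=np.float32),
                oligo=int(np.asarray(grp["input5"])),
                site_size=int(grp.attrs["site_size"]),
                provenance=str(grp.attrs.get("provenance", "")),
            )
            target = grp.attrs.get("target")
            out.append((ft, None if target is None else str(target)))
    return out
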