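"""Shared fixtures: synthetic complexes and small trained models.

Everything is generated programmatically; no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from pepdesign.featurize import featurize_complex
from pepdesign.fixtures import (SS_DIHEDRALS, ToySpec, build_ideal_backbone,
                                generate_toy_complex, planted_mapping_dataset)
from pepdesign.models import (ModelConfig, TrainConfig, build_single_designer,
                              train_single)
from pepdesign.structure_io import ProteinStructure, write_pdb


@pytest.fixture(scope="session")
def toy_record():
    return generate_toy_complex(ToySpec(seed=11))


@pytest.fixture(scope="session")
def toy_tensors(toy_record):
    return featurize_complex(toy_record)


@pytest.fixture(scope="session")
def planted_dataset():
    """Twenty planted complexes with featurized inputs and targets."""
    data = planted_mapping_dataset(ToySpec(n_complexes=20, seed=21))
    return [(featurize_complex(r), t) for r, t in data], data


@pytest.fixture(scope="session")
def quick_model(planted_dataset):
    """A briefly trained single-output model (shared, treated read-only)."""
    tensors, _ = planted_dataset
    model = build_single_designer(ModelConfig(seed=3))
    train_single(model, tensors, TrainConfig(stages=((8, 2e-3),), seed=3))
    return model


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Minimal 2-chain PDB with 10 backbone-complete residues per chain."""
    a = build_ideal_backbone(10, *SS_DIHEDRALS["H"], chain_id="A",
                             sequence="ACDEFGHIKL")
    b = build_ideal_backbone(10, *SS_DIHEDRALS["E"], chain_id="B",
                             sequence="MNPQRSTVWY")
    for res in b:
        for atom in ("n", "ca", "c", "o"):
            setattr(res, atom, getattr(res, atom) + np.array([0.0, 8.0, 0.0]))
    path = tmp_path / "two_chain.pdb"
    write_pdb(ProteinStructure(chains={"A": a, "B": b}, source_id="fix"), path)
    return path
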