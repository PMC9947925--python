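"""Recovery statistics, hot-spot analysis and the surrogate energy model.

Sequence recovery is exact amino-acid identity (no similarity-matrix
credit). Hot-spots are peptide residues whose alanine-scan binding
contribution is at least 3 REU; recovery restricted to those positions is
reported separately and left undefined (None) when a peptide has no
hot-spots — never coerced to zero.

The surrogate energy model is an explicitly non-Rosetta stand-in: a
deterministic contact-count pseudo-energy with per-residue weights from
side-chain size and hydropathy, additive over peptide residues. Real
per-residue energies can be supplied through the same interface
(:class:`TableEnergy`) to bypass it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA_ALPHABET, HYDROPATHY, PEPTIDE_LEN
from .extraction import ComplexRecord, _sidechain_proxy
from .models import DesignSet

HOTSPOT_THRESHOLD = 3.0  # REU; boundary is inclusive (>= 3)

# Side-chain heavy-atom counts (CB and beyond), a proxy for contact area.
_SIDECHAIN_SIZE = {
    "A": 1, "C": 2, "D": 4, "E": 5, "F": 7, "G": 0, "H": 6, "I": 4,
    "K": 5, "L": 4, "M": 4, "N": 4, "P": 3, "Q": 5, "R": 7, "S": 2,
    "T": 3, "V": 3, "W": 10, "Y": 8,
}


@dataclass
class HotspotLabel:
    index: int
    ddG: float
    is_hotspot: bool


@dataclass
class RecoveryReport:
    r_all: float
    r_hotspot: float | None
    per_position: list[float]
    per_ss: dict[str, float]
    n_residues: int
    n_hotspots: int
    diversity: float | None = None
    energy_model: str = "surrogate"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2))
        return path

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [("R_all", self.r_all), ("R_hotspot", self.r_hotspot),
                ("n_residues", self.n_residues),
                ("n_hotspots", self.n_hotspots),
                ("diversity", self.diversity),
                ("energy_model", self.energy_model)]
        rows += [(f"per_position_{i + 1}", v)
                 for i, v in enumerate(self.per_position)]
        rows += [(f"per_ss_{k}", v) for k, v in self.per_ss.items()]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            path, sep="\t", index=False)
        return path


def sequence_recovery(native: str, designed: str) -> float:
    """Fraction of positions with identical amino acids."""
    if len(native) != len(designed):
        raise ValueError(f"length mismatch: {len(native)} vs {len(designed)}")
    if not native:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(native, designed)) / len(native)


def hotspot_recovery(native: str, designed: str,
                     labels: list[HotspotLabel]) -> float | None:
    """Identity fraction restricted to hot-spot positions; None if none."""
    hot = [lab.index for lab in labels if lab.is_hotspot]
    if not hot:
        return None
    return sum(native[i] == designed[i] for i in hot) / len(hot)


def best_of_n_recovery(native: str, designs: DesignSet | list[str]) -> float:
    seqs = designs.sequences if isinstance(designs, DesignSet) else designs
    if not seqs:
        raise ValueError("no designs")
    return max(sequence_recovery(native, s) for s in seqs)


def diversity(designs: DesignSet | list[str]) -> float:
    """Mean pairwise Hamming distance (differing positions) over designs."""
    seqs = designs.sequences if isinstance(designs, DesignSet) else designs
    pairs = list(combinations(seqs, 2))
    if not pairs:
        return 0.0
    return float(np.mean([sum(a != b for a, b in zip(s1, s2))
                          for s1, s2 in pairs]))


def aa_distribution(sequences: list[str]) -> np.ndarray:
    """Normalized amino-acid frequencies (alphabetical order, length 20)."""
    if not sequences:
        raise ValueError("empty sequence list")
    counts = np.zeros(len(AA_ALPHABET))
    for seq in sequences:
        for aa in seq:
            counts[AA_ALPHABET.index(aa)] += 1
    return counts / counts.sum()


def aa_composition_table(native: list[str], designed: list[str]
                         ) -> pd.DataFrame:
    """Side-by-side native vs designed composition with enrichment ratio."""
    nat = aa_distribution(native)
    des = aa_distribution(designed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nat > 0, des / nat, np.inf)
    return pd.DataFrame({"native": nat, "designed": des, "ratio": ratio},
                        index=list(AA_ALPHABET))


# ---------------------------------------------------------------------------
# Energy models


class SurrogateEnergy:
    """Deterministic contact-count pseudo-energy (units: surrogate REU).

    Each peptide residue i contributes
    ``-(0.2 + w(aa_i)) * contacts_i`` to the binding pseudo-energy, where
    ``contacts_i`` counts site proxy atoms (backbone + ideal CB) within the
    contact shell of residue i's proxy atoms and ``w`` combines normalized
    side-chain size with hydropathy. Contributions are additive, so the
    alanine-scan contribution has the closed form
    ``ddG_i = (w(aa_i) - w(A)) * contacts_i``.
    """

    name = "surrogate"

    def __init__(self, contact_shell: float = 5.0, scale: float = 0.25):
        self.contact_shell = contact_shell
        self.scale = scale

    @staticmethod
    def residue_weight(aa: str) -> float:
        return 0.5 * _SIDECHAIN_SIZE[aa] / 10.0 + 0.5 * HYDROPATHY[aa]

    def _contacts(self, record: ComplexRecord) -> np.ndarray:
        site_atoms = np.concatenate(
            [np.vstack([r.backbone_coords(), _sidechain_proxy(r)[None]])
             for r in record.site])
        counts = np.zeros(len(record.peptide))
        for i, res in enumerate(record.peptide):
            atoms = np.vstack([res.backbone_coords(),
                               _sidechain_proxy(res)[None]])
            d = np.linalg.norm(site_atoms[:, None, :] - atoms[None, :, :],
                               axis=-1)
            counts[i] = np.sum(d.min(axis=1) <= self.contact_shell)
        return counts

    def per_residue_contribution(self, record: ComplexRecord) -> np.ndarray:
        counts = self._contacts(record)
        weights = np.array([0.2 + self.residue_weight(r.aa)
                            for r in record.peptide])
        return -self.scale * counts * weights

    def binding_energy(self, record: ComplexRecord) -> float:
        return float(self.per_residue_contribution(record).sum())

    def per_residue_ddG(self, record: ComplexRecord, index: int) -> float:
        counts = self._contacts(record)
        aa = record.peptide[index].aa
        return float(self.scale * counts[index]
                     * (self.residue_weight(aa) - self.residue_weight("A")))


class TableEnergy:
    """Externally supplied per-residue contributions (TSV bypass).

    The table needs columns ``residue_index`` (0-based peptide position) and
    ``ddG``; an optional single-row ``binding_energy`` column supplies the
    total.
    """

    name = "external-table"

    def __init__(self, ddgs: list[float], binding: float):
        if len(ddgs) != PEPTIDE_LEN:
            raise ValueError(f"need {PEPTIDE_LEN} per-residue values")
        self.ddgs = list(map(float, ddgs))
        self.binding = float(binding)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableEnergy":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("residue_index")
        binding = float(df["binding_energy"].iloc[0]) \
            if "binding_energy" in df else -1.0
        return cls(df["ddG"].tolist(), binding)

    def binding_energy(self, record: ComplexRecord) -> float:
        return self.binding

    def per_residue_ddG(self, record: ComplexRecord, index: int) -> float:
        return self.ddgs[index]


def alanine_scan(record: ComplexRecord, em=None,
                 threshold: float = HOTSPOT_THRESHOLD) -> list[HotspotLabel]:
    """Per-residue binding contributions with hot-spot labels (>= 3 REU)."""
    em = em if em is not None else SurrogateEnergy()
    labels = []
    for i in range(len(record.peptide)):
        ddg = em.per_residue_ddG(record, i)
        labels.append(HotspotLabel(index=i, ddG=ddg,
                                   is_hotspot=ddg >= threshold))
    return labels


# ---------------------------------------------------------------------------
# Aggregate reports


def evaluate_designs(items: list[tuple[ComplexRecord, str, DesignSet | str]],
                     em=None) -> RecoveryReport:
    """Aggregate recovery report over (complex, native, design) triples.

    The design may be a plain sequence or a :class:`DesignSet`; for sets the
    single-output entry drives R_all/R_hotspot and best-of-six/diversity are
    reported alongside.
    """
    em = em if em is not None else SurrogateEnergy()
    matched = total = 0
    pos_matched = np.zeros(PEPTIDE_LEN)
    pos_total = np.zeros(PEPTIDE_LEN)
    ss_matched: dict[str, float] = {"H": 0, "E": 0, "L": 0}
    ss_total: dict[str, float] = {"H": 0, "E": 0, "L": 0}
    hot_matched = hot_total = 0
    diversities = []
    for record, native, design in items:
        seq = design.single_output.sequence if isinstance(design, DesignSet) \
            else design
        if isinstance(design, DesignSet):
            diversities.append(diversity(design))
        labels = alanine_scan(record, em)
        for i, (a, b) in enumerate(zip(native, seq)):
            hit = a == b
            matched += hit
            total += 1
            pos_matched[i] += hit
            pos_total[i] += 1
            ss = record.peptide[i].ss if record.peptide[i].ss in "HEL" else "L"
            ss_matched[ss] += hit
            ss_total[ss] += 1
        for lab in labels:
            if lab.is_hotspot:
                hot_total += 1
                hot_matched += native[lab.index] == seq[lab.index]
    return RecoveryReport(
        r_all=matched / total if total else 0.0,
        r_hotspot=(hot_matched / hot_total) if hot_total else None,
        per_position=list(np.divide(pos_matched, pos_total,
                                    out=np.zeros(PEPTIDE_LEN),
                                    where=pos_total > 0)),
        per_ss={k: (ss_matched[k] / ss_total[k]) if ss_total[k] else 0.0
                for k in "HEL"},
        n_residues=int(total),
        n_hotspots=int(hot_total),
        diversity=float(np.mean(diversities)) if diversities else None,
        energy_model=getattr(em, "name", type(em).__name__),
    )
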