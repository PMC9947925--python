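"""Peptide-fragment and binding-site extraction from multichain complexes.

A design unit is a 6-residue contiguous fragment of a ligand chain (the
"peptide") plus the 24-48-residue patch of the partner chain(s) whose
backbone atoms lie closest to the peptide backbone (the "binding site").
Candidate complexes pass a set of energetic and geometric selection filters
before entering a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .constants import (CA_CA_MAX, NONPOLAR_AAS, PEPTIDE_LEN, SITE_MAX, SITE_MIN)
from .structure_io import BackboneResidue, ProteinStructure

DEFAULT_PROXIMITY_CUTOFF = 10.0  # Angstrom, min backbone-atom distance
SIDECHAIN_CONTACT_CUTOFF = 6.0   # Angstrom, criterion on interior residues
DDG_CONTRIBUTION_MIN = 0.5       # REU, per-residue binding contribution
HOTSPOT_DDG = 3.0                # REU, hot-spot threshold


class EnergyModel(Protocol):
    """Pluggable per-residue interface energy contract.

    Implementations must be deterministic for fixed inputs. Units are REU
    (Rosetta energy units) or surrogate-REU for non-Rosetta backends.
    """

    def binding_energy(self, record: "ComplexRecord") -> float:
        """Total binding free energy, negative = favourable."""
        ...

    def per_residue_ddG(self, record: "ComplexRecord", index: int) -> float:
        """Alanine-scan contribution of peptide residue ``index``."""
        ...


@dataclass
class ComplexRecord:
    """One peptide fragment posed against one binding-site patch."""

    peptide: list[BackboneResidue]
    site: list[BackboneResidue]
    oligomeric_label: int = 1  # 0 = homo-, 1 = hetero-oligomeric
    source_id: str = ""
    ligand_chain: str = ""
    start_res_seq: int = 0

    @property
    def provenance(self) -> str:
        return f"{self.source_id}/{self.ligand_chain}/{self.start_res_seq}"

    def peptide_sequence(self) -> str:
        return "".join(r.aa for r in self.peptide)

    def site_sequence(self) -> str:
        return "".join(r.aa for r in self.site)

    def peptide_coords(self) -> np.ndarray:
        """(6, 4, 3) backbone coordinates in N, CA, C, O order."""
        return np.stack([r.backbone_coords() for r in self.peptide])

    def site_coords(self) -> np.ndarray:
        return np.stack([r.backbone_coords() for r in self.site])

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        if len(self.peptide) != PEPTIDE_LEN:
            raise ValueError(f"peptide length {len(self.peptide)} != {PEPTIDE_LEN}")
        seqs = [r.res_seq for r in self.peptide]
        if any(b - a != 1 for a, b in zip(seqs, seqs[1:])):
            raise ValueError(f"peptide res_seq not consecutive: {seqs}")
        cas = np.stack([r.ca for r in self.peptide])
        gaps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        if np.any(gaps >= CA_CA_MAX):
            raise ValueError(f"peptide chain break: max CA-CA {gaps.max():.2f} A")
        if not SITE_MIN <= len(self.site) <= SITE_MAX:
            raise ValueError(f"site size {len(self.site)} outside "
                             f"[{SITE_MIN}, {SITE_MAX}]")
        if self.oligomeric_label not in (0, 1):
            raise ValueError(f"bad oligomeric label {self.oligomeric_label}")

    def copy(self) -> "ComplexRecord":
        return ComplexRecord(
            peptide=[r.copy() for r in self.peptide],
            site=[r.copy() for r in self.site],
            oligomeric_label=self.oligomeric_label,
            source_id=self.source_id, ligand_chain=self.ligand_chain,
            start_res_seq=self.start_res_seq)


def enumerate_fragments(chain: Sequence[BackboneResidue],
                        length: int = PEPTIDE_LEN) -> list[list[BackboneResidue]]:
    """All contiguous ``length``-residue windows without chain breaks.

    A break is a non-unit res_seq step or a CA-CA distance >= 4.2 A between
    consecutive residues. Chains shorter than ``length`` yield [].
    """
    windows: list[list[BackboneResidue]] = []
    n = len(chain)
    if n < length:
        return windows
    # breaks[i] is True when residues i, i+1 are not properly connected
    breaks = []
    for a, b in zip(chain, chain[1:]):
        gap = float(np.linalg.norm(b.ca - a.ca))
        breaks.append(b.res_seq - a.res_seq != 1 or gap >= CA_CA_MAX)
    for start in range(n - length + 1):
        if not any(breaks[start:start + length - 1]):
            windows.append(list(chain[start:start + length]))
    return windows


def select_binding_site(peptide: Sequence[BackboneResidue],
                        partner_residues: Sequence[BackboneResidue],
                        cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
                        ) -> list[BackboneResidue] | None:
    """Partner residues in immediate backbone proximity of the peptide.

    A residue qualifies when its minimum backbone-atom distance to any
    peptide backbone atom is <= ``cutoff``. Qualifying residues are ranked
    by that distance, truncated to the nearest 48, then restored to chain
    order (chain id, then res_seq). Returns None when fewer than 24 qualify.
    """
    if not partner_residues:
        return None
    pep = np.concatenate([r.backbone_coords() for r in peptide])  # (24, 3)
    mins = []
    for res in partner_residues:
        d = np.linalg.norm(res.backbone_coords()[:, None, :] - pep[None, :, :],
                           axis=-1)
        mins.append(float(d.min()))
    mins = np.asarray(mins)
    within = np.flatnonzero(mins <= cutoff)
    if within.size < SITE_MIN:
        return None
    ranked = within[np.argsort(mins[within], kind="stable")][:SITE_MAX]
    keep = sorted(ranked, key=lambda i: (partner_residues[i].chain_id,
                                         partner_residues[i].res_seq))
    return [partner_residues[i] for i in keep]


def _sidechain_proxy(res: BackboneResidue) -> np.ndarray:
    """CB position (ideal reconstruction from backbone); CA for glycine."""
    if res.aa == "G":
        return res.ca
    # ideal CB from N, CA, C (tetrahedral construction)
    n, ca, c = res.n, res.ca, res.c
    v1 = n - ca
    v2 = c - ca
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bisector = -(v1 + v2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    # 1.53 A bond, ~54.75 deg out of the N-CA-C plane
    direction = bisector * np.cos(np.radians(54.75)) + perp * np.sin(np.radians(54.75))
    return ca + 1.53 * direction


@dataclass
class FilterDecision:
    accepted: bool
    reason: str = ""  # first failed criterion when rejected


def apply_selection_filters(record: ComplexRecord, em: EnergyModel,
                            ddg_min: float = DDG_CONTRIBUTION_MIN,
                            contact_cutoff: float = SIDECHAIN_CONTACT_CUTOFF,
                            hotspot_ddg: float = HOTSPOT_DDG) -> FilterDecision:
    """Accept/reject a candidate complex by the dataset selection criteria.

    In order: (1) at least two peptide residues contribute > 0.5 REU to
    binding; (2) at least three non-terminal peptide residues lie within
    6 A of the site (closest side-chain heavy atoms; CB proxy on
    backbone-only input); (3) negative binding free energy; (4) at least
    one non-polar residue among the peptide hot-spots (>= 3 REU).
    The reason names the first failed criterion.
    """
    ddgs = [em.per_residue_ddG(record, i) for i in range(len(record.peptide))]
    if sum(1 for d in ddgs if d > ddg_min) < 2:
        return FilterDecision(False, "fewer than 2 residues with ddG > 0.5 REU")

    site_proxies = np.stack([_sidechain_proxy(r) for r in record.site])
    n_close = 0
    for res in record.peptide[1:-1]:  # non-terminal positions only
        d = np.linalg.norm(site_proxies - _sidechain_proxy(res), axis=1)
        if d.min() <= contact_cutoff:
            n_close += 1
    if n_close < 3:
        return FilterDecision(
            False, "fewer than 3 non-terminal residues within 6 A of site")

    if em.binding_energy(record) >= 0:
        return FilterDecision(False, "non-negative binding free energy")

    hotspots = [record.peptide[i].aa for i, d in enumerate(ddgs)
                if d >= hotspot_ddg]
    if not any(aa in NONPOLAR_AAS for aa in hotspots):
        return FilterDecision(False, "no non-polar residue among hot-spots")
    return FilterDecision(True, "")


def resolution_ok(structure: ProteinStructure, oligomeric_label: int,
                  is_antibody: bool = False) -> bool | None:
    """Resolution curation predicate; None when the header lacks resolution.

    Thresholds: 2.0 A (homo-oligomeric), 2.5 A (hetero-oligomeric),
    3.5 A (antibody-antigen).
    """
    if structure.resolution is None:
        return None
    limit = 3.5 if is_antibody else (2.0 if oligomeric_label == 0 else 2.5)
    return structure.resolution <= limit


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity over the shorter sequence."""
    from Bio import Align

    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for (s1, e1), (s2, e2) in zip(*aln.aligned)
        for o in range(e1 - s1)
        if a[s1 + o] == b[s2 + o]
    )
    return matches / min(len(a), len(b))


def label_oligomeric(record: ComplexRecord, parent: ProteinStructure,
                     identity_threshold: float = 0.9) -> int:
    """0 when peptide and site chains are (near-)identical copies, else 1."""
    pep_chain = record.peptide[0].chain_id
    site_chains = sorted({r.chain_id for r in record.site})
    pep_seq = parent.chain_sequence(pep_chain)
    for cid in site_chains:
        if cid == pep_chain:
            continue
        if sequence_identity(pep_seq, parent.chain_sequence(cid)) >= identity_threshold:
            return 0
    if site_chains == [pep_chain]:
        return 0  # intra-chain contact patch
    return 1


def extract_complexes(structure: ProteinStructure, ligand_chain: str,
                      em: EnergyModel, cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
                      ) -> tuple[list[ComplexRecord], pd.DataFrame]:
    """Full extraction pipeline for one ligand chain of a parsed structure.

    Returns accepted records and a manifest table covering every candidate
    window (accepted or not) with its rejection reason.
    """
    if ligand_chain not in structure.chains:
        raise KeyError(f"chain {ligand_chain!r} not in structure "
                       f"{sorted(structure.chains)}")
    partner = [r for cid, ch in structure.chains.items() if cid != ligand_chain
               for r in ch]
    rows = []
    accepted: list[ComplexRecord] = []
    for window in enumerate_fragments(structure.chains[ligand_chain]):
        start = window[0].res_seq
        site = select_binding_site(window, partner, cutoff=cutoff)
        if site is None:
            rows.append((structure.source_id, ligand_chain, start, -1, False,
                         "binding site below 24 residues"))
            continue
        record = ComplexRecord(peptide=[r.copy() for r in window],
                               site=[r.copy() for r in site],
                               source_id=structure.source_id,
                               ligand_chain=ligand_chain, start_res_seq=start)
        record.oligomeric_label = label_oligomeric(record, structure)
        decision = apply_selection_filters(record, em)
        rows.append((structure.source_id, ligand_chain, start, len(site),
                     decision.accepted, decision.reason))
        if decision.accepted:
            accepted.append(record)
    manifest = pd.DataFrame(rows, columns=["source_id", "ligand_chain",
                                           "start_res_seq", "site_size",
                                           "accepted", "reason"])
    return accepted, manifest
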