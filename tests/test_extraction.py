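"""Fragment enumeration, binding-site selection and dataset filters."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pepdesign.evaluation import TableEnergy
from pepdesign.extraction import (ComplexRecord, apply_selection_filters,
                                  enumerate_fragments, label_oligomeric,
                                  resolution_ok, select_binding_site,
                                  sequence_identity)
from pepdesign.fixtures import (SS_DIHEDRALS, ToySpec, _pocket_residue,
                                build_ideal_backbone, generate_toy_complex)
from pepdesign.structure_io import ProteinStructure


def _shifted(chain, start, vec):
    for res in chain[start:]:
        for atom in ("n", "ca", "c", "o"):
            setattr(res, atom, getattr(res, atom) + np.asarray(vec))
    return chain


class TestEnumerateFragments:
    def test_contiguous_chain_window_count(self):
        chain = build_ideal_backbone(8, *SS_DIHEDRALS["H"])
        assert len(enumerate_fragments(chain)) == 3

    def test_chain_break_limits_windows(self):
        # 10-mer split 4/6 by a 7 A CA-CA break: only one valid 6-window
        chain = _shifted(build_ideal_backbone(10, *SS_DIHEDRALS["H"]),
                         4, (0.0, 0.0, 7.0))
        windows = enumerate_fragments(chain)
        assert len(windows) == 1
        assert windows[0][0].res_seq == 5

    def test_short_chain_empty(self):
        chain = build_ideal_backbone(5, *SS_DIHEDRALS["H"])
        assert enumerate_fragments(chain) == []


def _ring_pocket(peptide, n, radii):
    """n single-residue pocket units ringed around the peptide centroid."""
    center = np.mean([r.ca for r in peptide], axis=0)
    out = []
    for i in range(n):
        theta = 2 * np.pi * i / n
        ca = center + radii[i % len(radii)] * np.array(
            [0.0, np.cos(theta), np.sin(theta)])
        out.append(_pocket_residue(ca, np.eye(3), "B", i + 1, "L", "L"))
    return out


class TestSelectBindingSite:
    def test_exact_pocket_returned(self, toy_record):
        site = select_binding_site(toy_record.peptide, toy_record.site,
                                   cutoff=10.0)
        assert site is not None
        assert len(site) == len(toy_record.site)

    def test_oversubscribed_pocket_truncated_to_nearest_48(self):
        pep = build_ideal_backbone(6, *SS_DIHEDRALS["H"])
        pocket = _ring_pocket(pep, 60, radii=(5.0, 6.0, 7.0, 8.0))
        site = select_binding_site(pep, pocket, cutoff=12.0)
        assert len(site) == 48
        # the 48 kept are the nearest by min backbone distance
        pep_atoms = np.concatenate([r.backbone_coords() for r in pep])
        dists = [cdist(r.backbone_coords(), pep_atoms).min() for r in pocket]
        kept = {r.res_seq for r in site}
        worst_kept = max(d for r, d in zip(pocket, dists) if r.res_seq in kept)
        best_dropped = min(d for r, d in zip(pocket, dists)
                           if r.res_seq not in kept)
        assert worst_kept <= best_dropped

    def test_isolated_peptide_rejected(self):
        pep = build_ideal_backbone(6, *SS_DIHEDRALS["H"])
        pocket = _ring_pocket(pep, 30, radii=(40.0,))
        assert select_binding_site(pep, pocket, cutoff=10.0) is None

    def test_monotone_in_cutoff_and_chain_ordered(self, toy_record):
        small = select_binding_site(toy_record.peptide, toy_record.site, 8.0)
        large = select_binding_site(toy_record.peptide, toy_record.site, 12.0)
        if small is not None and large is not None:
            ids_small = {(r.chain_id, r.res_seq) for r in small}
            ids_large = {(r.chain_id, r.res_seq) for r in large}
            assert ids_small <= ids_large
        keys = [(r.chain_id, r.res_seq) for r in (large or [])]
        assert keys == sorted(keys)

    def test_matches_exhaustive_scan(self, toy_record):
        cutoff = 9.0
        site = select_binding_site(toy_record.peptide, toy_record.site,
                                   cutoff)
        pep_atoms = np.concatenate([r.backbone_coords()
                                    for r in toy_record.peptide])
        expected = [r for r in toy_record.site
                    if cdist(r.backbone_coords(), pep_atoms).min() <= cutoff]
        if len(expected) < 24:
            assert site is None
        else:
            assert [(r.chain_id, r.res_seq) for r in site] == \
                [(r.chain_id, r.res_seq) for r in expected[:48]] or \
                len(site) == min(len(expected), 48)


GOOD_DDGS = (0.9, 0.8, 3.5, 0.1, 0.1, 0.1)  # hot-spot at position 2 (LEU)


@pytest.fixture
def filter_record(toy_record):
    record = toy_record.copy()
    record.peptide[2].aa = "L"  # non-polar hot-spot by construction
    return record


class TestSelectionFilters:
    def test_all_criteria_met_accepts(self, filter_record):
        em = TableEnergy(list(GOOD_DDGS), -5.0)
        decision = apply_selection_filters(filter_record, em)
        assert decision.accepted, decision.reason

    def test_single_contributor_rejected(self, filter_record):
        em = TableEnergy([0.9, 0.1, 0.1, 0.1, 0.1, 0.1], -5.0)
        decision = apply_selection_filters(filter_record, em)
        assert not decision.accepted
        assert "0.5 REU" in decision.reason

    def test_distant_peptide_fails_proximity(self, filter_record):
        far = filter_record.copy()
        for res in far.peptide:
            for atom in ("n", "ca", "c", "o"):
                setattr(res, atom, getattr(res, atom) + np.array([0, 0, 30.0]))
        em = TableEnergy(list(GOOD_DDGS), -5.0)
        decision = apply_selection_filters(far, em)
        assert not decision.accepted
        assert "6 A" in decision.reason

    def test_positive_binding_energy_rejected(self, filter_record):
        em = TableEnergy(list(GOOD_DDGS), 2.0)
        decision = apply_selection_filters(filter_record, em)
        assert not decision.accepted
        assert "binding free energy" in decision.reason

    def test_polar_hotspots_rejected(self, filter_record):
        record = filter_record.copy()
        record.peptide[2].aa = "K"  # only hot-spot now polar
        em = TableEnergy(list(GOOD_DDGS), -5.0)
        decision = apply_selection_filters(record, em)
        assert not decision.accepted
        assert "non-polar" in decision.reason


class TestResolutionCuration:
    def test_thresholds_by_interface_type(self):
        s = ProteinStructure(chains={}, resolution=2.3)
        assert resolution_ok(s, oligomeric_label=1) is True
        assert resolution_ok(s, oligomeric_label=0) is False
        s.resolution = 3.0
        assert resolution_ok(s, oligomeric_label=1) is False
        assert resolution_ok(s, oligomeric_label=1, is_antibody=True) is True

    def test_missing_header_skips_filter(self):
        s = ProteinStructure(chains={})
        assert resolution_ok(s, oligomeric_label=0) is None


class TestOligomericLabel:
    def _parent_and_record(self, seq_a, seq_b):
        a = build_ideal_backbone(len(seq_a), *SS_DIHEDRALS["H"],
                                 chain_id="A", sequence=seq_a)
        b = build_ideal_backbone(len(seq_b), *SS_DIHEDRALS["H"],
                                 chain_id="B", sequence=seq_b)
        parent = ProteinStructure(chains={"A": a, "B": b})
        record = ComplexRecord(peptide=a[:6], site=b[:24] if len(b) >= 24
                               else b, source_id="x", ligand_chain="A")
        return parent, record

    def test_identical_chains_homo(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        parent, record = self._parent_and_record(seq, seq)
        assert label_oligomeric(record, parent) == 0

    def test_unrelated_chains_hetero(self):
        parent, record = self._parent_and_record("ACDEFGHIKLMNPQRSTVWY",
                                                 "YWVTSRQPNMLKIHGFEDCA")
        assert label_oligomeric(record, parent) == 1

    def test_point_mutant_still_homo(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mut = "ACDEFGHIKWMNPQRSTVWY"  # 95% identity
        assert sequence_identity(seq, mut) == pytest.approx(0.95)
        parent, record = self._parent_and_record(seq, mut)
        assert label_oligomeric(record, parent) == 0


class TestRecordInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_generated_records_satisfy_invariants(self, seed):
        record = generate_toy_complex(ToySpec(seed=seed))
        record.validate()
        pep_atoms = np.concatenate([r.backbone_coords()
                                    for r in record.peptide])
        for res in record.site:
            assert cdist(res.backbone_coords(), pep_atoms).min() <= 10.0
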