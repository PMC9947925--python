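"""Recovery metrics, hot-spot labeling and the surrogate energy model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdesign.constants import AA_ALPHABET
from pepdesign.evaluation import (HotspotLabel, SurrogateEnergy, TableEnergy,
                                  aa_distribution, alanine_scan,
                                  best_of_n_recovery, diversity,
                                  evaluate_designs, hotspot_recovery,
                                  sequence_recovery)
from pepdesign.fixtures import ToySpec, generate_toy_complex

SEQS = st.text(alphabet=AA_ALPHABET, min_size=6, max_size=6)


class TestSequenceRecovery:
    @pytest.mark.parametrize("native,designed,expected", [
        ("ACDEFG", "ACDEFG", 1.0),
        ("ACDEFG", "ACDYYY", 0.5),
        ("ACDEFG", "VVVVVV", 0.0),
    ])
    def test_examples(self, native, designed, expected):
        assert sequence_recovery(native, designed) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sequence_recovery("ACDEFG", "ACDEF")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=SEQS, b=SEQS)
    def test_matches_brute_force(self, a, b):
        brute = sum(1 for i in range(6) if a[i] == b[i]) / 6
        assert sequence_recovery(a, b) == brute


class TestHotspots:
    def test_reported_ddg_quartet_all_hotspots(self):
        # four CDR-H3 contributions from an influenza-neutralizing antibody
        em = TableEnergy([3.2, 4.1, 3.9, 4.4, 1.0, 0.2], -10.0)
        record = generate_toy_complex(ToySpec(seed=2))
        labels = alanine_scan(record, em)
        assert [l.is_hotspot for l in labels] == [True] * 4 + [False] * 2

    def test_threshold_inclusive_at_3(self):
        record = generate_toy_complex(ToySpec(seed=2))
        labels = alanine_scan(record,
                              TableEnergy([2.99, 3.0, 0, 0, 0, 0], -1.0))
        assert [l.is_hotspot for l in labels[:2]] == [False, True]

    def test_no_hotspots_undefined_not_zero(self):
        record = generate_toy_complex(ToySpec(seed=2))
        labels = alanine_scan(record, TableEnergy([0.0] * 6, -1.0))
        assert all(not l.is_hotspot for l in labels)
        assert hotspot_recovery("ACDEFG", "ACDEFG", labels) is None

    def test_recovery_restricted_to_hotspot_positions(self):
        labels = [HotspotLabel(i, 5.0, i in (1, 3)) for i in range(6)]
        assert hotspot_recovery("ACDEFG", "XCXEXX".replace("X", "V"),
                                labels) == 1.0
        labels2 = [HotspotLabel(i, 5.0, i in (1, 3)) for i in range(6)]
        assert hotspot_recovery("ACDEFG", "ACVVVV", labels2) == 0.5


class TestMultiOutputMetrics:
    def test_best_of_n_is_max(self):
        native = "ACDEFG"
        designs = ["AVVVVV", "ACDVVV", "VVVVVV", "AVVVVV", "ACDVVV",
                   "ACDEVV"]
        assert best_of_n_recovery(native, designs) == pytest.approx(4 / 6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(native=SEQS, designs=st.lists(SEQS, min_size=2, max_size=6))
    def test_ordering_invariants(self, native, designs):
        best = best_of_n_recovery(native, designs)
        recs = [sequence_recovery(native, d) for d in designs]
        assert best == max(recs) >= np.mean(recs) >= min(recs)

    def test_diversity_examples(self):
        assert diversity(["AAAAAA"] * 6) == 0.0
        # two groups of three differing at 2 positions: 9 cross pairs of 15
        group1, group2 = "AAAAAA", "AAAAWW"
        assert diversity([group1] * 3 + [group2] * 3) == pytest.approx(1.2)
        maximal = ["ACDEFG", "CDEFGH", "DEFGHI", "EFGHIK", "FGHIKL",
                   "GHIKLM"]
        assert diversity(maximal) == 6.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(designs=st.lists(SEQS, min_size=6, max_size=6))
    def test_diversity_matches_pair_enumeration(self, designs):
        brute = []
        for i in range(6):
            for j in range(i + 1, 6):
                brute.append(sum(a != b
                                 for a, b in zip(designs[i], designs[j])))
        assert diversity(designs) == pytest.approx(np.mean(brute))


class TestAaDistribution:
    def test_examples_and_normalization(self):
        freqs = aa_distribution(["GGGGGG"])
        assert freqs[AA_ALPHABET.index("G")] == 1.0
        freqs2 = aa_distribution(["AAAGGG", "GGGAAA"])
        assert freqs2[AA_ALPHABET.index("A")] == pytest.approx(0.5)
        assert freqs2.sum() == pytest.approx(1.0)


class TestSurrogateEnergy:
    def test_no_contacts_zero_energy(self, toy_record):
        far = toy_record.copy()
        for res in far.peptide:
            for atom in ("n", "ca", "c", "o"):
                setattr(res, atom,
                        getattr(res, atom) + np.array([0.0, 0.0, 100.0]))
        assert SurrogateEnergy().binding_energy(far) == 0.0

    def test_contacting_complex_negative_and_additive(self, toy_record):
        em = SurrogateEnergy()
        total = em.binding_energy(toy_record)
        assert total < 0
        contributions = em.per_residue_contribution(toy_record)
        assert contributions.sum() == pytest.approx(total)

    def test_more_site_residues_strictly_lower_energy(self, toy_record):
        em = SurrogateEnergy()
        full = em.binding_energy(toy_record)
        smaller = toy_record.copy()
        # drop the site residue closest to the peptide
        pep = np.concatenate([r.backbone_coords()
                              for r in smaller.peptide])
        dists = [np.linalg.norm(r.backbone_coords()[:, None] - pep[None],
                                axis=-1).min() for r in smaller.site]
        smaller.site.pop(int(np.argmin(dists)))
        assert em.binding_energy(smaller) > full

    def test_deterministic(self, toy_record):
        em = SurrogateEnergy()
        assert em.binding_energy(toy_record) == \
            em.binding_energy(toy_record)
        assert em.per_residue_ddG(toy_record, 0) == \
            em.per_residue_ddG(toy_record, 0)


class TestReport:
    def test_r_all_equals_mean_per_position_and_bounds(self):
        items = []
        for seed, designed in ((1, None), (2, None), (3, None)):
            record = generate_toy_complex(ToySpec(seed=seed))
            native = record.peptide_sequence()
            mutated = "G" + native[1:5] + "G"
            items.append((record, native, mutated))
        report = evaluate_designs(items)
        assert 0.0 <= report.r_all <= 1.0
        assert report.r_all == pytest.approx(np.mean(report.per_position))
        assert report.n_residues == 18
        assert report.n_hotspots <= report.n_residues
        if report.r_hotspot is not None:
            assert 0.0 <= report.r_hotspot <= 1.0

    def test_report_serialization(self, tmp_path):
        record = generate_toy_complex(ToySpec(seed=4))
        native = record.peptide_sequence()
        report = evaluate_designs([(record, native, native)])
        assert report.r_all == 1.0
        out = report.to_json(tmp_path / "r.json")
        assert "surrogate" in out.read_text()
        report.to_tsv(tmp_path / "r.tsv")
        assert (tmp_path / "r.tsv").exists()
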