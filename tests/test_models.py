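"""Design-model contracts: shapes, normalization, training and export."""

import dataclasses

import numpy as np
import pytest

from pepdesign.constants import AA_ALPHABET
from pepdesign.evaluation import best_of_n_recovery, sequence_recovery
from pepdesign.featurize import featurize_complex
from pepdesign.fixtures import ToySpec, generate_toy_complex
from pepdesign.models import (DesignSet, ModelConfig, SequencePrediction,
                              TrainConfig, build_multi_designer,
                              build_single_designer, export_pssm, load_model,
                              save_model, select_best_model, stack_batch,
                              train_multi, train_single, training_recovery)


class TestBuildAndForward:
    def test_feature_tensor_second_dimension_is_peptide_length(
            self, quick_model, toy_tensors):
        f = quick_model.encode(stack_batch([toy_tensors]))
        assert f.shape[1] == 6

    def test_probs_row_stochastic_and_attention_normalized(
            self, quick_model, toy_tensors):
        pred = quick_model.predict(toy_tensors)
        pred.validate()
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(pred.attention.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(pred.attention >= 0)

    def test_prediction_deterministic(self, quick_model, toy_tensors):
        a = quick_model.predict(toy_tensors)
        b = quick_model.predict(toy_tensors)
        np.testing.assert_array_equal(a.probs, b.probs)
        assert a.sequence == b.sequence

    def test_padding_region_cannot_influence_prediction(self, quick_model):
        record = generate_toy_complex(ToySpec(seed=9, site_range=(24, 30)))
        ft = featurize_complex(record)
        clean = quick_model.predict(ft)
        junk = dataclasses.replace(ft, inter_maps=ft.inter_maps.copy(),
                                   site_aa=ft.site_aa.copy(),
                                   site_ss=ft.site_ss.copy())
        n = ft.site_size
        junk.inter_maps[n:] = 123.0
        junk.site_aa[n:] = 7
        junk.site_ss[n:] = 2
        dirty = quick_model.predict(junk)
        np.testing.assert_allclose(clean.probs, dirty.probs, atol=1e-12)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            build_single_designer(ModelConfig(conv_channels_a=(16, 16)))
        with pytest.raises(ValueError):
            build_single_designer(ModelConfig(feature_depth=0))


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, planted_dataset):
        tensors, _ = planted_dataset
        cfg = TrainConfig(stages=((4, 2e-3),), seed=5)
        m1 = build_single_designer(ModelConfig(seed=5))
        h1 = train_single(m1, tensors, cfg)
        m2 = build_single_designer(ModelConfig(seed=5))
        h2 = train_single(m2, tensors, cfg)
        assert h1[-1]["loss"] < h1[0]["loss"]
        assert h1[-1]["loss"] == h2[-1]["loss"]  # bit-reproducible

    def test_stagewise_mean_loss_non_increasing(self, planted_dataset):
        tensors, _ = planted_dataset
        model = build_single_designer(ModelConfig(seed=1))
        hist = train_single(model, tensors,
                            TrainConfig(stages=((6, 2e-3), (4, 5e-4),
                                                (2, 1e-4)), seed=1))
        by_stage = {}
        for h in hist:
            by_stage.setdefault(h["stage"], []).append(h["loss"])
        means = [np.mean(by_stage[s]) for s in sorted(by_stage)]
        assert means[0] >= means[1] >= means[2]

    def test_empty_dataset_rejected(self):
        model = build_single_designer(ModelConfig(seed=0))
        with pytest.raises(ValueError):
            train_single(model, [], TrainConfig())


class TestModelSelection:
    def test_argmax_and_tie_rule(self, planted_dataset):
        tensors, _ = planted_dataset
        models = [build_single_designer(ModelConfig(seed=s))
                  for s in (1, 2, 3)]
        trained = build_single_designer(ModelConfig(seed=4))
        train_single(trained, tensors, TrainConfig(stages=((10, 2e-3),),
                                                   seed=4))
        candidates = [models[0], trained, models[1]]
        assert select_best_model(candidates, [tensors]) is trained
        # single candidate returns itself; exact tie keeps the first listed
        assert select_best_model([models[0]], [tensors]) is models[0]
        clone = build_single_designer(ModelConfig(seed=1))
        assert select_best_model([models[0], clone], [tensors]) is models[0]


@pytest.fixture(scope="module")
def multi(quick_model, planted_dataset):
    tensors, _ = planted_dataset
    mm = build_multi_designer(quick_model, seed=7)
    state = {k: v.copy() for k, v in mm.encoder.state_dict().items()}
    train_multi(mm, tensors, TrainConfig(stages=((3, 1e-3), (2, 1e-4)),
                                         seed=7))
    return mm, state


class TestMultiDesigner:

    def test_exactly_six_designs_with_single_output_last(
            self, multi, quick_model, toy_tensors):
        mm, _ = multi
        ds = mm.predict(toy_tensors)
        assert len(ds.designs) == 6
        assert ds.sequences[5] == quick_model.predict(toy_tensors).sequence

    def test_encoder_weights_bit_identical_after_training(self, multi):
        mm, before = multi
        after = mm.encoder.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_best_of_six_dominates_single(self, multi, planted_dataset):
        mm, _ = multi
        tensors, _ = planted_dataset
        for ft, target in tensors[:6]:
            ds = mm.predict(ft)
            assert best_of_n_recovery(target, ds) >= \
                sequence_recovery(target, ds.sequences[5])

    def test_six_way_training_recovery_dominates_single(
            self, multi, quick_model, planted_dataset):
        mm, _ = multi
        tensors, _ = planted_dataset
        assert training_recovery(mm, tensors, best_of_n=True) >= \
            training_recovery(quick_model, tensors)

    def test_checkpoint_round_trip(self, multi, toy_tensors, tmp_path):
        mm, _ = multi
        path = save_model(mm, tmp_path / "m.npz")
        loaded = load_model(path)
        assert loaded.predict(toy_tensors).sequences == \
            mm.predict(toy_tensors).sequences

    def test_requires_single_model(self):
        with pytest.raises(TypeError):
            build_multi_designer("not a model")


class TestPssmExport:
    def _pred(self, probs):
        seq = "".join(AA_ALPHABET[i] for i in probs.argmax(axis=1))
        return SequencePrediction(probs=probs, sequence=seq,
                                  attention=np.full((6, 6), 1 / 6))

    def test_uniform_probs_tie_break_alphabetical(self):
        table, topk = export_pssm(self._pred(np.full((6, 20), 0.05)))
        assert topk[3][0] == ["A", "C", "D"]
        np.testing.assert_allclose(table.sum(axis=1), 1.0)

    def test_one_hot_headed_by_that_residue(self):
        probs = np.zeros((6, 20))
        probs[:, AA_ALPHABET.index("W")] = 1.0
        _, topk = export_pssm(self._pred(probs))
        assert all(row[0] == "W" for row in topk[3])
        assert {len(row) for row in topk[5]} == {5}
        assert {len(row) for row in topk[20]} == {20}

    def test_trained_model_table_rows_sum_to_one(self, quick_model,
                                                 toy_tensors):
        table, _ = export_pssm(quick_model.predict(toy_tensors))
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-8)
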