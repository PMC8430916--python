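"""Base-model training, transfer learning and the predicted-RI feature block."""

import numpy as np
import pytest

import gcri
from gcri import nn
from gcri.chem import parse_molecule
from gcri.models import (ConfigurationError, IncompatibleInitializationError,
                         IncompleteEnsembleError, NetSpec, TrainProtocol,
                         TrainedNet, build_net, ensemble_average,
                         evaluate_scaled_mae, feature_block_names, load_trained,
                         predict_ri, predict_ri_batch, ri_feature_block,
                         ri_feature_matrix, save_trained, train_base,
                         transfer_train)
from gcri.phases import NON_POLAR, POLAR, sp_encode
from gcri.simulate import build_corpus, default_phases, generate_library


def _constant_records(n=25, ri=1000.0):
    records = []
    for i in range(n):
        smiles = "O" + "C" * (i % 12 + 2) + ("N" if i % 3 else "")
        records.append(gcri.RetentionRecord(molecule=parse_molecule(smiles),
                                            phase="DB-5", family="non-polar", ri=ri))
    return records


@pytest.fixture(scope="module")
def mini_training(featurizer, registry):
    """A short but real MLP training run on a small simulated corpus."""
    library = generate_library(80, seed=7)
    nonpolar = [p for p in default_phases() if p.family == NON_POLAR]
    records, _ = build_corpus(library, nonpolar, seed=8)
    protocol = TrainProtocol(max_iterations=600, checkpoint_every=100, seed=3)
    net = train_base(NetSpec.mlp_desk(), records, protocol, registry, featurizer)
    return net, records, protocol


class TestTraining:
    def test_constant_target_convergence(self, featurizer, registry):
        records = _constant_records(ri=1000.0)
        protocol = TrainProtocol(max_iterations=1500, checkpoint_every=250, seed=1)
        net = train_base(NetSpec.mlp_desk(), records, protocol, registry, featurizer)
        enc = sp_encode("DB-5", registry, NON_POLAR)
        pred = predict_ri(net, parse_molecule("OCCCCC"), enc, featurizer)
        assert abs(pred - 1000.0) < 50.0  # within 0.05 on the /1000 scale

    def test_fixed_seed_reproducible(self, mini_training, featurizer, registry):
        net, records, protocol = mini_training
        again = train_base(NetSpec.mlp_desk(), records, protocol, registry, featurizer)
        assert net.history == again.history

    def test_validation_loss_improves(self, mini_training):
        net, _, _ = mini_training
        scores = [v for _, v in net.history]
        assert np.mean(scores[:2]) > np.mean(scores[-2:])

    def test_best_checkpoint_is_history_minimum(self, mini_training, featurizer, registry):
        net, records, _ = mini_training
        val_records = [r for r in records if r.compound_key in net.validation_keys]
        recomputed = evaluate_scaled_mae(net, val_records, registry, featurizer)
        assert recomputed == pytest.approx(min(v for _, v in net.history), abs=1e-7)

    def test_beats_mean_predictor(self, mini_training):
        net, records, _ = mini_training
        y = np.array([r.ri for r in records]) / 1000.0
        mean_mae = float(np.abs(y - y.mean()).mean())
        assert net.best_validation_mae < mean_mae

    def test_single_compound_cannot_split(self, featurizer, registry):
        records = _constant_records(n=1)
        with pytest.raises(ConfigurationError):
            train_base(NetSpec.mlp_desk(), records,
                       TrainProtocol(max_iterations=10, seed=0), registry, featurizer)

    def test_family_mismatch_rejected(self, featurizer, registry):
        records = _constant_records()
        with pytest.raises(ConfigurationError):
            from gcri.models import train_from_scratch
            train_from_scratch(NetSpec.mlp_desk(), records, POLAR,
                               TrainProtocol(max_iterations=10, seed=0),
                               registry, featurizer)


class TestTransfer:
    def _polar_records(self, n=30):
        records = []
        for i in range(n):
            smiles = "OC" + "C" * (i % 10 + 1)
            records.append(gcri.RetentionRecord(molecule=parse_molecule(smiles),
                                                phase="DB-WAX", family="polar",
                                                ri=700.0 + 10 * i))
        return records

    def test_zero_iterations_returns_init(self, mini_training, featurizer, registry):
        net, _, _ = mini_training
        out = transfer_train(net.final_params, net.spec, self._polar_records(),
                             TrainProtocol(max_iterations=0, seed=0),
                             registry, featurizer)
        for a, b in zip(out.best_params, net.final_params):
            np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, mini_training, featurizer, registry):
        net, _, _ = mini_training
        with pytest.raises(IncompatibleInitializationError):
            transfer_train(net.final_params, NetSpec.cnn_desk(),
                           self._polar_records(),
                           TrainProtocol(max_iterations=10, seed=0),
                           registry, featurizer)

    def test_parameter_count_conserved(self, mini_training, featurizer, registry):
        net, _, _ = mini_training
        out = transfer_train(net.final_params, net.spec, self._polar_records(),
                             TrainProtocol(max_iterations=50, checkpoint_every=25,
                                           seed=0),
                             registry, featurizer)
        assert [p.shape for p in out.final_params] == \
            [p.shape for p in net.final_params]


def _constant_net(spec, family, value=1.0):
    """A net that outputs ``value`` regardless of input: zero weights, head bias."""
    net = build_net(spec, np.random.default_rng(0))
    params = [np.zeros_like(p) for p in net.params]
    params[-1] = np.full_like(params[-1], value)  # head bias
    return TrainedNet(spec=spec, family=family, final_params=params,
                      best_params=params, history=[(1, 0.0)])


class TestPrediction:
    def test_constant_net_predicts_constant(self, registry, featurizer):
        net = _constant_net(NetSpec.mlp_desk(), NON_POLAR)
        enc = sp_encode("DB-1", registry, NON_POLAR)
        for smiles in ("CCO", "c1ccccc1C"):
            assert predict_ri(net, parse_molecule(smiles), enc, featurizer) == \
                pytest.approx(1000.0)

    def test_family_mismatch_raises(self, registry, featurizer):
        net = _constant_net(NetSpec.mlp_desk(), NON_POLAR)
        enc = sp_encode("DB-WAX", registry, POLAR)
        from gcri.models import EncodingFamilyError
        with pytest.raises(EncodingFamilyError):
            predict_ri(net, parse_molecule("CCO"), enc, featurizer)

    def test_invariant_to_smiles_rendering(self, mini_training, registry, featurizer):
        net, _, _ = mini_training
        enc = sp_encode("DB-5", registry, NON_POLAR)
        a = predict_ri(net, parse_molecule("OCC(C)CC"), enc, featurizer)
        b = predict_ri(net, parse_molecule("CCC(C)CO"), enc, featurizer)
        assert a == pytest.approx(b)

    def test_round_trip_serialization(self, mini_training, registry, featurizer,
                                      tmp_path):
        net, _, _ = mini_training
        save_trained(net, tmp_path / "model")
        loaded = load_trained(tmp_path / "model")
        enc = sp_encode("DB-5", registry, NON_POLAR)
        mols = [parse_molecule("OCCCC")]
        np.testing.assert_array_equal(predict_ri_batch(net, mols, enc, featurizer),
                                      predict_ri_batch(loaded, mols, enc, featurizer))
        assert loaded.history == net.history


class TestEnsemble:
    def test_mean(self):
        assert ensemble_average([1000.0, 1100.0]) == 1050.0

    def test_identity(self):
        assert ensemble_average([842.5]) == 842.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])


class TestFeatureBlock:
    def test_block_geometry(self, tiny_ensemble, featurizer):
        nets, registry, library = tiny_ensemble
        block = ri_feature_block(nets, library[0].molecule, registry, featurizer)
        assert block.shape == (114,)
        names = feature_block_names(registry)
        assert len(names) == 114 and len(set(names)) == 114
        assert names == feature_block_names(registry)  # stable ordering

    def test_constant_nets_give_unit_block(self, registry, featurizer):
        nets = {
            "cnn": _constant_net(NetSpec.cnn_desk(), NON_POLAR),
            "mlp": _constant_net(NetSpec.mlp_desk(), NON_POLAR),
            "cnn_polar": _constant_net(NetSpec.cnn_desk(), POLAR),
            "mlp_polar": _constant_net(NetSpec.mlp_desk(), POLAR),
        }
        block = ri_feature_block(nets, parse_molecule("CCO"), registry, featurizer)
        np.testing.assert_allclose(block, np.ones(114), atol=1e-6)

    def test_missing_net_rejected(self, tiny_ensemble, featurizer):
        nets, registry, library = tiny_ensemble
        partial = {k: v for k, v in nets.items() if k != "mlp_polar"}
        with pytest.raises(IncompleteEnsembleError):
            ri_feature_matrix(partial, [library[0].molecule], registry, featurizer)

    def test_matrix_rows_match_single_blocks(self, tiny_ensemble, featurizer):
        nets, registry, library = tiny_ensemble
        mols = [a.molecule for a in library[:3]]
        matrix = ri_feature_matrix(nets, mols, registry, featurizer)
        np.testing.assert_allclose(
            matrix[1], ri_feature_block(nets, mols[1], registry, featurizer),
            rtol=1e-4, atol=1e-5)  # float32 batch reductions reorder sums


def test_transfer_initialization_preserves_shapes():
    rng = np.random.default_rng(0)
    net = build_net(NetSpec.cnn_desk(), rng)
    n_before = nn.parameter_count(net)
    nn.set_params(net, [p.copy() for p in net.params])
    assert nn.parameter_count(net) == n_before
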