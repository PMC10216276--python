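"""Assembled variants, IC50 normalization, loss, parameter accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdinn.chemgraph import smiles_to_graph
from qdinn.model import (
    DrugResponseModel,
    ResponseRecord,
    denormalize_ic50,
    load_checkpoint,
    mse,
    normalize_ic50,
    save_checkpoint,
)


class TestNormalization:
    def test_reference_values(self):
        assert normalize_ic50(1.0) == pytest.approx(0.5, abs=1e-12)
        assert normalize_ic50(1024.0) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert normalize_ic50(1.0 / 1024.0) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_reciprocal_symmetry(self, rng):
        y = rng.uniform(0.01, 100.0, size=20)
        np.testing.assert_allclose(
            normalize_ic50(y) + normalize_ic50(1.0 / y), 1.0, atol=1e-12
        )

    def test_round_trip(self, rng):
        y = np.exp(rng.uniform(np.log(1e-6), np.log(1e6), size=100))
        back = denormalize_ic50(normalize_ic50(y))
        np.testing.assert_allclose(back, y, rtol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert normalize_ic50(lo) > normalize_ic50(hi)

    @pytest.mark.parametrize("bad", [0.0, -1.0, -1e-9])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            normalize_ic50(bad)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_denormalize_domain(self, bad):
        with pytest.raises(ValueError):
            denormalize_ic50(bad)


class TestMSE:
    def test_identical_vectors(self):
        assert mse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_case(self):
        assert mse([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_against_naive_loop(self, rng):
        p = rng.normal(size=37)
        t = rng.normal(size=37)
        total = 0.0
        for i in range(37):
            total += (p[i] - t[i]) ** 2
        assert mse(p, t) == pytest.approx(total / 37, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])


def test_response_record_normalizes_on_creation():
    rec = ResponseRecord("d", "c", 1024.0)
    assert rec.ic50_norm == pytest.approx(1.0 / 3.0)
    with pytest.raises(ValueError):
        ResponseRecord("d", "c", 0.0)


class TestHeadAccounting:
    def test_hybrid_rotation_angle_count(self):
        counts, total = DrugResponseModel("hybrid", seed=0).count_head_parameters()
        assert counts["rotation_angles"] == 1320
        assert counts["readout_affine"] == 2
        assert total == 1322

    def test_classical_layer_counts(self):
        counts, total = DrugResponseModel("classical", seed=0).count_head_parameters()
        assert counts["dense1"] == 2056
        assert counts["dense2"] == 9
        assert total == 2065


def test_variants_share_identical_trunks():
    """Same seed -> bit-identical trunk weights regardless of head kind."""
    hybrid = DrugResponseModel("hybrid", seed=3)
    classical = DrugResponseModel("classical", seed=3)
    trunk_keys = [k for k in hybrid.params if k.startswith(("cell.", "drug."))]
    assert trunk_keys == [k for k in classical.params if k.startswith(("cell.", "drug."))]
    for key in trunk_keys:
        np.testing.assert_array_equal(hybrid.params[key], classical.params[key])


def test_unknown_kind_rejected():
    with pytest.raises(ValueError):
        DrugResponseModel("quantumish", seed=0)


@pytest.fixture(scope="module")
def pair():
    graph = smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")
    profile = (np.random.default_rng(9).random(735) < 0.1).astype(float)
    return graph, profile


def test_hybrid_identity_head_predicts_one(pair):
    """Zero rotation angles, readout (1, 0): every prediction is 1."""
    model = DrugResponseModel("hybrid", seed=0)
    model.params["head.theta_initial"][...] = 0.0
    model.params["head.theta_blocks"][...] = 0.0
    graph, profile = pair
    assert model.predict(graph, profile) == pytest.approx(1.0, abs=1e-10)


def test_classical_zero_weights_predict_zero(pair):
    model = DrugResponseModel("classical", seed=0)
    for key in model.params:
        model.params[key][...] = 0.0
    graph, profile = pair
    assert model.predict(graph, profile) == 0.0


@pytest.mark.parametrize("kind", ["hybrid", "classical"])
def test_prediction_determinism(kind, pair):
    model = DrugResponseModel(kind, seed=1)
    graph, profile = pair
    assert model.predict(graph, profile) == model.predict(graph, profile)


def test_forward_batch_deduplicates_graphs(pair):
    graph, profile = pair
    model = DrugResponseModel("classical", seed=1)
    preds, cache = model.forward_batch([graph, graph], np.stack([profile, profile]))
    assert cache["n_unique"] == 1
    assert preds[0] == preds[1]


def test_hybrid_head_gradients_match_finite_differences(pair, rng):
    """End-to-end loss gradients through the quantum head and smooth trunk
    weights agree with central differences."""
    graph, profile = pair
    model = DrugResponseModel("hybrid", seed=2)
    graphs, profiles = [graph], profile[None, :]
    target = np.array([0.4])

    def loss():
        p, _ = model.forward_batch(graphs, profiles)
        return float(np.mean((p - target) ** 2))

    preds, cache = model.forward_batch(graphs, profiles)
    grads = model.backward_batch(2 * (preds - target), cache)
    checked = 0
    for key in ("head.theta_initial", "head.theta_blocks", "head.out_scale",
                "head.out_shift", "drug.gcn2_W", "drug.fc1_W", "cell.fc_W"):
        p = model.params[key]
        flat = p.reshape(-1) if p.ndim else None
        gflat = np.asarray(grads[key]).reshape(-1)
        for fi in rng.integers(0, p.size, size=min(2, p.size)):
            h = 1e-6
            if p.ndim:
                orig = flat[fi]
                flat[fi] = orig + h
                up = loss()
                flat[fi] = orig - h
                down = loss()
                flat[fi] = orig
            else:
                orig = float(p)
                p[...] = orig + h
                up = loss()
                p[...] = orig - h
                down = loss()
                p[...] = orig
            assert gflat[fi] == pytest.approx(
                (up - down) / (2 * h), rel=1e-4, abs=1e-9
            )
            checked += 1
    assert checked >= 10


def test_checkpoint_round_trip(tmp_path, pair):
    graph, profile = pair
    model = DrugResponseModel("classical", seed=5)
    before = model.predict(graph, profile)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    assert (tmp_path / "ckpt.manifest.txt").exists()
    fresh = DrugResponseModel("classical", seed=99)
    load_checkpoint(fresh, tmp_path / "ckpt.npz")
    assert fresh.predict(graph, profile) == before


def test_checkpoint_kind_mismatch_rejected(tmp_path):
    model = DrugResponseModel("classical", seed=5)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    with pytest.raises(ValueError, match="mismatch"):
        load_checkpoint(DrugResponseModel("hybrid", seed=5), tmp_path / "ckpt.npz")
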