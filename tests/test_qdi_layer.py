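"""The quantum depth-infused layer: circuit semantics, gradients, readout."""

import numpy as np
import pytest

from qdinn.quantum import (
    CircuitGeometry,
    QDILayer,
    QDIParams,
    Statevector,
    count_parameters,
    describe_circuit,
    parameter_shift,
    qdi_readout,
)


def zero_angle_params(geometry):
    return QDIParams(
        np.zeros((geometry.layers_initial, geometry.n_qubits)),
        np.zeros((geometry.n_blocks, geometry.layers_per_block, geometry.n_qubits)),
    )


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(), 1320),
        (dict(n_qubits=1, layers_initial=0, layers_per_block=1, n_blocks=1), 1),
        (dict(n_qubits=4, layers_initial=2, layers_per_block=3, n_blocks=5), 68),
    ],
)
def test_count_parameters(kwargs, expected):
    assert count_parameters(CircuitGeometry(**kwargs)) == expected


def test_initialized_params_match_count(small_geometry):
    params = QDIParams.initialize(small_geometry, np.random.default_rng(0))
    assert params.n_rotation_angles == count_parameters(small_geometry)
    assert np.all(params.theta_blocks >= 0) and np.all(params.theta_blocks < 2 * np.pi)


def test_zero_angles_give_unit_expectation(rng):
    """Identity rotations leave |0...0>; RZ only adds phase; CNOTs idle."""
    geometry = CircuitGeometry()
    layer = QDILayer(geometry)
    features = rng.normal(size=geometry.n_features)
    assert layer.forward(features, zero_angle_params(geometry)) == pytest.approx(
        1.0, abs=1e-12
    )


def test_expectation_bounded(small_layer, small_params, rng):
    features = rng.normal(size=(8, small_layer.geometry.n_features))
    raw = small_layer.forward(features, small_params)
    assert np.all(np.abs(raw) <= 1.0 + 1e-12)


def test_forward_matches_gate_by_gate_simulation(small_layer, small_params, rng):
    """Cross-check the fused implementation against an explicit gate loop
    written with the public single-state gate API."""
    g = small_layer.geometry
    features = rng.normal(size=g.n_features)
    sv = Statevector.zero(g.n_qubits)

    def variational(sv, thetas):
        for j in range(g.n_qubits):
            sv = sv.ry(j, thetas[j])
        for j in range(g.n_qubits - 1):
            sv = sv.cnot(j, j + 1)
        return sv

    for l in range(g.layers_initial):
        sv = variational(sv, small_params.theta_initial[l])
    for b in range(g.n_blocks):
        for j in range(g.n_qubits):
            sv = sv.rz(j, g.encoding_scale * features[b * g.n_qubits + j])
        for l in range(g.layers_per_block):
            sv = variational(sv, small_params.theta_blocks[b, l])
    for k in range(1, g.n_qubits):
        sv = sv.cnot(k, 0)
    assert small_layer.forward(features, small_params) == pytest.approx(
        sv.z_expectation(0), abs=1e-12
    )


def test_encoding_changes_state_only_when_observable(small_layer, small_params, rng):
    """Features do change the output once variational layers mix the axes."""
    f1 = rng.normal(size=small_layer.geometry.n_features)
    f2 = f1.copy()
    f2[0] += 1.0
    assert small_layer.forward(f1, small_params) != pytest.approx(
        small_layer.forward(f2, small_params), abs=1e-6
    )


def test_single_feature_response_is_sinusoidal(small_layer, small_params, rng):
    """Output vs. one feature is a + b cos(phi) + c sin(phi), exactly."""
    features = rng.normal(size=small_layer.geometry.n_features)
    target = 4  # a feature in the second encoding block

    def f_at(value):
        fs = features.copy()
        fs[target] = value
        return small_layer.forward(fs, small_params)

    base = [0.0, np.pi / 2, np.pi]
    design = np.array([[1.0, np.cos(a), np.sin(a)] for a in base])
    coeff = np.linalg.solve(design, [f_at(a) for a in base])
    for angle in np.linspace(-3.0, 3.0, 10):
        expected = coeff[0] + coeff[1] * np.cos(angle) + coeff[2] * np.sin(angle)
        assert f_at(angle) == pytest.approx(expected, abs=1e-9)


def test_adjoint_gradient_matches_parameter_shift(small_layer, small_params, rng):
    features = rng.normal(size=small_layer.geometry.n_features)
    grads = small_layer.gradient(features, small_params)
    g = small_layer.geometry
    for _ in range(10):
        which = rng.choice(["theta_initial", "theta_blocks", "features"])
        idx = tuple(
            int(rng.integers(0, s))
            for s in np.asarray(grads[which]).shape
        )
        shift = parameter_shift(small_layer, features, small_params, which, idx)
        assert grads[which][idx] == pytest.approx(shift, abs=1e-11)


def test_feature_gradients_vanish_at_zero_angles(rng):
    """At all-zero angles the output is constant 1 along feature directions."""
    geometry = CircuitGeometry(n_qubits=4, n_blocks=3)
    layer = QDILayer(geometry)
    params = zero_angle_params(geometry)
    features = rng.normal(size=geometry.n_features)
    grads = layer.gradient(features, params)
    np.testing.assert_allclose(grads["features"], 0.0, atol=1e-12)
    h = 1e-6
    for idx in (0, 5, 11):
        fp, fm = features.copy(), features.copy()
        fp[idx] += h
        fm[idx] -= h
        central = (layer.forward(fp, params) - layer.forward(fm, params)) / (2 * h)
        assert central == pytest.approx(0.0, abs=1e-6)


def test_encoding_scale_scales_feature_gradients(small_params, rng):
    base = CircuitGeometry(n_qubits=3, n_blocks=2, layers_initial=2, layers_per_block=2)
    scaled = CircuitGeometry(
        n_qubits=3, n_blocks=2, layers_initial=2, layers_per_block=2,
        encoding_scale=0.5,
    )
    features = rng.normal(size=base.n_features)
    out_base = QDILayer(base).forward(features * 0.5, small_params)
    out_scaled = QDILayer(scaled).forward(features, small_params)
    assert out_base == pytest.approx(out_scaled, abs=1e-12)


def test_readout_affine():
    params = QDIParams(np.zeros((1, 1)), np.zeros((1, 1, 1)), 1.0, 0.0)
    assert qdi_readout(1.0, params) == 1.0
    params.out_scale, params.out_shift = 0.0, 0.5
    assert qdi_readout(-0.73, params) == 0.5
    params.out_scale, params.out_shift = 0.25, 0.5
    assert qdi_readout(-1.0, params) == 0.25


def test_prediction_gradient_readout_terms(small_layer, small_params, rng):
    features = rng.normal(size=(3, small_layer.geometry.n_features))
    grads = small_layer.prediction_gradient(features, small_params)
    raw = small_layer.forward(features, small_params)
    np.testing.assert_allclose(grads["out_shift"], 1.0)
    np.testing.assert_allclose(grads["out_scale"], raw, atol=1e-14)


def test_rejects_wrong_feature_count(small_layer, small_params):
    with pytest.raises(ValueError, match="features"):
        small_layer.forward(np.zeros(5), small_params)


def test_describe_circuit_mentions_structure():
    text = describe_circuit()
    assert "1320 rotation angles" in text
    assert "encoding block 32" in text
    assert "CNOT(7->0)" in text
    assert text.count("variational layer") >= 165
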