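"""The quantum depth-infused layer on its own.

Feeds a random 256-feature vector through the 8-qubit data re-uploading
circuit, prints the raw Z-expectation of qubit 0 and the parameter count,
and then demonstrates two exact properties: the adjoint gradient equals the
parameter-shift derivative, and the output is a pure first-order sinusoid
in any single encoded feature.
"""

import numpy as np

from qdinn.quantum import (
    CircuitGeometry,
    QDILayer,
    QDIParams,
    count_parameters,
    parameter_shift,
)

rng = np.random.default_rng(0)
geometry = CircuitGeometry()  # 8 qubits, 32 encoding blocks, 5+5 layers
layer = QDILayer(geometry)
params = QDIParams.initialize(geometry, rng)
features = rng.normal(size=geometry.n_features)

raw = layer.forward(features, params)
print(f"trainable rotation angles: {count_parameters(geometry)}")
print(f"raw <Z_0> expectation: {raw:+.6f}  (always in [-1, 1])")

grads = layer.gradient(features, params)
idx = (12, 3, 5)  # block 13, layer 4, qubit 6
shift = parameter_shift(layer, features, params, "theta_blocks", idx)
print(f"adjoint gradient at theta{idx}:     {grads['theta_blocks'][idx]:+.12f}")
print(f"parameter-shift derivative (oracle): {shift:+.12f}")

# sinusoid in one feature: fit a + b cos + c sin from three points
target = 40
def f_at(v):
    f = features.copy()
    f[target] = v
    return layer.forward(f, params)

base = [0.0, np.pi / 2, np.pi]
coeff = np.linalg.solve(
    [[1, np.cos(a), np.sin(a)] for a in base], [f_at(a) for a in base]
)
probe = 1.234
predicted = coeff[0] + coeff[1] * np.cos(probe) + coeff[2] * np.sin(probe)
print(f"3-point sinusoid fit at phi={probe}: {predicted:+.12f}")
print(f"direct simulation:                  {f_at(probe):+.12f}")
# Both derivative pairs and both sinusoid values agree to ~1e-12: the layer
# is exactly differentiable and first-order Fourier in each feature.
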