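"""Input-output nonlinearities for the firing-rate model.

Each neuron converts its synaptic input x_i into a rate phi(x_i). The
default is tanh; a rectified-linear function with a negative floor is
provided because the homeostatic rules need an unbounded, asymmetric rate
function to reach a stationary state, and a hard sign function is provided
for the steep-nonlinearity reduction and for discrete-time capacity runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

_KINDS = ("tanh", "rectified_linear", "sign", "tanh_gain")


@dataclass(frozen=True)
class Nonlinearity:
    """Pointwise rate function phi.

    Parameters
    ----------
    kind
        One of ``tanh``, ``rectified_linear``, ``sign``, ``tanh_gain``.
    gain
        Slope parameter for ``tanh_gain`` (phi(z) = tanh(gain * z)).
    floor
        Lower cutoff for ``rectified_linear`` (phi(z) = max(floor, z)).
        The default of -5 gives the negative threshold required for the
        homeostatic rules to act on below-baseline rates.
    """

    kind: str = "tanh"
    gain: float = 1.0
    floor: float = -5.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown nonlinearity kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind == "tanh_gain" and not self.gain > 0:
            raise ConfigurationError("nonlinearity gain must be positive")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return apply_phi(z, self)


def apply_phi(x: np.ndarray, phi: Nonlinearity) -> np.ndarray:
    """Apply the nonlinearity elementwise. Same shape out as in."""
    x = np.asarray(x, dtype=float)
    if phi.kind == "tanh":
        return np.tanh(x)
    if phi.kind == "rectified_linear":
        return np.maximum(phi.floor, x)
    if phi.kind == "sign":
        return np.sign(x)
    if phi.kind == "tanh_gain":
        return np.tanh(phi.gain * x)
    raise ConfigurationError(f"unknown nonlinearity kind {phi.kind!r}")


TANH = Nonlinearity("tanh")
RELU_FLOOR = Nonlinearity("rectified_linear")
SIGN = Nonlinearity("sign")
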