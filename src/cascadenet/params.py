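"""Model parameters and network geometry.

The model lives on a one-dimensional ring of retinotopic positions: each of
the three layers (retina, LGN, V1) has ``N`` neurons whose receptive-field
centers tile the interval ``[-L, L)`` uniformly.  Periodic boundary
conditions apply throughout, so every distance between positions is the
circular (minimum-image) distance on a ring of circumference ``2L``.

All times are in milliseconds and all firing rates in Hz.  The optical input
strength ``A`` and the membrane potentials are in the model's own arbitrary
units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "LayerGeometry",
    "circular_distance",
    "default_params",
]

#: Conversion from Hz (the unit in which rates and the optical drive are
#: expressed) to events per millisecond (the unit of the integrator's time
#: axis).  Used in the adaptation equations, where a rate multiplies a
#: depression fraction to give a decay rate per millisecond.
RATE_PER_MS = 1e-3


@dataclass(frozen=True)
class ModelParams:
    """All scalar constants of the cascading-adaptation network.

    Parameters
    ----------
    g : float
        Feedforward synaptic gain (dimensionless).
    tau_m : float
        Membrane time constant of LGN and V1 neurons, ms.
    alpha : float
        Saturation firing rate of the rate function, Hz.
    beta : float
        Slope of the rate function, 1/(potential unit).
    theta : float
        Half-activation threshold of the rate function, potential units.
    tau_S : float
        Recovery time constant of short-term depression (STD) at the
        thalamocortical (LGN -> V1) synapses, ms.
    tau_r : float
        Recovery time constant of retinal adaptation, ms.
    f_S : float
        STD utilization fraction in (0, 1]: how strongly presynaptic firing
        depletes synaptic strength.
    f_r : float
        Retinal-adaptation depression fraction in (0, 1].
    A : float
        Peak optical strength of the fixated stimulus, Hz-like units.
    sigma1, sigma2 : float
        Widths of the Gaussian retina->LGN and LGN->V1 tuning curves,
        position units.
    sigma_O : float
        Width of the Gaussian stimulus profile, position units.  Not listed
        among the published constants; defaults to ``sigma1``.
    w_sum : float
        Total feedforward weight received by each neuron (the Gaussian
        weight rows are normalized to this sum, which makes the coupling
        independent of the grid resolution ``N``).  Dimensionless.
    N : int
        Neurons per layer.
    L : float
        Half-width of the retinotopic position domain, position units.
    dt : float
        Integration step, ms.
    """

    g: float = 1.8
    tau_m: float = 30.0
    alpha: float = 200.0
    beta: float = 1.0
    theta: float = 6.0
    tau_S: float = 200.0
    tau_r: float = 200.0
    f_S: float = 0.75
    f_r: float = 0.75
    A: float = 60.0
    sigma1: float = 1.5
    sigma2: float = 1.5
    sigma_O: float = 1.5
    w_sum: float = 0.8
    N: int = 1000
    L: float = 10.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        positive = (
            "tau_m", "tau_S", "tau_r", "sigma1", "sigma2", "sigma_O",
            "L", "dt", "alpha", "beta", "w_sum",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.A < 0:
            raise ValueError("A must be nonnegative (0 = dark trial)")
        for name in ("f_S", "f_r"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.N < 2:
            raise ValueError("N must be at least 2")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


def default_params() -> ModelParams:
    """The published parameter set, as shipped in ``defaults.yaml``."""
    with resources.files(__package__).joinpath("defaults.yaml").open() as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def circular_distance(a, b, L: float):
    """Minimum-image distance between positions on the ring ``[-L, L)``.

    ``a`` and ``b`` may be scalars or broadcastable arrays; the ring has
    circumference ``2 L``.
    """
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.minimum(d, 2 * L - d)


def wrap_position(x, L: float):
    """Wrap a position onto the ring ``[-L, L)``."""
    return (np.asarray(x) + L) % (2 * L) - L


@dataclass(frozen=True)
class LayerGeometry:
    """Receptive-field center positions of the three layers plus fixation.

    The three layers share the same cell-centered uniform grid
    ``x_k = -L + (k + 1/2) * (2L/N)``, which avoids a duplicated endpoint
    under the periodic boundary conditions.
    """

    positions_retina: np.ndarray
    positions_lgn: np.ndarray
    positions_v1: np.ndarray
    fixation: float = 0.0

    @classmethod
    def from_params(cls, params: ModelParams, fixation: float = 0.0) -> "LayerGeometry":
        x = -params.L + (np.arange(params.N) + 0.5) * (2 * params.L / params.N)
        return cls(positions_retina=x, positions_lgn=x.copy(),
                   positions_v1=x.copy(), fixation=float(fixation))

    @property
    def spacing(self) -> float:
        return float(self.positions_retina[1] - self.positions_retina[0])

    @property
    def half_width(self) -> float:
        x = self.positions_retina
        return float((x[-1] + 0.5 * (x[1] - x[0])))

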