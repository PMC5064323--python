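"""Network state, connectivity, and the right-hand side of the dynamics.

The model is a feedforward cascade

    optical drive O_k --(retinal adaptation r_k)--> retina R_k
    retina --(Gaussian weights W_jk)--> LGN membrane V_j, rate R_j
    LGN --(Gaussian weights W_ij, STD strength S_j)--> V1 membrane V_i, R_i

with dynamics (time in ms, rates in Hz)::

    tau_m dV_j/dt = -V_j + g * sum_k W_jk R_k
    R_j           = alpha / (1 + exp(-beta (V_j - theta)))
    tau_m dV_i/dt = -V_i + g * sum_j W_ij S_j R_j
    R_i           = alpha / (1 + exp(-beta (V_i - theta)))
    R_k           = r_k O_k
    dS_j/dt       = (1 - S_j)/tau_S - f_S S_j R_j * 1e-3
    dr_k/dt       = (1 - r_k)/tau_r - f_r r_k O_k * 1e-3

The factor 1e-3 converts the Hz-valued rate (or the Hz-like optical
strength) into events per millisecond so that it can act as a depletion
rate on the millisecond time axis shared by all time constants.

The weight matrices are circulant: Gaussian in the circular distance
between receptive-field centers, with every row normalized to sum to
``w_sum`` so the total synaptic weight a neuron receives does not depend on
the grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import RATE_PER_MS, LayerGeometry, ModelParams, circular_distance

__all__ = [
    "Connectivity",
    "NetworkState",
    "StateDerivative",
    "build_connectivity",
    "ring_kernel",
    "rate_function",
    "derivatives",
]


@dataclass(frozen=True)
class Connectivity:
    """Feedforward weight matrices.

    ``W_jk[j, k]`` is the weight from retinal cell *k* onto LGN neuron *j*;
    ``W_ij[i, j]`` from LGN neuron *j* onto V1 neuron *i*.  Both are
    circulant (translation invariant on the ring), strictly positive, and
    symmetric about the diagonal.
    """

    W_jk: np.ndarray
    W_ij: np.ndarray


def gaussian_row(distances: np.ndarray, sigma: float, w_sum: float) -> np.ndarray:
    """One row of a normalized Gaussian weight profile.

    The profile is ``exp(-d^2 / (2 sigma^2))`` scaled so the row sums to
    ``w_sum``.
    """
    if sigma <= 0:
        raise ValueError("tuning width sigma must be strictly positive")
    w = np.exp(-np.asarray(distances, dtype=float) ** 2 / (2.0 * sigma ** 2))
    return w * (w_sum / w.sum())


def ring_kernel(params: ModelParams, geometry: LayerGeometry, sigma: float) -> np.ndarray:
    """The first row of the circulant weight matrix with width ``sigma``.

    Because the grids of the two connected layers coincide, the full matrix
    is the circulant generated by this kernel; the simulator applies it by
    circular convolution instead of a dense matrix product.
    """
    x = geometry.positions_lgn
    d = circular_distance(x, x[0], params.L)
    return gaussian_row(d, sigma, params.w_sum)


def build_connectivity(params: ModelParams, geometry: LayerGeometry) -> Connectivity:
    """Dense Gaussian weight matrices for both feedforward projections.

    Raises
    ------
    ValueError
        If the geometry grid length does not match ``params.N`` or a tuning
        width is not positive.
    """
    for grid in (geometry.positions_retina, geometry.positions_lgn,
                 geometry.positions_v1):
        if len(grid) != params.N:
            raise ValueError(
                f"geometry grid length {len(grid)} does not match N={params.N}"
            )
    xj = geometry.positions_lgn[:, None]
    xk = geometry.positions_retina[None, :]
    d1 = circular_distance(xj, xk, params.L)
    xi = geometry.positions_v1[:, None]
    d2 = circular_distance(xi, geometry.positions_lgn[None, :], params.L)
    w1 = np.exp(-d1 ** 2 / (2.0 * params.sigma1 ** 2))
    w2 = np.exp(-d2 ** 2 / (2.0 * params.sigma2 ** 2))
    if not (params.sigma1 > 0 and params.sigma2 > 0):
        raise ValueError("sigma1 and sigma2 must be strictly positive")
    w1 *= params.w_sum / w1.sum(axis=1, keepdims=True)
    w2 *= params.w_sum / w2.sum(axis=1, keepdims=True)
    return Connectivity(W_jk=w1, W_ij=w2)


def rate_function(V, params: ModelParams):
    """Sigmoidal rate function ``alpha / (1 + exp(-beta (V - theta)))``.

    Monotonically increasing in ``V`` and bounded in ``(0, alpha)``; at
    ``V = theta`` it returns the half-saturation rate ``alpha / 2``.
    """
    V = np.asarray(V, dtype=float)
    # evaluate in a form that never overflows for very negative V
    z = params.beta * (V - params.theta)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = params.alpha / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = params.alpha * ez / (1.0 + ez)
    return out


@dataclass
class NetworkState:
    """Per-neuron dynamical variables at one instant.

    ``S`` is the synaptic strength of the thalamocortical synapses (one per
    LGN neuron, shared by all its V1 targets); ``r`` the retinal adaptation
    factor.  Both live in ``(0, 1]``.
    """

    V_lgn: np.ndarray
    V_v1: np.ndarray
    R_ret: np.ndarray
    R_lgn: np.ndarray
    R_v1: np.ndarray
    S: np.ndarray
    r: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, params: ModelParams) -> "NetworkState":
        """Rest state: zero potentials, fully recovered synapses."""
        z = np.zeros(params.N)
        return cls(V_lgn=z.copy(), V_v1=z.copy(), R_ret=z.copy(),
                   R_lgn=rate_function(z, params),
                   R_v1=rate_function(z, params),
                   S=np.ones(params.N), r=np.ones(params.N), t=0.0)

    def copy(self) -> "NetworkState":
        return NetworkState(*(v.copy() if isinstance(v, np.ndarray) else v
                              for v in (self.V_lgn, self.V_v1, self.R_ret,
                                        self.R_lgn, self.R_v1, self.S,
                                        self.r, self.t)))


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives of the dynamical variables (per ms)."""

    dV_lgn: np.ndarray
    dV_v1: np.ndarray
    dS: np.ndarray
    dr: np.ndarray


def derivatives(state: NetworkState, drive: np.ndarray, conn: Connectivity,
                params: ModelParams, std_enabled: bool = True) -> StateDerivative:
    """Right-hand side of the network dynamics.

    Also refreshes the algebraic rate variables (``R_ret``, ``R_lgn``,
    ``R_v1``) of ``state`` in place, since they are instantaneous functions
    of the drive and the potentials.

    With ``std_enabled=False`` the thalamocortical synapses are pinned at
    full strength: ``S`` is treated as 1 in the V1 drive and ``dS = 0``.
    """
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (params.N,) or state.V_lgn.shape != (params.N,):
        raise ValueError("state/drive dimensions do not match params.N")

    state.R_ret = state.r * drive
    state.R_lgn = rate_function(state.V_lgn, params)
    state.R_v1 = rate_function(state.V_v1, params)

    S_eff = state.S if std_enabled else np.ones(params.N)
    dV_lgn = (-state.V_lgn + params.g * (conn.W_jk @ state.R_ret)) / params.tau_m
    dV_v1 = (-state.V_v1 + params.g * (conn.W_ij @ (S_eff * state.R_lgn))) / params.tau_m
    if std_enabled:
        dS = (1.0 - state.S) / params.tau_S \
            - params.f_S * state.S * state.R_lgn * RATE_PER_MS
    else:
        dS = np.zeros(params.N)
    dr = (1.0 - state.r) / params.tau_r \
        - params.f_r * state.r * drive * RATE_PER_MS
    return StateDerivative(dV_lgn=dV_lgn, dV_v1=dV_v1, dS=dS, dr=dr)
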