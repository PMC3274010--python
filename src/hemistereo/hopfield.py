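"""Disparity-map smoothing by analog Hopfield-network energy minimization.

The smoothness constraint says disparities vary smoothly inside a
neighbourhood except at object edges.  Every matched (candidate) pixel
becomes a network node whose activation ``D_i`` is its disparity mapped
linearly to [-1, +1]; excluded pixels are absent from the network.  For
8-connected active neighbours the data consistency is

    w_ik = 1 - |D_i - D_k|      (in [-1, +1]),

which is turned into a connection weight ``T_ik`` by a sign rule that
rewards (lowers the energy of) consistent data with consistent states
and punishes every inconsistency; the self-data bias is ``U_i = B D_i``
frozen at the iteration's entry states.  The energy

    E = -(1/2) sum_ik T_ik D_i D_k - sum_i U_i D_i

is descended by integrating the analog Hopfield dynamics

    du_i/dt = -u_i / R_i + sum_k T_ik D_k + U_i,   D_i = tanh(u_i / beta)

with classical 4th-order Runge-Kutta.  Each outer iteration freezes
``T`` and ``U``, integrates K inner steps of size dt, then recomputes
them from the new states; the run stops when no node moves by more than
``epsilon_conv`` or after ``t_max`` outer iterations.

The hyperbolic-tangent activation saturates: a region whose states
share a sign is driven toward that extreme (+1 or -1).  This suits
disparity maps whose in-range values cluster at the map limits (near
objects clip at theta_max) and is the documented behaviour for
mid-range plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .matching import DisparityMap

__all__ = [
    "HNNParams",
    "HNNState",
    "normalize_disparity",
    "denormalize_disparity",
    "consistency_coefficient",
    "contextual_term",
    "connection_weight",
    "total_energy",
    "annealing_beta",
    "calibrate_beta0",
    "build_network",
    "hnn_iterate",
    "hnn_run",
]

_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class HNNParams:
    """Network constants.

    ``gain_beta`` is the activation scale (gain = 1/beta = 2.30);
    ``beta0`` feeds the optional annealing schedule
    ``beta(t) = beta0 / log10(t + 1)``; ``inner_steps_K`` Runge-Kutta
    steps of size ``dt`` are integrated per outer iteration (a single
    dt step would move states by ~1e-3, below the convergence
    tolerance, and stall the run).
    """

    neighbourhood_m: int = 8
    gain_beta: float = 0.43
    beta0: float = 4.35
    dt: float = 1e-3
    time_constant_Ri: float = 1.0
    const_A: float = 1.0
    const_B: float = 1.0
    epsilon_conv: float = 0.01
    t_max: int = 20
    inner_steps_K: int = 1000
    use_annealing: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gain_beta <= 0:
            raise ValueError("dt and gain_beta must be positive")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.const_A <= 0 or self.const_B <= 0:
            raise ValueError("const_A and const_B must be positive")
        if self.neighbourhood_m != 8:
            raise ValueError("only the 8-neighbourhood is implemented")


@dataclass
class HNNState:
    """States, inputs and bookkeeping of the network."""

    states_D: np.ndarray                    # (n,) activations in [-1, 1]
    inputs_u: np.ndarray                    # (n,) internal inputs
    active_index: np.ndarray                # (n, 2) row/col of active pixels
    shape: tuple[int, int]
    edges: tuple[np.ndarray, np.ndarray]    # directed neighbour pairs (i, k)
    energy_trace: list[float] = field(default_factory=list)
    changed_count_nc: int = -1
    iterations: int = 0
    inner_energy: list[np.ndarray] = field(default_factory=list)


def normalize_disparity(dtheta, theta_max: float):
    """Linear map [0, theta_max] -> [-1, +1]; NaN (null) stays NaN (inactive)."""
    d = np.asarray(dtheta, dtype=np.float64)
    out = 2.0 * d / theta_max - 1.0
    return float(out) if np.isscalar(dtheta) else out


def denormalize_disparity(D, theta_max: float):
    d = np.asarray(D, dtype=np.float64)
    out = (d + 1.0) * theta_max / 2.0
    return float(out) if np.isscalar(D) else out


def consistency_coefficient(D_i: float, D_k: float, are_neighbours: bool = True) -> float:
    """w_ik = 1 - |D_i - D_k| for neighbours, else 0 (also 0 for i = k)."""
    if not are_neighbours:
        return 0.0
    return 1.0 - abs(float(D_i) - float(D_k))


def contextual_term(D_i: float, neighbour_states) -> float:
    """Contextual consistency E_i = sum_k D_i * D_k over the neighbourhood."""
    nk = np.asarray(neighbour_states, dtype=np.float64)
    return float((float(D_i) * nk).sum())


def _sign_factor(w, D_i, D_k):
    """[sgn(w)]^(v+1) with sgn(0) = -1 and v = #negatives among {w, D_i, D_k}."""
    sgn = np.where(np.asarray(w) > 0, 1.0, -1.0)
    v = (np.asarray(w) < 0).astype(int) + (np.asarray(D_i) < 0) + (np.asarray(D_k) < 0)
    return sgn ** (v + 1)


def connection_weight(w_ik: float, D_i: float, D_k: float, i=0, k=1, A: float = 1.0) -> float:
    """T_ik from the consistency sign rule; the diagonal is forced to zero."""
    if i == k:
        return 0.0
    return float(A * _sign_factor(w_ik, D_i, D_k) * w_ik)


def total_energy(D: np.ndarray, T: sparse.spmatrix, U: np.ndarray) -> float:
    """E = -(1/2) D^T T D - U . D (the smoothing energy; T symmetric, zero diagonal)."""
    D = np.asarray(D, dtype=np.float64)
    return float(-0.5 * D @ (T @ D) - np.dot(U, D))


def annealing_beta(t: float, beta0: float = 4.35) -> float:
    """Annealing schedule beta(t) = beta0 / log10(t + 1)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return beta0 / np.log10(t + 1.0)


def calibrate_beta0(mean_delta_E: float) -> float:
    """beta0 = 5 <dE> (first-order Taylor solution of the 80%-acceptance rule)."""
    return 5.0 * mean_delta_E


def build_network(disparity: DisparityMap, params: HNNParams) -> HNNState:
    """Initialize nodes from the disparity map; null pixels are absent."""
    values = disparity.values
    active = np.isfinite(values)
    rows, cols = np.nonzero(active)
    n = rows.size
    idx_map = np.full(values.shape, -1, dtype=int)
    idx_map[rows, cols] = np.arange(n)

    ii, kk = [], []
    h, w = values.shape
    for dr, dc in _OFFSETS8:
        r2 = rows + dr
        c2 = cols + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        ok[ok] &= idx_map[r2[ok], c2[ok]] >= 0
        ii.append(np.arange(n)[ok])
        kk.append(idx_map[r2[ok], c2[ok]])
    edges = (np.concatenate(ii) if ii else np.empty(0, int),
             np.concatenate(kk) if kk else np.empty(0, int))

    D = normalize_disparity(values[rows, cols], disparity.theta_max)
    # initial internal inputs consistent with D = tanh(u / beta)
    clipped = np.clip(D, -1.0 + 1e-7, 1.0 - 1e-7)
    u = params.gain_beta * np.arctanh(clipped)
    return HNNState(
        states_D=np.asarray(D, dtype=np.float64).reshape(-1),
        inputs_u=u.reshape(-1),
        active_index=np.stack([rows, cols], axis=1) if n else np.empty((0, 2), int),
        shape=values.shape,
        edges=edges,
    )


def _weights_and_bias(state: HNNState, params: HNNParams):
    """Recompute w_ik, T_ik and U_i from the current states."""
    i, k = state.edges
    D = state.states_D
    w = 1.0 - np.abs(D[i] - D[k])
    T_vals = params.const_A * _sign_factor(w, D[i], D[k]) * w
    n = D.size
    T = sparse.csr_matrix((T_vals, (i, k)), shape=(n, n))
    U = params.const_B * D.copy()
    return T, U


def hnn_iterate(state: HNNState, params: HNNParams, record_inner_energy: bool = False) -> HNNState:
    """One outer iteration: freeze T and U, integrate K Runge-Kutta steps.

    Returns the same state object updated in place; ``changed_count_nc``
    holds the number of nodes whose activation moved by more than the
    convergence tolerance.
    """
    T, U = _weights_and_bias(state, params)
    beta = (
        annealing_beta(state.iterations + 1, params.beta0)
        if params.use_annealing
        else params.gain_beta
    )
    Ri = params.time_constant_Ri
    u = state.inputs_u.copy()
    D_prev = state.states_D.copy()

    def f(uu):
        return -uu / Ri + T @ np.tanh(uu / beta) + U

    dt = params.dt
    trace = []
    if record_inner_energy:
        trace.append(total_energy(np.tanh(u / beta), T, U))
    for _ in range(params.inner_steps_K):
        k1 = f(u)
        k2 = f(u + 0.5 * dt * k1)
        k3 = f(u + 0.5 * dt * k2)
        k4 = f(u + dt * k3)
        u = u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if record_inner_energy:
            trace.append(total_energy(np.tanh(u / beta), T, U))
    if not np.all(np.isfinite(u)):
        raise FloatingPointError(
            f"non-finite network input at outer iteration {state.iterations + 1}"
        )
    D = np.tanh(u / beta)
    state.inputs_u = u
    state.states_D = D
    state.iterations += 1
    state.changed_count_nc = int(np.sum(np.abs(D - D_prev) > params.epsilon_conv))
    state.energy_trace.append(total_energy(D, T, U))
    if record_inner_energy:
        state.inner_energy.append(np.asarray(trace))
    return state


def hnn_run(
    disparity: DisparityMap,
    params: HNNParams | None = None,
    record_inner_energy: bool = False,
) -> tuple[DisparityMap, HNNState]:
    """Smooth a disparity map until the network stabilizes.

    Iterates :func:`hnn_iterate` until ``nc = 0`` or ``t_max`` outer
    iterations, then maps the activations back to degrees.  Null pixels
    stay null.  Returns the smoothed map and the final network state
    (with the per-iteration energy trace).
    """
    params = params if params is not None else HNNParams()
    state = build_network(disparity, params)
    if state.states_D.size:
        for _ in range(params.t_max):
            hnn_iterate(state, params, record_inner_energy=record_inner_energy)
            if state.changed_count_nc == 0:
                break
    values = np.full(disparity.values.shape, np.nan)
    if state.states_D.size:
        rows, cols = state.active_index[:, 0], state.active_index[:, 1]
        out = denormalize_disparity(state.states_D, disparity.theta_max)
        values[rows, cols] = np.clip(out, 0.0, disparity.theta_max)
    return DisparityMap(values=values, theta_max=disparity.theta_max), state


def write_energy_trace(state: HNNState, path) -> None:
    """Energy trace as CSV (iteration, E, nc of the final iteration)."""
    import pandas as pd

    pd.DataFrame(
        {
            "iteration": np.arange(1, len(state.energy_trace) + 1),
            "energy": state.energy_trace,
        }
    ).to_csv(path, index=False)
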