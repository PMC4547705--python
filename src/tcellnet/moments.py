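"""Exact first and second moments of the branching network, and delta-method
moments of relative frequencies.

For a multi-type Galton-Watson process with mean offspring matrix ``M``
(rows = parent type) and per-parent offspring covariances ``V_j``, the count
vector Z(n) satisfies the standard recursions

    mu(n+1)    = M^T mu(n)
    Sigma(n+1) = M^T Sigma(n) M + sum_j mu_j(n) V_j

Relative frequencies f = Z_s / (1^T Z_s) over a measured scope ``s`` are
handled by first-order (delta-method) propagation through the normalization
map at the mean, giving a frequency mean ``pi`` and a singular covariance
``Omega`` whose rows sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelParameters,
    NetworkTopology,
    PopulationState,
    TypeSpace,
    build_type_space,
    offspring_covariance,
    offspring_mean_matrix,
)

__all__ = [
    "MomentState",
    "FrequencyMoments",
    "MomentOperators",
    "step_moments",
    "propagate_moments",
    "frequency_moments",
    "moments_to_frame",
]


@dataclass
class MomentState:
    """Mean vector (cells) and covariance (cells^2) over the type space at step n."""

    n: int
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        D = self.mean.shape[0]
        if self.cov.shape != (D, D):
            raise ValueError(f"cov shape {self.cov.shape} != ({D}, {D})")


@dataclass
class FrequencyMoments:
    """Delta-method mean ``pi`` and covariance ``Omega`` of scoped frequencies."""

    pi: np.ndarray
    omega: np.ndarray
    categories: tuple  # the (compartment, generation) labels, or indices

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)


class MomentOperators:
    """Precomputed mean matrix and offspring-covariance tensor for one theta."""

    def __init__(
        self,
        params: ModelParameters,
        topology: NetworkTopology,
        type_space: TypeSpace | None = None,
        allow_unnormalized_rho: bool = False,
    ):
        self.type_space = type_space or build_type_space(topology, params.p)
        ts = self.type_space
        self.M = offspring_mean_matrix(
            params, topology, ts, _allow_unnormalized_rho=allow_unnormalized_rho
        )
        # V[j] as a dense (D, D, D) tensor; D is a few dozen so this is cheap.
        D = ts.size
        self.V = np.zeros((D, D, D))
        for j, t in enumerate(ts.types):
            self.V[j] = offspring_covariance(
                t, params, topology, ts, _allow_unnormalized_rho=allow_unnormalized_rho
            )


def step_moments(state: MomentState, ops: MomentOperators) -> MomentState:
    """One step of the mean/covariance recursion."""
    M = ops.M
    if state.mean.shape[0] != M.shape[0]:
        raise ValueError("moment state dimension does not match operators")
    mean = M.T @ state.mean
    branching = np.tensordot(state.mean, ops.V, axes=1)
    cov = M.T @ state.cov @ M + branching
    cov = 0.5 * (cov + cov.T)
    return MomentState(n=state.n + 1, mean=mean, cov=cov)


def propagate_moments(
    initial: PopulationState,
    params: ModelParameters,
    topology: NetworkTopology,
    n_steps: int,
    ops: MomentOperators | None = None,
) -> list[MomentState]:
    """Moment trajectory for n = 0..n_steps from a deterministic initial state."""
    ops = ops or MomentOperators(params, topology)
    D = ops.type_space.size
    state = MomentState(n=initial.n, mean=initial.counts.astype(float), cov=np.zeros((D, D)))
    out = [state]
    for _ in range(n_steps):
        state = step_moments(state, ops)
        out.append(state)
    return out


def frequency_moments(
    state: MomentState, indices: np.ndarray, categories: tuple | None = None
) -> FrequencyMoments:
    """Delta-method moments of f = Z_s / (1^T Z_s) over the scoped categories.

    The Jacobian of z -> z / (1^T z) at mu_s is J = (I - pi 1^T) / S with
    S = 1^T mu_s, so Omega = J Sigma_s J^T; Omega 1 = 0 by construction.
    """
    idx = np.asarray(indices, dtype=int)
    mu_s = state.mean[idx]
    S = mu_s.sum()
    if S <= 0:
        raise ZeroDivisionError(
            "total expected count in scope is zero; frequencies undefined"
        )
    pi = mu_s / S
    sigma_s = state.cov[np.ix_(idx, idx)]
    J = (np.eye(len(idx)) - np.outer(pi, np.ones(len(idx)))) / S
    omega = J @ sigma_s @ J.T
    omega = 0.5 * (omega + omega.T)
    cats = categories if categories is not None else tuple(idx.tolist())
    return FrequencyMoments(pi=pi, omega=omega, categories=cats)


def moments_to_frame(
    trajectory: list[MomentState],
    type_space: TypeSpace,
    dt_hours: float = 4.0,
    t0_hours: float = 72.0,
):
    """Tidy export: columns n, time_hours, compartment, generation, mean, variance."""
    import pandas as pd

    rows = []
    for st in trajectory:
        var = np.diag(st.cov)
        for k, (comp, gen) in enumerate(type_space.types):
            rows.append(
                {
                    "n": st.n,
                    "time_hours": t0_hours + dt_hours * st.n,
                    "compartment": comp,
                    "generation": gen,
                    "mean": st.mean[k],
                    "variance": var[k],
                }
            )
    return pd.DataFrame(rows)
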