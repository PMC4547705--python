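"""Exact stochastic simulation of the branching dissemination network.

Cells of one type share a fate law, so the per-step update draws a single
multinomial over that type's fate outcomes with Z trials, which is equal in
law to sampling each of the Z cells independently.  One trajectory step costs
O(D) multinomial draws regardless of population size.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ModelParameters,
    NetworkTopology,
    PopulationState,
    TypeSpace,
    build_type_space,
    offspring_distribution,
    validate_parameters,
)

__all__ = ["FateTable", "simulate_step", "simulate_paths"]


class FateTable:
    """Per-type fate outcomes precompiled for fast repeated sampling."""

    def __init__(self, params: ModelParameters, topology: NetworkTopology,
                 type_space: TypeSpace | None = None):
        bad = validate_parameters(params, topology)
        if bad:
            raise ValueError("invalid parameters: " + "; ".join(bad))
        self.type_space = type_space or build_type_space(topology, params.p)
        ts = self.type_space
        self.probs: list[np.ndarray] = []
        # offspring[j] has one row per fate outcome, D columns of offspring counts
        self.offspring: list[np.ndarray] = []
        for t in ts.types:
            branches = offspring_distribution(t, params, topology)
            pr = np.array([p for p, _ in branches])
            off = np.zeros((len(branches), ts.size), dtype=np.int64)
            for b, (_, o) in enumerate(branches):
                for dest, cnt in o.items():
                    off[b, ts.index(*dest)] += cnt
            self.probs.append(pr)
            self.offspring.append(off)


def simulate_step(
    state: PopulationState,
    params: ModelParameters,
    topology: NetworkTopology,
    rng: np.random.Generator,
    fate_table: FateTable | None = None,
) -> PopulationState:
    """Advance every cell one step; rng is consumed only for nonzero types."""
    ft = fate_table or FateTable(params, topology, state.type_space)
    nxt = np.zeros(state.type_space.size, dtype=np.int64)
    for j in np.nonzero(state.counts)[0]:
        z = int(state.counts[j])
        fates = rng.multinomial(z, ft.probs[j])
        nxt += fates @ ft.offspring[j]
    return PopulationState(n=state.n + 1, counts=nxt, type_space=state.type_space)


def simulate_paths(
    initial: PopulationState,
    params: ModelParameters,
    topology: NetworkTopology,
    n_steps: int,
    n_paths: int,
    seed: int,
) -> np.ndarray:
    """Ensemble of independent trajectories.

    Returns an (n_paths, n_steps + 1, D) integer array.  Each path draws from
    its own substream spawned from ``seed``, so path i is reproducible and
    independent of ``n_paths``.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    ft = FateTable(params, topology, initial.type_space)
    D = initial.type_space.size
    out = np.zeros((n_paths, n_steps + 1, D), dtype=np.int64)
    streams = np.random.SeedSequence(seed).spawn(n_paths)
    for i in range(n_paths):
        rng = np.random.default_rng(streams[i])
        state = initial
        out[i, 0] = state.counts
        for n in range(1, n_steps + 1):
            state = simulate_step(state, params, topology, rng, ft)
            out[i, n] = state.counts
    return out
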