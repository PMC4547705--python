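"""CFSE-style synthetic datasets with the sacrifice-sampling study design.

Groups of animals are "sacrificed" at each measurement step: every animal's
organ x generation counts come from an independent stochastic realization of
the branching network started from a common initial draining-node population,
so inter-animal variability is exactly the branching-process noise (plus an
optional lognormal jitter of the initial size emulating extra inter-individual
heterogeneity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import COUNTS_COLUMNS, ObservedDataset, T0_HOURS
from .model import (
    ModelParameters,
    NetworkTopology,
    PopulationState,
    build_type_space,
    default_topology,
    reference_parameters,
)
from .simulate import FateTable, simulate_step

__all__ = ["DesignSpec", "generate_synthetic_dataset", "default_fixture",
           "FIXTURE_SEED"]

#: Fixture seed (fixed so the canonical dataset regenerates identically).
FIXTURE_SEED = 20150824

#: Fixture initial generation mix in the draining node at T = 72 h: mass over
#: generations 0-4, qualitatively matching 72 h CFSE histograms.
FIXTURE_COMPOSITION = {0: 0.10, 1: 0.25, 2: 0.30, 3: 0.25, 4: 0.10}


@dataclass
class DesignSpec:
    """Sampling design: who is measured when, and from what initial state."""

    animals_per_step: int = 5
    steps: tuple[int, ...] = (0, 3, 6)
    initial_size: int = 50_000
    initial_composition: dict[int, float] = field(
        default_factory=lambda: dict(FIXTURE_COMPOSITION)
    )
    theta_true: ModelParameters = field(default_factory=reference_parameters)
    topology: NetworkTopology = field(default_factory=default_topology)
    seed: int = FIXTURE_SEED
    size_jitter_cv: float = 0.0  # lognormal CV of per-animal initial size (0 = off)

    def __post_init__(self) -> None:
        if self.animals_per_step < 1:
            raise ValueError("need at least one animal per step")
        steps = tuple(sorted(int(s) for s in self.steps))
        if not steps or steps[0] != 0:
            raise ValueError(f"steps must start at 0, got {steps}")
        self.steps = steps
        tot = sum(self.initial_composition.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"initial composition sums to {tot}, not 1")

    def initial_counts(self) -> np.ndarray:
        """Deterministic per-generation counts in the source (length p + 1)."""
        p = self.theta_true.p
        vec = np.zeros(p + 1)
        for gen, frac in self.initial_composition.items():
            if not (0 <= gen <= p):
                raise ValueError(f"initial generation {gen} outside 0..{p}")
            vec[gen] = round(frac * self.initial_size)
        return vec


def _initial_state(design: DesignSpec, rng: np.random.Generator) -> PopulationState:
    ts = build_type_space(design.topology, design.theta_true.p)
    base = design.initial_counts()
    if design.size_jitter_cv > 0:
        cv = design.size_jitter_cv
        sigma = np.sqrt(np.log1p(cv**2))
        factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        base = np.round(base * factor)
    vec = np.zeros(ts.size)
    src = design.topology.source
    for gen, z in enumerate(base):
        vec[ts.index(src, gen)] = z
    return PopulationState(n=0, counts=vec, type_space=ts)


def generate_synthetic_dataset(design: DesignSpec) -> tuple[ObservedDataset, dict]:
    """Simulate one dataset under the design; returns (dataset, truth dict).

    Each animal is an independent path from the initial state to its sacrifice
    step; only the measured organs (source and sinks) are recorded, emulating
    the inaccessibility of cells in transit.
    """
    topo = design.topology
    params = design.theta_true
    p = params.p
    measured = topo.measured_compartments
    streams = np.random.SeedSequence(design.seed).spawn(
        len(design.steps) * design.animals_per_step
    )
    ft = None
    rows = []
    k = 0
    for n in design.steps:
        for a in range(design.animals_per_step):
            rng = np.random.default_rng(streams[k]); k += 1
            state = _initial_state(design, rng)
            if ft is None:
                ft = FateTable(params, topo, state.type_space)
            for _ in range(n):
                state = simulate_step(state, params, topo, rng, ft)
            ts = state.type_space
            animal_id = f"n{n}_a{a + 1}"
            for organ in measured:
                for gen in range(p + 1):
                    rows.append(
                        {
                            "animal_id": animal_id,
                            "time_hours": T0_HOURS + 4.0 * n,
                            "n": n,
                            "organ": organ,
                            "generation": gen,
                            "count": int(state.counts[ts.index(organ, gen)]),
                        }
                    )
    dataset = ObservedDataset(
        records=pd.DataFrame(rows, columns=COUNTS_COLUMNS), p=p, topology=topo
    )
    truth = {
        "theta_true": {
            k: float(v)
            for k, v in zip(
                ("delta_0", "gamma_0", "delta_1", "gamma_1", "delta_2", "gamma_2",
                 "m", "rho_spl", "rho_il", "rho_mes"),
                params.theta(),
            )
        },
        "seed": design.seed,
        "design": {
            "animals_per_step": design.animals_per_step,
            "steps": list(design.steps),
            "initial_size": design.initial_size,
            "initial_composition": {
                str(g): f for g, f in design.initial_composition.items()
            },
            "size_jitter_cv": design.size_jitter_cv,
        },
    }
    return dataset, truth


def default_fixture(seed: int = FIXTURE_SEED) -> tuple[ObservedDataset, dict]:
    """The canonical dataset: study parameter estimates as truth, 5 x 10^4
    initial draining-node cells over generations 0-4, 5 animals at each of
    n in {0, 3, 6}."""
    return generate_synthetic_dataset(DesignSpec(seed=seed))


def write_fixture_files(design: DesignSpec, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>_counts.csv`` and ``<prefix>_truth.json``."""
    dataset, truth = generate_synthetic_dataset(design)
    counts_path = f"{out_prefix}_counts.csv"
    truth_path = f"{out_prefix}_truth.json"
    dataset.to_csv(counts_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return counts_path, truth_path
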