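"""Multi-type Galton-Watson offspring law on a feedforward organ network.

The population is structured by *type* = (compartment, generation).  Compartments
form a feedforward dissemination network: a single source (the draining lymph
nodes, where antigen-driven proliferation starts), a chain of serial transfer
stages (lymphatic/blood vessels traversed en route), and terminal sinks (spleen
and distal lymph nodes).  Generation is the number of divisions a cell has
undergone since CFSE labeling; it is tracked up to a cap ``p`` set by the dye's
resolution.

Each cell acts independently once per time step of ``dt_hours``:

* in the source, generation ``i``: divide with probability ``gamma_i`` (two
  daughters of generation ``i+1``), stay quiescent with ``delta_i``, migrate out
  with ``m`` (only generations in the migrating set), or die with the residual
  probability;
* in a transfer stage: advance one stage (pure delay by default);
* leaving the last transfer stage: enter sink ``s`` with splitting probability
  ``rho_s``;
* in a sink: divide / quiesce / die with the same generation-indexed
  probabilities (no onward migration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "NetworkTopology",
    "TypeSpace",
    "PopulationState",
    "THETA_NAMES",
    "build_type_space",
    "offspring_distribution",
    "offspring_mean_matrix",
    "offspring_covariance",
    "validate_parameters",
    "reference_parameters",
    "default_topology",
]

#: Canonical ordering of the 10 estimated parameters.
THETA_NAMES = (
    "delta_0", "gamma_0", "delta_1", "gamma_1", "delta_2", "gamma_2",
    "m", "rho_spl", "rho_il", "rho_mes",
)

#: Config-file rho keys -> default sink compartment labels.
RHO_KEY_TO_SINK = {"spl": "SPL", "il": "ILN", "mes": "MLN"}
SINK_TO_RHO_KEY = {v: k for k, v in RHO_KEY_TO_SINK.items()}

_SIMPLEX_TOL = 1e-12


class ConfigurationError(ValueError):
    """Invalid topology / type-space configuration."""


class ParameterError(ValueError):
    """Parameter vector violates a model invariant."""


@dataclass(frozen=True)
class NetworkTopology:
    """Feedforward compartment graph: source -> TR1 -> ... -> TRK -> sinks.

    ``transfer_stages`` are the *occupied* intermediate compartments.  A cell
    leaving the source spends one step per transfer stage plus the terminal
    splitting transition, so the source-to-sink transit takes
    ``len(transfer_stages) + 1`` steps.
    """

    source: str = "DR"
    transfer_stages: tuple[str, ...] = ("TR1", "TR2")
    sinks: tuple[str, ...] = ("SPL", "ILN", "MLN")

    def __post_init__(self) -> None:
        if not self.source:
            raise ConfigurationError("topology needs a source compartment")
        labels = (self.source, *self.transfer_stages, *self.sinks)
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate compartment labels in {labels}")

    @classmethod
    def from_transit_time(
        cls,
        transit_hours: float,
        dt_hours: float,
        source: str = "DR",
        sinks: Sequence[str] = ("SPL", "ILN", "MLN"),
    ) -> "NetworkTopology":
        """Build the transfer chain from a physical transit time.

        The transit is discretized into ``round(transit_hours / dt_hours)``
        serial transitions (12 h at a 4 h step gives 3), the last of which is
        the split into the sinks; the chain therefore has one fewer occupied
        stage than transitions.
        """
        n_transitions = round(transit_hours / dt_hours)
        if n_transitions < 1:
            raise ConfigurationError(
                f"transit {transit_hours} h shorter than one step of {dt_hours} h"
            )
        stages = tuple(f"TR{k}" for k in range(1, n_transitions))
        return cls(source=source, transfer_stages=stages, sinks=tuple(sinks))

    @property
    def n_transit_steps(self) -> int:
        """Number of steps from leaving the source to arriving in a sink."""
        return len(self.transfer_stages) + 1

    @property
    def compartments(self) -> tuple[str, ...]:
        return (self.source, *self.transfer_stages, *self.sinks)

    @property
    def measured_compartments(self) -> tuple[str, ...]:
        """Organs observable by flow cytometry (transfer stages are not)."""
        return (self.source, *self.sinks)


@dataclass(frozen=True)
class ModelParameters:
    """The parameter vector theta plus structural constants.

    ``gamma`` and ``delta`` are per-generation probabilities; generations past
    ``len(gamma) - 1`` reuse the last entry (the default length-3 vectors
    implement the "generations i > 2 behave like generation 2" rule).
    """

    gamma: tuple[float, ...]
    delta: tuple[float, ...]
    m: float
    rho: Mapping[str, float]  # sink label -> splitting probability
    dt_hours: float = 4.0
    p: int = 7
    migrating_generations: frozenset[int] = frozenset({1, 2, 3})
    proliferate_in_transit: bool = False
    divide_at_cap: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        object.__setattr__(self, "delta", tuple(float(d) for d in self.delta))
        object.__setattr__(self, "rho", dict(self.rho))
        object.__setattr__(
            self, "migrating_generations", frozenset(int(i) for i in self.migrating_generations)
        )

    # -- generation-indexed accessors (cap rule) --------------------------------
    def gamma_of(self, i: int) -> float:
        g = self.gamma[min(i, len(self.gamma) - 1)]
        if i >= self.p and not self.divide_at_cap:
            return 0.0
        return g

    def delta_of(self, i: int) -> float:
        return self.delta[min(i, len(self.delta) - 1)]

    def m_of(self, i: int) -> float:
        return self.m if i in self.migrating_generations else 0.0

    def theta(self) -> np.ndarray:
        """The 10-vector (delta_0, gamma_0, ..., m, rho_spl, rho_il, rho_mes)."""
        rho = [self.rho[RHO_KEY_TO_SINK[k]] for k in ("spl", "il", "mes")]
        return np.array(
            [self.delta_of(0), self.gamma_of(0),
             self.delta_of(1), self.gamma_of(1),
             self.delta_of(2), self.gamma_of(2),
             self.m, *rho],
            dtype=float,
        )

    def with_theta(self, theta: Sequence[float]) -> "ModelParameters":
        """Replace the 10 estimated entries, keeping structural constants."""
        t = [float(x) for x in theta]
        if len(t) != 10:
            raise ParameterError(f"theta must have 10 entries, got {len(t)}")
        rho = {"SPL": t[7], "ILN": t[8], "MLN": t[9]}
        return replace(
            self,
            delta=(t[0], t[2], t[4]),
            gamma=(t[1], t[3], t[5]),
            m=t[6],
            rho=rho,
        )

    # -- config round trip --------------------------------------------------------
    def to_config_dict(self, topology: NetworkTopology | None = None) -> dict:
        d: dict = {
            "dt_hours": self.dt_hours,
            "p": self.p,
            "migrating_generations": sorted(self.migrating_generations),
            "proliferate_in_transit": self.proliferate_in_transit,
            "divide_at_cap": self.divide_at_cap,
            "parameters": {
                "gamma": list(self.gamma),
                "delta": list(self.delta),
                "m": self.m,
                "rho": {SINK_TO_RHO_KEY.get(s, s): self.rho[s] for s in self.rho},
            },
        }
        if topology is not None:
            d["n_transfer_stages"] = len(topology.transfer_stages)
            d["topology"] = {
                "source": topology.source,
                "transfer_stages": list(topology.transfer_stages),
                "sinks": list(topology.sinks),
            }
        return d

    @classmethod
    def from_config_dict(cls, d: Mapping) -> tuple["ModelParameters", NetworkTopology]:
        pars = d["parameters"]
        rho_in = pars["rho"]
        rho = {RHO_KEY_TO_SINK.get(k, k): float(v) for k, v in rho_in.items()}
        dt = float(d.get("dt_hours", 4.0))
        if "topology" in d:
            t = d["topology"]
            topo = NetworkTopology(
                source=t["source"],
                transfer_stages=tuple(t["transfer_stages"]),
                sinks=tuple(t["sinks"]),
            )
        elif "n_transfer_stages" in d:
            n = int(d["n_transfer_stages"])
            topo = NetworkTopology(
                transfer_stages=tuple(f"TR{k}" for k in range(1, n + 1)),
                sinks=tuple(rho.keys()),
            )
        elif "transit_hours" in d:
            topo = NetworkTopology.from_transit_time(
                float(d["transit_hours"]), dt, sinks=tuple(rho.keys())
            )
        else:
            topo = NetworkTopology(sinks=tuple(rho.keys()))
        params = cls(
            gamma=tuple(pars["gamma"]),
            delta=tuple(pars["delta"]),
            m=float(pars["m"]),
            rho=rho,
            dt_hours=dt,
            p=int(d.get("p", 7)),
            migrating_generations=frozenset(d.get("migrating_generations", (1, 2, 3))),
            proliferate_in_transit=bool(d.get("proliferate_in_transit", False)),
            divide_at_cap=bool(d.get("divide_at_cap", True)),
        )
        return params, topo


def reference_parameters(**overrides) -> ModelParameters:
    """Division/quiescence/migration/splitting probabilities estimated in the
    murine nasal-immunization CFSE study this model was developed against.

    Generation-0 cells barely divide (gamma_0 = 0.06) and die with probability
    1 - 0.43 - 0.06 = 0.51 per 4 h step; ~14% of cells in generations 1-3
    leave the draining node per step, and 95% of emigrants settle in the spleen.
    """
    base = dict(
        gamma=(0.06, 0.29, 0.24),
        delta=(0.43, 0.31, 0.23),
        m=0.14,
        rho={"SPL": 0.95, "ILN": 0.01, "MLN": 0.04},
    )
    base.update(overrides)
    return ModelParameters(**base)


def default_topology() -> NetworkTopology:
    """The study network: 12 h source-to-sink transit at a 4 h step."""
    return NetworkTopology.from_transit_time(12.0, 4.0)


class TypeSpace:
    """Bijective index over (compartment, generation) pairs.

    Ordering: compartments in topology order (source, transfer stages, sinks),
    generations 0..p ascending within each compartment.
    """

    def __init__(self, topology: NetworkTopology, p: int):
        if p < 2:
            raise ConfigurationError(f"generation cap p must be >= 2, got {p}")
        self.topology = topology
        self.p = int(p)
        self.types: tuple[tuple[str, int], ...] = tuple(
            (c, i) for c in topology.compartments for i in range(p + 1)
        )
        self._index = {t: k for k, t in enumerate(self.types)}

    @property
    def size(self) -> int:
        return len(self.types)

    def index(self, compartment: str, generation: int) -> int:
        try:
            return self._index[(compartment, int(generation))]
        except KeyError:
            raise KeyError(f"unknown type ({compartment}, {generation})") from None

    def indices_of(self, compartments: Iterable[str]) -> np.ndarray:
        comps = set(compartments)
        return np.array([k for k, (c, _) in enumerate(self.types) if c in comps], dtype=int)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TypeSpace)
            and self.types == other.types
        )

    def __repr__(self) -> str:
        return f"TypeSpace({self.topology.compartments}, p={self.p}, D={self.size})"


def build_type_space(topology: NetworkTopology, p: int) -> TypeSpace:
    """Enumerate the D = (#compartments) * (p+1) types in canonical order."""
    return TypeSpace(topology, p)


@dataclass
class PopulationState:
    """Integer cell counts over a type space at step ``n`` (n = 0 <-> T = 72 h)."""

    n: int
    counts: np.ndarray
    type_space: TypeSpace

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.type_space.size,):
            raise ValueError(
                f"counts shape {c.shape} != type-space size ({self.type_space.size},)"
            )
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = np.round(c).astype(np.int64)

    @classmethod
    def from_dict(
        cls, counts: Mapping[tuple[str, int], float], type_space: TypeSpace, n: int = 0
    ) -> "PopulationState":
        vec = np.zeros(type_space.size)
        for (comp, gen), z in counts.items():
            vec[type_space.index(comp, gen)] = z
        return cls(n=n, counts=vec, type_space=type_space)

    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Offspring law
# ---------------------------------------------------------------------------

def _proliferation_branches(
    gamma: float, delta: float, here: tuple[str, int], nxt: tuple[str, int]
) -> list[tuple[float, dict]]:
    """Divide / quiesce / die branches within one compartment."""
    branches = []
    if gamma > 0:
        branches.append((gamma, {nxt: 2}))
    if delta > 0:
        branches.append((delta, {here: 1}))
    death = 1.0 - gamma - delta
    branches.append((death, {}))
    return branches


def offspring_distribution(
    cell_type: tuple[str, int],
    params: ModelParameters,
    topology: NetworkTopology,
    *,
    _allow_unnormalized_rho: bool = False,
) -> list[tuple[float, dict[tuple[str, int], int]]]:
    """Single-step fate law of one cell: list of (probability, offspring dict).

    Probabilities sum to 1 exactly; zero-probability branches are omitted.
    """
    comp, i = cell_type
    i = int(i)
    if not (0 <= i <= params.p):
        raise ParameterError(f"generation {i} outside 0..{params.p}")
    gamma, delta = params.gamma_of(i), params.delta_of(i)
    i_next = min(i + 1, params.p)

    if comp == topology.source:
        m_i = params.m_of(i)
        death = 1.0 - gamma - delta - m_i
        if death < -_SIMPLEX_TOL:
            raise ParameterError(
                f"gamma_{i} + delta_{i} + m_{i} = {gamma + delta + m_i:.6g} > 1 "
                f"for generation {i} in the source"
            )
        branches: list[tuple[float, dict]] = []
        if gamma > 0:
            branches.append((gamma, {(comp, i_next): 2}))
        if delta > 0:
            branches.append((delta, {(comp, i): 1}))
        if m_i > 0:
            if topology.transfer_stages:
                branches.append((m_i, {(topology.transfer_stages[0], i): 1}))
            elif topology.sinks:
                # degenerate chain: migration splits straight into the sinks
                for s in topology.sinks:
                    r = params.rho.get(s, 0.0)
                    if r > 0:
                        branches.append((m_i * r, {(s, i): 1}))
            else:
                # source-only network: emigration leaves the observed system
                branches.append((m_i, {}))
        branches.append((max(death, 0.0), {}))
        return _close(branches, _allow_unnormalized_rho)

    if comp in topology.transfer_stages:
        k = topology.transfer_stages.index(comp)
        last = k == len(topology.transfer_stages) - 1
        if last:
            destinations = [
                (params.rho.get(s, 0.0), s) for s in topology.sinks
            ]
        else:
            destinations = [(1.0, topology.transfer_stages[k + 1])]
        branches = []
        for r, dest in destinations:
            if r <= 0:
                continue
            if params.proliferate_in_transit:
                death = 1.0 - gamma - delta
                if death < -_SIMPLEX_TOL:
                    raise ParameterError(
                        f"gamma_{i} + delta_{i} = {gamma + delta:.6g} > 1 in transit"
                    )
                if gamma > 0:
                    branches.append((r * gamma, {(dest, i_next): 2}))
                if delta > 0:
                    branches.append((r * delta, {(dest, i): 1}))
            else:
                branches.append((r, {(dest, i): 1}))
        if params.proliferate_in_transit:
            branches.append((max(1.0 - gamma - delta, 0.0), {}))
        else:
            rho_total = sum(r for r, _ in destinations)
            branches.append((max(1.0 - rho_total, 0.0), {}))
        return _close(branches, _allow_unnormalized_rho)

    if comp in topology.sinks:
        death = 1.0 - gamma - delta
        if death < -_SIMPLEX_TOL:
            raise ParameterError(
                f"gamma_{i} + delta_{i} = {gamma + delta:.6g} > 1 "
                f"for generation {i} in sink {comp}"
            )
        branches = []
        if gamma > 0:
            branches.append((gamma, {(comp, i_next): 2}))
        if delta > 0:
            branches.append((delta, {(comp, i): 1}))
        branches.append((max(death, 0.0), {}))
        return _close(branches, _allow_unnormalized_rho)

    raise ConfigurationError(f"compartment {comp!r} not in topology")


def _close(branches, allow_unnormalized: bool):
    """Merge duplicate offspring dicts and check normalization."""
    merged: dict = {}
    for prob, off in branches:
        key = tuple(sorted(off.items()))
        if key in merged:
            merged[key] = (merged[key][0] + prob, off)
        else:
            merged[key] = (prob, off)
    out = [(p, off) for p, off in merged.values() if p > 0.0]
    total = math.fsum(p for p, _ in out)
    if not allow_unnormalized and abs(total - 1.0) > 1e-9:
        raise ParameterError(f"fate probabilities sum to {total!r}, not 1")
    return out


def offspring_mean_matrix(
    params: ModelParameters,
    topology: NetworkTopology,
    type_space: TypeSpace | None = None,
    *,
    _allow_unnormalized_rho: bool = False,
) -> np.ndarray:
    """D x D matrix M with M[j, k] = E[# type-k offspring of one type-j cell]."""
    ts = type_space or build_type_space(topology, params.p)
    M = np.zeros((ts.size, ts.size))
    for j, t in enumerate(ts.types):
        for prob, off in offspring_distribution(
            t, params, topology, _allow_unnormalized_rho=_allow_unnormalized_rho
        ):
            for dest, cnt in off.items():
                M[j, ts.index(*dest)] += prob * cnt
    return M


def offspring_covariance(
    cell_type: tuple[str, int],
    params: ModelParameters,
    topology: NetworkTopology,
    type_space: TypeSpace | None = None,
    *,
    _allow_unnormalized_rho: bool = False,
) -> np.ndarray:
    """D x D covariance of the offspring vector of one type-``cell_type`` cell.

    V_j = sum_k p_k o_k o_k^T - mu_j mu_j^T over the fate outcomes o_k.
    """
    ts = type_space or build_type_space(topology, params.p)
    D = ts.size
    second = np.zeros((D, D))
    mu = np.zeros(D)
    for prob, off in offspring_distribution(
        cell_type, params, topology, _allow_unnormalized_rho=_allow_unnormalized_rho
    ):
        o = np.zeros(D)
        for dest, cnt in off.items():
            o[ts.index(*dest)] += cnt
        second += prob * np.outer(o, o)
        mu += prob * o
    V = second - np.outer(mu, mu)
    return 0.5 * (V + V.T)


def validate_parameters(
    params: ModelParameters, topology: NetworkTopology | None = None
) -> list[str]:
    """Return every violated invariant (empty list when valid)."""
    topo = topology or default_topology()
    violations: list[str] = []
    if params.p < 2:
        violations.append(f"generation cap p = {params.p} < 2")
    for i in range(params.p + 1):
        g, d, mi = params.gamma_of(i), params.delta_of(i), params.m_of(i)
        for name, v in (("gamma", g), ("delta", d)):
            if not (0.0 <= v <= 1.0):
                violations.append(f"{name}_{i} = {v:.6g} outside [0, 1]")
        if g + d + mi > 1.0 + _SIMPLEX_TOL:
            term = f"gamma_{i}+delta_{i}+m" if mi > 0 else f"gamma_{i}+delta_{i}"
            violations.append(f"{term} = {g + d + mi:.6g} > 1")
    if not (0.0 <= params.m <= 1.0):
        violations.append(f"m = {params.m:.6g} outside [0, 1]")
    rho_sum = math.fsum(params.rho.get(s, 0.0) for s in topo.sinks)
    if topo.sinks and abs(rho_sum - 1.0) > _SIMPLEX_TOL:
        violations.append(f"splitting probabilities sum to {rho_sum!r}, not 1")
    for s in topo.sinks:
        r = params.rho.get(s, 0.0)
        if not (0.0 <= r <= 1.0):
            violations.append(f"rho[{s}] = {r:.6g} outside [0, 1]")
    mig = params.migrating_generations
    if 0 in mig:
        violations.append("generation 0 must not migrate")
    if params.p in mig:
        violations.append(f"generation p = {params.p} must not migrate")
    if any(i < 0 or i > params.p for i in mig):
        violations.append(f"migrating generations {sorted(mig)} outside 0..{params.p}")
    return violations
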