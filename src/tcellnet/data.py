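"""Generation-resolved cell-count datasets from sacrifice experiments.

Each record is one (animal, organ, generation) count at the animal's single
measurement step; animals are sacrificed, so every animal appears at exactly
one time point and time points index different individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NetworkTopology, default_topology

__all__ = ["ObservedDataset", "COUNTS_COLUMNS", "T0_HOURS"]

COUNTS_COLUMNS = ["animal_id", "time_hours", "n", "organ", "generation", "count"]
T0_HOURS = 72.0  # model step n = 0


class SchemaError(ValueError):
    """Counts table violates the dataset schema."""


@dataclass
class ObservedDataset:
    """Long-format per-animal, per-organ, per-generation counts.

    ``records`` columns: animal_id, time_hours, n, organ, generation, count.
    """

    records: pd.DataFrame
    p: int = 7
    topology: NetworkTopology | None = None

    def __post_init__(self) -> None:
        self.topology = self.topology or default_topology()
        df = self.records.copy()
        missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df[COUNTS_COLUMNS]
        self._validate(df)
        df["n"] = df["n"].astype(int)
        df["generation"] = df["generation"].astype(int)
        df["count"] = df["count"].astype(np.int64)
        self.records = df.reset_index(drop=True)

    def _validate(self, df: pd.DataFrame) -> None:
        organs = set(self.topology.measured_compartments)
        for row, rec in enumerate(df.itertuples(index=False)):
            if rec.organ not in organs:
                raise SchemaError(f"row {row}: unknown organ {rec.organ!r}")
            c = rec.count
            if c < 0 or float(c) != int(c):
                raise SchemaError(f"row {row}: count {c!r} not a non-negative integer")
            g = rec.generation
            if g < 0 or g > self.p or float(g) != int(g):
                raise SchemaError(f"row {row}: generation {g!r} outside 0..{self.p}")
            if abs(float(rec.time_hours) - (T0_HOURS + 4.0 * int(rec.n))) > 1e-9:
                raise SchemaError(
                    f"row {row}: time_hours {rec.time_hours} != 72 + 4*n for n={rec.n}"
                )
        steps = df.groupby("animal_id")["n"].nunique()
        multi = steps[steps > 1]
        if len(multi):
            raise SchemaError(
                f"animals observed at more than one time step: {list(multi.index)}"
            )

    # -- accessors -------------------------------------------------------------
    @property
    def steps(self) -> tuple[int, ...]:
        return tuple(sorted(self.records["n"].unique()))

    def animals_at(self, n: int) -> tuple:
        return tuple(sorted(self.records.loc[self.records["n"] == n, "animal_id"].unique()))

    def count_matrix(self, animal_id) -> pd.DataFrame:
        """Organ x generation count table for one animal (missing cells = 0)."""
        sub = self.records[self.records["animal_id"] == animal_id]
        organs = list(self.topology.measured_compartments)
        mat = (
            sub.pivot_table(index="organ", columns="generation", values="count",
                            aggfunc="sum", fill_value=0)
            .reindex(index=organs, columns=range(self.p + 1), fill_value=0)
        )
        return mat.astype(np.int64)

    def count_vector(self, animal_id, categories) -> np.ndarray:
        """Counts for one animal over an ordered (organ, generation) category list."""
        mat = self.count_matrix(animal_id)
        return np.array([mat.loc[organ, gen] for organ, gen in categories], dtype=float)

    def frequencies(self, animal_id, categories) -> np.ndarray:
        """Per-animal relative frequencies over a scope (sums to 1)."""
        z = self.count_vector(animal_id, categories)
        total = z.sum()
        if total <= 0:
            raise ZeroDivisionError(f"animal {animal_id!r} has no cells in scope")
        return z / total

    def mean_source_counts(self, n: int = 0) -> np.ndarray:
        """Average draining-node generation profile over the animals at step n.

        Used as the deterministic initial condition of the likelihood.
        """
        animals = self.animals_at(n)
        if not animals:
            raise ValueError(f"no animals measured at step {n}")
        src = self.topology.source
        profiles = [
            self.count_matrix(a).loc[src].to_numpy(dtype=float) for a in animals
        ]
        return np.mean(profiles, axis=0)

    # -- IO ----------------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, p: int = 7, topology: NetworkTopology | None = None
                 ) -> "ObservedDataset":
        try:
            df = pd.read_csv(path)
        except (ValueError, OSError) as exc:
            raise SchemaError(f"cannot read counts CSV {path}: {exc}") from exc
        return cls(records=df, p=p, topology=topology)

    def equals(self, other: "ObservedDataset") -> bool:
        a = self.records.sort_values(COUNTS_COLUMNS).reset_index(drop=True)
        b = other.records.sort_values(COUNTS_COLUMNS).reset_index(drop=True)
        return a.equals(b)
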