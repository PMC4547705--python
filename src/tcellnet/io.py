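"""Readers and writers: model configuration (YAML/JSON), counts CSV, fit JSON."""

from __future__ import annotations

import json
import math
from pathlib import Path

from .data import ObservedDataset
from .inference import FitResult
from .model import ModelParameters, NetworkTopology

__all__ = [
    "load_config",
    "save_config",
    "read_counts_csv",
    "write_counts_csv",
    "write_fit_json",
    "read_fit_json",
]


def load_config(path) -> tuple[ModelParameters, NetworkTopology]:
    """Read a model configuration file (.yaml/.yml or .json)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return ModelParameters.from_config_dict(d)


def save_config(params: ModelParameters, topology: NetworkTopology, path) -> None:
    """Write the configuration; write -> read -> write is byte-identical."""
    path = Path(path)
    d = params.to_config_dict(topology)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(d, default_flow_style=False, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_counts_csv(path, p: int = 7, topology: NetworkTopology | None = None
                    ) -> ObservedDataset:
    return ObservedDataset.from_csv(path, p=p, topology=topology)


def write_counts_csv(dataset: ObservedDataset, path) -> None:
    dataset.to_csv(path)


def _encode_float(x: float):
    # JSON has no NaN literal; serialize as null and restore on read
    return None if (isinstance(x, float) and math.isnan(x)) else x


def write_fit_json(fit: FitResult, path) -> None:
    """Serialize a fit with full float precision and stable key order."""
    payload = {
        "theta": {k: _encode_float(v) for k, v in fit.theta.items()},
        "se": {k: _encode_float(v) for k, v in fit.se.items()},
        "nll": fit.nll,
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "singular_information": fit.singular_information,
        "rho_identifiable": fit.rho_identifiable,
        "start_diagnostics": fit.start_diagnostics,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> FitResult:
    d = json.loads(Path(path).read_text())

    def dec(mapping):
        return {k: (math.nan if v is None else float(v)) for k, v in mapping.items()}

    return FitResult(
        theta=dec(d["theta"]),
        se=dec(d["se"]),
        nll=float(d["nll"]),
        converged=bool(d["converged"]),
        n_starts=int(d["n_starts"]),
        start_diagnostics=list(d.get("start_diagnostics", [])),
        singular_information=bool(d.get("singular_information", False)),
        rho_identifiable=bool(d.get("rho_identifiable", True)),
    )
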