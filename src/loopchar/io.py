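"""Result serialization: CSV for tabular results, JSON for scalar records."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["write_results", "read_sweep", "SCHEMA_VERSION"]

SCHEMA_VERSION = "loopchar-results/1"


def _jsonable(obj: Any):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(result: Any, path, seed: int | None = None) -> Path:
    """Serialize a result to ``path``.

    DataFrames go to CSV; dataclasses, dicts and lists go to JSON wrapped in
    a versioned envelope that records the seed when given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if isinstance(result, pd.DataFrame):
            result.to_csv(path, index=False)
        else:
            payload = {"schema": SCHEMA_VERSION, "result": _jsonable(result)}
            if seed is not None:
                payload["seed"] = int(seed)
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path)
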