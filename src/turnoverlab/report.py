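"""Run-summary reporting: one JSON of configs/seeds/metrics plus TSV tables."""

from __future__ import annotations

import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = ["write_run_summary", "write_table"]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_run_summary(path, config: dict, metrics: dict, seeds: dict | None = None) -> None:
    """Write a single machine-readable summary of one pipeline run."""
    doc = {
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": _jsonable(config),
        "seeds": _jsonable(seeds or {}),
        "metrics": _jsonable(metrics),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    """Write one analysis table as TSV."""
    frame.to_csv(path, sep="\t", index=index)
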