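"""Run archiving: every experiment writes its resolved configuration, a
JSON report of the typed readouts, and (where applicable) numeric traces
as HDF5 and/or CSV. Reading restores the numeric arrays exactly."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Dict, Optional

import h5py
import numpy as np
import pandas as pd

from .errors import MissingArtifactError


def _jsonable(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)  # JSON has no inf/nan
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_run(
    out_dir,
    report: Optional[dict] = None,
    arrays: Optional[Dict[str, np.ndarray]] = None,
    tables: Optional[Dict[str, pd.DataFrame]] = None,
    config_text: Optional[str] = None,
) -> Path:
    """Archive a run: report.json, traces.h5 (one dataset per array),
    <name>.csv per table, and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report is not None:
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    if arrays:
        with h5py.File(out / "traces.h5", "w") as f:
            for name, arr in arrays.items():
                f.create_dataset(name, data=np.asarray(arr))
    if tables:
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    if config_text is not None:
        (out / "config.yaml").write_text(config_text)
    return out


def read_run(run_dir) -> dict:
    """Restore an archived run; raises MissingArtifactError naming the
    first absent artifact."""
    run = Path(run_dir)
    if not run.is_dir():
        raise MissingArtifactError(f"run directory {run} does not exist")
    report_path = run / "report.json"
    if not report_path.exists():
        raise MissingArtifactError(f"missing artifact: {report_path}")
    out: dict = {"report": json.loads(report_path.read_text())}
    h5 = run / "traces.h5"
    arrays = {}
    if h5.exists():
        with h5py.File(h5, "r") as f:
            f.visititems(
                lambda name, node: arrays.__setitem__(name, np.array(node))
                if isinstance(node, h5py.Dataset) else None
            )
    out["arrays"] = arrays
    out["tables"] = {
        p.stem: pd.read_csv(p) for p in sorted(run.glob("*.csv"))
    }
    cfg = run / "config.yaml"
    out["config_text"] = cfg.read_text() if cfg.exists() else None
    return out
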