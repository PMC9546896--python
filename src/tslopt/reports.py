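"""Report writers: CSV/JSON outputs with embedded provenance.

Every written artifact carries the seeds (and, when available, the config
hash) needed to regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import RunConfig, config_hash
from .exceptions import TsloptError
from .scheduler import Schedule, write_schedule_json
from .simulate import MCReport

__all__ = ["write_report", "write_mc_report", "write_metrics_json"]

#: Column schema of the Monte Carlo CSV report.
MC_CSV_COLUMNS = ["model", "criterion", "k", "parameter", "mnae", "std", "combined_nae", "seed"]


def write_mc_report(report: MCReport, path, config: RunConfig | None = None) -> None:
    """Flatten an MCReport to CSV (one row per schedule × parameter)."""
    combined = report.combined.set_index("schedule")["combined_nae"]
    df = report.table.copy()
    df["combined_nae"] = df["schedule"].map(combined)
    df["seed"] = report.seed
    df = df[["schedule"] + MC_CSV_COLUMNS]
    header = f"# replicates={report.replicates} snr={report.snr} seed={report.seed}"
    if config is not None:
        header += f" config_hash={config_hash(config)}"
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise TsloptError(f"cannot write report to {path}: {exc}") from exc


def write_metrics_json(metrics: dict, path, config: RunConfig | None = None, seed: int | None = None) -> None:
    doc = dict(metrics)
    if seed is not None:
        doc["seed"] = seed
    if config is not None:
        doc["config_hash"] = config_hash(config)
    path = Path(path)
    try:
        path.write_text(json.dumps(doc, indent=2, default=float) + "\n")
    except OSError as exc:
        raise TsloptError(f"cannot write metrics to {path}: {exc}") from exc


def write_report(obj, path, config: RunConfig | None = None, **meta) -> None:
    """Dispatch on report type: MCReport → CSV, Schedule → JSON, dict → JSON."""
    if isinstance(obj, MCReport):
        write_mc_report(obj, path, config)
    elif isinstance(obj, Schedule):
        write_schedule_json(obj, path, **meta)
    elif isinstance(obj, dict):
        write_metrics_json(obj, path, config, meta.get("seed"))
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise TsloptError(f"do not know how to write a {type(obj).__name__}")
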