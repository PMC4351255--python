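"""Result serialization: experiment summaries and per-network tables.

Everything is plain text: the summary as JSON, the per-network table as
tab-separated values, and a snapshot of the configuration that produced
the run, so a result directory is self-describing and re-runnable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, dump_config, load_config
from .training import ExperimentResult

SUMMARY_FILE = "summary.json"
TABLE_FILE = "networks.tsv"
CONFIG_FILE = "config.ini"


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(result: ExperimentResult, out_dir, config: RunConfig = None):
    """Write summary + per-network table (+ config snapshot) to a dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / SUMMARY_FILE).write_text(
        json.dumps(_jsonify(result.summary), indent=2) + "\n")
    result.table.to_csv(out / TABLE_FILE, sep="\t", index=False)
    if config is not None:
        (out / CONFIG_FILE).write_text(dump_config(config))
    return out


def read_results(out_dir):
    """Read back what :func:`write_results` wrote.

    Returns (ExperimentResult, RunConfig or None).
    """
    out = Path(out_dir)
    summary = json.loads((out / SUMMARY_FILE).read_text())
    table = pd.read_csv(out / TABLE_FILE, sep="\t")
    cfg = None
    if (out / CONFIG_FILE).exists():
        cfg = load_config(out / CONFIG_FILE)
    return ExperimentResult(task=summary.get("task", ""), table=table,
                            summary=summary), cfg


def write_trial_log(logs, path):
    """Serialize a per-step trial log as tab-separated text."""
    rows = []
    for lg in logs:
        row = dict(t=lg.t, action=lg.action, reward=lg.reward,
                   delta=lg.delta)
        row.update({f"q_{k}": v for k, v in enumerate(lg.q)})
        row.update({f"y_reg_{j}": v for j, v in enumerate(lg.y_reg)})
        row.update({f"y_mem_{m}": v for m, v in enumerate(lg.y_mem)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
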