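"""Readers and writers for the package's tabular interchange formats.

Rates, traces, doses and binding series travel as CSV; expression
matrices and sample metadata as TSV; gene sets as GMT (name, description,
members, tab-separated); fit reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .simulate import ExpressionStudy

__all__ = [
    "read_rates",
    "read_trace",
    "read_table",
    "write_expression",
    "read_expression",
    "read_gmt",
    "write_report",
]


def read_rates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"effector_conc", "pep_conc", "rate"}
    if not need <= set(df.columns):
        raise ValueError(f"rate table must have columns {sorted(need)}")
    return df


def read_trace(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_min", "od340"} <= set(df.columns):
        raise ValueError("trace must have columns time_min, od340")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic CSV reader (doses: conc/activity; binding: conc/signal)."""
    return pd.read_csv(path)


def write_expression(study: ExpressionStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.matrix.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    study.meta.to_csv(out / "samples.tsv", sep="\t", index=False)


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    mat = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return ExpressionStudy(matrix=mat, meta=meta)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line, tab-separated name, description,
    then member genes; empty member lists are rejected."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = members
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_report(fit: Any, path: str | Path) -> None:
    """Serialise a fit dataclass (parameters, SEs, residuals, flags) to JSON."""
    Path(path).write_text(json.dumps(_jsonable(fit), indent=2, default=str) + "\n")
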