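"""Table readers/writers and JSON serialization of fit results.

Time-series tables are TSV or CSV with a header row: first column
``time``, one column per species.  Relative-abundance tables must have
rows summing to 1; small deviations (< 0.05) are renormalized with a
warning, larger ones rejected.  Non-uniform grids are accepted — real
sampling designs skip days.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AbundanceSeries, CompositionSeries, GLVParams
from .ilv import FitResult
from .metrics import InteractionNetwork

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_truth",
    "read_truth",
    "write_fit_result",
    "read_fit_result",
    "write_network",
]

ROW_SUM_TOLERANCE = 0.05


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(
    path: str | Path, mode: str = "relative"
) -> CompositionSeries | AbundanceSeries:
    """Load a time-series table as compositions or absolute abundances."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = header[1:]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species names in header")
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("expected a time column plus at least 2 species")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.isfinite(values).all() or not np.isfinite(times).all():
        raise ValueError("non-numeric or non-finite cells in table")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time column must be strictly increasing")
    if mode == "absolute":
        return AbundanceSeries(times, values, labels)
    if mode != "relative":
        raise ValueError("mode must be 'relative' or 'absolute'")
    sums = values.sum(axis=1)
    dev = np.abs(sums - 1.0)
    if np.any(dev >= ROW_SUM_TOLERANCE):
        k = int(np.argmax(dev))
        raise ValueError(
            f"row {k} sums to {sums[k]:.4g}; deviations >= "
            f"{ROW_SUM_TOLERANCE} are rejected in relative mode"
        )
    if np.any(dev > 1e-8):
        warnings.warn(
            "rows deviated from unit sum by up to "
            f"{dev.max():.3g}; renormalized",
            stacklevel=2,
        )
        values = values / sums[:, None]
    values = np.clip(values, 0.0, 1.0)
    values = values / values.sum(axis=1, keepdims=True)
    return CompositionSeries(times, values, labels)


def write_timeseries(
    series: CompositionSeries | AbundanceSeries, path: str | Path
) -> None:
    path = Path(path)
    values = series.X if isinstance(series, CompositionSeries) else series.N
    df = pd.DataFrame(values, columns=series.labels)
    df.insert(0, "time", series.times)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_truth(params: GLVParams, path: str | Path) -> None:
    """Ground-truth sidecar JSON for a simulated dataset."""
    Path(path).write_text(
        json.dumps(
            {
                "r": params.r.tolist(),
                "B": params.B.tolist(),
                "self_interactions": params.self_interactions,
            },
            indent=1,
        )
    )


def read_truth(path: str | Path) -> GLVParams:
    d = json.loads(Path(path).read_text())
    return GLVParams(
        np.asarray(d["r"]), np.asarray(d["B"]), d.get("self_interactions", False)
    )


def write_fit_result(fit: FitResult, path: str | Path, **extra) -> None:
    d = fit.to_dict()
    d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1))


def read_fit_result(path: str | Path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        params=GLVParams(np.asarray(d["r"]), np.asarray(d["B"])),
        x0=np.asarray(d["x0"]),
        Nsum0=d["Nsum0"],
        rmse=d["rmse"],
        backend=d["backend"],
        best_iteration=d["best_iteration"],
        restart=d.get("restart", 0),
    )


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Edge list TSV: source, target, weight, sign."""
    rows = []
    for src, tgt, w, sign in net.edges:
        name = net.labels[src] if net.labels else f"sp{src + 1}"
        tname = net.labels[tgt] if net.labels else f"sp{tgt + 1}"
        rows.append({"source": name, "target": tname, "weight": w, "sign": sign})
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        Path(path), sep="\t", index=False
    )
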