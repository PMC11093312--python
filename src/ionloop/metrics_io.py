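"""Experiment-log I/O and tracking-quality metrics.

Delivery experiment logs are tables with one row per 1 s sample and four
columns: ``d`` (desired trajectory / reference), ``err`` (tracking error,
output minus reference), ``u`` (applied voltage) and ``plot_timer`` (time
in seconds).  The measured output is not deposited directly; it is
recovered as ``output = d + err``.  Both CSV and XLSX dialects are read,
with case-insensitive column matching and tolerance for underscore
irregularities in the timer column name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentLog",
    "MetricsReport",
    "read_log",
    "write_log",
    "average_output",
    "steady_state_relative_error",
    "max_abs_voltage",
    "compute_metrics",
]

_REQUIRED = ("d", "err", "u", "plot_timer")


@dataclass
class ExperimentLog:
    """Validated per-sample experiment log with a derived output column."""

    d: np.ndarray
    err: np.ndarray
    u: np.ndarray
    plot_timer: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.d)
        for name in ("err", "u", "plot_timer"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if n == 0:
            raise ValueError("empty experiment log")

    @property
    def output(self) -> np.ndarray:
        """Measured output, reconstructed as reference + error."""
        return self.d + self.err

    def __len__(self) -> int:
        return len(self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "d": self.d, "err": self.err, "u": self.u,
            "plot_timer": self.plot_timer,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "<frame>") -> "ExperimentLog":
        cols = _resolve_columns(df, source)
        arrays = {}
        for canon, actual in cols.items():
            series = pd.to_numeric(df[actual], errors="coerce")
            bad = series.index[series.isna() & df[actual].notna()]
            if len(bad):
                raise ValueError(
                    f"{source}: non-numeric value in column {actual!r} "
                    f"at row {bad[0]}")
            arrays[canon] = series.dropna().to_numpy(dtype=float)
        n = min(len(a) for a in arrays.values())
        return cls(**{k: a[:n] for k, a in arrays.items()})


def _canonical(name: str) -> str:
    return str(name).strip().lower().replace("_", "").replace(" ", "")


def _resolve_columns(df: pd.DataFrame, source: str) -> dict[str, str]:
    lookup = {_canonical(c): c for c in df.columns}
    resolved = {}
    for canon in _REQUIRED:
        key = _canonical(canon)
        if key in lookup:
            resolved[canon] = lookup[key]
        elif canon == "plot_timer" and "timer" in lookup:
            resolved[canon] = lookup["timer"]
        else:
            raise ValueError(f"{source}: missing required column {canon!r}")
    return resolved


def read_log(path: str | Path, dialect: str | None = None) -> ExperimentLog:
    """Read an experiment log from CSV or XLSX.

    ``dialect`` is inferred from the suffix when omitted.  Missing columns
    raise a named error; non-numeric cells raise a row-indexed error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        df = pd.read_excel(path)
    elif dialect == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExperimentLog.from_frame(df, source=str(path))


def write_log(log: ExperimentLog, path: str | Path) -> None:
    """Write a log in the deposited four-column layout (CSV or XLSX)."""
    path = Path(path)
    df = log.to_frame()
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class MetricsReport:
    """Tracking-quality summary of one experiment log."""

    average_output: float                  # mean reconstructed output (nA)
    steady_state_relative_error: float     # % over t > settling cutoff
    max_abs_voltage: float                 # V
    n_samples: int
    settling_cutoff: float                 # s

    def to_dict(self) -> dict:
        return {
            "average_output": self.average_output,
            "steady_state_relative_error_pct": self.steady_state_relative_error,
            "max_abs_voltage": self.max_abs_voltage,
            "n_samples": self.n_samples,
            "settling_cutoff_s": self.settling_cutoff,
        }


def average_output(log: ExperimentLog) -> float:
    """Arithmetic mean of the reconstructed output over the full experiment."""
    return float(np.mean(log.output))


def steady_state_relative_error(log: ExperimentLog, cutoff_s: float = 100.0,
                                mode: str = "per_sample") -> float:
    """Mean relative tracking error (%) after the settling window.

    The system is considered at steady state after ``cutoff_s`` seconds
    (default 100 s, allowing the output to reach the reference from a cold
    start).  ``per_sample`` (default) averages ``|err|/reference`` sample
    by sample; ``aggregate`` divides the mean absolute error by the mean
    reference.
    """
    mask = log.plot_timer > cutoff_s
    if not np.any(mask):
        raise ValueError(f"log does not extend beyond the {cutoff_s} s cutoff")
    err = np.abs(log.err[mask])
    ref = log.d[mask]
    if mode == "per_sample":
        if np.any(ref == 0):
            raise ValueError("relative error undefined: zero reference sample")
        return float(np.mean(err / np.abs(ref)) * 100.0)
    if mode == "aggregate":
        mref = np.mean(np.abs(ref))
        if mref == 0:
            raise ValueError("relative error undefined: zero mean reference")
        return float(np.mean(err) / mref * 100.0)
    raise ValueError(f"unknown mode {mode!r}")


def max_abs_voltage(log: ExperimentLog) -> float:
    """Largest absolute applied voltage in the log."""
    if len(log.u) == 0:
        raise ValueError("empty voltage column")
    return float(np.max(np.abs(log.u)))


def compute_metrics(log: ExperimentLog, cutoff_s: float = 100.0,
                    mode: str = "per_sample") -> MetricsReport:
    """All tracking metrics of a log in one report."""
    return MetricsReport(
        average_output=average_output(log),
        steady_state_relative_error=steady_state_relative_error(
            log, cutoff_s=cutoff_s, mode=mode),
        max_abs_voltage=max_abs_voltage(log),
        n_samples=len(log),
        settling_cutoff=cutoff_s,
    )
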