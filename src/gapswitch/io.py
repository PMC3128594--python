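"""Tabular I/O for expression profiles and trajectories.

The single interchange format is a TSV table with columns ``gene``,
``x_percent_el`` and ``conc_nM`` (plus an optional leading ``time`` column
for trajectories), matching the tabular layout of quantitative embryo
expression databases.  Profiles read from disk are linearly resampled onto
the model grid; writes use a deterministic column order and 6-significant-
digit floats so identical data produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import AxisGrid, GradientSet
from .dynamics import Trajectory

__all__ = ["read_profiles", "write_profiles", "write_trajectory", "ProfileParseError"]

_REQUIRED = ["gene", "x_percent_el", "conc_nM"]


class ProfileParseError(ValueError):
    """Malformed profile table."""


def read_profiles(path, grid: Optional[AxisGrid] = None) -> GradientSet:
    """Read a profile TSV and resample each gene onto the model grid.

    Raises :class:`ProfileParseError` with 1-based line numbers for
    malformed rows (the header is line 1).
    """
    path = Path(path)
    grid = grid or AxisGrid()
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ProfileParseError(f"{path}: cannot parse TSV: {exc}") from exc

    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ProfileParseError(f"{path}: missing column(s): {', '.join(missing)}")
    unknown = [c for c in frame.columns if c not in _REQUIRED + ["time"]]
    if unknown:
        raise ProfileParseError(f"{path}: unknown column(s): {', '.join(unknown)}")

    for col in ("x_percent_el", "conc_nM"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2   # +1 header, +1 zero-based
            raise ProfileParseError(f"{path}: line {line}: non-numeric {col}")
        frame[col] = values
    neg = frame["conc_nM"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ProfileParseError(f"{path}: line {line}: negative concentration")
    dup = frame.duplicated(subset=[c for c in ("gene", "x_percent_el", "time")
                                   if c in frame.columns])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ProfileParseError(f"{path}: line {line}: duplicate (gene, x) row")

    return GradientSet.from_frame(frame, grid=grid)


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col != "gene":
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    return out


def write_profiles(gradients: GradientSet, path) -> None:
    """Write a GradientSet as a deterministic profile TSV."""
    frame = gradients.to_frame()
    _format_frame(frame).to_csv(path, sep="\t", index=False)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as tidy TSV (time, gene, x_percent_el, conc_nM)."""
    frame = trajectory.to_frame()
    _format_frame(frame).to_csv(path, sep="\t", index=False)
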