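"""BED-style interval track input/output.

Tracks are BED3+1: ``contig  start  end  [value]`` with 0-based half-open
coordinates.  The optional fourth column is either a float (covariates such
as recombination rate or replication timing) or a category label (chromatin
state).  Overlap within one track is invalid and rejected on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError
from .records import Interval, IntervalTrack


def read_intervals(
    path: str | Path, value_type: str = "auto"
) -> IntervalTrack:
    """Read a BED3+1 file into an :class:`IntervalTrack`.

    ``value_type`` is ``"float"``, ``"str"`` or ``"auto"`` (floats where the
    whole column parses as numeric, labels otherwise).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        return IntervalTrack()
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected >= 3 columns, got {df.shape[1]}")
    values: list[object]
    if df.shape[1] >= 4:
        col = df[3]
        if value_type == "str":
            values = list(col)
        else:
            numeric = pd.to_numeric(col, errors="coerce")
            if numeric.notna().all():
                values = list(numeric.astype(float))
            elif value_type == "float":
                bad = int(numeric.isna().idxmax()) + 1
                raise ParseError(
                    f"{path}: non-numeric value column at data line {bad}"
                )
            else:
                values = list(col)
    else:
        values = [None] * len(df)

    track = IntervalTrack()
    for i, (contig, start, end) in enumerate(
        zip(df[0], df[1], df[2]), start=1
    ):
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-integer bounds") from exc
        if start_i >= end_i:
            raise ParseError(
                f"{path}: line {i}: start {start_i} >= end {end_i}"
            )
        try:
            track.add(Interval(contig, start_i, end_i, values[i - 1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return track


def write_intervals(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            if iv.value is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            elif isinstance(iv.value, float):
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.value:.10g}\n")
            else:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.value}\n")
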