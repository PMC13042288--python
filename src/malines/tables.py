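"""TSV tables: TE calls, SV calls, and line metadata.

Dialects (tab-separated, one header row):

* TE calls: ``line_id  family  contig  breakpoint  event_type  support``
  (breakpoint 1-based; event_type ``insertion``/``excision``).
* SV calls: ``contig  start  end  sv_type  length  quality  spanning_reads
  split_reads  carrier_lines  genotyped_lines`` where the last two columns
  are comma-separated line ids; ``genotyped_lines`` may be ``*`` for "all
  lines of the panel/block".
* Line metadata: ``line_id  treatment  generations  adjusted_generations``;
  per-(line, contig) median depths live in a companion table
  ``line_id  contig  median_depth``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError
from .records import LineMeta, SVRecord, SVType, TECall, TEEventType

TE_COLUMNS = ["line_id", "family", "contig", "breakpoint", "event_type", "support"]
SV_COLUMNS = [
    "contig",
    "start",
    "end",
    "sv_type",
    "length",
    "quality",
    "spanning_reads",
    "split_reads",
    "carrier_lines",
    "genotyped_lines",
]


def read_te_calls(path: str | Path) -> list[TECall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != TE_COLUMNS:
        raise ParseError(f"{path}: expected columns {TE_COLUMNS}, got {list(df.columns)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            event_type = TEEventType(row.event_type)
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {i}: unknown event_type {row.event_type!r}"
            ) from exc
        calls.append(
            TECall(
                line_id=row.line_id,
                family=row.family,
                contig=row.contig,
                breakpoint=int(row.breakpoint),
                event_type=event_type,
                support=int(row.support),
            )
        )
    return calls


def write_te_calls(calls: Iterable[TECall], path: str | Path) -> None:
    rows = [
        (c.line_id, c.family, c.contig, c.breakpoint, c.event_type.value, c.support)
        for c in calls
    ]
    pd.DataFrame(rows, columns=TE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_table(
    path: str | Path, panel_line_ids: Sequence[str]
) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != SV_COLUMNS:
        raise ParseError(f"{path}: expected columns {SV_COLUMNS}, got {list(df.columns)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sv_type = SVType(row.sv_type)
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: unknown sv_type {row.sv_type!r}") from exc
        carrier_field = row.carrier_lines if isinstance(row.carrier_lines, str) else ""
        carriers = set(carrier_field.split(",")) if carrier_field else set()
        genotyped = (
            set(panel_line_ids)
            if row.genotyped_lines == "*"
            else set(row.genotyped_lines.split(","))
        )
        presence = {line: line in carriers for line in genotyped}
        records.append(
            SVRecord(
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                sv_type=sv_type,
                length=int(row.length),
                quality=float(row.quality),
                spanning_read_support=int(row.spanning_reads),
                split_read_support=int(row.split_reads),
                per_line_presence=presence,
            )
        )
    return records


def write_sv_table(
    records: Iterable[SVRecord], path: str | Path, panel_line_ids: Sequence[str]
) -> None:
    rows = []
    for r in records:
        genotyped = sorted(r.per_line_presence)
        geno_field = (
            "*" if set(genotyped) == set(panel_line_ids) else ",".join(genotyped)
        )
        rows.append(
            (
                r.contig,
                r.start,
                r.end,
                r.sv_type.value,
                r.length,
                f"{r.quality:g}",
                r.spanning_read_support,
                r.split_read_support,
                ",".join(r.carrier_lines),
                geno_field,
            )
        )
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_line_meta(
    path: str | Path, depths_path: str | Path | None = None
) -> dict[str, LineMeta]:
    df = pd.read_csv(path, sep="\t")
    meta = {
        str(r.line_id): LineMeta(
            line_id=str(r.line_id),
            treatment=r.treatment,
            generations=int(r.generations),
            adjusted_generations=float(r.adjusted_generations),
        )
        for r in df.itertuples(index=False)
    }
    if depths_path is not None:
        dd = pd.read_csv(depths_path, sep="\t")
        for r in dd.itertuples(index=False):
            meta[str(r.line_id)].median_depth[r.contig] = float(r.median_depth)
    return meta


def write_line_meta(
    meta: dict[str, LineMeta],
    path: str | Path,
    depths_path: str | Path | None = None,
) -> None:
    rows = [
        (m.line_id, m.treatment, m.generations, m.adjusted_generations)
        for m in meta.values()
    ]
    pd.DataFrame(
        rows, columns=["line_id", "treatment", "generations", "adjusted_generations"]
    ).to_csv(path, sep="\t", index=False)
    if depths_path is not None:
        drows = [
            (m.line_id, contig, depth)
            for m in meta.values()
            for contig, depth in sorted(m.median_depth.items())
        ]
        pd.DataFrame(drows, columns=["line_id", "contig", "median_depth"]).to_csv(
            depths_path, sep="\t", index=False
        )
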