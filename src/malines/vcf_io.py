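"""Read and write the panel VCF dialect.

The dialect is VCF 4.2 with site annotations MQ, QD, FS, SOR, MQRankSum and
ReadPosRankSum as float INFO keys, FORMAT ``GT:AD:DP``, and one sample column
per mutation-accumulation line.  Reading goes through :mod:`pysam`; writing
is a small text emitter so that float formatting is stable (6 significant
digits) and ``write -> read -> write`` is byte-identical.

Multiallelic rows are split into one :class:`VariantRecord` per ALT allele.
Per-allele read support comes from the allele's AD entry; site-level
annotations are copied to every child record.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import ConfigurationError, ParseError
from .records import ANNOTATION_KEYS, Genotype, LineCall, VariantRecord

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    *[
        f'##INFO=<ID={k},Number=1,Type=Float,Description="{d}">'
        for k, d in [
            ("MQ", "RMS mapping quality"),
            ("QD", "Quality by depth"),
            ("FS", "Fisher strand bias (phred)"),
            ("SOR", "Symmetric odds ratio of strand bias"),
            ("MQRankSum", "Mapping quality rank-sum (alt vs ref reads)"),
            ("ReadPosRankSum", "Read position rank-sum (alt vs ref reads)"),
        ]
    ],
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
]


def _fmt_float(v: float) -> str:
    return f"{v:.6g}"


def _canon(v: float) -> float:
    """Canonicalize a float to the writer's 6-significant-digit precision.

    pysam surfaces INFO floats at float32 precision; re-rounding makes
    read(write(x)) an exact identity for values representable at 6 digits.
    """
    return float(f"{float(v):.6g}")


def _genotype_for_allele(gt: tuple, allele_index: int) -> Genotype:
    if gt is None or any(a is None for a in gt) or len(gt) == 0:
        return Genotype.MISSING
    copies = sum(1 for a in gt if a == allele_index)
    if copies == 0:
        return Genotype.HOM_REF
    if copies == len(gt):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(
    path: str | Path,
    panel_line_ids: Sequence[str],
    contigs: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Parse a panel VCF into split, normalized :class:`VariantRecord`\\ s.

    Parameters
    ----------
    path
        Uncompressed VCF 4.2 file following the documented dialect.
    panel_line_ids
        Expected sample names; a mismatch with the header is a
        :class:`ConfigurationError`.
    contigs
        If given, keep only records on these contigs (e.g. to route
        chromosome 4 to a separate output).

    Raises
    ------
    ParseError
        Malformed header or non-monotone positions within a contig, naming
        the offending line number.
    """
    path = Path(path)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF header: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if list(panel_line_ids) != samples:
            raise ConfigurationError(
                f"{path}: header samples {samples} != panel {list(panel_line_ids)}"
            )
        records: list[VariantRecord] = []
        last_pos: dict[str, int] = {}
        for i, row in enumerate(vf):
            lineno = n_header + i + 1
            if row.chrom in last_pos and row.pos < last_pos[row.chrom]:
                raise ParseError(
                    f"{path}:{lineno}: non-monotone position {row.pos} on "
                    f"{row.chrom}"
                )
            last_pos[row.chrom] = row.pos
            if contigs is not None and row.chrom not in contigs:
                continue
            annotations = {}
            for key in ANNOTATION_KEYS:
                if key in row.info:
                    annotations[key] = _canon(row.info[key])
            for ai, alt in enumerate(row.alts or (), start=1):
                calls = {}
                for sample in samples:
                    sc = row.samples[sample]
                    gt = sc.get("GT")
                    ad = sc.get("AD")
                    dp = sc.get("DP")
                    alt_reads = 0
                    if ad is not None and len(ad) > ai and ad[ai] is not None:
                        alt_reads = int(ad[ai])
                    total = int(dp) if dp is not None else 0
                    calls[sample] = LineCall(
                        genotype=_genotype_for_allele(gt, ai),
                        alt_read_count=alt_reads,
                        total_depth=total,
                    )
                records.append(
                    VariantRecord(
                        contig=row.chrom,
                        position=row.pos,
                        ref_allele=row.ref,
                        alt_allele=alt,
                        site_annotations=dict(annotations),
                        per_line_calls=calls,
                    )
                )
    return records


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    panel_line_ids: Sequence[str],
    contig_lengths: dict[str, int],
) -> None:
    """Serialize records (already one-ALT-per-record) to the panel dialect.

    Records are written sorted by (contig order in ``contig_lengths``,
    position), as the reader requires monotone positions.
    """
    order = {c: i for i, c in enumerate(contig_lengths)}
    recs = sorted(records, key=lambda r: (order.get(r.contig, math.inf), r.position))
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel_line_ids)
            + "\n"
        )
        for rec in recs:
            info = ";".join(
                f"{k}={_fmt_float(rec.site_annotations[k])}"
                for k in ANNOTATION_KEYS
                if k in rec.site_annotations
            )
            fields = [
                rec.contig,
                str(rec.position),
                ".",
                rec.ref_allele,
                rec.alt_allele,
                ".",
                ".",
                info or ".",
                "GT:AD:DP",
            ]
            for line_id in panel_line_ids:
                call = rec.per_line_calls[line_id]
                ref_reads = max(call.total_depth - call.alt_read_count, 0)
                fields.append(
                    f"{_GT_STRING[call.genotype]}:"
                    f"{ref_reads},{call.alt_read_count}:{call.total_depth}"
                )
            fh.write("\t".join(fields) + "\n")
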