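"""Line-unique variant selection, filtering, proximity exclusion and
clustering into mutation events.

The stage order mirrors how an MA callset is reduced in practice:

1. :func:`select_line_unique` — keep variants carried by exactly one line,
   with a called genotype in every line (convergent identical mutations are
   vanishingly unlikely; shared calls are artifacts or pre-existing
   variation).
2. :func:`apply_variant_filters` — the hard-filter stack in variant mode
   against the owner line's evidence.
3. :func:`exclude_near_sv_te` — drop point variants within the proximity
   radius of a structural variant or TE insertion.
4. :func:`cluster_variants` — chain surviving variants per (line, contig)
   into events: singletons are SNV/INDEL, multi-member chains are MNV
   (all-SNV) or COMPLEX (at least one INDEL), each counted once.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .filters import FilterThresholds, site_passes_filters
from .records import (
    Genotype,
    IntervalTrack,
    LineMeta,
    SVRecord,
    TEEventType,
    VariantRecord,
    Zygosity,
)


class EventCategory(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    MNV = "MNV"
    COMPLEX = "COMPLEX"
    SV = "SV"


@dataclass
class MutationEvent:
    """A filtered, clustered mutation assigned to one line."""

    line_id: str
    category: EventCategory
    contig: str
    start: int  # 1-based position of first member
    end: int  # 1-based position of last member
    members: list[VariantRecord] = field(default_factory=list)
    zygosity: Zygosity | None = None
    genic: bool | None = None
    consequence: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Rejection:
    contig: str
    position: int
    line_id: str | None
    reason: str


def select_line_unique(
    records: Iterable[VariantRecord],
) -> tuple[list[tuple[VariantRecord, str]], list[Rejection]]:
    """Keep variants with exactly one carrier line and no missing genotypes.

    Returns ``(candidates, rejections)`` where each candidate is
    ``(record, owner_line_id)``.  Rejection reasons: ``uncalled_site`` (a
    line has no called genotype), ``shared`` (>1 carrier), ``no_carrier``.
    """
    candidates: list[tuple[VariantRecord, str]] = []
    rejections: list[Rejection] = []
    for rec in records:
        carriers = [
            line
            for line, call in rec.per_line_calls.items()
            if call.genotype in (Genotype.HET, Genotype.HOM_ALT)
        ]
        missing = any(
            call.genotype is Genotype.MISSING
            for call in rec.per_line_calls.values()
        )
        if missing:
            reason = "uncalled_site"
        elif len(carriers) > 1:
            reason = "shared"
        elif not carriers:
            reason = "no_carrier"
        else:
            candidates.append((rec, carriers[0]))
            continue
        rejections.append(
            Rejection(rec.contig, rec.position, carriers[0] if len(carriers) == 1 else None, reason)
        )
    return candidates, rejections


def apply_variant_filters(
    candidates: Sequence[tuple[VariantRecord, str]],
    thresholds: FilterThresholds,
    line_meta: dict[str, LineMeta],
) -> tuple[list[tuple[VariantRecord, str]], list[Rejection]]:
    """Run the variant-mode filter stack against each owner line's evidence.

    The rejection log records the first failed rule, in the canonical rule
    order, for every dropped candidate.
    """
    survivors: list[tuple[VariantRecord, str]] = []
    rejections: list[Rejection] = []
    for rec, owner in candidates:
        call = rec.per_line_calls[owner]
        median = line_meta[owner].median_depth[rec.contig]
        ok, rule = site_passes_filters(
            rec.site_annotations,
            call.total_depth,
            median,
            thresholds,
            mode="variant",
            alt_read_count=call.alt_read_count,
        )
        if ok:
            survivors.append((rec, owner))
        else:
            rejections.append(Rejection(rec.contig, rec.position, owner, rule))
    return survivors, rejections


def _sv_distance(position: int, sv: SVRecord) -> int:
    """Distance from a 1-based point to an SV's nearest edge (0 if inside)."""
    first, last = sv.start + 1, sv.end  # 1-based inclusive span
    return max(first - position, position - last, 0)


def exclude_near_sv_te(
    variants: Sequence[tuple[VariantRecord, str]],
    sv_records: Sequence[SVRecord],
    te_breakpoints: Sequence[tuple[str, int, TEEventType]],
    proximity_bp: int = 1000,
    include_excisions: bool = False,
) -> tuple[list[tuple[VariantRecord, str]], list[Rejection]]:
    """Remove point variants within ``proximity_bp`` (inclusive) of an SV or
    TE insertion breakpoint.

    ``te_breakpoints`` are ``(contig, 1-based breakpoint, event_type)``
    tuples; excisions participate only when ``include_excisions`` is set.
    """
    te_by_contig: dict[str, list[int]] = {}
    for contig, bp, etype in te_breakpoints:
        if etype is TEEventType.EXCISION and not include_excisions:
            continue
        te_by_contig.setdefault(contig, []).append(bp)
    sv_by_contig: dict[str, list[SVRecord]] = {}
    for sv in sv_records:
        sv_by_contig.setdefault(sv.contig, []).append(sv)

    kept: list[tuple[VariantRecord, str]] = []
    rejections: list[Rejection] = []
    for rec, owner in variants:
        near = any(
            abs(rec.position - bp) <= proximity_bp
            for bp in te_by_contig.get(rec.contig, [])
        ) or any(
            _sv_distance(rec.position, sv) <= proximity_bp
            for sv in sv_by_contig.get(rec.contig, [])
        )
        if near:
            rejections.append(Rejection(rec.contig, rec.position, owner, "near_sv_te"))
        else:
            kept.append((rec, owner))
    return kept, rejections


def filter_sv_records(
    sv_records: Sequence[SVRecord],
    thresholds: FilterThresholds,
    max_quality: float,
    blocks: Sequence[set[str]] | None = None,
) -> tuple[list[SVRecord], list[Rejection]]:
    """Apply the SV call filters.

    A record survives iff it is carried by exactly one line, every line of
    that carrier's block has a called genotype, it has at least
    ``sv_min_support`` spanning OR split reads, and its quality equals the
    dialect's maximum possible score.  ``blocks`` partitions the panel into
    the sample blocks the SV caller was run on (default: one block holding
    every genotyped line of each record).
    """
    survivors: list[SVRecord] = []
    rejections: list[Rejection] = []
    for sv in sv_records:
        carriers = sv.carrier_lines
        if len(carriers) != 1:
            reason = "not_unique"
        else:
            block = None
            if blocks is not None:
                block = next((b for b in blocks if carriers[0] in b), None)
            genotyped = set(sv.per_line_presence)
            if block is not None and not block <= genotyped:
                reason = "uncalled_in_block"
            elif (
                sv.spanning_read_support < thresholds.sv_min_support
                and sv.split_read_support < thresholds.sv_min_support
            ):
                reason = "min_support"
            elif sv.quality != max_quality:
                reason = "not_max_quality"
            else:
                survivors.append(sv)
                continue
        rejections.append(
            Rejection(sv.contig, sv.start + 1, carriers[0] if carriers else None, reason)
        )
    return survivors, rejections


def cluster_variants(
    variants: Sequence[tuple[VariantRecord, str]],
    cluster_bp: int = 1000,
    linkage: str = "single",
) -> list[MutationEvent]:
    """Chain surviving variants per (line, contig) into mutation events.

    ``linkage="single"`` (default) chains sorted variants whenever the gap to
    the previous member is <= ``cluster_bp`` (inclusive); a chain may
    therefore span more than ``cluster_bp`` end to end.  ``linkage="span"``
    additionally breaks a chain when adding a member would push the
    end-to-end span past ``cluster_bp``.  Output order is deterministic
    (line, contig, position) regardless of input order.
    """
    if linkage not in ("single", "span"):
        raise ValueError(f"unknown linkage {linkage!r}")
    groups: dict[tuple[str, str], list[VariantRecord]] = {}
    for rec, owner in variants:
        groups.setdefault((owner, rec.contig), []).append(rec)

    events: list[MutationEvent] = []
    for (line_id, contig) in sorted(groups):
        members = sorted(
            groups[(line_id, contig)], key=lambda r: (r.position, r.ref_allele, r.alt_allele)
        )
        chain: list[VariantRecord] = []
        for rec in members:
            if not chain:
                chain = [rec]
                continue
            gap_ok = rec.position - chain[-1].position <= cluster_bp
            span_ok = linkage == "single" or rec.position - chain[0].position <= cluster_bp
            if gap_ok and span_ok:
                chain.append(rec)
            else:
                events.append(_chain_to_event(line_id, contig, chain))
                chain = [rec]
        if chain:
            events.append(_chain_to_event(line_id, contig, chain))
    return events


def _chain_to_event(line_id: str, contig: str, chain: list[VariantRecord]) -> MutationEvent:
    if len(chain) == 1:
        category = EventCategory.SNV if chain[0].is_snv else EventCategory.INDEL
    elif all(r.is_snv for r in chain):
        category = EventCategory.MNV
    else:
        category = EventCategory.COMPLEX
    event = MutationEvent(
        line_id=line_id,
        category=category,
        contig=contig,
        start=chain[0].position,
        end=chain[-1].position,
        members=list(chain),
    )
    event.zygosity = classify_zygosity(event)
    return event


def classify_zygosity(event: MutationEvent) -> Zygosity:
    """Homozygous iff every member is hom-alt in the owner line; heterozygous
    iff every member is het; anything else is mixed."""
    genotypes = {m.per_line_calls[event.line_id].genotype for m in event.members}
    if genotypes == {Genotype.HOM_ALT}:
        return Zygosity.HOMOZYGOUS
    if genotypes == {Genotype.HET}:
        return Zygosity.HETEROZYGOUS
    return Zygosity.MIXED


def sv_to_event(sv: SVRecord) -> MutationEvent:
    """Promote a surviving unique SV record to a mutation event."""
    (carrier,) = sv.carrier_lines
    return MutationEvent(
        line_id=carrier,
        category=EventCategory.SV,
        contig=sv.contig,
        start=sv.start + 1,
        end=sv.end,
        members=[],
    )


def annotate_genic(
    events: Iterable[MutationEvent], gene_track: IntervalTrack
) -> None:
    """Set each event's genic flag from its start position (in place)."""
    for event in events:
        event.genic = gene_track.contains_point(event.contig, event.start)
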