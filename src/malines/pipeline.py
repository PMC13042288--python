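"""End-to-end orchestration: calls -> filtered, clustered mutation events.

Stage order: line-uniqueness, variant-mode hard filters, SV filtering, TE
merging, SV/TE proximity exclusion, clustering, zygosity, genic annotation.
Each stage's rejections are kept, tagged with their reason, so planted
artifacts can be audited one by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import (
    EventCategory,
    MutationEvent,
    Rejection,
    annotate_genic,
    apply_variant_filters,
    cluster_variants,
    exclude_near_sv_te,
    filter_sv_records,
    select_line_unique,
    sv_to_event,
)
from .filters import FilterThresholds
from .records import IntervalTrack, LineMeta, SVRecord, TECall, VariantRecord
from .te import TEEvent, merge_te_calls, select_de_novo


@dataclass
class PipelineResult:
    events: list[MutationEvent]  # point-mutation events plus SV events
    te_events: list[TEEvent]  # all merged TE events
    te_de_novo: list[TEEvent]
    sv_survivors: list[SVRecord]
    rejections: list[Rejection] = field(default_factory=list)
    te_excluded: list[tuple[TEEvent, str]] = field(default_factory=list)

    def events_of(self, category: EventCategory) -> list[MutationEvent]:
        return [e for e in self.events if e.category is category]

    def counts_by_line(
        self, category: EventCategory, line_ids
    ) -> dict[str, int]:
        counts = {line: 0 for line in line_ids}
        for event in self.events_of(category):
            counts[event.line_id] += 1
        return counts


def run_pipeline(
    records: list[VariantRecord],
    sv_records: list[SVRecord],
    te_calls: list[TECall],
    line_meta: dict[str, LineMeta],
    thresholds: FilterThresholds = FilterThresholds(),
    sv_max_quality: float = 999.0,
    gene_track: IntervalTrack | None = None,
    include_te_excisions_in_exclusion: bool = False,
    cluster_linkage: str = "single",
) -> PipelineResult:
    candidates, rej_unique = select_line_unique(records)
    filtered, rej_filters = apply_variant_filters(candidates, thresholds, line_meta)

    sv_survivors, rej_sv = filter_sv_records(sv_records, thresholds, sv_max_quality)

    te_events = merge_te_calls(te_calls, thresholds.te_merge_bp)
    te_de_novo, te_excluded = select_de_novo(te_events)

    te_breakpoints = [
        (e.contig, e.breakpoint, e.event_type) for e in te_events
    ]
    kept, rej_proximity = exclude_near_sv_te(
        filtered,
        sv_survivors,
        te_breakpoints,
        proximity_bp=thresholds.proximity_bp,
        include_excisions=include_te_excisions_in_exclusion,
    )

    events = cluster_variants(kept, thresholds.cluster_bp, linkage=cluster_linkage)
    events.extend(sv_to_event(sv) for sv in sv_survivors)
    if gene_track is not None:
        annotate_genic(events, gene_track)

    return PipelineResult(
        events=events,
        te_events=te_events,
        te_de_novo=te_de_novo,
        sv_survivors=sv_survivors,
        rejections=rej_unique + rej_filters + rej_sv + rej_proximity,
        te_excluded=te_excluded,
    )


def events_to_frame(events) -> pd.DataFrame:
    rows = [
        {
            "line_id": e.line_id,
            "category": e.category.value,
            "contig": e.contig,
            "start": e.start,
            "end": e.end,
            "n_members": e.n_members,
            "zygosity": e.zygosity.value if e.zygosity else "",
            "genic": "" if e.genic is None else int(e.genic),
            "consequence": e.consequence or "",
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "line_id", "category", "contig", "start", "end",
            "n_members", "zygosity", "genic", "consequence",
        ],
    )


def rejections_to_frame(rejections) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": r.contig,
                "position": r.position,
                "line_id": r.line_id or "",
                "reason": r.reason,
            }
            for r in rejections
        ],
        columns=["contig", "position", "line_id", "reason"],
    )
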