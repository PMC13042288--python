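"""Callable-site accounting and coverage-based aneuploidy screening.

A reference site is *callable* when it is outside the repeat mask and passes
the non-variant filter stack in **every** line of the panel.  Per-line filter
failures arrive as sparse interval tracks (everything not listed passes),
which is how the synthetic generator and real per-site summaries both
naturally express them.

The bookkeeping identity ``total = repeat_masked + filter_failed + callable``
holds exactly: ``filter_failed`` counts only sites that are not already
repeat-masked, so the three classes partition the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .filters import FilterThresholds, site_passes_filters
from .records import IntervalTrack

AUTOSOMES = ("2L", "2R", "3L", "3R")


@dataclass
class CallableMask:
    """Per-contig callable bit-set plus the partition summary counts."""

    callable_by_contig: dict[str, np.ndarray]  # bool arrays, index = 0-based pos
    gc_by_contig: dict[str, np.ndarray] | None = None
    masked_count: dict[str, int] = field(default_factory=dict)
    failed_count: dict[str, int] = field(default_factory=dict)

    @property
    def contigs(self) -> list[str]:
        return sorted(self.callable_by_contig)

    def total_sites(self, contig: str | None = None) -> int:
        if contig is not None:
            return int(self.callable_by_contig[contig].size)
        return sum(a.size for a in self.callable_by_contig.values())

    def callable_sites(self, contig: str | None = None) -> int:
        if contig is not None:
            return int(np.count_nonzero(self.callable_by_contig[contig]))
        return sum(
            int(np.count_nonzero(a)) for a in self.callable_by_contig.values()
        )

    def callable_gc_sites(self, contig: str | None = None) -> int:
        if self.gc_by_contig is None:
            return 0
        contigs = [contig] if contig is not None else self.contigs
        return sum(
            int(np.count_nonzero(self.callable_by_contig[c] & self.gc_by_contig[c]))
            for c in contigs
        )

    def is_callable(self, contig: str, position_1based: int) -> bool:
        return bool(self.callable_by_contig[contig][position_1based - 1])

    def count_callable(self, contig: str, start: int, end: int) -> int:
        """Callable sites within half-open ``[start, end)``."""
        return int(np.count_nonzero(self.callable_by_contig[contig][start:end]))

    def count_gc(self, contig: str, start: int, end: int) -> int:
        if self.gc_by_contig is None:
            return 0
        window = self.callable_by_contig[contig][start:end]
        return int(np.count_nonzero(window & self.gc_by_contig[contig][start:end]))

    def callable_in_track(self, track: IntervalTrack) -> int:
        return sum(
            self.count_callable(iv.contig, iv.start, iv.end)
            for iv in track
            if iv.contig in self.callable_by_contig
        )

    def summary(self) -> dict[str, dict[str, int]]:
        out = {}
        for contig in self.contigs:
            total = self.total_sites(contig)
            callable_n = self.callable_sites(contig)
            out[contig] = {
                "total": total,
                "masked": self.masked_count.get(contig, 0),
                "failed": self.failed_count.get(contig, 0),
                "callable": callable_n,
                "callable_gc": self.callable_gc_sites(contig),
            }
        return out

    def totals(self) -> dict[str, int]:
        per = self.summary()
        keys = ("total", "masked", "failed", "callable", "callable_gc")
        return {k: sum(row[k] for row in per.values()) for k in keys}


def _track_to_bool(
    track: IntervalTrack, contig: str, length: int
) -> np.ndarray:
    out = np.zeros(length, dtype=bool)
    for iv in track.on(contig):
        if iv.end > length:
            raise ConfigurationError(
                f"interval [{iv.start},{iv.end}) exceeds {contig} length {length}"
            )
        out[iv.start : iv.end] = True
    return out


def compute_callable_mask(
    contig_lengths: dict[str, int],
    repeat_mask: IntervalTrack,
    per_line_fail_tracks: dict[str, IntervalTrack],
    gc_by_contig: dict[str, np.ndarray] | None = None,
) -> CallableMask:
    """Combine the repeat mask with every line's filter failures.

    Parameters
    ----------
    per_line_fail_tracks
        For each line, the intervals (0-based half-open) where the
        non-variant filter stack fails for that line; a site is callable only
        if no line fails there.
    """
    for track in list(per_line_fail_tracks.values()) + [repeat_mask]:
        for contig in track.contigs:
            if contig not in contig_lengths:
                raise ConfigurationError(
                    f"contig {contig!r} not in the genome definition"
                )
    callable_by_contig: dict[str, np.ndarray] = {}
    masked_count: dict[str, int] = {}
    failed_count: dict[str, int] = {}
    for contig, length in contig_lengths.items():
        masked = _track_to_bool(repeat_mask, contig, length)
        failed = np.zeros(length, dtype=bool)
        for track in per_line_fail_tracks.values():
            failed |= _track_to_bool(track, contig, length)
        failed &= ~masked  # partition: masked takes precedence in accounting
        callable_by_contig[contig] = ~(masked | failed)
        masked_count[contig] = int(np.count_nonzero(masked))
        failed_count[contig] = int(np.count_nonzero(failed))
    return CallableMask(
        callable_by_contig=callable_by_contig,
        gc_by_contig=gc_by_contig,
        masked_count=masked_count,
        failed_count=failed_count,
    )


def fail_intervals_from_site_stats(
    site_stats,
    line_median_depth: float,
    thresholds: FilterThresholds,
    contig: str,
    strict_callable: bool = True,
) -> IntervalTrack:
    """Turn an explicit per-site statistics table into a failure track.

    ``site_stats`` is a DataFrame with a 1-based ``position`` column, a
    ``depth`` column, and any subset of the annotation columns; each row is
    evaluated with the non-variant filter stack.  Adjacent failing sites are
    merged into maximal intervals.
    """
    from .records import ANNOTATION_KEYS, Interval

    failing: list[int] = []
    for row in site_stats.itertuples(index=False):
        annotations = {
            k: getattr(row, k)
            for k in ANNOTATION_KEYS
            if hasattr(row, k) and not np.isnan(getattr(row, k))
        }
        ok, _ = site_passes_filters(
            annotations,
            int(row.depth),
            line_median_depth,
            thresholds,
            mode="nonvariant",
            strict_callable=strict_callable,
        )
        if not ok:
            failing.append(int(row.position) - 1)
    track = IntervalTrack()
    if not failing:
        return track
    failing.sort()
    run_start = prev = failing[0]
    for pos in failing[1:]:
        if pos != prev + 1:
            track.add(Interval(contig, run_start, prev + 1))
            run_start = pos
        prev = pos
    track.add(Interval(contig, run_start, prev + 1))
    return track


def summarize_totals(
    total_sites: int, non_callable: int, repeat_masked: int
) -> dict[str, float]:
    """Complete the callable-site partition from three of its totals.

    Given the reference-site total, the non-callable total and the
    repeat-masked portion of it, returns the filter-failed remainder, the
    callable total and the callable percentage (the partition identity
    ``total = masked + failed + callable``).
    """
    if not 0 <= repeat_masked <= non_callable <= total_sites:
        raise ValueError("totals are not a valid partition")
    filter_failed = non_callable - repeat_masked
    callable_n = total_sites - non_callable
    return {
        "filter_failed": filter_failed,
        "callable": callable_n,
        "callable_percent": 100.0 * callable_n / total_sites,
    }


def detect_aneuploidy(
    per_line_contig_depth: dict[str, dict[str, float]],
    ratio_threshold: float = 1.4,
    autosomes: tuple[str, ...] = AUTOSOMES,
) -> list[tuple[str, str, float]]:
    """Flag (line, contig) pairs whose mean depth is elevated vs the line.

    The reference level is the line's median depth across autosomal contigs;
    a contig at ratio >= ``ratio_threshold`` (default 1.4, between disomy at
    1.0 and trisomy at 1.5) is reported as a trisomy candidate.
    """
    flags = []
    for line_id, depths in per_line_contig_depth.items():
        if len(depths) < 2:
            raise ValueError(f"line {line_id}: need >= 2 contigs")
        auto = [d for c, d in depths.items() if c in autosomes]
        baseline = float(np.median(auto if auto else list(depths.values())))
        if baseline <= 0:
            raise ValueError(f"line {line_id}: zero baseline depth")
        for contig, depth in sorted(depths.items()):
            ratio = depth / baseline
            if ratio >= ratio_threshold:
                flags.append((line_id, contig, float(ratio)))
    return flags
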