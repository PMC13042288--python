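"""The hard-filter stack applied symmetrically to variant and non-variant sites.

All comparisons are inclusive as printed (>= / <=): a site sitting exactly on
every boundary passes.  In ``variant`` mode the alt-read-support rule applies
in addition; the depth window (relative to the line's chromosome-wide median)
applies in both modes.

Missing annotations fail closed for variant candidacy.  For callable-site
(non-variant) evaluation the behaviour is governed by ``strict_callable``:
``True`` (default) treats a missing annotation as a failure, ``False`` lets
it pass.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FilterThresholds", "site_passes_filters", "RULE_ORDER"]


@dataclass(frozen=True)
class FilterThresholds:
    """Filter thresholds; defaults follow standard GATK hard-filter practice.

    ``proximity_bp`` is the SV/TE exclusion radius, ``cluster_bp`` the
    event-clustering gap, ``te_merge_bp`` the TE breakpoint merge window and
    ``sv_min_support`` the spanning/split read floor for SV calls.
    """

    min_alt_reads: int = 10
    min_MQ: float = 50.0
    min_QD: float = 2.0
    max_FS: float = 60.0
    max_SOR: float = 3.0
    max_abs_MQRankSum: float = 8.0
    max_abs_ReadPosRankSum: float = 4.0
    depth_lo_frac: float = 0.5
    depth_hi_frac: float = 2.0
    proximity_bp: int = 1000
    cluster_bp: int = 1000
    te_merge_bp: int = 50
    sv_min_support: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_alt_reads",
            "min_MQ",
            "min_QD",
            "max_FS",
            "max_SOR",
            "max_abs_MQRankSum",
            "max_abs_ReadPosRankSum",
            "depth_lo_frac",
            "depth_hi_frac",
            "proximity_bp",
            "cluster_bp",
            "te_merge_bp",
            "sv_min_support",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_lo_frac >= self.depth_hi_frac:
            raise ValueError("depth_lo_frac must be < depth_hi_frac")


#: canonical rule evaluation order; rejection logs report the FIRST failure.
RULE_ORDER = (
    "min_alt_reads",
    "min_MQ",
    "min_QD",
    "max_FS",
    "max_SOR",
    "max_abs_MQRankSum",
    "max_abs_ReadPosRankSum",
    "depth_window",
)


def site_passes_filters(
    annotations: dict[str, float],
    depth: int,
    line_median_depth: float,
    thresholds: FilterThresholds,
    mode: str = "variant",
    alt_read_count: int = 0,
    strict_callable: bool = True,
) -> tuple[bool, str | None]:
    """Evaluate one site for one line; returns ``(passed, first_failed_rule)``.

    ``mode`` is ``"variant"`` or ``"nonvariant"``.  Variant mode is strictly
    stricter: it adds the ``min_alt_reads`` rule and fails closed on missing
    annotations regardless of ``strict_callable``.
    """
    if mode not in ("variant", "nonvariant"):
        raise ValueError(f"unknown mode {mode!r}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if line_median_depth <= 0:
        raise ValueError("line median depth must be positive")

    fail_on_missing = mode == "variant" or strict_callable

    def check(key: str, rule: str, ok) -> str | None:
        value = annotations.get(key)
        if value is None:
            return f"missing:{key}" if fail_on_missing else None
        return None if ok(value) else rule

    if mode == "variant" and alt_read_count < thresholds.min_alt_reads:
        return False, "min_alt_reads"
    checks = (
        check("MQ", "min_MQ", lambda v: v >= thresholds.min_MQ),
        check("QD", "min_QD", lambda v: v >= thresholds.min_QD),
        check("FS", "max_FS", lambda v: v <= thresholds.max_FS),
        check("SOR", "max_SOR", lambda v: v <= thresholds.max_SOR),
        check(
            "MQRankSum",
            "max_abs_MQRankSum",
            lambda v: abs(v) <= thresholds.max_abs_MQRankSum,
        ),
        check(
            "ReadPosRankSum",
            "max_abs_ReadPosRankSum",
            lambda v: abs(v) <= thresholds.max_abs_ReadPosRankSum,
        ),
    )
    for failed in checks:
        if failed is not None:
            return False, failed
    lo = thresholds.depth_lo_frac * line_median_depth
    hi = thresholds.depth_hi_frac * line_median_depth
    if not (lo <= depth <= hi):
        return False, "depth_window"
    return True, None
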