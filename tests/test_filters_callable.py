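"""Filter stack semantics and callable-site accounting."""

import numpy as np
import pandas as pd
import pytest

import malines as m
from malines.callable_sites import (
    detect_aneuploidy,
    fail_intervals_from_site_stats,
    summarize_totals,
)
from malines.filters import site_passes_filters

THR = m.FilterThresholds()

BOUNDARY = {
    "MQ": 50.0,
    "QD": 2.0,
    "FS": 60.0,
    "SOR": 3.0,
    "MQRankSum": -8.0,
    "ReadPosRankSum": 4.0,
}


def test_all_boundaries_inclusive():
    ok, rule = site_passes_filters(
        BOUNDARY, depth=50, line_median_depth=100, thresholds=THR,
        mode="variant", alt_read_count=10,
    )
    assert ok and rule is None


@pytest.mark.parametrize(
    "change, expected_rule",
    [
        (dict(alt=9), "min_alt_reads"),
        (dict(ann={"MQ": 49.999}), "min_MQ"),
        (dict(ann={"QD": 1.9}), "min_QD"),
        (dict(ann={"FS": 60.001}), "max_FS"),
        (dict(ann={"SOR": 3.5}), "max_SOR"),
        (dict(ann={"MQRankSum": 8.5}), "max_abs_MQRankSum"),
        (dict(ann={"ReadPosRankSum": -4.5}), "max_abs_ReadPosRankSum"),
        (dict(depth=201), "depth_window"),
        (dict(depth=49), "depth_window"),
    ],
)
def test_single_rule_failures(change, expected_rule):
    ann = dict(BOUNDARY, **change.get("ann", {}))
    ok, rule = site_passes_filters(
        ann,
        depth=change.get("depth", 100),
        line_median_depth=100,
        thresholds=THR,
        mode="variant",
        alt_read_count=change.get("alt", 10),
    )
    assert not ok and rule == expected_rule


def test_missing_annotation_handling():
    ann = {k: v for k, v in BOUNDARY.items() if k != "MQRankSum"}
    ok, rule = site_passes_filters(ann, 100, 100, THR, "variant", alt_read_count=10)
    assert not ok and rule == "missing:MQRankSum"
    ok, _ = site_passes_filters(ann, 100, 100, THR, "nonvariant", strict_callable=True)
    assert not ok
    ok, _ = site_passes_filters(ann, 100, 100, THR, "nonvariant", strict_callable=False)
    assert ok


def test_variant_mode_strictly_stricter(rng):
    """Symmetry: passing variant mode implies passing nonvariant mode."""
    for _ in range(500):
        ann = {
            "MQ": float(rng.uniform(40, 60)),
            "QD": float(rng.uniform(0, 5)),
            "FS": float(rng.uniform(0, 80)),
            "SOR": float(rng.uniform(0, 5)),
            "MQRankSum": float(rng.uniform(-10, 10)),
            "ReadPosRankSum": float(rng.uniform(-6, 6)),
        }
        depth = int(rng.integers(10, 250))
        alt = int(rng.integers(0, depth + 1))
        v_ok, _ = site_passes_filters(ann, depth, 100, THR, "variant", alt)
        nv_ok, _ = site_passes_filters(ann, depth, 100, THR, "nonvariant")
        assert not v_ok or nv_ok


def test_tightening_is_monotone(rng):
    """Tightening any threshold never increases the pass count."""
    sites = []
    for _ in range(400):
        sites.append(
            (
                {
                    "MQ": float(rng.uniform(40, 60)),
                    "QD": float(rng.uniform(0, 5)),
                    "FS": float(rng.uniform(0, 80)),
                    "SOR": float(rng.uniform(0, 5)),
                    "MQRankSum": float(rng.uniform(-10, 10)),
                    "ReadPosRankSum": float(rng.uniform(-6, 6)),
                },
                int(rng.integers(10, 250)),
            )
        )

    def n_pass(thr):
        return sum(
            site_passes_filters(ann, depth, 100, thr, "nonvariant")[0]
            for ann, depth in sites
        )

    base = n_pass(THR)
    tighter = [
        m.FilterThresholds(min_MQ=55),
        m.FilterThresholds(min_QD=3),
        m.FilterThresholds(max_FS=40),
        m.FilterThresholds(max_SOR=2),
        m.FilterThresholds(max_abs_MQRankSum=5),
        m.FilterThresholds(max_abs_ReadPosRankSum=2),
        m.FilterThresholds(depth_lo_frac=0.8, depth_hi_frac=1.5),
    ]
    for thr in tighter:
        assert n_pass(thr) <= base


def test_callable_mask_toy_arithmetic():
    """1,000 sites, 100 repeat-masked, 50 failing in one line -> 850 callable."""
    lengths = {"2L": 1000}
    repeat = m.IntervalTrack([m.Interval("2L", 0, 100)])
    fails = {
        "L1": m.IntervalTrack([m.Interval("2L", 200, 250)]),
        "L2": m.IntervalTrack(),
    }
    mask = m.compute_callable_mask(lengths, repeat, fails)
    t = mask.totals()
    assert t == {"total": 1000, "masked": 100, "failed": 50, "callable": 850, "callable_gc": 0}


def test_callable_partition_identity(default_experiment):
    t = default_experiment.mask.totals()
    assert t["total"] == t["masked"] + t["failed"] + t["callable"]
    assert t["callable_gc"] <= t["callable"]


def test_printed_bookkeeping_totals():
    """The published partition: 133,880,608 reference sites, 34,422,478
    non-callable of which 20,052,895 repeat-masked."""
    out = summarize_totals(133_880_608, 34_422_478, 20_052_895)
    assert out["filter_failed"] == 14_369_583
    assert out["callable"] == 99_458_130
    assert round(out["callable_percent"]) == 74


def test_callable_mask_brute_force_oracle(rng):
    """10 kb genome with explicit per-site stats vs a site-by-site loop."""
    length = 10_000
    lengths = {"2L": length}
    positions = np.arange(1, length + 1)
    lines = ["L1", "L2", "L3"]
    medians = {"L1": 100.0, "L2": 80.0, "L3": 120.0}
    stats_by_line = {}
    for line in lines:
        stats_by_line[line] = pd.DataFrame(
            {
                "position": positions,
                "MQ": rng.uniform(45, 60, length),
                "QD": rng.uniform(0, 10, length),
                "FS": rng.uniform(0, 70, length),
                "SOR": rng.uniform(0, 4, length),
                "MQRankSum": rng.uniform(-10, 10, length),
                "ReadPosRankSum": rng.uniform(-6, 6, length),
                "depth": rng.integers(30, 260, length),
            }
        )
    repeat = m.IntervalTrack([m.Interval("2L", 1000, 1500)])
    fail_tracks = {
        line: fail_intervals_from_site_stats(df, medians[line], THR, "2L")
        for line, df in stats_by_line.items()
    }
    mask = m.compute_callable_mask(lengths, repeat, fail_tracks)

    # independent brute force, straight from the rules
    brute = np.ones(length, dtype=bool)
    brute[1000:1500] = False
    for line in lines:
        df = stats_by_line[line]
        for i in range(length):
            if not brute[i]:
                continue
            ann = {
                k: df[k].iloc[i]
                for k in ("MQ", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum")
            }
            ok, _ = site_passes_filters(
                ann, int(df["depth"].iloc[i]), medians[line], THR, "nonvariant"
            )
            if not ok:
                brute[i] = False
    assert mask.callable_sites() == int(brute.sum())
    assert np.array_equal(mask.callable_by_contig["2L"], brute)


def test_aneuploidy_flags():
    depths = {"L1": {"2L": 100, "2R": 101, "3L": 99, "3R": 100, "4": 150}}
    flags = detect_aneuploidy(depths)
    assert [(f[0], f[1]) for f in flags] == [("L1", "4")]
    depths = {"L1": {"2L": 100, "2R": 100, "3L": 100, "3R": 100, "X": 100}}
    assert detect_aneuploidy(depths) == []


def test_aneuploidy_detection_under_noise():
    """A 1.5x contig with NB depth noise is flagged in >= 19/20 seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        contigs = ["2L", "2R", "3L", "3R", "4"]

        def mean_depth(scale):
            base = 100.0 * scale
            reads = rng.negative_binomial(10, 10 / (10 + base), size=2000)
            return float(reads.mean())

        depths = {c: mean_depth(1.5 if c == "4" else 1.0) for c in contigs}
        flags = detect_aneuploidy({"L1": depths})
        if any(f[1] == "4" for f in flags):
            hits += 1
    assert hits >= 19
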