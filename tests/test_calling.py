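"""Line-unique selection, filter application, exclusion and clustering."""

import numpy as np
import pytest

import malines as m
from malines.calling import (
    EventCategory,
    cluster_variants,
    exclude_near_sv_te,
    filter_sv_records,
    select_line_unique,
)
from malines.records import Genotype, LineCall, TEEventType

PANEL = ["A", "B", "C"]


def _record(position, genotypes, contig="2L", ref="A", alt="G", ann=None):
    calls = {
        line: LineCall(g, 30 if g in (Genotype.HET, Genotype.HOM_ALT) else 0, 60)
        for line, g in genotypes.items()
    }
    return m.VariantRecord(
        contig, position, ref, alt,
        ann or {"MQ": 55.0, "QD": 20.0, "FS": 2.0, "SOR": 1.0,
                "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
        calls,
    )


def test_select_line_unique_cases():
    het_a = _record(100, {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF})
    shared = _record(200, {"A": Genotype.HET, "B": Genotype.HET, "C": Genotype.HOM_REF})
    uncalled = _record(300, {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.MISSING})
    candidates, rejections = select_line_unique([het_a, shared, uncalled])
    assert candidates == [(het_a, "A")]
    assert {(r.position, r.reason) for r in rejections} == {
        (200, "shared"),
        (300, "uncalled_site"),
    }


def _line_meta():
    meta = {}
    for line in PANEL:
        lm = m.LineMeta(line_id=line, treatment="dsb_plus")
        lm.median_depth = {"2L": 100.0, "X": 100.0}
        meta[line] = lm
    return meta


def test_variant_filters_log_first_failed_rule():
    bad = _record(
        500,
        {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF},
        ann={"MQ": 55.0, "QD": 1.9, "FS": 2.0, "SOR": 1.0,
             "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
    )
    survivors, rejections = m.apply_variant_filters([(bad, "A")], m.FilterThresholds(), _line_meta())
    assert survivors == []
    assert rejections[0].reason == "min_QD"


def test_variant_filters_brute_force(rng):
    """1,000 random candidates: survivor set equals an independent loop."""
    thr = m.FilterThresholds()
    meta = _line_meta()
    candidates = []
    for i in range(1000):
        depth = int(rng.integers(20, 250))
        alt = int(rng.integers(0, depth + 1))
        rec = m.VariantRecord(
            "2L", 1000 + 2 * i, "A", "G",
            {
                "MQ": float(rng.uniform(45, 60)),
                "QD": float(rng.uniform(0, 6)),
                "FS": float(rng.uniform(0, 80)),
                "SOR": float(rng.uniform(0, 4)),
                "MQRankSum": float(rng.uniform(-10, 10)),
                "ReadPosRankSum": float(rng.uniform(-6, 6)),
            },
            {
                "A": LineCall(Genotype.HET, alt, depth),
                "B": LineCall(Genotype.HOM_REF, 0, 100),
                "C": LineCall(Genotype.HOM_REF, 0, 100),
            },
        )
        candidates.append((rec, "A"))
    survivors, _ = m.apply_variant_filters(candidates, thr, meta)

    def naive_pass(rec):
        a = rec.site_annotations
        call = rec.per_line_calls["A"]
        return (
            call.alt_read_count >= 10
            and a["MQ"] >= 50 and a["QD"] >= 2 and a["FS"] <= 60 and a["SOR"] <= 3
            and abs(a["MQRankSum"]) <= 8 and abs(a["ReadPosRankSum"]) <= 4
            and 50 <= call.total_depth <= 200
        )

    expected = [(r, "A") for r, _ in candidates if naive_pass(r)]
    assert survivors == expected
    assert 0 < len(survivors) < 1000


def _sv(contig, start, end, carriers, quality=999.0, spanning=20, split=0, panel=PANEL):
    return m.SVRecord(
        contig=contig, start=start, end=end, sv_type=m.SVType.DELETION,
        length=end - start, quality=quality,
        spanning_read_support=spanning, split_read_support=split,
        per_line_presence={l: l in carriers for l in panel},
    )


def test_proximity_exclusion_boundaries():
    snv = _record(5000, {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF})
    # SV whose nearest edge (1-based 6000) is exactly 1,000 away: removed
    sv = _sv("2L", 5999, 8000, ["B"])
    kept, removed = exclude_near_sv_te([(snv, "A")], [sv], [])
    assert kept == [] and removed[0].reason == "near_sv_te"
    # TE insertion at 6001: distance 1,001, kept
    kept, removed = exclude_near_sv_te(
        [(snv, "A")], [], [("2L", 6001, TEEventType.INSERTION)]
    )
    assert kept == [(snv, "A")] and removed == []
    # excisions are ignored unless opted in
    kept, _ = exclude_near_sv_te(
        [(snv, "A")], [], [("2L", 5100, TEEventType.EXCISION)]
    )
    assert kept == [(snv, "A")]
    kept, _ = exclude_near_sv_te(
        [(snv, "A")], [], [("2L", 5100, TEEventType.EXCISION)], include_excisions=True
    )
    assert kept == []


def test_proximity_exclusion_brute_force(rng):
    variants = []
    for i in range(500):
        pos = int(rng.integers(1, 100_000))
        variants.append(
            (_record(pos, {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}), "A")
        )
    svs = []
    for _ in range(20):
        start = int(rng.integers(0, 95_000))
        svs.append(_sv("2L", start, start + int(rng.integers(300, 4000)), ["B"]))
    tes = [("2L", int(rng.integers(1, 100_000)), TEEventType.INSERTION) for _ in range(30)]
    kept, removed = exclude_near_sv_te(variants, svs, tes)

    def naive_near(pos):
        for sv in svs:
            if max(sv.start + 1 - pos, pos - sv.end, 0) <= 1000:
                return True
        return any(abs(pos - bp) <= 1000 for _, bp, _ in tes)

    expected_removed = {r.position for r, _ in variants if naive_near(r.position)}
    assert {r.position for r in removed} == expected_removed
    assert len(kept) + len(removed) == len(variants)


def test_sv_filters():
    thr = m.FilterThresholds()
    keep = _sv("2L", 100, 600, ["A"], quality=999.0, spanning=10, split=0)
    low = _sv("2L", 100, 600, ["A"], quality=999.0, spanning=9, split=9)
    notmax = _sv("2L", 100, 600, ["A"], quality=998.0)
    shared = _sv("2L", 100, 600, ["A", "B"])
    survivors, rejections = filter_sv_records([keep, low, notmax, shared], thr, 999.0)
    assert survivors == [keep]
    assert [r.reason for r in rejections] == ["min_support", "not_max_quality", "not_unique"]


def test_clustering_definitions():
    meta = {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}
    snv1, snv2 = _record(100, meta), _record(900, meta)
    events = cluster_variants([(snv1, "A"), (snv2, "A")])
    assert [e.category for e in events] == [EventCategory.MNV]

    deletion = _record(600, meta, ref="ATTT", alt="A")
    events = cluster_variants([(snv1, "A"), (deletion, "A")])
    assert [e.category for e in events] == [EventCategory.COMPLEX]

    # single-linkage: consecutive gaps of 900 chain even though the ends
    # are 1,800 apart
    chain = [(_record(p, meta), "A") for p in (100, 1000, 1900)]
    events = cluster_variants(chain)
    assert len(events) == 1
    assert events[0].category is EventCategory.MNV
    assert events[0].n_members == 3

    # span-limited linkage breaks that chain
    events = cluster_variants(chain, linkage="span")
    assert len(events) == 2

    # different lines never cluster together
    events = cluster_variants([(snv1, "A"), (snv2, "B")])
    assert sorted(e.category.value for e in events) == ["SNV", "SNV"]


def test_clustering_order_invariance_and_partition(rng):
    meta = {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}
    variants = [
        (_record(int(rng.integers(1, 50_000)), meta), str(rng.choice(["A", "B"])))
        for _ in range(300)
    ]
    base = cluster_variants(variants)
    assert sum(e.n_members for e in base) == len(variants)
    for _ in range(3):
        shuffled = list(variants)
        rng.shuffle(shuffled)
        again = cluster_variants(shuffled)
        assert [
            (e.line_id, e.contig, tuple(v.position for v in e.members)) for e in again
        ] == [(e.line_id, e.contig, tuple(v.position for v in e.members)) for e in base]


def test_clustering_brute_force(rng):
    """Union-find over the pairwise <=1 kb graph gives the same partition."""
    meta = {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}
    for trial in range(20):
        positions = sorted(
            int(p) for p in rng.choice(np.arange(1, 30_000), size=60, replace=False)
        )
        variants = [(_record(p, meta), "A") for p in positions]
        events = cluster_variants(variants)

        parent = list(range(len(positions)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if abs(positions[i] - positions[j]) <= 1000:
                    parent[find(i)] = find(j)
        expected = {}
        for i, p in enumerate(positions):
            expected.setdefault(find(i), []).append(p)
        expected_sets = sorted(tuple(v) for v in expected.values())
        got_sets = sorted(tuple(v.position for v in e.members) for e in events)
        assert got_sets == expected_sets


def test_zygosity_classification():
    hom = {"A": Genotype.HOM_ALT, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}
    het = {"A": Genotype.HET, "B": Genotype.HOM_REF, "C": Genotype.HOM_REF}
    (event,) = cluster_variants([(_record(100, hom), "A")])
    assert event.zygosity is m.Zygosity.HOMOZYGOUS
    (event,) = cluster_variants([(_record(100, het), "A")])
    assert event.zygosity is m.Zygosity.HETEROZYGOUS
    (event,) = cluster_variants([(_record(100, het), "A"), (_record(600, hom), "A")])
    assert event.zygosity is m.Zygosity.MIXED
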