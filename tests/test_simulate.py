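"""The synthetic generator: determinism, null model, planted means, truth."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

import malines as m
from malines.simulate import score_recovery


def _null_rates():
    return dict(
        snv_rate=0.0, indel_rate=0.0, mnv_rate=0.0, complex_rate=0.0, sv_rate=0.0,
        te_insertion_rate={"dsb_plus": 0.0, "dsb_minus": 0.0},
        te_excision_rate={"dsb_plus": 0.0, "dsb_minus": 0.0},
        segregating_te_count=0,
    )


def _small(seed=0, **kw):
    base = dict(
        seed=seed,
        n_lines_per_group=(3, 3),
        contig_lengths={"2L": 400_000, "X": 400_000},
        te_insertion_rate={"dsb_plus": 0.15, "dsb_minus": 0.2},
        te_excision_rate={"dsb_plus": 0.05, "dsb_minus": 0.05},
        n_windows=50,
    )
    base.update(kw)
    return m.SimulationConfig(**base)


def test_determinism_byte_identical(tmp_path):
    for name in ("a", "b"):
        m.generate_experiment(_small(seed=9)).write(tmp_path / name)
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False), rel


def test_different_seeds_differ():
    a = m.generate_experiment(_small(seed=1))
    b = m.generate_experiment(_small(seed=2))
    assert [e.positions for e in a.truth.events] != [e.positions for e in b.truth.events]


def test_null_model_contains_only_artifacts():
    # near-SV/TE artifacts are excluded: they require planting a real event
    exp = m.generate_experiment(
        _small(
            seed=4,
            near_sv_artifact_count=0,
            near_te_artifact_count=0,
            **_null_rates(),
        )
    )
    assert exp.truth.events == []
    assert all(not t.de_novo for t in exp.truth.te_events)
    # every variant record corresponds to a planted artifact site
    artifact_sites = {(a.contig, a.position) for a in exp.truth.artifacts}
    for rec in exp.records:
        assert (rec.contig, rec.position) in artifact_sites


def test_zero_callable_genome_is_an_error():
    with pytest.raises(m.errors.ConfigurationError):
        m.generate_experiment(_small(repeat_fraction=1.0, fail_fraction=0.0))


def test_planted_snv_count_matches_poisson_mean():
    """snv_rate 1e-7, 10 lines, 30 generations, 1 Mb fully callable:
    lambda = rate x callable x generations x lines = 30; the mean over
    20 seeds sits within 3*sqrt(lambda)."""
    counts = []
    for seed in range(20):
        cfg = m.SimulationConfig(
            seed=seed,
            n_lines_per_group=(5, 5),
            contig_lengths={"2L": 500_000, "2R": 500_000},
            snv_rate=1e-7,
            repeat_fraction=0.0,
            fail_fraction=0.0,
            **{
                k: v
                for k, v in _null_rates().items()
                if k != "snv_rate"
            },
            n_windows=50,
        )
        exp = m.generate_experiment(cfg)
        assert exp.mask.callable_sites() == 1_000_000
        counts.append(sum(1 for e in exp.truth.events if e.category == "SNV"))
    lam = 1e-7 * 1_000_000 * 30 * 10  # = 30
    assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam)


def test_zygosity_labels_match_truth(default_experiment, default_pipeline):
    truth_by_key = {
        (e.line_id, e.contig, e.positions): e.zygosity
        for e in default_experiment.truth.events
        if e.category != "SV"
    }
    for event in default_pipeline.events:
        if event.category.value == "SV":
            continue
        key = (event.line_id, event.contig, tuple(v.position for v in event.members))
        assert event.zygosity.value == truth_by_key[key]


def test_score_recovery_perfect_on_noise_free(default_experiment, default_pipeline):
    report = score_recovery(
        default_pipeline.events,
        default_pipeline.te_de_novo,
        default_pipeline.rejections,
        default_experiment.truth,
    )
    for cat, r in report["by_category"].items():
        assert r["precision"] == 1.0 and r["recall"] == 1.0, (cat, r)
    assert report["artifacts_all_ok"]


def test_score_recovery_empty_is_defined():
    exp = m.generate_experiment(
        _small(
            seed=6,
            shared_artifact_count=0,
            uncalled_artifact_count=0,
            near_sv_artifact_count=0,
            near_te_artifact_count=0,
            artifact_counts_by_filter={},
            sv_artifact_counts={},
            **_null_rates(),
        )
    )
    report = score_recovery([], [], [], exp.truth)
    for r in report["by_category"].values():
        assert r["tp"] == r["fp"] == r["fn"] == 0
    assert report["artifacts_all_ok"]


def test_large_jitter_breaks_merging():
    """Calls jittered beyond the merge window split into separate events."""
    cfg = _small(
        seed=8,
        te_large_jitter_frac=1.0,
        **(_null_rates() | {"segregating_te_count": 10}),
    )
    exp = m.generate_experiment(cfg)
    events = m.merge_te_calls(exp.te_calls)
    # each planted multi-carrier event fragments: more events than planted
    assert len(events) > len(exp.truth.te_events)
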