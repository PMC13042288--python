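"""Window projection, annotation, NB fits, GLMM and likelihood-ratio tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import malines as m
from malines.simulate import simulate_window_counts
from malines.windows import likelihood_ratio_test, project_covariate


def _track(intervals):
    return m.IntervalTrack([m.Interval(*iv) for iv in intervals])


def test_projection_constant_and_hand_value():
    track = _track([("2L", 0, 50, 2.0), ("2L", 50, 150, 4.0)])
    assert project_covariate(track, [("2L", 0, 100)]) == [3.0]
    constant = _track([("2L", 0, 1000, 7.5)])
    vals = project_covariate(constant, [("2L", 10, 20), ("2L", 500, 900)])
    assert vals == [7.5, 7.5]
    # no overlap -> missing
    assert project_covariate(track, [("X", 0, 100)]) == [None]


def test_projection_brute_force(rng):
    track_ivs = []
    pos = 0
    values = {}
    while pos < 50_000:
        end = pos + int(rng.integers(50, 400))
        v = float(np.round(rng.uniform(0, 10), 6))
        track_ivs.append(("2L", pos, min(end, 50_000), v))
        values[(pos, min(end, 50_000))] = v
        pos = end
    track = _track(track_ivs)
    per_bp = np.empty(50_000)
    for (s, e), v in values.items():
        per_bp[s:e] = v
    windows = []
    for _ in range(1000):
        s = int(rng.integers(0, 49_000))
        windows.append(("2L", s, s + int(rng.integers(10, 900))))
    got = project_covariate(track, windows)
    for (contig, s, e), g in zip(windows, got):
        expected = per_bp[s : min(e, 50_000)].mean()
        assert g == pytest.approx(expected, rel=1e-12)
        assert min(v for v in values.values()) <= g <= max(values.values())


def test_annotate_windows_assignment_and_exclusion(default_experiment):
    exp = default_experiment
    events = [
        e for e in m.run_pipeline(
            exp.records, exp.sv_records, exp.te_calls, exp.line_meta
        ).events
    ]
    included, excluded = m.annotate_windows(
        exp.window_track, exp.mask, exp.recomb_track, exp.timing_track,
        events=events, n_lines=len(exp.line_ids),
    )
    assert all(w.callable_sites > 0 for w in included)
    for w, reason in excluded:
        assert reason in ("missing_recombination", "missing_timing", "zero_callable")
    # every event start falls in exactly the window containing it
    total = sum(w.counts.get("point", 0) for w in included) + sum(
        w.counts.get("SV", 0) for w in included
    )
    assignable = 0
    all_windows = included + [w for w, _ in excluded]
    for e in events:
        p0 = e.start - 1
        n_hit = sum(
            1 for w in all_windows
            if w.contig == e.contig and w.start <= p0 < w.end
        )
        assert n_hit == 1
        assignable += sum(
            1 for w in included if w.contig == e.contig and w.start <= p0 < w.end
        )
    assert total == assignable


def test_window_boundary_assignment():
    windows = m.IntervalTrack(
        [m.Interval("2L", 0, 100, "BK"), m.Interval("2L", 100, 200, "RE")]
    )
    mask = m.CallableMask({"2L": np.ones(200, dtype=bool)})
    recomb = _track([("2L", 0, 200, 2.0)])
    timing = _track([("2L", 0, 200, 0.5)])
    from malines.calling import EventCategory, MutationEvent

    event = MutationEvent("L1", EventCategory.SNV, "2L", start=101, end=101)
    included, _ = m.annotate_windows(windows, mask, recomb, timing, [event], n_lines=1)
    by_start = {w.start: w.counts.get("point", 0) for w in included}
    # 1-based 101 is 0-based 100: second window
    assert by_start == {0: 0, 100: 1}


def test_scale_covariates():
    assert m.scale_covariates([1, 2, 3]).tolist() == [0.5, 1.0, 1.5]
    assert m.scale_covariates([4, 4, 4]).tolist() == [1.0, 1.0, 1.0]
    z = m.scale_covariates([1, 2, 3], mode="z_score")
    assert z.mean() == pytest.approx(0.0)


def test_nb_intercept_only_equals_log_mean(rng):
    y = rng.poisson(4.0, size=500)
    X = pd.DataFrame({"const": np.ones(y.size)})
    fit = m.fit_nb(y, X)
    assert fit.coef["const"] == pytest.approx(np.log(y.mean()), abs=1e-6)


def test_nb_large_theta_matches_poisson(rng):
    y = rng.poisson(3.0, size=400)
    X = pd.DataFrame({"const": np.ones(y.size), "x": rng.normal(size=y.size)})
    nb = m.fit_nb(y, X, theta=1e8)
    pois = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
    assert nb.coef["const"] == pytest.approx(pois.params[0], abs=1e-6)
    assert nb.coef["x"] == pytest.approx(pois.params[1], abs=1e-6)


def test_offset_shift_invariance(rng):
    """Scaling all powers by c shifts only the intercept, by -log c."""
    x = rng.normal(size=600)
    power = rng.uniform(1e4, 2e5, size=600)
    mu = power * np.exp(-9.0 + 0.3 * x)
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    X = pd.DataFrame({"const": np.ones(600), "x": x})
    fit1 = m.fit_nb(y, X, offset=np.log(power), theta=2.0)
    fit2 = m.fit_nb(y, X, offset=np.log(10.0 * power), theta=2.0)
    assert fit2.coef["x"] == pytest.approx(fit1.coef["x"], abs=1e-8)
    assert fit2.coef["const"] == pytest.approx(fit1.coef["const"] - np.log(10.0), abs=1e-8)


def test_duplicated_data_same_coefficients(rng):
    x = rng.normal(size=300)
    mu = np.exp(1.0 + 0.4 * x)
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    X = pd.DataFrame({"const": np.ones(300), "x": x})
    fit1 = m.fit_nb(y, X)
    X2 = pd.concat([X, X], ignore_index=True)
    fit2 = m.fit_nb(np.r_[y, y], X2)
    assert fit2.coef["x"] == pytest.approx(fit1.coef["x"], abs=1e-4)
    assert fit2.coef["const"] == pytest.approx(fit1.coef["const"], abs=1e-4)


def test_lrt_identical_fits():
    class Fake:
        param_names = ["const", "x"]
        loglik = -120.0

    res = likelihood_ratio_test(Fake(), Fake())
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_fit_nb_against_r_glm_nb(tmp_path, rng):
    """Cross-check the NB2 MLE against R's MASS::glm.nb on one dataset."""
    x = rng.normal(size=250)
    mu = np.exp(1.2 - 0.5 * x)
    y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu))
    df = pd.DataFrame({"y": y, "x": x})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(MASS))
            d <- read.csv("{csv}")
            f <- glm.nb(y ~ x, data = d)
            cat(coef(f)[1], coef(f)[2], f$theta, sep = "\\n")
            """
        )
    )
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        timeout=300,
    )
    if proc.returncode != 0:
        pytest.skip(f"Rscript unavailable: {proc.stderr[:200]}")
    r_const, r_x, r_theta = (float(v) for v in proc.stdout.strip().split("\n"))
    X = pd.DataFrame({"const": np.ones(y.size), "x": x})
    fit = m.fit_nb(y, X)
    assert fit.coef["const"] == pytest.approx(r_const, abs=2e-4)
    assert fit.coef["x"] == pytest.approx(r_x, abs=2e-4)
    assert fit.theta == pytest.approx(r_theta, rel=5e-3)


def _window_frame(rng, n=400):
    power = rng.uniform(5e4, 2e5, size=n)
    df = pd.DataFrame(
        {
            "state": rng.choice(["BK", "RE", "YE", "BL", "GR"], size=n,
                                p=[0.5, 0.12, 0.15, 0.12, 0.11]),
            "recomb": rng.lognormal(np.log(2), 0.6, size=n),
            "timing": rng.uniform(-1, 1, size=n),
            "gc_content": rng.normal(0.43, 0.05, size=n).clip(0.2, 0.7),
            "power": power,
        }
    )
    return df


def test_treatment_interaction_null_and_recovery(rng):
    df = _window_frame(rng, n=400)
    counts, _ = simulate_window_counts(
        df, {"const": -11.0, "gc_content": -0.3, "recomb": 0.2}, theta=2.0,
        rng=rng, sigma=0.3,
    )
    for col, v in counts.items():
        df[col] = v
    # identical counts in both treatments: interactions ~ 0, LRT p ~ 1
    df2 = df.copy()
    df2["point_dsb_plus"] = df["point"]
    df2["point_dsb_minus"] = df["point"]
    out = m.fit_treatment_interaction(df2, interactions=["recomb"], n_quad=9)
    assert abs(out["full"].coef["treatment:recomb"]) < 0.02
    assert out["lrt"].p_value > 0.5

    # a planted interaction is detected with the right sign
    counts, _ = simulate_window_counts(
        df, {"const": -11.0, "gc_content": -0.3, "recomb": 0.2}, theta=2.0,
        rng=np.random.default_rng(42), sigma=0.3,
        treatment_interaction={"recomb": 0.4},
    )
    df3 = df.copy()
    df3["point_dsb_plus"] = counts["point_dsb_plus"]
    df3["point_dsb_minus"] = counts["point_dsb_minus"]
    out = m.fit_treatment_interaction(df3, interactions=["recomb"], n_quad=9)
    est = out["full"].coef["treatment:recomb"]
    se = out["full"].coef_se["treatment:recomb"]
    assert est > 0
    assert abs(est - 0.4) < 2.5 * se
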