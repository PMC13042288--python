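"""Covariate-annotated genomic windows and negative-binomial regressions.

Windows are chromatin-state-defined intervals.  Continuous covariate tracks
(crossover recombination rate, replication timing) are projected onto them by
overlap-weighted averaging; callable-site and G/C counts come from the
callable mask; each mutation or TE event is assigned to the window containing
its start position.  Windows missing recombination or timing data, or with
zero callable sites, are excluded (and logged).

The fixed-effect regression is an nbinom2 (variance ``mu + mu^2/theta``)
negative-binomial fit with *power* (callable sites x lines) entering either
as a log offset (default: exposure model) or as a linear predictor.  The
treatment-interaction model stacks the two treatment counts per window and
adds a per-window random intercept (see :mod:`malines.nbglmm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .calling import EventCategory, MutationEvent
from .callable_sites import CallableMask
from .nbglmm import NBMixedResult, fit_nb_glmm
from .records import IntervalTrack, LineMeta
from .stats_tests import TestResult
from .te import TEEvent

CHROMATIN_STATES = ("RE", "YE", "BL", "GR", "BK")
BASELINE_STATE = "BK"  # the large repressed class is the reference level
POINT_CATEGORIES = (
    EventCategory.SNV,
    EventCategory.INDEL,
    EventCategory.MNV,
    EventCategory.COMPLEX,
)


@dataclass
class GenomicWindow:
    contig: str
    start: int  # 0-based half-open
    end: int
    chromatin_state: str
    recombination_rate: float | None = None
    replication_timing: float | None = None
    callable_sites: int = 0
    gc_sites: int = 0
    power: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class NBRegressionFit:
    param_names: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    theta: float
    loglik: float
    converged: bool
    n_obs: int
    offset_spec: str
    options: dict = field(default_factory=dict)


def project_covariate(
    track: IntervalTrack, windows: Sequence[tuple[str, int, int]]
) -> list[float | None]:
    """Overlap-weighted average track value per window.

    ``windows`` are (contig, start, end) half-open triples.  A window with no
    overlapping track interval gets ``None`` (missing).
    """
    by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig in track.contigs:
        ivs = track.on(contig)
        by_contig[contig] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            np.array([float(iv.value) for iv in ivs]),
        )
    out: list[float | None] = []
    for contig, w_start, w_end in windows:
        if contig not in by_contig:
            out.append(None)
            continue
        starts, ends, values = by_contig[contig]
        overlap = np.minimum(ends, w_end) - np.maximum(starts, w_start)
        overlap = np.clip(overlap, 0, None)
        total = overlap.sum()
        if total == 0:
            out.append(None)
        else:
            out.append(float((overlap * values).sum() / total))
    return out


def annotate_windows(
    window_track: IntervalTrack,
    mask: CallableMask,
    recomb_track: IntervalTrack,
    timing_track: IntervalTrack,
    events: Iterable[MutationEvent] = (),
    te_events: Iterable[TEEvent] = (),
    line_meta: dict[str, LineMeta] | None = None,
    n_lines: int | None = None,
) -> tuple[list[GenomicWindow], list[tuple[GenomicWindow, str]]]:
    """Build the annotated window table and apply the exclusion rules.

    ``window_track`` carries the chromatin-state label as its value.  Counts
    recorded per window: each point-mutation category, ``point`` (their sum),
    ``TE``, and — when ``line_meta`` is given — ``point_dsb_plus`` /
    ``point_dsb_minus`` and ``TE_dsb_plus`` / ``TE_dsb_minus``.

    Returns ``(included, excluded)`` where each exclusion carries its reason
    (``missing_recombination``, ``missing_timing`` or ``zero_callable``).
    """
    if n_lines is None:
        n_lines = len(line_meta) if line_meta else 0
    triples = [(iv.contig, iv.start, iv.end) for iv in window_track]
    recomb = project_covariate(recomb_track, triples)
    timing = project_covariate(timing_track, triples)
    windows: list[GenomicWindow] = []
    for iv, r, t in zip(window_track, recomb, timing):
        callable_n = (
            mask.count_callable(iv.contig, iv.start, iv.end)
            if iv.contig in mask.callable_by_contig
            else 0
        )
        gc_n = (
            mask.count_gc(iv.contig, iv.start, iv.end)
            if iv.contig in mask.callable_by_contig
            else 0
        )
        windows.append(
            GenomicWindow(
                contig=iv.contig,
                start=iv.start,
                end=iv.end,
                chromatin_state=str(iv.value),
                recombination_rate=r,
                replication_timing=t,
                callable_sites=callable_n,
                gc_sites=gc_n,
                power=float(callable_n * n_lines),
                counts={},
            )
        )

    index: dict[str, list[tuple[int, int, GenomicWindow]]] = {}
    for w in windows:
        index.setdefault(w.contig, []).append((w.start, w.end, w))

    def bump(contig: str, pos_1based: int, keys: list[str]) -> None:
        start0 = pos_1based - 1
        for w_start, w_end, w in index.get(contig, []):
            if w_start <= start0 < w_end:
                for key in keys:
                    w.counts[key] = w.counts.get(key, 0) + 1
                return

    for event in events:
        keys = [event.category.value]
        if event.category in POINT_CATEGORIES:
            keys.append("point")
            if line_meta is not None:
                keys.append(f"point_{line_meta[event.line_id].treatment}")
        bump(event.contig, event.start, keys)
    for te in te_events:
        keys = ["TE"]
        if line_meta is not None and len(te.carrier_lines) == 1:
            (line,) = te.carrier_lines
            keys.append(f"TE_{line_meta[line].treatment}")
        bump(te.contig, te.breakpoint, keys)

    included, excluded = [], []
    for w in windows:
        if w.recombination_rate is None:
            excluded.append((w, "missing_recombination"))
        elif w.replication_timing is None:
            excluded.append((w, "missing_timing"))
        elif w.callable_sites == 0:
            excluded.append((w, "zero_callable"))
        else:
            included.append(w)
    return included, excluded


def windows_to_frame(windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {
            "contig": w.contig,
            "start": w.start,
            "end": w.end,
            "state": w.chromatin_state,
            "recomb": w.recombination_rate,
            "timing": w.replication_timing,
            "callable": w.callable_sites,
            "gc": w.gc_sites,
            "gc_content": w.gc_sites / w.callable_sites if w.callable_sites else np.nan,
            "power": w.power,
        }
        row.update(w.counts)
        rows.append(row)
    return pd.DataFrame(rows).fillna({c: 0 for c in ("point", "TE")})


def scale_covariates(values, mode: str = "divide_by_mean") -> np.ndarray:
    """Scale a covariate; ``divide_by_mean`` (default) or ``z_score``."""
    values = np.asarray(values, dtype=float)
    if mode == "divide_by_mean":
        mean = values.mean()
        if mean == 0:
            raise ValueError("cannot mean-scale a zero-mean covariate")
        return values / mean
    if mode == "z_score":
        sd = values.std(ddof=0)
        return (values - values.mean()) / (sd if sd else 1.0)
    raise ValueError(f"unknown scaling mode {mode!r}")


def build_design(
    df: pd.DataFrame,
    count_col: str = "point",
    power: str = "offset",
    covariates: Sequence[str] = ("gc_content", "recomb", "timing"),
    scale: dict[str, str] | None = None,
    states: Sequence[str] = CHROMATIN_STATES,
    baseline_state: str = BASELINE_STATE,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray | None]:
    """Response, design matrix and offset for the window regression.

    G/C content and recombination are mean-scaled by default (as recorded in
    ``scale``); chromatin state enters as indicators against
    ``baseline_state``; power enters as ``log`` offset or as a linearly
    scaled predictor.
    """
    scale = scale or {"gc_content": "divide_by_mean", "recomb": "divide_by_mean"}
    y = df[count_col].fillna(0).to_numpy(dtype=float)
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for cov in covariates:
        vals = df[cov].to_numpy(dtype=float)
        if cov in scale:
            vals = scale_covariates(vals, scale[cov])
        X[cov] = vals
    for state in states:
        if state != baseline_state and (df["state"] == state).any():
            X[f"state_{state}"] = (df["state"] == state).astype(float)
    offset = None
    if power == "offset":
        offset = np.log(df["power"].to_numpy(dtype=float))
    elif power == "predictor":
        X["power"] = scale_covariates(df["power"].to_numpy(dtype=float))
    elif power != "none":
        raise ValueError(f"unknown power handling {power!r}")
    return y, X, offset


def fit_nb(
    counts,
    design: pd.DataFrame,
    offset=None,
    theta: float | None = None,
) -> NBRegressionFit:
    """Maximum-likelihood nbinom2 regression (log link).

    Dispersion ``theta`` is estimated jointly by default (statsmodels NB2
    MLE, Poisson-initialized); passing ``theta`` fixes it and fits a GLM
    with the corresponding negative-binomial family instead.
    """
    y = np.asarray(counts, dtype=float)
    if y.size < 10:
        raise ValueError("need >= 10 windows")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X = np.asarray(design, dtype=float)
    names = list(design.columns)
    if theta is not None:
        family = sm.families.NegativeBinomial(alpha=1.0 / theta)
        res = sm.GLM(y, X, family=family, offset=offset).fit()
        coef = dict(zip(names, res.params))
        se = dict(zip(names, res.bse))
        converged = bool(res.converged)
        loglik = float(res.llf)
        theta_hat = theta
        options = {"fixed_theta": theta}
    else:
        poisson = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        start = np.append(poisson.params, 0.5)  # alpha start
        model = sm.NegativeBinomial(y, X, loglike_method="nb2", offset=offset)
        res = model.fit(
            start_params=start, method="bfgs", maxiter=200, disp=0, gtol=1e-7
        )
        coef = dict(zip(names, res.params[:-1]))
        se = dict(zip(names, res.bse[:-1]))
        alpha = float(res.params[-1])
        theta_hat = 1.0 / alpha if alpha > 0 else float("inf")
        converged = bool(res.mle_retvals.get("converged", False))
        loglik = float(res.llf)
        options = {"alpha": alpha}
    z = {k: coef[k] / se[k] if se[k] else np.nan for k in coef}
    p = {k: float(2 * stats.norm.sf(abs(v))) for k, v in z.items()}
    return NBRegressionFit(
        param_names=names,
        coef=coef,
        se=se,
        z=z,
        p=p,
        theta=float(theta_hat),
        loglik=loglik,
        converged=converged,
        n_obs=int(y.size),
        offset_spec="log_power" if offset is not None else "none",
        options=options,
    )


def likelihood_ratio_test(full, reduced) -> TestResult:
    """Chi-square LRT of nested fits (works for fixed and mixed fits)."""
    df_full = len(full.param_names)
    df_reduced = len(reduced.param_names)
    df = df_full - df_reduced
    if df < 0:
        raise ValueError("reduced model must not have more parameters than full")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 and stat > 0 else 1.0
    return TestResult("likelihood_ratio", float(stat), p, 1, options={"df": df})


def fit_treatment_interaction(
    df: pd.DataFrame,
    count_cols: tuple[str, str] = ("point_dsb_plus", "point_dsb_minus"),
    covariates: Sequence[str] = ("gc_content", "recomb", "timing"),
    interactions: Sequence[str] | None = None,
    power: str = "offset",
    power_split: tuple[float, float] = (0.5, 0.5),
    n_quad: int = 15,
    drop: str = "joint",
) -> dict:
    """Treatment-interaction NB GLMM on stacked per-treatment window counts.

    The window table is duplicated (one row per treatment), treatment enters
    as a main effect plus interactions with ``interactions`` (default: all of
    ``covariates`` and the chromatin-state indicators), and window identity
    is a random intercept.  ``power_split`` apportions each window's power to
    the two treatments (fraction of lines per group).  Returns the full fit,
    the no-interaction reduced fit, and their LRT (``drop="joint"``) or
    one-at-a-time LRTs (``drop="each"``).
    """
    y1 = df[count_cols[0]].fillna(0).to_numpy(dtype=float)
    y2 = df[count_cols[1]].fillna(0).to_numpy(dtype=float)
    n = len(df)
    _, x_base, _ = build_design(df, count_col=count_cols[0], power="none", covariates=covariates)
    base_names = [c for c in x_base.columns if c != "const"]
    if interactions is None:
        interactions = base_names
    x0 = x_base.to_numpy(dtype=float)
    treatment = np.r_[np.zeros(n), np.ones(n)]  # 1 = second count column
    stacked = np.vstack([x0, x0])
    names = list(x_base.columns) + ["treatment"]
    cols = [stacked, treatment[:, None]]
    inter_names = []
    for name in interactions:
        j = list(x_base.columns).index(name)
        cols.append((stacked[:, j] * treatment)[:, None])
        inter_names.append(f"treatment:{name}")
    X_full = np.hstack(cols)
    names_full = names + inter_names
    X_reduced = np.hstack(cols[:2])
    offset = None
    offset_spec = "none"
    if power == "offset":
        p1 = np.log(df["power"].to_numpy(dtype=float) * power_split[0])
        p2 = np.log(df["power"].to_numpy(dtype=float) * power_split[1])
        offset = np.r_[p1, p2]
        offset_spec = "log_power"
    y = np.r_[y1, y2]
    groups = np.r_[np.arange(n), np.arange(n)]
    full = fit_nb_glmm(
        y, X_full, groups, names_full, offset=offset, n_quad=n_quad,
        offset_spec=offset_spec,
    )
    reduced = fit_nb_glmm(
        y, X_reduced, groups, names, offset=offset, n_quad=n_quad,
        offset_spec=offset_spec, start=np.r_[full.params[: len(names)], full.params[-2:]],
    )
    out = {"full": full, "reduced": reduced}
    if drop == "joint":
        out["lrt"] = likelihood_ratio_test(full, reduced)
    elif drop == "each":
        lrts = {}
        for name in inter_names:
            keep = [i for i, nm in enumerate(names_full) if nm != name]
            sub = fit_nb_glmm(
                y, X_full[:, keep], groups, [names_full[i] for i in keep],
                offset=offset, n_quad=n_quad, offset_spec=offset_spec,
            )
            lrts[name] = likelihood_ratio_test(full, sub)
        out["lrt"] = lrts
    else:
        raise ValueError(f"unknown drop mode {drop!r}")
    return out
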