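"""Mutation-rate estimation and the headline comparison statistics.

Rates are ratios of totals: events summed over lines divided by the summed
opportunity.  For per-site scopes the opportunity of a line is its callable
sites times its adjusted generation count; for per-genome scopes (TE
insertions/excisions) it is the nominal generation count.  Confidence
intervals come from a seeded percentile bootstrap over lines, the natural
resampling unit of an MA panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateEstimate",
    "TractFoldParams",
    "estimate_rate",
    "group_difference_percent",
    "relative_increase_percent",
    "tract_fold_excess",
]


@dataclass
class RateEstimate:
    mutation_type: str
    scope: str  # "per_site_per_generation" | "per_genome_per_generation"
    point: float
    ci_lower: float
    ci_upper: float
    event_count: int
    opportunity: float
    ci_method: str

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.point <= self.ci_upper):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class TractFoldParams:
    """Inputs to the repair-tract fold-excess model.

    ``n_dsb_per_generation`` programmed meiotic DSBs per genome per
    generation, ``tract_length_bp`` synthesis per repair tract, and the
    genome size over which the per-site rates were measured (callable-site
    total).
    """

    n_dsb_per_generation: float = 24.0
    tract_length_bp: float = 5000.0
    genome_sites: float = 99_458_130.0

    def __post_init__(self) -> None:
        if min(self.n_dsb_per_generation, self.tract_length_bp, self.genome_sites) <= 0:
            raise ValueError("all tract-model parameters must be positive")


def estimate_rate(
    per_line_counts: dict[str, int],
    per_line_opportunity: dict[str, float],
    mutation_type: str = "",
    scope: str = "per_site_per_generation",
    n_boot: int = 10_000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> RateEstimate:
    """Pooled rate with a 95% CI.

    ``ci_method="bootstrap"`` resamples lines with replacement (percentile
    interval, deterministic given ``seed``); ``"poisson"`` uses the exact
    chi-square interval for the total count.  With zero events the point is
    0 and the interval one-sided (lower bound 0, Poisson-exact upper).
    """
    lines = sorted(per_line_counts)
    if set(lines) != set(per_line_opportunity):
        raise ValueError("counts and opportunities must cover the same lines")
    counts = np.array([per_line_counts[l] for l in lines], dtype=float)
    opps = np.array([per_line_opportunity[l] for l in lines], dtype=float)
    total_opp = float(opps.sum())
    if total_opp <= 0 or (opps <= 0).any():
        raise ValueError("opportunity must be positive for every line")
    total = float(counts.sum())
    point = total / total_opp

    if total == 0:
        upper = stats.chi2.ppf(0.975, 2) / 2 / total_opp
        return RateEstimate(
            mutation_type, scope, 0.0, 0.0, float(upper), 0, total_opp, "poisson_upper"
        )
    if ci_method == "poisson":
        lo = stats.chi2.ppf(0.025, 2 * total) / 2 / total_opp
        hi = stats.chi2.ppf(0.975, 2 * (total + 1)) / 2 / total_opp
        return RateEstimate(
            mutation_type, scope, point, float(lo), float(hi), int(total), total_opp, "poisson"
        )
    if ci_method != "bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(lines), size=(n_boot, len(lines)))
    boot = counts[idx].sum(axis=1) / opps[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    # percentile intervals can exclude the pooled point in tiny panels;
    # clamp so the bracket invariant holds
    lo, hi = min(lo, point), max(hi, point)
    return RateEstimate(
        mutation_type, scope, point, float(lo), float(hi), int(total), total_opp,
        f"bootstrap_percentile(n={n_boot},seed={seed})",
    )


def per_site_opportunity(
    callable_sites: dict[str, float], adjusted_generations: dict[str, float]
) -> dict[str, float]:
    return {
        line: callable_sites[line] * adjusted_generations[line]
        for line in callable_sites
    }


def group_difference_percent(rate_a: float, rate_b: float) -> float | None:
    """Absolute group difference as a percent of the group mean, 2 decimals.

    Returns ``None`` (missing) when both rates are zero.
    """
    if rate_a == 0 and rate_b == 0:
        return None
    return round(100.0 * abs(rate_a - rate_b) / ((rate_a + rate_b) / 2.0), 2)


def relative_increase_percent(rate_ref: float, rate_alt: float) -> float:
    """Percent change of ``rate_alt`` relative to ``rate_ref`` (signed)."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (rate_alt - rate_ref) / rate_ref


def tract_fold_excess(
    rate_plus: float, rate_minus: float, params: TractFoldParams = TractFoldParams()
) -> float:
    """Fold elevation of the mutation rate inside DSB repair tracts.

    Model: the whole per-site rate excess of the DSB-forming group is
    confined to ``n_dsb * tract_length`` bp of repair synthesis per genome
    per generation, on top of the background rate of the DSB-free group::

        fold = 1 + (r+ - r-) * G / (n_dsb * L * r-)
    """
    if rate_minus <= 0:
        raise ValueError("background rate must be positive")
    if rate_plus < rate_minus:
        raise ValueError("model undefined when the DSB group rate is lower")
    excess = (rate_plus - rate_minus) * params.genome_sites
    tract_bp = params.n_dsb_per_generation * params.tract_length_bp
    return 1.0 + excess / (tract_bp * rate_minus)
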