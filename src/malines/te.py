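"""Transposable-element event reconciliation, rates and tests.

Raw TE calls from different lines frequently report slightly different
breakpoints for one underlying insertion, so calls of the same family, contig
and event type are merged by single-linkage chaining of sorted breakpoints
with gap <= the merge window (inclusive).  An event carried by exactly one
line is interpreted as de novo; multi-line events are logged as segregating
or recurrent and excluded from rate estimation.

An apparent excision cannot be distinguished from a deletion spanning the
reference TE copy; events carry that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .rates import RateEstimate, estimate_rate
from .records import LineMeta, TECall, TEEventType
from .stats_tests import TestResult

EXCISION_CAVEAT = (
    "apparent excision; indistinguishable from a deletion removing the TE"
)


@dataclass
class TEEvent:
    family: str
    contig: str
    breakpoint: int  # lower median of member breakpoints, 1-based
    event_type: TEEventType
    carrier_lines: frozenset[str]
    members: list[TECall] = field(default_factory=list)
    caveat: str | None = None

    @property
    def is_de_novo(self) -> bool:
        return len(self.carrier_lines) == 1


def merge_te_calls(
    calls: Iterable[TECall], te_merge_bp: int = 50
) -> list[TEEvent]:
    """Merge calls into events; order-invariant and idempotent.

    Chains are per (family, contig, event_type); a call joins the current
    chain when its breakpoint is within ``te_merge_bp`` (inclusive) of the
    previous member's.
    """
    groups: dict[tuple[str, str, TEEventType], list[TECall]] = {}
    for call in calls:
        groups.setdefault((call.family, call.contig, call.event_type), []).append(call)
    events: list[TEEvent] = []
    for (family, contig, etype) in sorted(groups, key=lambda k: (k[0], k[1], k[2].value)):
        members = sorted(
            groups[(family, contig, etype)], key=lambda c: (c.breakpoint, c.line_id)
        )
        chain: list[TECall] = []
        for call in members:
            if chain and call.breakpoint - chain[-1].breakpoint > te_merge_bp:
                events.append(_chain_to_event(family, contig, etype, chain))
                chain = []
            chain.append(call)
        if chain:
            events.append(_chain_to_event(family, contig, etype, chain))
    return events


def _chain_to_event(
    family: str, contig: str, etype: TEEventType, chain: list[TECall]
) -> TEEvent:
    breakpoints = sorted(c.breakpoint for c in chain)
    representative = breakpoints[(len(breakpoints) - 1) // 2]  # lower median
    return TEEvent(
        family=family,
        contig=contig,
        breakpoint=representative,
        event_type=etype,
        carrier_lines=frozenset(c.line_id for c in chain),
        members=list(chain),
        caveat=EXCISION_CAVEAT if etype is TEEventType.EXCISION else None,
    )


def select_de_novo(
    events: Iterable[TEEvent],
) -> tuple[list[TEEvent], list[tuple[TEEvent, str]]]:
    """Keep single-carrier events; log the rest as segregating/recurrent."""
    de_novo, excluded = [], []
    for event in events:
        if event.is_de_novo:
            de_novo.append(event)
        else:
            excluded.append((event, "segregating_or_recurrent"))
    return de_novo, excluded


def te_rates(
    events: Sequence[TEEvent],
    line_meta: dict[str, LineMeta],
    by: str = "event_type",
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, RateEstimate]:
    """Per-genome-per-generation rates over the panel's nominal generations.

    ``by``: ``"overall"``, ``"event_type"``, ``"family"`` or ``"group"``
    (treatment groups, insertions only by convention handled by the caller
    via pre-filtering).  The denominator of a stratum is the summed nominal
    generation count of the lines it covers.
    """
    def strata(event: TEEvent) -> str:
        if by == "overall":
            return "all"
        if by == "event_type":
            return event.event_type.value
        if by == "family":
            return event.family
        if by == "group":
            (line,) = event.carrier_lines
            return line_meta[line].treatment
        raise ValueError(f"unknown stratification {by!r}")

    def lines_of(stratum: str) -> list[str]:
        if by == "group":
            return [l for l, m in line_meta.items() if m.treatment == stratum]
        return list(line_meta)

    keys = sorted({strata(e) for e in events})
    if by == "event_type":
        keys = sorted(set(keys) | {t.value for t in TEEventType})
    out = {}
    for key in keys:
        lines = lines_of(key)
        counts = {line: 0 for line in lines}
        for event in events:
            if strata(event) != key:
                continue
            (line,) = event.carrier_lines
            if line in counts:
                counts[line] += 1
        opportunity = {l: float(line_meta[l].generations) for l in lines}
        out[key] = estimate_rate(
            counts, opportunity, mutation_type=f"TE:{key}",
            scope="per_genome_per_generation", n_boot=n_boot, seed=seed,
        )
    return out


def per_line_family_counts(
    events: Sequence[TEEvent], line_ids: Sequence[str]
) -> dict[str, dict[str, int]]:
    """line_id -> family -> de novo event count (insertions and excisions as
    passed; filter beforehand to restrict)."""
    out: dict[str, dict[str, int]] = {line: {} for line in line_ids}
    for event in events:
        (line,) = event.carrier_lines
        fam = out.setdefault(line, {})
        fam[event.family] = fam.get(event.family, 0) + 1
    return out


def _poisson_chi2(counts: np.ndarray) -> tuple[float, int]:
    """Chi-square of the per-line count distribution vs Poisson(mean).

    Bins 0..K with the upper tail pooled at K = max(count); expected bin
    masses come from the Poisson pmf at the sample mean.
    """
    lam = counts.mean()
    k_max = int(counts.max())
    observed = np.bincount(counts, minlength=k_max + 1).astype(float)
    pmf = stats.poisson.pmf(np.arange(k_max + 1), lam)
    pmf[-1] += stats.poisson.sf(k_max, lam)
    expected = pmf * counts.size
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    return float(np.nansum(terms[expected > 0])), k_max


def family_activity_tests(
    counts_by_line: dict[str, dict[str, int]],
    n_sims: int = 10_000,
    seed: int = 0,
    top_k: int = 5,
) -> dict:
    """Tests of independent mobilization across TE families.

    1. Poisson dispersion: the number of *active families* per line (any
       count >= 1) is compared to the Poisson expectation via a chi-square
       statistic whose p-value is simulated parametrically (counts redrawn
       from Poisson at the sample mean, statistic re-computed with the
       simulated sample's own mean; add-one corrected).
    2. Pairwise Spearman correlations of per-line insertion counts for the
       ``top_k`` most active families.
    """
    lines = sorted(counts_by_line)
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    families = sorted({f for per in counts_by_line.values() for f in per})
    matrix = np.array(
        [[counts_by_line[l].get(f, 0) for f in families] for l in lines], dtype=int
    )
    active = (matrix >= 1).sum(axis=1)
    observed_stat, _ = _poisson_chi2(active)
    rng = np.random.default_rng(seed)
    lam = active.mean()
    count = 0
    for _ in range(n_sims):
        sim = rng.poisson(lam, size=active.size)
        sim_stat, _ = _poisson_chi2(sim)
        if sim_stat >= observed_stat:
            count += 1
    dispersion = TestResult(
        "poisson_dispersion_chi2", observed_stat, (count + 1) / (n_sims + 1), 2,
        (active.size,), {"n_sims": n_sims, "seed": seed, "mean": float(lam)},
    )
    totals = matrix.sum(axis=0)
    top = np.argsort(-totals, kind="stable")[: min(top_k, len(families))]
    spearman: dict[tuple[str, str], tuple[float, float]] = {}
    for i_pos, i in enumerate(top):
        for j in top[i_pos + 1 :]:
            rho, p = stats.spearmanr(matrix[:, i], matrix[:, j])
            spearman[(families[i], families[j])] = (float(rho), float(p))
    return {
        "dispersion": dispersion,
        "spearman": spearman,
        "active_families_per_line": dict(zip(lines, active.tolist())),
        "top_families": [families[i] for i in top],
    }


def x_enrichment(
    events: Sequence[TEEvent],
    contig_lengths: dict[str, int],
    x_contig: str = "X",
) -> TestResult:
    """Exact binomial test of the X-linked event fraction against the
    chromosome-size expectation."""
    n = len(events)
    if n == 0:
        raise ValueError("no events")
    k = sum(1 for e in events if e.contig == x_contig)
    p0 = contig_lengths[x_contig] / sum(contig_lengths.values())
    res = stats.binomtest(k, n, p0, alternative="two-sided")
    return TestResult(
        "x_enrichment_binomial", float(k), float(res.pvalue), 2, (n,),
        {"p_null": p0},
    )
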