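"""Mutation-spectrum statistics.

SNVs are collapsed to the six strand-symmetric classes (a C>T on either
strand is the class G:C>A:T, and so on), with Wilson score intervals on the
multinomial proportions, a bootstrap interval on Ts/Tv, binomial tests of
G/C-site origin bias against the callable-site composition, indel size and
deletion-bias summaries, and genic / nonsynonymous fractions against their
null expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .stats_tests import TestResult

#: strand-collapsed class of each (ref, alt) pair.
CLASS_OF = {
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
}
CLASSES = ("A:T>C:G", "A:T>G:C", "A:T>T:A", "G:C>A:T", "G:C>C:G", "G:C>T:A")
TRANSITION_CLASSES = frozenset({"A:T>G:C", "G:C>A:T"})
GC_ORIGIN_CLASSES = frozenset({"G:C>A:T", "G:C>C:G", "G:C>T:A"})


def classify_snv(ref: str, alt: str) -> str:
    if ref == alt:
        raise ValueError("ref and alt must differ")
    try:
        return CLASS_OF[(ref.upper(), alt.upper())]
    except KeyError as exc:
        raise ValueError(f"not a single-nucleotide change: {ref}>{alt}") from exc


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    proportions: dict[str, float]
    wilson_ci: dict[str, tuple[float, float]]
    transitions: int
    transversions: int
    ts_tv: float
    ts_tv_ci: tuple[float, float]
    gc_origin: int
    at_origin: int
    options: dict = field(default_factory=dict)


def snv_spectrum(
    ref_alt_pairs, n_boot: int = 10_000, seed: int = 0
) -> SpectrumSummary:
    """Six-class spectrum with 95% Wilson intervals and a bootstrap Ts/Tv CI.

    ``ref_alt_pairs`` is an iterable of (ref, alt) single bases; the
    bootstrap resamples mutations (events), deterministic given ``seed``.
    """
    labels = np.array([classify_snv(r, a) for r, a in ref_alt_pairs])
    n = labels.size
    if n == 0:
        raise ValueError("no SNVs")
    counts = {c: int(np.sum(labels == c)) for c in CLASSES}
    proportions = {c: counts[c] / n for c in CLASSES}
    wilson = {
        c: tuple(
            float(v)
            for v in proportion_confint(counts[c], n, alpha=0.05, method="wilson")
        )
        for c in CLASSES
    }
    is_ts = np.isin(labels, list(TRANSITION_CLASSES))
    ts, tv = int(is_ts.sum()), int(n - is_ts.sum())
    ts_tv = ts / tv if tv else float("inf")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_ts = is_ts[idx].sum(axis=1)
    with np.errstate(divide="ignore"):
        boot = boot_ts / (n - boot_ts)
    ci = tuple(float(v) for v in np.percentile(boot, [2.5, 97.5]))
    gc_origin = int(np.isin(labels, list(GC_ORIGIN_CLASSES)).sum())
    return SpectrumSummary(
        class_counts=counts,
        proportions=proportions,
        wilson_ci=wilson,
        transitions=ts,
        transversions=tv,
        ts_tv=ts_tv,
        ts_tv_ci=ci,
        gc_origin=gc_origin,
        at_origin=n - gc_origin,
        options={"n_boot": n_boot, "seed": seed},
    )


def gc_at_bias(
    ref_alt_pairs, callable_gc_fraction: float
) -> tuple[float, TestResult]:
    """Fraction of SNVs originating at G/C sites, tested against the
    callable-site G/C composition (exact two-sided binomial)."""
    if not 0.0 < callable_gc_fraction < 1.0:
        raise ValueError("callable G/C fraction must be in (0, 1)")
    labels = [classify_snv(r, a) for r, a in ref_alt_pairs]
    k = sum(1 for c in labels if c in GC_ORIGIN_CLASSES)
    n = len(labels)
    res = stats.binomtest(k, n, callable_gc_fraction, alternative="two-sided")
    return k / n, TestResult(
        "gc_at_bias_binomial", float(k), float(res.pvalue), 2, (n,),
        {"p_null": callable_gc_fraction},
    )


def indel_stats(signed_lengths) -> dict:
    """Deletion-bias binomial test and per-sign size medians.

    ``signed_lengths``: negative = deletion, positive = insertion.  Medians
    use the lower median on even counts.
    """
    lengths = np.asarray(list(signed_lengths), dtype=int)
    if (lengths == 0).any():
        raise ValueError("indel lengths must be nonzero")
    deletions = np.sort(-lengths[lengths < 0])
    insertions = np.sort(lengths[lengths > 0])
    res = stats.binomtest(
        deletions.size, lengths.size, 0.5, alternative="two-sided"
    )
    def lower_median(x):
        return int(x[(x.size - 1) // 2]) if x.size else None
    return {
        "n_deletions": int(deletions.size),
        "n_insertions": int(insertions.size),
        "deletion_bias_test": TestResult(
            "deletion_bias_binomial", float(deletions.size), float(res.pvalue),
            2, (int(lengths.size),), {"p_null": 0.5},
        ),
        "median_deletion_bp": lower_median(deletions),
        "median_insertion_bp": lower_median(insertions),
    }


def genic_fractions(
    n_genic_snv: int,
    n_snv: int,
    n_genic_indel: int,
    n_indel: int,
    genic_null: float,
    n_nonsyn: int = 0,
    n_coding_snv: int = 0,
    nonsyn_null: float = 0.744,
) -> dict:
    """Genic and nonsynonymous fractions against their null expectations.

    ``genic_null`` is the fraction of callable sites inside gene intervals
    (compute it with :func:`genic_null_fraction`); ``nonsyn_null`` defaults
    to the literature expectation for random coding changes.
    """
    out = {
        "genic_null": genic_null,
        "snv_genic_fraction": n_genic_snv / n_snv if n_snv else float("nan"),
        "indel_genic_fraction": n_genic_indel / n_indel if n_indel else float("nan"),
    }
    if n_snv:
        res = stats.binomtest(n_genic_snv, n_snv, genic_null)
        out["snv_genic_test"] = TestResult(
            "snv_genic_binomial", float(n_genic_snv), float(res.pvalue), 2,
            (n_snv,), {"p_null": genic_null},
        )
    if n_indel:
        res = stats.binomtest(n_genic_indel, n_indel, genic_null)
        out["indel_genic_test"] = TestResult(
            "indel_genic_binomial", float(n_genic_indel), float(res.pvalue), 2,
            (n_indel,), {"p_null": genic_null},
        )
    if n_coding_snv:
        res = stats.binomtest(n_nonsyn, n_coding_snv, nonsyn_null)
        out["nonsynonymous_fraction"] = n_nonsyn / n_coding_snv
        out["nonsynonymous_test"] = TestResult(
            "nonsynonymous_binomial", float(n_nonsyn), float(res.pvalue), 2,
            (n_coding_snv,), {"p_null": nonsyn_null},
        )
    return out


def genic_null_fraction(mask, gene_track) -> float:
    """Callable sites inside genes over all callable sites."""
    total = mask.callable_sites()
    if total == 0:
        raise ValueError("no callable sites")
    return mask.callable_in_track(gene_track) / total
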