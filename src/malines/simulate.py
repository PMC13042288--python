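"""Synthetic two-treatment MA experiment with planted ground truth.

The generator emulates the *final products* of an MA sequencing study — a
panel VCF, TE and SV call tables, repeat mask, gene intervals, covariate
tracks and chromatin-state windows — not reads or alignments.  Every planted
quantity is recorded in :class:`SyntheticTruth` so each downstream stage has
an oracle: true events with line/zygosity/positions, artifacts with the
filter rule they must trip, TE events with breakpoint jitter below (or, on
request, above) the merge window, and per-window negative-binomial counts
drawn from known regression coefficients.

Defaults are the study conditions: 16 + 19 lines, 30 generations, per-type
rates at the reported point estimates, a ~74% callable genome, and a mean
depth near 99.  Planted events are spaced (>= 3 kb reservation) so that
clustering and proximity exclusion act only where the truth says they
should; artifact placement deliberately violates exactly one rule each.

Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .callable_sites import CallableMask, compute_callable_mask
from .errors import ConfigurationError
from .filters import FilterThresholds
from .records import (
    Genotype,
    Interval,
    IntervalTrack,
    LineCall,
    LineMeta,
    SVRecord,
    SVType,
    TECall,
    TEEventType,
    VariantRecord,
)

SV_MAX_QUALITY = 999.0

#: margin reserved around every planted feature; exceeds the 1 kb proximity
#: radius and the 1 kb clustering gap so planted events never interact.
RESERVE_MARGIN = 3000

TE_FAMILIES = ("roo", "Doc", "S", "H", "I", "F", "Rt1a", "hobo", "jockey", "copia")
TE_FAMILY_WEIGHTS = (0.22, 0.18, 0.14, 0.12, 0.09, 0.08, 0.06, 0.05, 0.03, 0.03)

#: epsilon by which each planted artifact overshoots its threshold
ARTIFACT_MARGINS = {
    "min_alt_reads": 5,  # alt reads planted at threshold - 5
    "min_MQ": 5.0,
    "min_QD": 0.5,
    "max_FS": 10.0,
    "max_SOR": 1.0,
    "max_abs_MQRankSum": 1.0,
    "max_abs_ReadPosRankSum": 1.0,
    "depth_window": 0.5,  # planted at 2.5x the line median
}


def _default_contigs() -> dict[str, int]:
    return {c: 1_000_000 for c in ("2L", "2R", "3L", "3R", "X")}


def _default_class_probs() -> dict[str, float]:
    # G/C-origin classes sum to 0.60; transition fraction 0.53
    return {
        "A:T>C:G": 0.08,
        "A:T>G:C": 0.20,
        "A:T>T:A": 0.12,
        "G:C>A:T": 0.33,
        "G:C>C:G": 0.12,
        "G:C>T:A": 0.15,
    }


def _default_te_ins() -> dict[str, float]:
    return {"dsb_plus": 0.482, "dsb_minus": 0.681}


def _default_te_exc() -> dict[str, float]:
    return {"dsb_plus": 0.119, "dsb_minus": 0.136}


def _default_state_freqs() -> dict[str, float]:
    return {"BK": 0.50, "YE": 0.15, "RE": 0.12, "BL": 0.12, "GR": 0.11}


def _default_window_coefs() -> dict[str, float]:
    return {
        "const": -11.5,
        "gc_content": -0.3,
        "recomb": 0.2,
        "timing": -0.05,
        "state_RE": 0.3,
        "state_YE": -0.2,
        "state_BL": 0.1,
        "state_GR": 0.0,
    }


def _default_artifact_counts() -> dict[str, int]:
    return {rule: 2 for rule in ARTIFACT_MARGINS}


@dataclass
class SimulationConfig:
    """Study conditions of the simulated MA experiment (see module docs)."""

    seed: int = 0
    n_lines_per_group: tuple[int, int] = (16, 19)
    generations: int = 30
    contig_lengths: dict[str, int] = field(default_factory=_default_contigs)

    # per-site per-generation rates (point estimates of the real panel)
    snv_rate: float = 5.85e-9
    indel_rate: float = 1.71e-9
    mnv_rate: float = 5.0e-10
    complex_rate: float = 6.0e-10
    sv_rate: float = 2.2e-10
    # per-genome per-generation TE rates, by treatment group
    te_insertion_rate: dict[str, float] = field(default_factory=_default_te_ins)
    te_excision_rate: dict[str, float] = field(default_factory=_default_te_exc)

    # spectrum
    class_probs: dict[str, float] = field(default_factory=_default_class_probs)
    indel_deletion_bias: float = 0.6
    deletion_size_p: float = 0.11  # geometric; median ~6 bp
    insertion_size_p: float = 0.045  # geometric; median ~15 bp

    # zygosity
    hom_fraction_autosome: float = 0.55
    hom_fraction_x: float = 0.70

    # genome composition
    gc_fraction: float = 0.43
    repeat_fraction: float = 0.15
    fail_fraction: float = 0.11  # panel-level filter-failed fraction
    gene_fraction: float = 0.75
    block_bp: int = 2000

    # sequencing nuisance
    median_depth_mean: float = 99.0
    median_depth_sd: float = 8.0
    depth_dispersion: float = 10.0

    # artifacts
    artifact_counts_by_filter: dict[str, int] = field(
        default_factory=_default_artifact_counts
    )
    shared_artifact_count: int = 8
    uncalled_artifact_count: int = 4
    near_sv_artifact_count: int = 2
    near_te_artifact_count: int = 2
    sv_artifact_counts: dict[str, int] = field(
        default_factory=lambda: {"min_support": 2, "not_max_quality": 2, "not_unique": 2}
    )

    # TE call nuisance
    te_jitter_bp: int = 20
    te_large_jitter_frac: float = 0.0
    segregating_te_count: int = 6

    # window model
    n_windows: int = 1000
    state_freqs: dict[str, float] = field(default_factory=_default_state_freqs)
    window_coefs: dict[str, float] = field(default_factory=_default_window_coefs)
    window_theta: float = 2.0
    window_sigma: float = 0.0  # per-window random intercept SD (treatment draw)
    treatment_interaction: dict[str, float] = field(default_factory=dict)

    trisomy: tuple[str, str] | None = None  # (line_id, contig)

    def __post_init__(self) -> None:
        probs = list(self.class_probs.values()) + [
            self.indel_deletion_bias,
            self.hom_fraction_autosome,
            self.hom_fraction_x,
            self.gc_fraction,
            self.repeat_fraction,
            self.fail_fraction,
            self.gene_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("spectrum class probabilities must sum to 1")
        rates = (self.snv_rate, self.indel_rate, self.mnv_rate, self.complex_rate, self.sv_rate)
        if any(r < 0 for r in rates):
            raise ConfigurationError("rates must be non-negative")
        if self.window_theta <= 0:
            raise ConfigurationError("window_theta must be positive")
        if any(length < 10_000 for length in self.contig_lengths.values()):
            raise ConfigurationError("contig lengths must be >= 10 kb")

    @property
    def line_ids(self) -> list[str]:
        n_plus, n_minus = self.n_lines_per_group
        return [f"P{i:02d}" for i in range(1, n_plus + 1)] + [
            f"M{i:02d}" for i in range(1, n_minus + 1)
        ]

    def treatment_of(self, line_id: str) -> str:
        return "dsb_plus" if line_id.startswith("P") else "dsb_minus"


@dataclass
class PlantedEvent:
    line_id: str
    category: str  # SNV | INDEL | MNV | COMPLEX | SV
    contig: str
    positions: tuple[int, ...]  # 1-based member positions (SV: (start, end))
    zygosity: str | None = None
    ref_alts: tuple[tuple[str, str], ...] = ()
    indel_lengths: tuple[int, ...] = ()  # signed, for INDEL members


@dataclass
class PlantedTE:
    lines: tuple[str, ...]
    family: str
    contig: str
    breakpoint: int
    event_type: str
    de_novo: bool


@dataclass
class PlantedArtifact:
    kind: str  # variant | sv
    contig: str
    position: int
    expected_reason: str
    line_id: str | None = None


@dataclass
class SyntheticTruth:
    seed: int
    events: list[PlantedEvent] = field(default_factory=list)
    te_events: list[PlantedTE] = field(default_factory=list)
    artifacts: list[PlantedArtifact] = field(default_factory=list)
    callable_sites: int = 0
    callable_gc_sites: int = 0
    rates: dict[str, float] = field(default_factory=dict)
    window_coefs: dict[str, float] = field(default_factory=dict)
    window_theta: float = 0.0
    window_expected: list[float] = field(default_factory=list)


class _Reserver:
    """Per-contig reservation list preventing planted features interacting."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def free(self, contig: str, start: int, end: int, margin: int = RESERVE_MARGIN) -> bool:
        starts = self._starts.get(contig, [])
        ends = self._ends.get(contig, [])
        i = bisect.bisect_left(starts, start - margin)
        if i > 0 and ends[i - 1] > start - margin:
            return False
        j = i
        while j < len(starts) and starts[j] < end + margin:
            if ends[j] > start - margin:
                return False
            j += 1
        return True

    def reserve(self, contig: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(contig, [])
        ends = self._ends.setdefault(contig, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


@dataclass
class Experiment:
    """Everything one synthetic run produces, in memory."""

    config: SimulationConfig
    line_meta: dict[str, LineMeta]
    records: list[VariantRecord]
    te_calls: list[TECall]
    sv_records: list[SVRecord]
    repeat_mask: IntervalTrack
    gene_track: IntervalTrack
    recomb_track: IntervalTrack
    timing_track: IntervalTrack
    window_track: IntervalTrack
    per_line_fail_tracks: dict[str, IntervalTrack]
    gc_by_contig: dict[str, np.ndarray]
    mask: CallableMask
    window_table: pd.DataFrame
    truth: SyntheticTruth

    @property
    def line_ids(self) -> list[str]:
        return self.config.line_ids

    def write(self, out_dir: str | Path) -> None:
        """Emit the experiment as the pipeline's standard file formats."""
        from .intervals import write_intervals
        from .tables import write_line_meta, write_sv_table, write_te_calls
        from .vcf_io import write_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(self.records, out / "panel.vcf", self.line_ids, self.config.contig_lengths)
        write_te_calls(self.te_calls, out / "te.tsv")
        write_sv_table(self.sv_records, out / "sv.tsv", self.line_ids)
        write_intervals(self.repeat_mask, out / "repeats.bed")
        write_intervals(self.gene_track, out / "genes.bed")
        write_intervals(self.recomb_track, out / "recomb.bed")
        write_intervals(self.timing_track, out / "timing.bed")
        write_intervals(self.window_track, out / "windows.bed")
        write_line_meta(self.line_meta, out / "lines.tsv", out / "depths.tsv")
        fail_dir = out / "fail_tracks"
        fail_dir.mkdir(exist_ok=True)
        for line_id, track in self.per_line_fail_tracks.items():
            write_intervals(track, fail_dir / f"{line_id}.bed")
        with open(out / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=1, default=_jsonify)
        self.window_table.to_csv(out / "window_table.tsv", sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# --- genome scaffolding -----------------------------------------------------


def _block_tracks(cfg: SimulationConfig, rng: np.random.Generator):
    """Repeat mask, per-line fail tracks, gene track from random 2 kb blocks."""
    repeat = IntervalTrack()
    genes = IntervalTrack()
    fail_tracks: dict[str, IntervalTrack] = {l: IntervalTrack() for l in cfg.line_ids}
    lines = cfg.line_ids
    for contig, length in cfg.contig_lengths.items():
        n_blocks = length // cfg.block_bp
        roles = rng.random(n_blocks)
        is_repeat = roles < cfg.repeat_fraction
        is_fail = (roles >= cfg.repeat_fraction) & (
            roles < cfg.repeat_fraction + cfg.fail_fraction
        )
        for kind, flags in (("repeat", is_repeat), ("fail", is_fail)):
            idx = np.flatnonzero(flags)
            if idx.size == 0:
                continue
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in runs:
                start = int(run[0]) * cfg.block_bp
                end = (int(run[-1]) + 1) * cfg.block_bp
                if kind == "repeat":
                    repeat.add(Interval(contig, start, end))
                else:
                    # a failure belongs to 1-3 lines; the union is what counts
                    for line in rng.choice(lines, size=rng.integers(1, 4), replace=False):
                        fail_tracks[str(line)].add(Interval(contig, start, end))
        # genes: alternate gene/intergenic segments targeting gene_fraction
        pos = 0
        while pos < length:
            gene_len = int(rng.integers(5_000, 20_000))
            gap_len = max(int(gene_len * (1 - cfg.gene_fraction) / cfg.gene_fraction), 1)
            end = min(pos + gene_len, length)
            genes.add(Interval(contig, pos, end))
            pos = end + gap_len
    return repeat, fail_tracks, genes


def _gc_masks(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Deterministic per-site G/C identity (no FASTA is emitted).

    Base composition drifts along each contig (isochore-like): the local G/C
    fraction is drawn per 10 kb block around ``cfg.gc_fraction`` so that
    windows differ measurably in composition, as real windows do.
    """
    import zlib

    block = 10_000
    out = {}
    for contig, length in sorted(cfg.contig_lengths.items()):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(contig.encode())])
        )
        n_blocks = length // block + 1
        local = np.clip(
            rng.normal(cfg.gc_fraction, 0.07, size=n_blocks), 0.2, 0.8
        )
        per_site = np.repeat(local, block)[:length]
        out[contig] = rng.random(length) < per_site
    return out


def _covariate_track(
    cfg: SimulationConfig, rng: np.random.Generator, kind: str
) -> IntervalTrack:
    track = IntervalTrack()
    for contig, length in cfg.contig_lengths.items():
        pos = 0
        while pos < length:
            seg = int(rng.integers(20_000, 80_000))
            end = min(pos + seg, length)
            if kind == "recomb":
                value = float(np.round(rng.lognormal(np.log(2.0), 0.6), 6))
            else:  # replication timing, arbitrary units in [-1, 1]
                value = float(np.round(rng.uniform(-1.0, 1.0), 6))
            track.add(Interval(contig, pos, end, value))
            pos = end
    return track


def _window_track(cfg: SimulationConfig, rng: np.random.Generator) -> IntervalTrack:
    total_bp = sum(cfg.contig_lengths.values())
    mean_len = total_bp / cfg.n_windows
    states = list(cfg.state_freqs)
    probs = np.array([cfg.state_freqs[s] for s in states], dtype=float)
    probs /= probs.sum()
    track = IntervalTrack()
    for contig, length in cfg.contig_lengths.items():
        pos = 0
        while pos < length:
            w = int(rng.uniform(0.5, 1.5) * mean_len)
            end = min(pos + max(w, 500), length)
            state = str(rng.choice(states, p=probs))
            track.add(Interval(contig, pos, end, state))
            pos = end
    return track


# --- variant evidence -------------------------------------------------------


def _passing_annotations(rng: np.random.Generator) -> dict[str, float]:
    return {
        "MQ": round(float(rng.uniform(55, 60)), 3),
        "QD": round(float(rng.uniform(10, 30)), 3),
        "FS": round(float(rng.uniform(0, 10)), 3),
        "SOR": round(float(rng.uniform(0.3, 1.5)), 3),
        "MQRankSum": round(float(rng.uniform(-2, 2)), 3),
        "ReadPosRankSum": round(float(rng.uniform(-2, 2)), 3),
    }


def _depth(rng: np.random.Generator, median: float, dispersion: float) -> int:
    """NB depth around the line median, clipped into the passing window."""
    p = dispersion / (dispersion + median)
    d = int(rng.negative_binomial(dispersion, p))
    lo, hi = int(np.ceil(0.5 * median)), int(np.floor(2.0 * median))
    return int(np.clip(d, lo, hi))


def _carrier_call(
    rng: np.random.Generator, median: float, dispersion: float, homozygous: bool
) -> LineCall:
    depth = _depth(rng, median, dispersion)
    if homozygous:
        alt = depth
    else:
        alt = int(rng.binomial(depth, 0.5))
        alt = int(np.clip(alt, 10, depth))  # variant-mode support floor
    return LineCall(
        genotype=Genotype.HOM_ALT if homozygous else Genotype.HET,
        alt_read_count=alt,
        total_depth=depth,
    )


def _ref_call(rng: np.random.Generator, median: float, dispersion: float) -> LineCall:
    depth = _depth(rng, median, dispersion)
    return LineCall(genotype=Genotype.HOM_REF, alt_read_count=0, total_depth=depth)


_CLASS_PAIRS = {
    "A:T>C:G": (("A", "C"), ("T", "G")),
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
    "G:C>A:T": (("G", "A"), ("C", "T")),
    "G:C>C:G": (("G", "C"), ("C", "G")),
    "G:C>T:A": (("G", "T"), ("C", "A")),
}
_BASES_AT = ("A", "T")
_BASES_GC = ("G", "C")


def generate_experiment(config: SimulationConfig) -> Experiment:
    """Run the generator; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lines = cfg.line_ids

    repeat_mask, fail_tracks, gene_track = _block_tracks(cfg, rng)
    gc_by_contig = _gc_masks(cfg)
    mask = compute_callable_mask(
        cfg.contig_lengths, repeat_mask, fail_tracks, gc_by_contig
    )
    if mask.callable_sites() == 0:
        raise ConfigurationError("zero callable genome after masking")

    # callable position pools, split by reference base class
    pools: dict[str, dict[str, np.ndarray]] = {}
    for contig in cfg.contig_lengths:
        callable_arr = mask.callable_by_contig[contig]
        gc = gc_by_contig[contig]
        pools[contig] = {
            "any": np.flatnonzero(callable_arr),
            "gc": np.flatnonzero(callable_arr & gc),
            "at": np.flatnonzero(callable_arr & ~gc),
        }
    contigs = sorted(cfg.contig_lengths)
    contig_weights = np.array(
        [pools[c]["any"].size for c in contigs], dtype=float
    )
    contig_weights /= contig_weights.sum()

    reserver = _Reserver()
    truth = SyntheticTruth(
        seed=cfg.seed,
        callable_sites=mask.callable_sites(),
        callable_gc_sites=mask.callable_gc_sites(),
        rates={
            "snv": cfg.snv_rate,
            "indel": cfg.indel_rate,
            "mnv": cfg.mnv_rate,
            "complex": cfg.complex_rate,
            "sv": cfg.sv_rate,
            "te_insertion": dict(cfg.te_insertion_rate),
            "te_excision": dict(cfg.te_excision_rate),
        },
        window_coefs=dict(cfg.window_coefs),
        window_theta=cfg.window_theta,
    )

    # line metadata
    line_meta: dict[str, LineMeta] = {}
    for line in lines:
        meta = LineMeta(
            line_id=line,
            treatment=cfg.treatment_of(line),
            generations=cfg.generations,
            adjusted_generations=float(cfg.generations),
        )
        for contig in contigs:
            depth = float(
                np.round(max(rng.normal(cfg.median_depth_mean, cfg.median_depth_sd), 20), 1)
            )
            if cfg.trisomy == (line, contig):
                depth = float(np.round(depth * 1.5, 1))
            meta.median_depth[contig] = depth
        line_meta[line] = meta

    def sample_site(
        base_kind: str, span: int = 0, margin: int = RESERVE_MARGIN,
        max_tries: int = 2000,
    ):
        """A reserved callable 0-based position of the requested base class."""
        for _ in range(max_tries):
            contig = str(rng.choice(contigs, p=contig_weights))
            pool = pools[contig][base_kind]
            if pool.size == 0:
                continue
            pos0 = int(pool[rng.integers(pool.size)])
            if pos0 + span + 1 > cfg.contig_lengths[contig]:
                continue
            if reserver.free(contig, pos0, pos0 + span + 1, margin=margin):
                reserver.reserve(contig, pos0, pos0 + span + 1)
                return contig, pos0
        raise ConfigurationError("could not place event; genome too crowded")

    records: list[VariantRecord] = []

    def make_record(contig, pos1, ref, alt, owner, homozygous, override=None):
        calls = {}
        for line in lines:
            median = line_meta[line].median_depth[contig]
            if line == owner:
                calls[line] = _carrier_call(rng, median, cfg.depth_dispersion, homozygous)
            else:
                calls[line] = _ref_call(rng, median, cfg.depth_dispersion)
        rec = VariantRecord(
            contig=contig,
            position=pos1,
            ref_allele=ref,
            alt_allele=alt,
            site_annotations=_passing_annotations(rng),
            per_line_calls=calls,
        )
        if override:
            override(rec)
        return rec

    def draw_class() -> str:
        classes = sorted(cfg.class_probs)
        probs = np.array([cfg.class_probs[c] for c in classes])
        return str(rng.choice(classes, p=probs / probs.sum()))

    def draw_class_at(gc_site: bool) -> str:
        """Class conditioned on the origin base kind of an already-fixed site."""
        classes = sorted(
            c for c in cfg.class_probs if c.startswith("G:C") == gc_site
        )
        probs = np.array([cfg.class_probs[c] for c in classes])
        return str(rng.choice(classes, p=probs / probs.sum()))

    def snv_ref_alt(klass: str, gc_site: bool) -> tuple[str, str]:
        pairs = [p for p in _CLASS_PAIRS[klass] if (p[0] in _BASES_GC) == gc_site]
        return pairs[int(rng.integers(len(pairs)))]

    def indel_alleles(pos_kind_base: str) -> tuple[str, str, int]:
        deletion = bool(rng.random() < cfg.indel_deletion_bias)
        if deletion:
            size = int(rng.geometric(cfg.deletion_size_p))
            inserted = "".join(rng.choice(list("ACGT"), size=size))
            return pos_kind_base + inserted, pos_kind_base, -size
        size = int(rng.geometric(cfg.insertion_size_p))
        inserted = "".join(rng.choice(list("ACGT"), size=size))
        return pos_kind_base, pos_kind_base + inserted, size

    def zygosity_for(contig: str) -> bool:
        p = cfg.hom_fraction_x if contig == "X" else cfg.hom_fraction_autosome
        return bool(rng.random() < p)

    per_site_opportunity = mask.callable_sites() * cfg.generations

    for line in lines:
        for _ in range(rng.poisson(cfg.snv_rate * per_site_opportunity)):
            klass = draw_class()
            gc_site = klass.startswith("G:C")
            contig, pos0 = sample_site("gc" if gc_site else "at")
            homozygous = zygosity_for(contig)
            ref, alt = snv_ref_alt(klass, gc_site)
            records.append(make_record(contig, pos0 + 1, ref, alt, line, homozygous))
            truth.events.append(
                PlantedEvent(
                    line, "SNV", contig, (pos0 + 1,),
                    "homozygous" if homozygous else "heterozygous",
                    ((ref, alt),),
                )
            )
        for _ in range(rng.poisson(cfg.indel_rate * per_site_opportunity)):
            contig, pos0 = sample_site("any", span=90)
            homozygous = zygosity_for(contig)
            base = "G" if gc_by_contig[contig][pos0] else "A"
            ref, alt, signed = indel_alleles(base)
            records.append(make_record(contig, pos0 + 1, ref, alt, line, homozygous))
            truth.events.append(
                PlantedEvent(
                    line, "INDEL", contig, (pos0 + 1,),
                    "homozygous" if homozygous else "heterozygous",
                    ((ref, alt),), (signed,),
                )
            )
        for _ in range(rng.poisson(cfg.mnv_rate * per_site_opportunity)):
            n_members = int(rng.integers(2, 4))
            contig, anchor0 = sample_site("any", span=1000)
            homozygous = zygosity_for(contig)
            positions, ref_alts = [], []
            offsets = np.sort(rng.choice(np.arange(0, 950), size=n_members, replace=False))
            for off in offsets:
                pos0 = anchor0 + int(off)
                gc_site = bool(gc_by_contig[contig][pos0])
                klass = draw_class_at(gc_site)
                ref, alt = snv_ref_alt(klass, gc_site)
                records.append(make_record(contig, pos0 + 1, ref, alt, line, homozygous))
                positions.append(pos0 + 1)
                ref_alts.append((ref, alt))
            truth.events.append(
                PlantedEvent(
                    line, "MNV", contig, tuple(positions),
                    "homozygous" if homozygous else "heterozygous",
                    tuple(ref_alts),
                )
            )
        for _ in range(rng.poisson(cfg.complex_rate * per_site_opportunity)):
            contig, anchor0 = sample_site("any", span=1000)
            homozygous = zygosity_for(contig)
            base = "G" if gc_by_contig[contig][anchor0] else "A"
            ref_i, alt_i, signed = indel_alleles(base)
            records.append(make_record(contig, anchor0 + 1, ref_i, alt_i, line, homozygous))
            off = int(rng.integers(100, 900))
            gc_site = bool(gc_by_contig[contig][anchor0 + off])
            klass = draw_class_at(gc_site)
            ref_s, alt_s = snv_ref_alt(klass, gc_site)
            records.append(make_record(contig, anchor0 + 1 + off, ref_s, alt_s, line, homozygous))
            truth.events.append(
                PlantedEvent(
                    line, "COMPLEX", contig, (anchor0 + 1, anchor0 + 1 + off),
                    "homozygous" if homozygous else "heterozygous",
                    ((ref_i, alt_i), (ref_s, alt_s)), (signed,),
                )
            )

    # --- structural variants -------------------------------------------------
    sv_records: list[SVRecord] = []

    def plant_sv(owner_lines, spanning, split, quality, record_truth):
        length = int(rng.integers(265, 7800))
        for _ in range(2000):
            contig = str(rng.choice(contigs, p=contig_weights))
            start0 = int(rng.integers(2000, cfg.contig_lengths[contig] - length - 2000))
            if reserver.free(contig, start0, start0 + length):
                reserver.reserve(contig, start0, start0 + length)
                break
        else:
            raise ConfigurationError("could not place SV")
        sv = SVRecord(
            contig=contig,
            start=start0,
            end=start0 + length,
            sv_type=SVType(
                str(rng.choice(["deletion", "insertion", "tandem_duplication"]))
            ),
            length=length,
            quality=quality,
            spanning_read_support=spanning,
            split_read_support=split,
            per_line_presence={l: l in owner_lines for l in lines},
        )
        sv_records.append(sv)
        if record_truth:
            truth.events.append(
                PlantedEvent(owner_lines[0], "SV", contig, (start0 + 1, start0 + length))
            )
        return sv

    for line in lines:
        for _ in range(rng.poisson(cfg.sv_rate * per_site_opportunity)):
            plant_sv(
                [line],
                spanning=int(rng.integers(10, 60)),
                split=int(rng.integers(0, 60)),
                quality=SV_MAX_QUALITY,
                record_truth=True,
            )

    # --- TE calls -------------------------------------------------------------
    te_calls: list[TECall] = []
    families = list(TE_FAMILIES)
    fam_probs = np.array(TE_FAMILY_WEIGHTS) / sum(TE_FAMILY_WEIGHTS)

    #: TE events pack more densely than point variants: they only need to
    #: stay > proximity_bp away from planted variants and > the merge window
    #: away from each other.
    te_margin = 1200

    def plant_te(carriers, event_type, large_jitter=False):
        family = str(rng.choice(families, p=fam_probs))
        contig, pos0 = sample_site("any", span=200, margin=te_margin)
        bp = pos0 + 1
        offsets = []
        for i, line in enumerate(carriers):
            if large_jitter and i > 0:
                jit = int(rng.integers(60, 150)) * int(rng.choice([-1, 1]))
            else:
                jit = int(rng.integers(-cfg.te_jitter_bp, cfg.te_jitter_bp + 1))
            offsets.append(jit)
            te_calls.append(
                TECall(
                    line_id=line,
                    family=family,
                    contig=contig,
                    breakpoint=max(bp + jit, 1),
                    event_type=TEEventType(event_type),
                    support=int(rng.integers(5, 40)),
                )
            )
        truth.te_events.append(
            PlantedTE(
                tuple(carriers), family, contig, bp, event_type,
                de_novo=len(carriers) == 1 and not large_jitter,
            )
        )

    for line in lines:
        group = cfg.treatment_of(line)
        for _ in range(rng.poisson(cfg.te_insertion_rate[group] * cfg.generations)):
            plant_te([line], "insertion")
        for _ in range(rng.poisson(cfg.te_excision_rate[group] * cfg.generations)):
            plant_te([line], "excision")
    n_large = int(round(cfg.segregating_te_count * cfg.te_large_jitter_frac))
    for i in range(cfg.segregating_te_count):
        carriers = [
            str(l)
            for l in rng.choice(lines, size=int(rng.integers(2, 5)), replace=False)
        ]
        plant_te(carriers, "insertion", large_jitter=i < n_large)

    # --- planted artifacts ----------------------------------------------------
    thr = FilterThresholds()

    def artifact_override(rule):
        def apply(rec: VariantRecord) -> None:
            margin = ARTIFACT_MARGINS[rule]
            ann = rec.site_annotations
            if rule == "min_MQ":
                ann["MQ"] = round(thr.min_MQ - margin, 3)
            elif rule == "min_QD":
                ann["QD"] = round(thr.min_QD - margin, 3)
            elif rule == "max_FS":
                ann["FS"] = round(thr.max_FS + margin, 3)
            elif rule == "max_SOR":
                ann["SOR"] = round(thr.max_SOR + margin, 3)
            elif rule == "max_abs_MQRankSum":
                ann["MQRankSum"] = round(-(thr.max_abs_MQRankSum + margin), 3)
            elif rule == "max_abs_ReadPosRankSum":
                ann["ReadPosRankSum"] = round(thr.max_abs_ReadPosRankSum + margin, 3)
        return apply

    for rule, count in cfg.artifact_counts_by_filter.items():
        for _ in range(count):
            owner = str(rng.choice(lines))
            contig, pos0 = sample_site("any")
            ref, alt = ("G", "T") if gc_by_contig[contig][pos0] else ("A", "C")
            rec = make_record(contig, pos0 + 1, ref, alt, owner, homozygous=False)
            if rule == "min_alt_reads":
                call = rec.per_line_calls[owner]
                rec.per_line_calls[owner] = LineCall(
                    Genotype.HET,
                    alt_read_count=thr.min_alt_reads - ARTIFACT_MARGINS[rule],
                    total_depth=call.total_depth,
                )
            elif rule == "depth_window":
                median = line_meta[owner].median_depth[contig]
                depth = int(median * (thr.depth_hi_frac + ARTIFACT_MARGINS[rule]))
                rec.per_line_calls[owner] = LineCall(
                    Genotype.HET, alt_read_count=depth // 2, total_depth=depth
                )
            else:
                artifact_override(rule)(rec)
            records.append(rec)
            truth.artifacts.append(
                PlantedArtifact("variant", contig, pos0 + 1, rule, owner)
            )

    for _ in range(cfg.shared_artifact_count):
        contig, pos0 = sample_site("any")
        ref, alt = ("C", "A") if gc_by_contig[contig][pos0] else ("T", "G")
        carriers = [str(l) for l in rng.choice(lines, size=2, replace=False)]
        rec = make_record(contig, pos0 + 1, ref, alt, carriers[0], homozygous=False)
        median = line_meta[carriers[1]].median_depth[contig]
        rec.per_line_calls[carriers[1]] = _carrier_call(
            rng, median, cfg.depth_dispersion, homozygous=False
        )
        records.append(rec)
        truth.artifacts.append(PlantedArtifact("variant", contig, pos0 + 1, "shared"))

    for _ in range(cfg.uncalled_artifact_count):
        owner = str(rng.choice(lines))
        contig, pos0 = sample_site("any")
        ref, alt = ("G", "C") if gc_by_contig[contig][pos0] else ("A", "T")
        rec = make_record(contig, pos0 + 1, ref, alt, owner, homozygous=False)
        other = str(rng.choice([l for l in lines if l != owner]))
        rec.per_line_calls[other] = LineCall(Genotype.MISSING, 0, 0)
        records.append(rec)
        truth.artifacts.append(
            PlantedArtifact("variant", contig, pos0 + 1, "uncalled_site", owner)
        )

    # near-SV / near-TE artifacts: passing variants inside the exclusion radius
    for kind, count in (
        ("sv", cfg.near_sv_artifact_count),
        ("te", cfg.near_te_artifact_count),
    ):
        for _ in range(count):
            owner = str(rng.choice(lines))
            if kind == "sv":
                sv = plant_sv(
                    [owner], spanning=int(rng.integers(10, 60)), split=0,
                    quality=SV_MAX_QUALITY, record_truth=True,
                )
                contig, pos1 = sv.contig, sv.end + int(rng.integers(200, 900))
            else:
                plant_te([owner], "insertion")
                planted = truth.te_events[-1]
                contig = planted.contig
                pos1 = min(
                    planted.breakpoint + int(rng.integers(200, 900)),
                    cfg.contig_lengths[contig],
                )
            ref, alt = ("C", "G") if gc_by_contig[contig][pos1 - 1] else ("T", "A")
            records.append(make_record(contig, pos1, ref, alt, owner, homozygous=False))
            truth.artifacts.append(
                PlantedArtifact("variant", contig, pos1, "near_sv_te", owner)
            )

    for reason, count in cfg.sv_artifact_counts.items():
        for _ in range(count):
            owner = str(rng.choice(lines))
            if reason == "min_support":
                sv = plant_sv([owner], 5, 5, SV_MAX_QUALITY, record_truth=False)
            elif reason == "not_max_quality":
                sv = plant_sv(
                    [owner], int(rng.integers(10, 60)), 0, SV_MAX_QUALITY - 400,
                    record_truth=False,
                )
            else:  # not_unique
                pair = [str(l) for l in rng.choice(lines, size=2, replace=False)]
                sv = plant_sv(pair, int(rng.integers(10, 60)), 0, SV_MAX_QUALITY, False)
            truth.artifacts.append(
                PlantedArtifact("sv", sv.contig, sv.start + 1, reason)
            )

    # --- covariates, windows, window-model counts ----------------------------
    recomb_track = _covariate_track(cfg, rng, "recomb")
    timing_track = _covariate_track(cfg, rng, "timing")
    window_track = _window_track(cfg, rng)

    from .windows import annotate_windows, windows_to_frame

    included, _ = annotate_windows(
        window_track, mask, recomb_track, timing_track,
        events=(), te_events=(), n_lines=len(lines),
    )
    table = windows_to_frame(included)
    counts, expected = simulate_window_counts(
        table, cfg.window_coefs, cfg.window_theta, rng,
        sigma=cfg.window_sigma,
        treatment_interaction=cfg.treatment_interaction or None,
        n_lines_per_group=cfg.n_lines_per_group,
    )
    for col, values in counts.items():
        table[col] = values
    truth.window_expected = [float(v) for v in expected]

    return Experiment(
        config=cfg,
        line_meta=line_meta,
        records=records,
        te_calls=te_calls,
        sv_records=sv_records,
        repeat_mask=repeat_mask,
        gene_track=gene_track,
        recomb_track=recomb_track,
        timing_track=timing_track,
        window_track=window_track,
        per_line_fail_tracks=fail_tracks,
        gc_by_contig=gc_by_contig,
        mask=mask,
        window_table=table,
        truth=truth,
    )


def simulate_window_counts(
    table: pd.DataFrame,
    coefs: dict[str, float],
    theta: float,
    rng: np.random.Generator,
    sigma: float = 0.0,
    treatment_interaction: dict[str, float] | None = None,
    treatment_main: float = 0.0,
    n_lines_per_group: tuple[int, int] = (16, 19),
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw nbinom2 window counts from known coefficients.

    The linear predictor uses log(power) as an offset plus the configured
    coefficients on mean-scaled G/C content and recombination, raw timing and
    chromatin-state indicators.  Returns ``(counts, expected)`` where counts
    holds ``point`` (combined draw) and, when a random intercept or
    interaction is configured, per-treatment draws ``point_dsb_plus`` /
    ``point_dsb_minus`` sharing each window's random effect.
    """
    from .windows import build_design

    tmp = table.copy()
    tmp["point"] = 0
    _, X, offset = build_design(tmp, count_col="point", power="offset")
    eta = offset + sum(
        coefs.get(name, 0.0) * X[name].to_numpy() for name in X.columns
    )
    expected = np.exp(eta)

    def nb_draw(mu):
        return rng.negative_binomial(theta, theta / (theta + mu))

    counts = {"point": nb_draw(expected)}
    n_total = sum(n_lines_per_group)
    frac = (n_lines_per_group[0] / n_total, n_lines_per_group[1] / n_total)
    u = rng.normal(0.0, sigma, size=len(tmp)) if sigma > 0 else np.zeros(len(tmp))
    inter = np.zeros(len(tmp))
    if treatment_interaction:
        inter = sum(
            beta * X[name].to_numpy() for name, beta in treatment_interaction.items()
        )
    mu_plus = expected * frac[0] * np.exp(u)
    mu_minus = expected * frac[1] * np.exp(u + treatment_main + inter)
    counts["point_dsb_plus"] = nb_draw(mu_plus)
    counts["point_dsb_minus"] = nb_draw(mu_minus)
    return counts, expected


# --- recovery scoring -------------------------------------------------------


def score_recovery(
    events,
    te_de_novo,
    rejections,
    truth: SyntheticTruth,
    te_merge_bp: int = 50,
) -> dict:
    """Match pipeline output against the planted truth.

    Point events match on (line, category, exact member-position tuple);
    SVs on (line, exact span); TE events on (line, family, contig,
    breakpoint within the merge window).  Artifacts are checked against the
    rejection log for the correct reason at the correct site.
    """
    truth_keys = {
        (e.line_id, e.category, e.contig, tuple(e.positions)): e
        for e in truth.events
    }
    matched = set()
    fp = []
    for ev in events:
        if ev.category.value == "SV":
            key = (ev.line_id, "SV", ev.contig, (ev.start, ev.end))
        else:
            key = (
                ev.line_id,
                ev.category.value,
                ev.contig,
                tuple(m.position for m in ev.members),
            )
        if key in truth_keys and key not in matched:
            matched.add(key)
        else:
            fp.append(key)
    categories = sorted({k[1] for k in truth_keys} | {k[1] for k in fp})
    report: dict = {"by_category": {}}
    for cat in categories:
        tp = sum(1 for k in matched if k[1] == cat)
        fn = sum(1 for k in truth_keys if k[1] == cat) - tp
        fpc = sum(1 for k in fp if k[1] == cat)
        precision = tp / (tp + fpc) if (tp + fpc) else float("nan")
        recall = tp / (tp + fn) if (tp + fn) else float("nan")
        report["by_category"][cat] = {
            "tp": tp, "fp": fpc, "fn": fn,
            "precision": precision, "recall": recall,
        }

    truth_te = [t for t in truth.te_events if t.de_novo]
    te_matched = set()
    te_fp = 0
    for ev in te_de_novo:
        (line,) = ev.carrier_lines
        hit = None
        for i, t in enumerate(truth_te):
            if i in te_matched:
                continue
            if (
                t.lines == (line,)
                and t.family == ev.family
                and t.contig == ev.contig
                and abs(t.breakpoint - ev.breakpoint) <= te_merge_bp
                and t.event_type == ev.event_type.value
            ):
                hit = i
                break
        if hit is None:
            te_fp += 1
        else:
            te_matched.add(hit)
    tp = len(te_matched)
    fn = len(truth_te) - tp
    report["by_category"]["TE"] = {
        "tp": tp, "fp": te_fp, "fn": fn,
        "precision": tp / (tp + te_fp) if (tp + te_fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
    }

    reject_index: dict[tuple[str, int], set[str]] = {}
    for r in rejections:
        reject_index.setdefault((r.contig, r.position), set()).add(r.reason)
    artifact_results = []
    for art in truth.artifacts:
        reasons = reject_index.get((art.contig, art.position), set())
        artifact_results.append(
            {
                "contig": art.contig,
                "position": art.position,
                "expected": art.expected_reason,
                "observed": sorted(reasons),
                "ok": art.expected_reason in reasons,
            }
        )
    report["artifacts"] = artifact_results
    report["artifacts_all_ok"] = all(a["ok"] for a in artifact_results)
    return report
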