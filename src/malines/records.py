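"""Core record types shared by every pipeline stage.

Coordinate contract
-------------------
Internally everything is 0-based half-open, with one exception:
:class:`VariantRecord.position` stays 1-based to mirror VCF.  The only
sanctioned crossing point between the two conventions is
:func:`point_to_interval` / :func:`interval_to_point`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

ANNOTATION_KEYS = ("MQ", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

#: contigs analysed by default: the major female recombining arms.
DEFAULT_CONTIGS = ("2L", "2R", "3L", "3R", "X")


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Zygosity(enum.Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    MIXED = "mixed"


def point_to_interval(position: int) -> tuple[int, int]:
    """1-based point ``p`` -> half-open ``[p-1, p)``."""
    if position < 1:
        raise ValueError(f"1-based position must be >= 1, got {position}")
    return position - 1, position


def interval_to_point(start: int, end: int) -> int:
    """Half-open single-site ``[s, s+1)`` -> 1-based point ``s+1``."""
    if end != start + 1:
        raise ValueError(f"not a single-site interval: [{start}, {end})")
    return start + 1


@dataclass(frozen=True)
class LineCall:
    """Evidence for one line at one variant site."""

    genotype: Genotype
    alt_read_count: int = 0
    total_depth: int = 0

    def __post_init__(self) -> None:
        if self.alt_read_count < 0 or self.total_depth < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class VariantRecord:
    """One called variant (post multiallelic splitting) across the panel.

    ``site_annotations`` holds the GATK-style site statistics; keys absent
    from the VCF row stay absent here (missing is meaningful to the filters,
    zero is not a substitute).
    """

    contig: str
    position: int  # 1-based, mirrors VCF
    ref_allele: str
    alt_allele: str
    site_annotations: dict[str, float] = field(default_factory=dict)
    per_line_calls: dict[str, LineCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def indel_length(self) -> int:
        """Signed length change (negative = deletion); 0 for SNVs."""
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class Interval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    value: object = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )


class IntervalTrack:
    """Per-contig sorted, non-overlapping intervals with optional values.

    BED semantics: 0-based half-open.  Overlap within one track is rejected
    at construction, which catches most malformed covariate files early.
    """

    def __init__(self, intervals: list[Interval] | None = None):
        self._by_contig: dict[str, list[Interval]] = {}
        for iv in intervals or []:
            self.add(iv)

    def add(self, iv: Interval) -> None:
        lst = self._by_contig.setdefault(iv.contig, [])
        lst.append(iv)
        lst.sort(key=lambda x: (x.start, x.end))
        for a, b in zip(lst, lst[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals on {iv.contig}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def on(self, contig: str) -> list[Interval]:
        return list(self._by_contig.get(contig, []))

    def __iter__(self):
        for contig in self.contigs:
            yield from self._by_contig[contig]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_contig.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalTrack):
            return NotImplemented
        return list(self) == list(other)

    def total_bp(self, contig: Optional[str] = None) -> int:
        ivs = self.on(contig) if contig else list(self)
        return sum(iv.end - iv.start for iv in ivs)

    def contains_point(self, contig: str, position_1based: int) -> bool:
        start, _ = point_to_interval(position_1based)
        return any(
            iv.start <= start < iv.end for iv in self._by_contig.get(contig, [])
        )


class SVType(enum.Enum):
    DELETION = "deletion"
    INSERTION = "insertion"
    TANDEM_DUPLICATION = "tandem_duplication"


@dataclass
class SVRecord:
    """A structural-variant call with its read support and quality."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    sv_type: SVType
    length: int
    quality: float
    spanning_read_support: int
    split_read_support: int
    #: line_id -> genotype present/absent; missing line => no called genotype
    per_line_presence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("SV length must be positive")
        if self.spanning_read_support < 0 or self.split_read_support < 0:
            raise ValueError("read supports must be non-negative")

    @property
    def carrier_lines(self) -> list[str]:
        return sorted(k for k, v in self.per_line_presence.items() if v)


class TEEventType(enum.Enum):
    INSERTION = "insertion"
    EXCISION = "excision"


@dataclass(frozen=True)
class TECall:
    """One raw transposable-element call in one line."""

    line_id: str
    family: str
    contig: str
    breakpoint: int  # 1-based
    event_type: TEEventType
    support: int = 0

    def __post_init__(self) -> None:
        if self.breakpoint < 1:
            raise ValueError("breakpoint must be >= 1")
        if not self.family:
            raise ValueError("family must be non-empty")


@dataclass
class LineMeta:
    """Per-line experiment metadata.

    ``treatment`` distinguishes the group forming programmed meiotic DSBs
    (``dsb_plus``) from the group in which they are abolished (``dsb_minus``).
    ``adjusted_generations`` feeds per-site rate denominators; the nominal
    ``generations`` feeds per-genome TE rates.
    """

    line_id: str
    treatment: str  # "dsb_plus" | "dsb_minus"
    generations: int = 30
    adjusted_generations: float | None = None
    median_depth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in ("dsb_plus", "dsb_minus"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.adjusted_generations is None:
            self.adjusted_generations = float(self.generations)
        if self.adjusted_generations <= 0:
            raise ValueError("adjusted_generations must be positive")
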