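"""Core domain types for deamination-based m6A sequencing data.

The vocabulary follows the underlying chemistry: an accessible, unmethylated
adenosine is deaminated to inosine (read as G), so a methylated or shielded A
survives as "persistent A".  Every type here is a thin, validated container;
all estimation lives in :mod:`etamseq.estimate` and :mod:`etamseq.calling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

STRANDS = ("+", "-")
#: Bases accepted in read observations (RNA alphabet; T is normalised to U).
READ_BASES = frozenset("AGCUN")


class EtamError(Exception):
    """Base class for all package errors."""


class ParseError(EtamError):
    """A malformed on-disk record; message names the offending line."""


class ValidationError(EtamError):
    """An in-memory object violates a type invariant."""


class ParameterError(EtamError):
    """An argument outside its legal range."""


class EstimationError(EtamError):
    """An estimator was called on data it cannot handle."""


class BoundaryError(EtamError):
    """A site too close to a contig end for its sequence context."""


class ReferenceMismatchError(EtamError):
    """The reference base at a putative A site is not A."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A strand-resolved adenosine position (0-based)."""

    contig: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.contig}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __str__(self) -> str:  # e.g. "chr1:100:+"
        return f"{self.contig}:{self.pos}:{self.strand}"


@dataclass
class SiteCount:
    """Observed persistent-A / converted-G read counts at one site.

    ``other_count`` (non-A/G observations) is carried through I/O but never
    enters model math: the model is binomial on A vs G only.
    """

    site: GenomicSite
    a_count: int
    g_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        for name in ("a_count", "g_count", "other_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def coverage(self) -> int:
        """A + G depth (the model's binomial n)."""
        return self.a_count + self.g_count


@dataclass
class SampleTable:
    """All per-site counts for one sample, keyed by site.

    ``role`` is one of ``treated`` (deaminated mRNA), ``ivt``
    (modification-free in-vitro-transcribed control), ``fto_minus``
    (untreated half of an FTO experiment) or ``fto_plus`` (demethylated).
    """

    ROLES = ("treated", "ivt", "fto_minus", "fto_plus")

    label: str
    role: str
    sites: Dict[GenomicSite, SiteCount] = field(default_factory=dict)
    conversion_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValidationError(f"unknown sample role {self.role!r}; expected one of {self.ROLES}")
        if self.conversion_rate is not None:
            self._check_rate(self.conversion_rate)

    @staticmethod
    def _check_rate(c: float) -> None:
        if not 0.0 <= c <= 1.0:
            raise ValidationError(f"conversion rate must be in [0, 1], got {c}")

    def set_conversion_rate(self, c: float) -> None:
        self._check_rate(c)
        self.conversion_rate = c

    def add(self, count: SiteCount) -> None:
        if count.site in self.sites:
            raise ValidationError(f"duplicate site {count.site}")
        self.sites[count.site] = count

    def get(self, site: GenomicSite) -> Optional[SiteCount]:
        return self.sites.get(site)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteCount]:
        return iter(self.sites.values())

    def __contains__(self, site: GenomicSite) -> bool:
        return site in self.sites


def _normalise_base(b: str) -> str:
    b = b.upper().replace("T", "U")
    if b not in READ_BASES:
        raise ValidationError(f"illegal base symbol {b!r}")
    return b


@dataclass
class ReadObservation:
    """One read's observed bases at its reference-A positions.

    Carrier for the read-level processing filter: reads in which the
    deaminase left more than half of the covered A positions unconverted are
    discarded before counting.
    """

    read_id: str
    umi: Optional[str]
    contig: str
    strand: str
    ref_a_positions: List[int]
    observed: List[str]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if len(self.ref_a_positions) != len(self.observed):
            raise ValidationError(
                f"read {self.read_id}: {len(self.ref_a_positions)} positions vs "
                f"{len(self.observed)} observed bases"
            )
        for prev, nxt in zip(self.ref_a_positions, self.ref_a_positions[1:]):
            if nxt <= prev:
                raise ValidationError(f"read {self.read_id}: positions not strictly increasing")
        self.observed = [_normalise_base(b) for b in self.observed]

    @property
    def n_ref_a(self) -> int:
        return len(self.ref_a_positions)

    @property
    def unconverted_fraction(self) -> Optional[float]:
        """Fraction of covered reference-A positions still read as A.

        ``None`` when the read covers no reference A (the fraction is 0/0).
        """
        if not self.ref_a_positions:
            return None
        return sum(1 for b in self.observed if b == "A") / len(self.observed)


@dataclass
class MethylCall:
    """One evaluated site with its methylation estimates and test results.

    ``apparent_m`` is the persistent-A-based estimate before accessibility
    correction; ``true_m`` divides out accessibility; ``exposed_m`` =
    true_m x accessibility is the filterable quantity (>= 10% cutoff).
    """

    site: GenomicSite
    apparent_m: float
    accessibility: Optional[float]
    true_m: Optional[float]
    exposed_m: float
    p_value: float
    q_value: float
    treated_counts: Tuple[int, int]
    control_counts: Tuple[int, int]
    motif5: Optional[str] = None
    passed: bool = False


@dataclass
class ProbeObservation:
    """UMI-collapsed counts for one synthetic spike-in probe."""

    probe_id: str
    designed_m6a_fraction: float
    a_count: int
    g_count: int
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.designed_m6a_fraction <= 1.0:
            raise ValidationError(
                f"designed m6A fraction must be in [0, 1], got {self.designed_m6a_fraction}"
            )

    @property
    def coverage(self) -> int:
        return self.a_count + self.g_count


@dataclass
class CalibrationFit:
    """Linear fit of persistent-A readout vs designed m6A fraction."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(f"r_squared must be in [0, 1], got {self.r_squared}")
        self.r_squared = min(self.r_squared, 1.0)


@dataclass
class AccessibilityEstimate:
    """Per-site deaminase accessibility from a modification-free control.

    0 = fully blocked, 1 = fully accessible. ``shrunken_s`` is filled by
    :func:`etamseq.estimate.shrink_accessibility`.
    """

    site: GenomicSite
    raw_s: float
    control_counts: Tuple[int, int]
    shrunken_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.raw_s <= 1.0:
            raise ValidationError(f"raw_s must be in [0, 1], got {self.raw_s}")

    @property
    def best(self) -> float:
        """Shrunken estimate when available, else the raw one."""
        return self.raw_s if self.shrunken_s is None else self.shrunken_s


@dataclass
class FTOFit:
    """Joint (methylation, accessibility) maximum-likelihood fit from an
    FTO-minus / FTO-plus sample pair."""

    site: GenomicSite
    m_hat: float
    s_hat: float
    e_used: float
    loglik: float


@dataclass
class CallParams:
    """The published call funnel: coverage, FDR and exposed-level cutoffs."""

    min_coverage: int = 10
    fdr_threshold: float = 0.05
    exposed_threshold: float = 0.10
    mode: str = "ivt"
    exclusion_sites: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.mode not in ("ivt", "fto"):
            raise ValidationError(f"mode must be 'ivt' or 'fto', got {self.mode!r}")
        for name in ("fdr_threshold", "exposed_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.min_coverage < 0:
            raise ValidationError("min_coverage must be non-negative")
        if self.exclusion_sites is not None:
            self.exclusion_sites = frozenset(self.exclusion_sites)


@dataclass
class TranscriptAnnotation:
    """Exon structure of one transcript (0-based, half-open intervals)."""

    transcript_id: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValidationError(f"empty exon interval ({a}, {b}) in {self.transcript_id}")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValidationError(f"overlapping exons in {self.transcript_id}")

    def to_transcript_coord(self, genomic_pos: int) -> Optional[int]:
        """Spliced (exon-concatenated) coordinate of a genomic position.

        Returns ``None`` for intronic/outside positions.  Minus-strand
        transcripts count from the 3' end of the genomic span (5' of the
        transcript).
        """
        offset = 0
        hit = None
        for (a, b) in self.exons:
            if a <= genomic_pos < b:
                hit = offset + (genomic_pos - a)
                break
            offset += b - a
        if hit is None:
            return None
        if self.strand == "-":
            total = sum(b - a for a, b in self.exons)
            hit = total - 1 - hit
        return hit


@dataclass
class LoadBin:
    """A transcript's total methylation load and its tertile bin."""

    BINS = ("high", "medium", "low", "none")

    transcript_id: str
    load: float
    bin: str

    def __post_init__(self) -> None:
        if self.bin not in self.BINS:
            raise ValidationError(f"bin must be one of {self.BINS}, got {self.bin!r}")
        if self.load < 0:
            raise ValidationError("load must be non-negative")
        if (self.load == 0) != (self.bin == "none"):
            raise ValidationError("load == 0 exactly for the 'none' bin")
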