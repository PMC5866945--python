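"""Shared domain types for the array-design / QC / mapping / QTL pipeline.

Coordinates are 1-based inclusive throughout (VCF / GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")

#: Closed vocabulary for the genomic-region classification of a variant.
REGION_CLASSES = ("intergenic", "coding", "intronic")

#: Closed vocabulary for coding / splice effect labels.
EFFECT_LABELS = (
    "synonymous_coding",
    "nonsynonymous_coding",
    "stop_gained",
    "stop_lost",
    "synonymous_stop",
    "start_lost",
    "synonymous_start",
    "splice_site_donor",
    "splice_site_acceptor",
)

#: Closed vocabulary of Axiom-style SNP quality categories.
SNP_CATEGORIES = (
    "PolyHighResolution",
    "MonoHighResolution",
    "NoMinorHom",
    "HomHomResolution",
    "OTV",
    "CallRateBelowThreshold",
    "AAvarianceX",
    "AAvarianceY",
    "BBvarianceX",
    "BBvarianceY",
    "Other",
)

#: Genotype-call alphabet used in TSV files and its internal single-letter form.
CALL_TO_CODE = {"AA": "A", "BB": "B", "AB": "H", "NC": "U"}
CODE_TO_CALL = {v: k for k, v in CALL_TO_CODE.items()}


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene model with CDS exons (no UTR exons).

    ``exons`` are 1-based inclusive, strand-sorted ascending by start, and
    non-overlapping.  The CDS reading frame starts at the first base of the
    5'-most exon (last exon in genome coordinates for '-' strand genes).
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class SsrTract:
    """A perfect tandem repeat: 1-based inclusive span and its motif."""

    chrom: str
    start: int
    end: int
    motif: str


@dataclass
class SyntheticGenome:
    """A small multi-chromosome genome with genes and SSR tracts planted."""

    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    ssr_tracts: list[SsrTract] = field(default_factory=list)

    def sequence(self, chrom: str) -> str:
        return self.chromosomes[chrom]


@dataclass(frozen=True)
class VariantRecord:
    """One panel variant: position, alleles, site quality, allele counts.

    ``allele_counts`` holds observed counts per allele in REF-first order and
    sums to (2 x panel size) minus missing alleles.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    allele_counts: tuple[int, ...]
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if any(alt == self.ref for alt in self.alts):
            raise ValueError("alt allele equals ref")
        if len(self.allele_counts) != 1 + len(self.alts):
            raise ValueError("allele_counts must cover ref and every alt")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class ProbeCandidate:
    """A 71-mer design window centred on a SNP, with per-filter flags."""

    variant: VariantRecord
    window: str
    gc_fraction: float
    flags: dict[str, bool]
    region: str | None = None
    effect: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.window) != 71:
            raise ValueError("probe window must be exactly 71 bases")
        if self.window[35] != self.variant.ref:
            raise ValueError("window centre base must equal the ref allele")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")


@dataclass
class DesignReport:
    """Attrition accounting for the sequential design filters."""

    input_count: int
    removed: dict[str, int]
    survivor_count: int
    region_counts: dict[str, int] = field(default_factory=dict)
    effect_counts: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = self.survivor_count + sum(self.removed.values())
        if total != self.input_count:
            raise ValueError(
                f"attrition does not conserve: {self.input_count} in, "
                f"{self.survivor_count} out + {sum(self.removed.values())} removed"
            )

    def region_percentages(self) -> dict[str, float]:
        total = sum(self.region_counts.values())
        if total == 0:
            return {k: 0.0 for k in self.region_counts}
        return {k: 100.0 * v / total for k, v in self.region_counts.items()}


@dataclass(frozen=True)
class SampleQc:
    """Per-sample dish-QC value and genotype call rate, both in [0, 1]."""

    sample_id: str
    dqc: float
    call_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dqc <= 1.0 and 0.0 <= self.call_rate <= 1.0):
            raise ValueError("dqc and call_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterSummary:
    """Mean/SD of contrast (x) and size (y) for one genotype cluster."""

    genotype: str  # AA, AB, BB or OTV
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float


@dataclass
class SnpQcMetrics:
    """Per-SNP QC metrics computed from cluster summaries and calls."""

    snp_id: str
    call_rate: float
    n_clusters: int
    fld: float | None
    hom_fld: float | None
    het_so: float | None
    hom_ro: float | None
    var_x: dict[str, float]
    var_y: dict[str, float]
    minor_hom_count: int
    otv_flag: bool
    category: str | None = None


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point linkage estimate between a marker pair in a RIL population."""

    marker_i: str
    marker_j: str
    n_informative: int
    big_r: float  # observed recombinant fraction R
    r: float      # corrected meiotic recombination fraction
    lod: float


@dataclass
class LinkageGroup:
    """Ordered markers with cumulative Kosambi cM positions."""

    name: str
    markers: list[str]
    positions_cm: list[float]

    @property
    def length_cm(self) -> float:
        return self.positions_cm[-1] if self.positions_cm else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]

    @property
    def total_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)


@dataclass
class ScanProfile:
    """A genome scan for one trait in one environment: LOD / effect / PVE."""

    trait: str
    location: str
    year: str
    groups: list[str]
    positions_cm: list[float]
    lod: list[float]
    additive: list[float]
    pve: list[float]


@dataclass
class QtlResult:
    trait: str
    location: str
    year: str
    group: str
    peak_cm: float
    interval_cm: tuple[float, float]
    lod: float
    additive: float
    pve: float
    robust: bool = False
    stable: bool = False
    consistent: bool = False
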