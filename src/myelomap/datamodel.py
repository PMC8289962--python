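"""Domain types for optical-genome-mapping SV/CNV analysis.

Coordinates are 1-based inclusive throughout (the convention of Bionano
SMAP-style tables); BED input/output converts to and from 0-based half-open
at the I/O boundary.  Chromosome names are normalised to bare ``1``..``22``,
``X``, ``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "SV_TYPES",
    "PIPELINES",
    "SOMATIC_STATUSES",
    "CNV_SUPPORT_STATES",
    "SIZE_BINS",
    "ConfigurationError",
    "FormatError",
    "normalize_chrom",
    "GenomeModel",
    "load_genome_model",
    "GenomicBreakpoint",
    "SVCall",
    "CNVSegment",
    "GenePanel",
    "SampleMeta",
    "HighRiskLocus",
    "AnalysisConfig",
    "validate_call",
]

SV_TYPES = (
    "deletion",
    "insertion",
    "duplication",
    "inversion",
    "translocation_inter",
    "intra_rearrangement",
)
#: sized SV types whose two breakpoints delimit a genomic interval
SPAN_TYPES = ("deletion", "duplication", "inversion", "intra_rearrangement")
PIPELINES = ("de_novo", "rare_variant", "merged")
SOMATIC_STATUSES = ("unknown", "somatic_like", "polymorphic")
CNV_SUPPORT_STATES = ("none", "loss", "gain", "neutral", "unassessed")
SIZE_BINS = ("small", "medium", "large", "not_applicable")

_CHROM_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(_CHROM_ORDER)}


class ConfigurationError(ValueError):
    """Invalid analysis or simulation configuration."""


class FormatError(ValueError):
    """Malformed input table or file."""


def normalize_chrom(chrom: object) -> str:
    """Normalise a chromosome label to bare ``1``..``22``, ``X``, ``Y`` form.

    A leading ``chr`` prefix (any case) is stripped; numeric labels lose
    leading zeros; the label itself is not validated against a genome.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        c = str(int(c))
    return c.upper() if c.lower() in ("x", "y") else c


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Deterministic ordering: 1..22, X, Y, then anything else lexically."""
    c = normalize_chrom(chrom)
    return (_CHROM_RANK.get(c, len(_CHROM_ORDER)), c)


class GenomeModel(dict):
    """Mapping chromosome name -> length in bp (1-based inclusive coords)."""

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self, key=chrom_sort_key))

    def contains(self, chrom: str, pos: int) -> bool:
        c = normalize_chrom(chrom)
        return c in self and 1 <= pos <= self[c]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("myelomap").joinpath("data", name)))


def load_genome_model(source: object = "hg38") -> GenomeModel:
    """Load a genome model (chromosome -> length).

    Parameters
    ----------
    source
        ``"hg38"`` for the packaged GRCh38 chromosome-sizes table, a path to
        a two-column TSV (chrom, length), or a mapping.
    """
    if isinstance(source, Mapping):
        pairs = [(normalize_chrom(c), int(l)) for c, l in source.items()]
    else:
        if source == "hg38":
            path = _data_path("hg38_chrom_sizes.tsv")
        else:
            path = Path(str(source))
            if not path.exists():
                raise ConfigurationError(
                    f"unknown genome {source!r}: not 'hg38' and no such table file"
                )
        pairs = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"genome table line needs 2 columns: {line!r}")
            pairs.append((normalize_chrom(fields[0]), int(fields[1])))
    if not pairs:
        raise ConfigurationError("empty genome model")
    for c, l in pairs:
        if l <= 0:
            raise ConfigurationError(f"non-positive length for chromosome {c}")
    return GenomeModel(pairs)


@dataclass(frozen=True, order=True)
class GenomicBreakpoint:
    """A single breakpoint: chromosome and 1-based position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", int(self.pos))


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call.

    ``size_bp`` is absent only for interchromosomal translocations.  For
    insertions it is the inserted length and may exceed the breakpoint span
    (optical-map insertions are anchored between labels); for the other sized
    types it is expected to be consistent with the span.
    """

    call_id: str
    sample_id: str
    pipeline: str
    sv_type: str
    bp_a: GenomicBreakpoint
    bp_b: GenomicBreakpoint
    size_bp: Optional[int] = None
    vaf_pct: Optional[float] = None
    n_molecules: int = 0
    somatic_status: str = "unknown"
    cnv_support: str = "none"
    provenance: frozenset = frozenset()
    # optional annotations carried through the pipeline
    original_type: Optional[str] = None
    size_bin: Optional[str] = None
    clonality: Optional[str] = None
    n_genes: Optional[int] = None

    @property
    def span_bp(self) -> Optional[int]:
        """Breakpoint separation for same-chromosome calls, else ``None``."""
        if self.bp_a.chrom != self.bp_b.chrom:
            return None
        return abs(self.bp_b.pos - self.bp_a.pos)

    def interval(self) -> tuple[str, int, int]:
        """(chrom, lo, hi) of the same-chromosome span; raises otherwise."""
        if self.bp_a.chrom != self.bp_b.chrom:
            raise ValueError(f"{self.call_id}: interchromosomal call has no interval")
        lo, hi = sorted((self.bp_a.pos, self.bp_b.pos))
        return (self.bp_a.chrom, lo, hi)


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment, 1-based inclusive, integer copy number."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(
                f"CNV segment start {self.start} > end {self.end} "
                f"({self.sample_id} chr{self.chrom})"
            )
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenePanel:
    """Named set of gene intervals (1-based inclusive) with category tags."""

    name: str
    genes: list  # of (chrom, start, end, symbol)
    categories: dict = field(default_factory=dict)  # symbol -> frozenset of tags

    def __post_init__(self) -> None:
        symbols = [g[3] for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"panel {self.name}: duplicate symbols {dup[:5]}")
        for chrom, start, end, _ in self.genes:
            if start > end or start < 1:
                raise ValueError(f"panel {self.name}: invalid interval {chrom}:{start}-{end}")

    @property
    def symbols(self) -> frozenset:
        return frozenset(g[3] for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata; ``group`` is EMM or MM."""

    sample_id: str
    group: str
    infiltration_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("EMM", "MM"):
            raise ValueError(f"group must be EMM or MM, got {self.group!r}")


@dataclass(frozen=True)
class HighRiskLocus:
    """A recurrently prognostic myeloma region (e.g. TP53_17p13, GAIN_1q21)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end or self.start < 1:
            raise ValueError(f"locus {self.name}: invalid interval {self.start}-{self.end}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every threshold of the analysis procedure.

    Published thresholds (defaults): VAF filter strictly > 5 %, molecule
    support >= 10, subclonal iff VAF <= 25 %, SV size floor 500 bp, small
    deletions up to 50 kbp, medium events up to 5 Mbp, and same-chromosome
    calls with breakpoints >= 5 Mbp apart re-typed as intrachromosomal
    rearrangements.  The remaining tolerances are gap-filling plumbing with
    declared defaults.
    """

    min_vaf_pct: float = 5.0
    min_molecules: int = 10
    clonal_cutoff_pct: float = 25.0
    sv_min_size_bp: int = 500
    small_max_bp: int = 50_000
    medium_max_bp: int = 5_000_000
    intra_span_bp: int = 5_000_000
    merge_bp_tolerance_bp: int = 10_000
    merge_reciprocal_overlap: float = 0.5
    control_match_tolerance_bp: int = 10_000
    complex_link_window_bp: int = 1_000_000
    cnv_support_flank_bp: int = 50_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_vaf_pct < self.clonal_cutoff_pct <= 100):
            raise ConfigurationError(
                "need 0 < min_vaf_pct < clonal_cutoff_pct <= 100, got "
                f"{self.min_vaf_pct}, {self.clonal_cutoff_pct}"
            )
        if not (self.sv_min_size_bp < self.small_max_bp < self.medium_max_bp <= self.intra_span_bp):
            raise ConfigurationError(
                "need sv_min_size_bp < small_max_bp < medium_max_bp <= intra_span_bp"
            )
        for name in (
            "merge_bp_tolerance_bp",
            "control_match_tolerance_bp",
            "complex_link_window_bp",
            "cnv_support_flank_bp",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0 < self.merge_reciprocal_overlap <= 1):
            raise ConfigurationError("merge_reciprocal_overlap must be in (0, 1]")


# size-vs-span consistency slack for non-insertion sized types: optical-map
# coordinates are label-anchored, so the printed event size may differ from
# the breakpoint span; only a size clearly exceeding the span is flagged.
_SIZE_SLACK_BP = 1000
_SIZE_SLACK_FRAC = 0.05


def validate_call(call: SVCall, genome: GenomeModel) -> list:
    """Return a list of invariant-violation descriptions (empty iff valid).

    Total: never raises, whatever the field values.
    """
    violations: list[str] = []
    try:
        if call.sv_type not in SV_TYPES:
            violations.append(f"unknown sv_type {call.sv_type!r}")
        if call.pipeline not in PIPELINES:
            violations.append(f"unknown pipeline {call.pipeline!r}")
        for label, bp in (("bp_a", call.bp_a), ("bp_b", call.bp_b)):
            if bp.chrom not in genome:
                violations.append(f"{label}: chromosome {bp.chrom!r} not in genome model")
            elif not 1 <= bp.pos <= genome[bp.chrom]:
                violations.append(
                    f"{label}: position {bp.pos} outside chr{bp.chrom} "
                    f"(length {genome[bp.chrom]})"
                )
        if call.sv_type == "translocation_inter":
            if call.bp_a.chrom == call.bp_b.chrom:
                violations.append("translocation_inter breakpoints on one chromosome")
        elif call.sv_type in SV_TYPES:
            if call.bp_a.chrom != call.bp_b.chrom:
                violations.append(f"{call.sv_type} breakpoints on different chromosomes")
            elif call.bp_a.pos > call.bp_b.pos:
                violations.append("bp_a.pos > bp_b.pos for same-chromosome call")
            if call.size_bp is None:
                violations.append(f"size_bp absent for {call.sv_type}")
        if call.size_bp is not None:
            if call.size_bp < 0:
                violations.append(f"negative size_bp {call.size_bp}")
            elif (
                call.sv_type in SPAN_TYPES
                and call.bp_a.chrom == call.bp_b.chrom
            ):
                span = abs(call.bp_b.pos - call.bp_a.pos)
                if call.size_bp > span + max(_SIZE_SLACK_BP, _SIZE_SLACK_FRAC * span):
                    violations.append(
                        f"size_bp {call.size_bp} inconsistent with span {span}"
                    )
        if call.vaf_pct is not None and not 0 <= call.vaf_pct <= 100:
            violations.append(f"vaf_pct {call.vaf_pct} outside [0, 100]")
        if call.n_molecules < 0:
            violations.append(f"negative n_molecules {call.n_molecules}")
        if call.somatic_status not in SOMATIC_STATUSES:
            violations.append(f"unknown somatic_status {call.somatic_status!r}")
        if call.cnv_support not in CNV_SUPPORT_STATES:
            violations.append(f"unknown cnv_support {call.cnv_support!r}")
        if not set(call.provenance) <= {"de_novo", "rare_variant"}:
            violations.append(f"invalid provenance {set(call.provenance)!r}")
    except Exception as exc:  # totality: report, never raise
        violations.append(f"unvalidatable call: {exc!r}")
    return violations


def effective_provenance(call: SVCall) -> frozenset:
    """Provenance of a call, inferred from its pipeline when unset."""
    if call.provenance:
        return frozenset(call.provenance)
    if call.pipeline in ("de_novo", "rare_variant"):
        return frozenset({call.pipeline})
    return frozenset()


def sort_calls(calls: Iterable[SVCall]) -> list:
    """Deterministic genomic ordering of calls."""
    return sorted(
        calls,
        key=lambda c: (
            c.sample_id,
            chrom_sort_key(c.bp_a.chrom),
            c.bp_a.pos,
            chrom_sort_key(c.bp_b.chrom),
            c.bp_b.pos,
            c.sv_type,
            c.call_id,
        ),
    )
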