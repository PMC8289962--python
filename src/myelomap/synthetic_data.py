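"""Synthetic cohort generator with ground truth.

No patient-level optical-mapping callsets are publicly deposited for this
disease setting, so every pipeline stage is exercised on simulated inputs
that carry the statistical structure the analysis assumes:

* paired caller outputs (de novo / rare variant) sharing true events, with
  per-caller breakpoint jitter, sensitivity, detection floors (the de novo
  assembly pipeline calls events from 500 bp but needs a substantial allele
  fraction; the rare-variant pipeline calls events from 5 kbp down to 5 %
  VAF) and false calls;
* germline-like polymorphisms shared by every sample and present in the
  control-SV database, so the somatic filter can be scored against truth;
* VAF mixtures spanning the subclonal (5–25 %) and clonal (25–50 %) ranges;
* group structure: every EMM sample carries chromosome-1 intrachromosomal
  rearrangements (span >= 5 Mbp) plus an excess of small deletions, while MM
  samples carry more interchromosomal translocations, including
  three-chromosome complex chains;
* copy-number profiles consistent with the large rearrangements (deletions
  over CN = 1 segments, insertions over CN = 3, inversions copy-neutral).

Event counts are Poisson, sizes log-uniform within per-type ranges, and
positions uniform (length-weighted) outside the masked subtelomeric flanks;
chromosome-1 rearrangements in EMM are beta-skewed towards the p arm.  All
output is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .datamodel import (
    AnalysisConfig,
    CNVSegment,
    ConfigurationError,
    GenePanel,
    GenomeModel,
    GenomicBreakpoint,
    SampleMeta,
    SVCall,
    load_genome_model,
)
from .io_formats import write_bed, write_cnv_table, write_sv_table
from .merge_filter import ControlRecord, ControlSVDatabase

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthSet",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_gene_panel",
    "simulate_panel_suite",
    "write_cohort",
]

_SOMATIC_CHROMS = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings; defaults mirror the published cohort conditions
    (4 EMM / 7 MM; somatic deletion medians 45 vs 34 with the small-deletion
    excess 37 vs 24 in EMM; ~18 insertions, ~3 inversions, ~3 duplications
    per patient; 1–4 chromosome-1 rearrangements per EMM sample; complex
    3-chromosome chains in about 4/7 of MM)."""

    n_emm: int = 4
    n_mm: int = 7
    deletion_mean_emm: float = 45.0
    deletion_mean_mm: float = 34.0
    small_deletion_share_emm: float = 37.0 / 45.0
    small_deletion_share_mm: float = 24.0 / 34.0
    insertion_mean: float = 18.0
    inversion_mean: float = 3.0
    duplication_mean: float = 3.0
    translocation_mean_emm: float = 1.25
    translocation_mean_mm: float = 3.0
    complex_prob_mm: float = 4.0 / 7.0
    emm_chr1_intra_min: int = 1
    emm_chr1_intra_max: int = 4
    other_intra_mean: float = 1.0
    clonal_share: float = 0.5
    subclonal_vaf_range: tuple = (5.5, 25.0)
    clonal_vaf_range: tuple = (25.5, 49.0)
    n_polymorphisms: int = 30
    extra_cnv_mean: float = 2.0
    de_novo_jitter_sd_bp: float = 500.0
    rare_variant_jitter_sd_bp: float = 300.0
    de_novo_sensitivity: float = 0.95
    rare_variant_sensitivity: float = 0.95
    de_novo_false_calls: float = 5.0
    rare_variant_false_calls: float = 5.0
    de_novo_min_size_bp: int = 500
    de_novo_min_vaf_pct: float = 20.0
    rare_variant_min_size_bp: int = 5_000
    rare_variant_min_vaf_pct: float = 5.0
    mask_flank_bp: int = 1_000_000
    min_event_gap_bp: int = 100_000
    n_panel_genes: int = 800
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ConfigurationError("rng_seed is mandatory for reproducibility")
        for name in (
            "deletion_mean_emm",
            "deletion_mean_mm",
            "insertion_mean",
            "inversion_mean",
            "duplication_mean",
            "translocation_mean_emm",
            "translocation_mean_mm",
            "other_intra_mean",
            "extra_cnv_mean",
            "de_novo_false_calls",
            "rare_variant_false_calls",
            "de_novo_jitter_sd_bp",
            "rare_variant_jitter_sd_bp",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in (
            "small_deletion_share_emm",
            "small_deletion_share_mm",
            "complex_prob_mm",
            "clonal_share",
            "de_novo_sensitivity",
            "rare_variant_sensitivity",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_emm < 0 or self.n_mm < 0 or self.n_emm + self.n_mm == 0:
            raise ConfigurationError("cohort must contain at least one sample")
        if not 1 <= self.emm_chr1_intra_min <= self.emm_chr1_intra_max:
            raise ConfigurationError("need 1 <= emm_chr1_intra_min <= emm_chr1_intra_max")

    @classmethod
    def noiseless(cls, rng_seed: int = 0, **overrides) -> "SimulationConfig":
        """Zero jitter, perfect sensitivity, no false calls, no caller VAF
        floor — under these settings the pipeline output must equal the
        planted somatic truth exactly."""
        params = dict(
            de_novo_jitter_sd_bp=0.0,
            rare_variant_jitter_sd_bp=0.0,
            de_novo_sensitivity=1.0,
            rare_variant_sensitivity=1.0,
            de_novo_false_calls=0.0,
            rare_variant_false_calls=0.0,
            de_novo_min_vaf_pct=0.0,
            rng_seed=rng_seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class TruthEvent:
    """One planted event with its expected downstream classification."""

    event_id: str
    sample_id: str
    sv_type: str
    bp_a: GenomicBreakpoint
    bp_b: GenomicBreakpoint
    size_bp: Optional[int]
    vaf_pct: float
    n_molecules: int
    somatic: bool
    expected_cnv_support: str = "none"
    group_driver: Optional[str] = None
    complex_id: Optional[str] = None


@dataclass
class TruthSet:
    """Planted events plus a trace from every emitted caller call back to
    its truth event (or to a false-call marker)."""

    events: list
    call_trace: dict  # call_id -> event_id | "false"

    def somatic_events(self, sample_id: Optional[str] = None) -> list:
        return [
            e
            for e in self.events
            if e.somatic and (sample_id is None or e.sample_id == sample_id)
        ]


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the truth."""

    de_novo: dict  # sample_id -> list[SVCall]
    rare_variant: dict
    cnv: list  # CNVSegment
    control_db: ControlSVDatabase
    panels: list  # GenePanel
    masks: list  # (chrom, start, end) 1-based inclusive
    meta: list  # SampleMeta
    truth: TruthSet
    sample_ids: tuple
    config: SimulationConfig


# log-uniform size ranges per event type (bp)
_SIZE_RANGES = {
    ("deletion", "small"): (500, 50_000),
    ("deletion", "large"): (50_001, 3_000_000),
    ("insertion", None): (500, 20_000),
    ("inversion", None): (5_000, 3_000_000),
    ("duplication", None): (10_000, 1_000_000),
    ("intra", None): (6_000_000, 60_000_000),
}


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


class _Placer:
    """Non-overlapping event placement outside masked flanks."""

    def __init__(self, genome: GenomeModel, flank_bp: int, gap_bp: int, rng: np.random.Generator):
        self.genome = genome
        self.flank = flank_bp
        self.gap = gap_bp
        self.rng = rng
        self.occupied: dict = {}

    def _free(self, chrom: str, lo: int, hi: int) -> bool:
        return all(
            hi + self.gap < a or lo - self.gap > b for a, b in self.occupied.get(chrom, ())
        )

    def reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.occupied.setdefault(chrom, []).append((lo, hi))

    def place(self, chrom: str, span: int, p_arm_skew: bool = False) -> Optional[tuple]:
        """Return (lo, hi) for an event of the given span, or None if the
        chromosome cannot host it."""
        length = self.genome[chrom]
        lo_min = self.flank + 1
        lo_max = length - self.flank - span
        if lo_max <= lo_min:
            return None
        for _ in range(200):
            if p_arm_skew:
                lo = int(lo_min + self.rng.beta(2.0, 5.0) * (lo_max - lo_min))
            else:
                lo = int(self.rng.integers(lo_min, lo_max + 1))
            hi = lo + span
            if self._free(chrom, lo, hi):
                self.reserve(chrom, lo, hi)
                return lo, hi
        return None

    def random_chrom(self, exclude: tuple = ()) -> str:
        chroms = [c for c in _SOMATIC_CHROMS if c not in exclude]
        weights = np.array([self.genome[c] for c in chroms], dtype=float)
        return str(self.rng.choice(chroms, p=weights / weights.sum()))


def _draw_vaf(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    lo, hi = (
        cfg.clonal_vaf_range if rng.random() < cfg.clonal_share else cfg.subclonal_vaf_range
    )
    return float(round(rng.uniform(lo, hi), 2))


def simulate_gene_panel(
    n_genes: int, genome: Optional[GenomeModel] = None, seed: int = 0, name: str = "panel"
) -> GenePanel:
    """Random panel of non-overlapping gene intervals, reproducible by seed.

    Genes are apportioned to chromosomes by length and placed in per-gene
    slots, so intervals never overlap.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    genome = genome or load_genome_model("hg38")
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome.chromosomes if c in _SOMATIC_CHROMS]
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    per_chrom = np.floor(lengths / lengths.sum() * n_genes).astype(int)
    k = 0
    while per_chrom.sum() < n_genes:  # distribute the remainder
        per_chrom[k % len(chroms)] += 1
        k += 1
    genes = []
    idx = 0
    min_len, max_len = 2_000, 200_000
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        slot = genome[chrom] // count
        if slot <= min_len + 1:
            raise ConfigurationError(
                f"{count} genes exceed the packable capacity of chr{chrom}"
            )
        for j in range(count):
            length = int(rng.integers(min_len, min(max_len, slot - 1)))
            start = int(j * slot + rng.integers(1, slot - length))
            genes.append((chrom, start, start + length - 1, f"G{idx:05d}"))
            idx += 1
    return GenePanel(name=name, genes=genes)


_PANEL_PROPORTIONS = {
    "cancer": 0.50,
    "cell_cycle": 0.45,
    "inflammation": 0.20,
    "bone_metabolism": 0.10,
    "mm": 0.05,
}


def simulate_panel_suite(
    n_genes: int = 800,
    genome: Optional[GenomeModel] = None,
    seed: int = 0,
    proportions: Optional[dict] = None,
) -> list:
    """Overlapping keyword-style panels drawn from one gene universe.

    Each universe gene joins each panel independently with the panel's
    membership proportion, emulating keyword panels that share genes.
    """
    proportions = proportions or dict(_PANEL_PROPORTIONS)
    universe = simulate_gene_panel(n_genes, genome=genome, seed=seed, name="universe")
    rng = np.random.default_rng(seed + 1)
    panels = []
    for name, prop in proportions.items():
        member = rng.random(len(universe.genes)) < prop
        genes = [g for g, take in zip(universe.genes, member) if take]
        if not genes:  # guarantee non-empty panels
            genes = [universe.genes[int(rng.integers(len(universe.genes)))]]
        panels.append(
            GenePanel(
                name=name,
                genes=genes,
                categories={g[3]: frozenset({name}) for g in genes},
            )
        )
    return panels


def _somatic_truth_for_sample(
    sample: SampleMeta,
    cfg: SimulationConfig,
    placer: _Placer,
    rng: np.random.Generator,
    next_id,
) -> tuple:
    """Plant one sample's somatic events; returns (events, cnv_segments)."""
    events: list[TruthEvent] = []
    cnv: list[CNVSegment] = []
    is_emm = sample.group == "EMM"

    def add_event(sv_type, chrom, lo, hi, size, driver=None, cnv_support="none", complex_id=None):
        events.append(
            TruthEvent(
                event_id=next_id(),
                sample_id=sample.sample_id,
                sv_type=sv_type,
                bp_a=GenomicBreakpoint(chrom if sv_type != "translocation_inter" else lo[0], lo if sv_type != "translocation_inter" else lo[1]),
                bp_b=GenomicBreakpoint(chrom if sv_type != "translocation_inter" else hi[0], hi if sv_type != "translocation_inter" else hi[1]),
                size_bp=size,
                vaf_pct=_draw_vaf(rng, cfg),
                n_molecules=int(rng.integers(10, 61)),
                somatic=True,
                expected_cnv_support=cnv_support,
                group_driver=driver,
                complex_id=complex_id,
            )
        )

    def plant_intra(chrom: str, driver: Optional[str]) -> None:
        span = _log_uniform(rng, *_SIZE_RANGES[("intra", None)])
        placed = placer.place(chrom, span, p_arm_skew=(chrom == "1"))
        if placed is None:
            return
        lo, hi = placed
        kind = str(rng.choice(["deletion", "insertion", "inversion"], p=[0.5, 0.25, 0.25]))
        if kind == "deletion":
            support = "loss"
            cnv.append(CNVSegment(sample.sample_id, chrom, lo, hi, 1))
        elif kind == "insertion":
            support = "gain"
            cnv.append(CNVSegment(sample.sample_id, chrom, lo, hi, 3))
        else:
            support = "neutral"
        add_event(kind, chrom, lo, hi, span, driver=driver, cnv_support=support)

    # chromosome-1 rearrangements drive the EMM phenotype
    if is_emm:
        for _ in range(int(rng.integers(cfg.emm_chr1_intra_min, cfg.emm_chr1_intra_max + 1))):
            plant_intra("1", driver="emm_chr1_intra")
    for _ in range(rng.poisson(cfg.other_intra_mean)):
        plant_intra(placer.random_chrom(exclude=("1",)), driver=None)

    # deletions with the group-specific small-size excess
    del_mean = cfg.deletion_mean_emm if is_emm else cfg.deletion_mean_mm
    small_share = cfg.small_deletion_share_emm if is_emm else cfg.small_deletion_share_mm
    n_del = rng.poisson(del_mean)
    n_small = rng.binomial(n_del, small_share)
    for i in range(n_del):
        size_key = ("deletion", "small" if i < n_small else "large")
        size = _log_uniform(rng, *_SIZE_RANGES[size_key])
        chrom = placer.random_chrom()
        placed = placer.place(chrom, size)
        if placed is None:
            continue
        lo, hi = placed
        add_event("deletion", chrom, lo, hi, hi - lo, driver="small_deletion_excess" if i < n_small else None)

    for sv_type, mean in (
        ("insertion", cfg.insertion_mean),
        ("inversion", cfg.inversion_mean),
        ("duplication", cfg.duplication_mean),
    ):
        for _ in range(rng.poisson(mean)):
            size = _log_uniform(rng, *_SIZE_RANGES[(sv_type, None)])
            chrom = placer.random_chrom()
            span = 100 if sv_type == "insertion" else size  # insertions anchor between labels
            placed = placer.place(chrom, span)
            if placed is None:
                continue
            lo, hi = placed
            add_event(sv_type, chrom, lo, hi, size)

    # interchromosomal translocations; MM may carry a 3-chromosome chain
    def plant_translocation(chrom_a, pos_a, chrom_b, pos_b, complex_id=None, driver=None):
        (ca, pa), (cb, pb) = sorted(
            [(chrom_a, pos_a), (chrom_b, pos_b)], key=lambda t: (len(t[0]), t[0], t[1])
        )
        add_event(
            "translocation_inter", None, (ca, pa), (cb, pb), None,
            driver=driver, complex_id=complex_id,
        )

    def random_breakpoint(chrom: str) -> Optional[int]:
        placed = placer.place(chrom, 1)
        return None if placed is None else placed[0]

    t_mean = cfg.translocation_mean_emm if is_emm else cfg.translocation_mean_mm
    for _ in range(rng.poisson(t_mean)):
        ca = placer.random_chrom()
        cb = placer.random_chrom(exclude=(ca,))
        pa, pb = random_breakpoint(ca), random_breakpoint(cb)
        if pa is None or pb is None:
            continue
        plant_translocation(ca, pa, cb, pb)
    if not is_emm and rng.random() < cfg.complex_prob_mm:
        hub = placer.random_chrom()
        others = [placer.random_chrom(exclude=(hub,))]
        others.append(placer.random_chrom(exclude=(hub, others[0])))
        hub_pos = random_breakpoint(hub)
        if hub_pos is not None:
            complex_id = f"{sample.sample_id}_cx"
            for other in others:
                other_pos = random_breakpoint(other)
                linked = hub_pos + int(rng.integers(10_000, 400_000))
                if other_pos is None:
                    continue
                plant_translocation(hub, linked, other, other_pos,
                                    complex_id=complex_id, driver="mm_complex_chain")

    # benign-looking extra CNV segments (not tied to an SV call)
    for _ in range(rng.poisson(cfg.extra_cnv_mean)):
        size = _log_uniform(rng, 1_000_000, 10_000_000)
        chrom = placer.random_chrom()
        placed = placer.place(chrom, size)
        if placed is None:
            continue
        lo, hi = placed
        cnv.append(CNVSegment(sample.sample_id, chrom, lo, hi, int(rng.choice([1, 3]))))

    return events, cnv


def _emit_caller_calls(
    events: Iterable[TruthEvent],
    pipeline: str,
    cfg: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
    trace: dict,
) -> list:
    jitter_sd = cfg.de_novo_jitter_sd_bp if pipeline == "de_novo" else cfg.rare_variant_jitter_sd_bp
    sens = cfg.de_novo_sensitivity if pipeline == "de_novo" else cfg.rare_variant_sensitivity
    min_size = cfg.de_novo_min_size_bp if pipeline == "de_novo" else cfg.rare_variant_min_size_bp
    min_vaf = cfg.de_novo_min_vaf_pct if pipeline == "de_novo" else cfg.rare_variant_min_vaf_pct
    calls = []
    for ev in events:
        detectable = (ev.size_bp is None or ev.size_bp >= min_size) and ev.vaf_pct >= min_vaf
        if not detectable or rng.random() >= sens:
            continue

        def jitter(bp: GenomicBreakpoint) -> GenomicBreakpoint:
            if jitter_sd == 0:
                return bp
            pos = int(round(bp.pos + rng.normal(0.0, jitter_sd)))
            return GenomicBreakpoint(bp.chrom, min(max(pos, 1), genome[bp.chrom]))

        bp_a, bp_b = jitter(ev.bp_a), jitter(ev.bp_b)
        if bp_a.chrom == bp_b.chrom and bp_a.pos > bp_b.pos:
            bp_a, bp_b = bp_b, bp_a
        if ev.sv_type == "insertion" or ev.sv_type == "translocation_inter":
            size = ev.size_bp
        else:
            size = abs(bp_b.pos - bp_a.pos)
        call_id = f"{ev.sample_id}|{pipeline}|{ev.event_id}"
        trace[call_id] = ev.event_id
        calls.append(
            SVCall(
                call_id=call_id,
                sample_id=ev.sample_id,
                pipeline=pipeline,
                sv_type=ev.sv_type,
                bp_a=bp_a,
                bp_b=bp_b,
                size_bp=size,
                vaf_pct=ev.vaf_pct,
                n_molecules=ev.n_molecules,
                provenance=frozenset({pipeline}),
            )
        )
    return calls


def _emit_false_calls(
    sample_id: str,
    pipeline: str,
    cfg: SimulationConfig,
    placer: _Placer,
    rng: np.random.Generator,
    trace: dict,
) -> list:
    rate = cfg.de_novo_false_calls if pipeline == "de_novo" else cfg.rare_variant_false_calls
    calls = []
    for k in range(rng.poisson(rate)):
        sv_type = str(rng.choice(["deletion", "insertion", "duplication", "inversion"]))
        size = _log_uniform(rng, 500, 100_000)
        chrom = placer.random_chrom()
        placed = placer.place(chrom, size if sv_type != "insertion" else 100)
        if placed is None:
            continue
        lo, hi = placed
        call_id = f"{sample_id}|{pipeline}|F{k:03d}"
        trace[call_id] = "false"
        calls.append(
            SVCall(
                call_id=call_id,
                sample_id=sample_id,
                pipeline=pipeline,
                sv_type=sv_type,
                bp_a=GenomicBreakpoint(chrom, lo),
                bp_b=GenomicBreakpoint(chrom, hi),
                size_bp=size if sv_type == "insertion" else hi - lo,
                vaf_pct=float(round(rng.uniform(2.0, 40.0), 2)),
                n_molecules=int(rng.integers(3, 50)),
                provenance=frozenset({pipeline}),
            )
        )
    return calls


def simulate_cohort(
    cfg: Optional[SimulationConfig] = None,
    genome: Optional[GenomeModel] = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort with truth labels.

    Deterministic given ``cfg.rng_seed``.  Invalid configurations raise
    before any output is produced.
    """
    cfg = cfg or SimulationConfig()
    genome = genome or load_genome_model("hg38")
    rng = np.random.default_rng(cfg.rng_seed)

    meta = [SampleMeta(f"EMM{i + 1}", "EMM") for i in range(cfg.n_emm)] + [
        SampleMeta(f"MM{i + 1}", "MM") for i in range(cfg.n_mm)
    ]
    masks = []
    for chrom in _SOMATIC_CHROMS:
        masks.append((chrom, 1, cfg.mask_flank_bp))
        masks.append((chrom, genome[chrom] - cfg.mask_flank_bp + 1, genome[chrom]))

    counter = {"n": 0}

    def next_id() -> str:
        counter["n"] += 1
        return f"T{counter['n']:05d}"

    # shared polymorphisms: same coordinates in every sample and in the DB
    poly_placer = _Placer(genome, cfg.mask_flank_bp, cfg.min_event_gap_bp, rng)
    poly_template = []
    for _ in range(cfg.n_polymorphisms):
        sv_type = str(rng.choice(["deletion", "insertion", "duplication"]))
        size = _log_uniform(rng, 500, 60_000)
        chrom = poly_placer.random_chrom()
        placed = poly_placer.place(chrom, size if sv_type != "insertion" else 100)
        if placed is None:
            continue
        lo, hi = placed
        poly_template.append(
            (sv_type, chrom, lo, hi, size if sv_type == "insertion" else hi - lo)
        )
    control_db = ControlSVDatabase(
        records=[
            ControlRecord(
                sv_type=t,
                bp_a=GenomicBreakpoint(c, lo),
                bp_b=GenomicBreakpoint(c, hi),
                size_bp=size,
            )
            for t, c, lo, hi, size in poly_template
        ]
    )

    events: list[TruthEvent] = []
    cnv: list[CNVSegment] = []
    trace: dict = {}
    de_novo: dict = {}
    rare_variant: dict = {}
    for sample in meta:
        placer = _Placer(genome, cfg.mask_flank_bp, cfg.min_event_gap_bp, rng)
        placer.occupied = {c: list(v) for c, v in poly_placer.occupied.items()}
        sample_events = [
            TruthEvent(
                event_id=next_id(),
                sample_id=sample.sample_id,
                sv_type=t,
                bp_a=GenomicBreakpoint(c, lo),
                bp_b=GenomicBreakpoint(c, hi),
                size_bp=size,
                vaf_pct=float(round(rng.uniform(40.0, 50.0), 2)),
                n_molecules=int(rng.integers(10, 61)),
                somatic=False,
            )
            for t, c, lo, hi, size in poly_template
        ]
        somatic, sample_cnv = _somatic_truth_for_sample(sample, cfg, placer, rng, next_id)
        sample_events.extend(somatic)
        events.extend(sample_events)
        cnv.extend(sample_cnv)
        de_novo[sample.sample_id] = _emit_caller_calls(
            sample_events, "de_novo", cfg, genome, rng, trace
        ) + _emit_false_calls(sample.sample_id, "de_novo", cfg, placer, rng, trace)
        rare_variant[sample.sample_id] = _emit_caller_calls(
            sample_events, "rare_variant", cfg, genome, rng, trace
        ) + _emit_false_calls(sample.sample_id, "rare_variant", cfg, placer, rng, trace)

    panels = simulate_panel_suite(cfg.n_panel_genes, genome=genome, seed=cfg.rng_seed)
    return SimulatedCohort(
        de_novo=de_novo,
        rare_variant=rare_variant,
        cnv=cnv,
        control_db=control_db,
        panels=panels,
        masks=masks,
        meta=meta,
        truth=TruthSet(events=events, call_trace=trace),
        sample_ids=tuple(m.sample_id for m in meta),
        config=cfg,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write every pipeline input (SV-TSV, CNV TSV, BED, meta, truth JSON)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pipeline, table in (("de_novo", cohort.de_novo), ("rare_variant", cohort.rare_variant)):
        calls = [c for sample in cohort.sample_ids for c in table[sample]]
        paths[pipeline] = write_sv_table(calls, outdir / f"{pipeline}.tsv")
    paths["cnv"] = write_cnv_table(cohort.cnv, outdir / "cnv.tsv")
    control_calls = [
        SVCall(
            call_id=f"ctrl_{k}",
            sample_id="control",
            pipeline="merged",
            sv_type=r.sv_type,
            bp_a=r.bp_a,
            bp_b=r.bp_b,
            size_bp=r.size_bp,
        )
        for k, r in enumerate(cohort.control_db.records)
    ]
    paths["control_db"] = write_sv_table(control_calls, outdir / "control_db.tsv")
    with open(outdir / "masks.bed", "w") as fh:
        for chrom, start, end in cohort.masks:
            fh.write(f"chr{chrom}\t{start - 1}\t{end}\tmask\n")
    paths["masks"] = outdir / "masks.bed"
    panel_dir = outdir / "panels"
    panel_dir.mkdir(exist_ok=True)
    for panel in cohort.panels:
        write_bed(panel, panel_dir / f"{panel.name}.bed")
    paths["panels"] = panel_dir
    meta_frame = pd.DataFrame(
        [{"sample_id": m.sample_id, "group": m.group} for m in cohort.meta]
    )
    meta_frame.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    paths["meta"] = outdir / "meta.tsv"
    truth = {
        "events": [
            {
                **{k: v for k, v in asdict(ev).items() if k not in ("bp_a", "bp_b")},
                "bp_a": [ev.bp_a.chrom, ev.bp_a.pos],
                "bp_b": [ev.bp_b.chrom, ev.bp_b.pos],
            }
            for ev in cohort.truth.events
        ],
        "call_trace": cohort.truth.call_trace,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = outdir / "truth.json"
    return paths
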