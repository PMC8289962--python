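"""Stage 2: size bins, clonality, intrachromosomal-rearrangement calling with
copy-number support, complex-rearrangement detection and high-risk-locus
flagging.

Size classes follow the published bins: small 500 bp–50 kbp, medium
50 kbp–5 Mbp (half-open on the left), large > 5 Mbp; events below 500 bp are
sub-threshold.  A same-chromosome call whose breakpoints are at least 5 Mbp
apart is re-typed as an intrachromosomal rearrangement and typed by its
copy-number context: deletion-like when supported by copy-number loss,
insertion-like by gain, inversion-like when copy-neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import networkx as nx

from .datamodel import (
    AnalysisConfig,
    CNVSegment,
    HighRiskLocus,
    SVCall,
    _data_path,
)
from .io_formats import read_bed

__all__ = [
    "ComplexRearrangement",
    "RiskFlagMatrix",
    "assign_size_bin",
    "classify_clonality",
    "call_intrachromosomal_rearrangements",
    "detect_complex_rearrangements",
    "flag_high_risk_loci",
    "load_default_high_risk_loci",
    "classify_calls",
]

FLAGS = ("sv", "cnv_loss", "cnv_gain", "translocation")


@dataclass(frozen=True)
class ComplexRearrangement:
    """A chain of linked translocations touching >= 3 chromosomes."""

    sample_id: str
    member_call_ids: tuple
    chromosomes: frozenset

    def __post_init__(self) -> None:
        if len(self.member_call_ids) < 2 or len(self.chromosomes) < 3:
            raise ValueError("complex rearrangement needs >= 2 members over >= 3 chromosomes")


@dataclass
class RiskFlagMatrix:
    """Per (sample, locus) flag sets; every cell is present (possibly empty)."""

    samples: tuple
    loci: tuple  # HighRiskLocus
    _flags: dict  # (sample_id, locus_name) -> frozenset

    def flags(self, sample_id: str, locus_name: str) -> frozenset:
        return self._flags[(sample_id, locus_name)]

    def to_frame(self):
        import pandas as pd

        data = {
            locus.name: [
                ",".join(sorted(self._flags[(s, locus.name)])) or "none" for s in self.samples
            ]
            for locus in self.loci
        }
        return pd.DataFrame(data, index=list(self.samples))

    def to_dict(self) -> dict:
        return {
            s: {l.name: sorted(self._flags[(s, l.name)]) for l in self.loci}
            for s in self.samples
        }


def assign_size_bin(call: SVCall, config: Optional[AnalysisConfig] = None) -> Optional[str]:
    """Size class of a call: small / medium / large / not_applicable.

    Interchromosomal translocations have no size and map to
    ``not_applicable``.  Sub-threshold sizes (< 500 bp by default) are not
    binned: a warning is emitted and ``None`` returned so batch callers can
    filter them out.
    """
    config = config or AnalysisConfig()
    if call.sv_type == "translocation_inter":
        return "not_applicable"
    if call.size_bp is None:
        raise ValueError(f"{call.call_id}: size_bp absent for {call.sv_type}")
    if call.size_bp < config.sv_min_size_bp:
        warnings.warn(
            f"{call.call_id}: size {call.size_bp} bp below the {config.sv_min_size_bp} bp "
            "detection floor; not binned",
            stacklevel=2,
        )
        return None
    if call.size_bp <= config.small_max_bp:
        return "small"
    if call.size_bp <= config.medium_max_bp:
        return "medium"
    return "large"


def classify_clonality(call: SVCall, config: Optional[AnalysisConfig] = None) -> str:
    """``subclonal`` iff VAF <= the clonal cutoff (25 % default), else ``clonal``."""
    config = config or AnalysisConfig()
    if call.vaf_pct is None:
        raise ValueError(f"{call.call_id}: VAF missing, clonality undefined")
    return "subclonal" if call.vaf_pct <= config.clonal_cutoff_pct else "clonal"


def _majority_cn_state(
    segments: list, lo: int, hi: int, flank_bp: int
) -> str:
    """Length-weighted majority CN state (loss/gain/neutral) over [lo, hi].

    The span is trimmed by ``flank_bp`` at each end (breakpoint-edge segments
    are noisy); uncovered bases count as neutral (CN = 2).  Ties resolve to
    neutral.
    """
    t_lo, t_hi = lo + flank_bp, hi - flank_bp
    if t_lo > t_hi:  # span shorter than the flanks: use the untrimmed span
        t_lo, t_hi = lo, hi
    total = t_hi - t_lo + 1
    weights = {"loss": 0, "gain": 0, "neutral": 0}
    covered = 0
    for seg in segments:
        ov = min(seg.end, t_hi) - max(seg.start, t_lo) + 1
        if ov <= 0:
            continue
        covered += ov
        if seg.copy_number < 2:
            weights["loss"] += ov
        elif seg.copy_number > 2:
            weights["gain"] += ov
        else:
            weights["neutral"] += ov
    weights["neutral"] += total - covered
    best = max(weights.values())
    winners = [k for k, v in weights.items() if v == best]
    return "neutral" if len(winners) > 1 else winners[0]


def call_intrachromosomal_rearrangements(
    calls: Iterable[SVCall],
    cnv: Iterable[CNVSegment],
    config: Optional[AnalysisConfig] = None,
    profiled_samples: Optional[set] = None,
) -> list:
    """Re-type same-chromosome calls spanning >= 5 Mbp as intrachromosomal
    rearrangements, with copy-number support.

    Only ``sv_type`` and ``cnv_support`` change (the original type is kept in
    ``original_type``); breakpoints, VAF and sample assignment never do.
    ``cnv_support`` is the length-weighted majority CN state of segments
    overlapping the span trimmed by ``cnv_support_flank_bp`` per end, or
    ``unassessed`` when the sample has no CNV profile.
    """
    config = config or AnalysisConfig()
    cnv = list(cnv)
    if profiled_samples is None:
        profiled_samples = {s.sample_id for s in cnv}
    by_sample_chrom: dict = {}
    for seg in cnv:
        by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)

    out = []
    for call in calls:
        span = call.span_bp
        if span is None or span < config.intra_span_bp:
            out.append(call)
            continue
        chrom, lo, hi = call.interval()
        if call.sample_id not in profiled_samples:
            support = "unassessed"
        else:
            support = _majority_cn_state(
                by_sample_chrom.get((call.sample_id, chrom), []),
                lo,
                hi,
                config.cnv_support_flank_bp,
            )
        out.append(
            replace(
                call,
                sv_type="intra_rearrangement",
                cnv_support=support,
                original_type=call.original_type
                or (call.sv_type if call.sv_type != "intra_rearrangement" else None),
            )
        )
    return out


def detect_complex_rearrangements(
    calls: Iterable[SVCall], config: Optional[AnalysisConfig] = None
) -> list:
    """Find chains of translocations involving >= 3 chromosomes per sample.

    Translocations are graph nodes; an edge joins two translocations of one
    sample sharing a chromosome with breakpoints on that chromosome within
    ``complex_link_window_bp``.  Connected components with >= 2 members
    touching >= 3 distinct chromosomes are emitted.
    """
    config = config or AnalysisConfig()
    trans = [c for c in calls if c.sv_type == "translocation_inter"]
    by_sample: dict = {}
    for c in trans:
        by_sample.setdefault(c.sample_id, []).append(c)

    events = []
    for sample in sorted(by_sample):
        nodes = by_sample[sample]
        graph = nx.Graph()
        graph.add_nodes_from(range(len(nodes)))
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                linked = any(
                    bp1.chrom == bp2.chrom
                    and abs(bp1.pos - bp2.pos) <= config.complex_link_window_bp
                    for bp1 in (a.bp_a, a.bp_b)
                    for bp2 in (b.bp_a, b.bp_b)
                )
                if linked:
                    graph.add_edge(i, j)
        for component in nx.connected_components(graph):
            members = sorted(component)
            chroms = set()
            for k in members:
                chroms.update((nodes[k].bp_a.chrom, nodes[k].bp_b.chrom))
            if len(members) >= 2 and len(chroms) >= 3:
                events.append(
                    ComplexRearrangement(
                        sample_id=sample,
                        member_call_ids=tuple(sorted(nodes[k].call_id for k in members)),
                        chromosomes=frozenset(chroms),
                    )
                )
    return events


def _overlaps(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    return max(lo1, lo2) <= min(hi1, hi2)


def flag_high_risk_loci(
    calls: Iterable[SVCall],
    cnv: Iterable[CNVSegment],
    loci: Iterable[HighRiskLocus],
    samples: Optional[Iterable[str]] = None,
) -> RiskFlagMatrix:
    """Flag each (sample, locus) cell with the aberration classes touching it.

    ``cnv_loss`` / ``cnv_gain``: a CNV segment with CN below / above 2
    overlaps the locus; ``translocation``: a translocation breakpoint lies
    inside it; ``sv``: any other call's span overlaps it.  Flags coexist.
    """
    calls = list(calls)
    cnv = list(cnv)
    loci = tuple(loci)
    if samples is None:
        samples = sorted({c.sample_id for c in calls} | {s.sample_id for s in cnv})
    samples = tuple(samples)

    flags = {(s, l.name): set() for s in samples for l in loci}
    for seg in cnv:
        for locus in loci:
            if seg.chrom == locus.chrom and _overlaps(seg.start, seg.end, locus.start, locus.end):
                if seg.copy_number < 2:
                    flags[(seg.sample_id, locus.name)].add("cnv_loss")
                elif seg.copy_number > 2:
                    flags[(seg.sample_id, locus.name)].add("cnv_gain")
    for call in calls:
        for locus in loci:
            key = (call.sample_id, locus.name)
            if key not in flags:
                continue
            if call.sv_type == "translocation_inter":
                for bp in (call.bp_a, call.bp_b):
                    if bp.chrom == locus.chrom and locus.start <= bp.pos <= locus.end:
                        flags[key].add("translocation")
            else:
                chrom, lo, hi = call.interval()
                if chrom == locus.chrom and _overlaps(lo, hi, locus.start, locus.end):
                    flags[key].add("sv")
    return RiskFlagMatrix(
        samples=samples,
        loci=loci,
        _flags={k: frozenset(v) for k, v in flags.items()},
    )


def load_default_high_risk_loci() -> list:
    """Packaged hg38 cytoband-level coordinates of the high-risk myeloma loci
    (17p13/TP53, 13q14/RB1, 8q24/MYC, 1q21, 1p32, 14q32/IGH, 2p11/IGK,
    22q11/IGL); override by supplying any BED."""
    panel = read_bed(_data_path("high_risk_loci_hg38.bed"), name="high_risk")
    return [HighRiskLocus(name=sym, chrom=chrom, start=start, end=end) for chrom, start, end, sym in panel.genes]


def classify_calls(
    calls: Iterable[SVCall],
    cnv: Iterable[CNVSegment],
    config: Optional[AnalysisConfig] = None,
) -> list:
    """Convenience stage-2 chain: intra re-typing, then size bin and
    clonality annotations on every call.  Sub-threshold calls are dropped
    (with a warning from :func:`assign_size_bin`)."""
    config = config or AnalysisConfig()
    retyped = call_intrachromosomal_rearrangements(calls, cnv, config)
    out = []
    for call in retyped:
        size_bin = assign_size_bin(call, config)
        if size_bin is None:
            continue
        clonality = classify_clonality(call, config) if call.vaf_pct is not None else None
        out.append(replace(call, size_bin=size_bin, clonality=clonality))
    return out
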