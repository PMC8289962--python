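"""Stage 1: merge the two caller pipelines, then mask, somatic- and
quality-filter the callset.

The de novo (assembly) and rare-variant (molecule-cluster) pipelines call
overlapping but not identical SV sets.  Calls of identical type whose
breakpoints agree within a tolerance (and, for sized types, whose intervals
reciprocally overlap) are unified; matching is greedy by ascending breakpoint
distance with deterministic tie-breaking.  The somatic filter removes calls
matching a control-genome SV database (polymorphisms); the quality filter
keeps calls with VAF strictly above 5 % and at least ten supporting
molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .datamodel import (
    AnalysisConfig,
    GenomicBreakpoint,
    SVCall,
    effective_provenance,
    sort_calls,
)

__all__ = [
    "ControlRecord",
    "ControlSVDatabase",
    "match_pairs",
    "merge_pipelines",
    "apply_region_masks",
    "filter_somatic",
    "filter_quality",
    "run_stage1",
]


@dataclass(frozen=True)
class ControlRecord:
    """One control-genome SV (a polymorphism candidate)."""

    sv_type: str
    bp_a: GenomicBreakpoint
    bp_b: GenomicBreakpoint
    size_bp: Optional[int] = None


@dataclass
class ControlSVDatabase:
    """SVs seen in mapped control genomes with no disease phenotype."""

    records: list

    @classmethod
    def from_calls(cls, calls: Iterable[SVCall]) -> "ControlSVDatabase":
        return cls(
            records=[
                ControlRecord(sv_type=c.sv_type, bp_a=c.bp_a, bp_b=c.bp_b, size_bp=c.size_bp)
                for c in calls
            ]
        )

    def __len__(self) -> int:
        return len(self.records)


def _interval(bp_a: GenomicBreakpoint, bp_b: GenomicBreakpoint) -> tuple:
    lo, hi = sorted((bp_a.pos, bp_b.pos))
    return lo, hi


def _reciprocal_overlap(a, b) -> float:
    """min(overlap/len_a, overlap/len_b) of two 1-based inclusive intervals."""
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    overlap = min(a_hi, b_hi) - max(a_lo, b_lo) + 1
    if overlap <= 0:
        return 0.0
    len_a = a_hi - a_lo + 1
    len_b = b_hi - b_lo + 1
    return min(overlap / len_a, overlap / len_b)


def _size_ratio(size_a: Optional[int], size_b: Optional[int]) -> float:
    if not size_a or not size_b:
        return 1.0  # no size information: do not veto the match
    lo, hi = sorted((size_a, size_b))
    return lo / hi if hi else 1.0


def match_distance(a: SVCall, b: SVCall, tolerance_bp: int, reciprocal_overlap: float):
    """Breakpoint distance of two same-type calls if they are mergeable.

    Returns ``(distance, overlap_score)`` or ``None`` when the pair does not
    satisfy the matching criteria:

    * identical sv_type and chromosome pair;
    * both corresponding breakpoints within ``tolerance_bp`` (insertions are
      anchored on bp_a only and additionally require a size ratio at least
      ``reciprocal_overlap``);
    * sized span types additionally require reciprocal interval overlap at
      least ``reciprocal_overlap``.
    """
    if a.sv_type != b.sv_type:
        return None
    if (a.bp_a.chrom, a.bp_b.chrom) != (b.bp_a.chrom, b.bp_b.chrom):
        return None
    dist_a = abs(a.bp_a.pos - b.bp_a.pos)
    dist_b = abs(a.bp_b.pos - b.bp_b.pos)
    if a.sv_type == "insertion":
        if dist_a > tolerance_bp:
            return None
        ratio = _size_ratio(a.size_bp, b.size_bp)
        if ratio < reciprocal_overlap:
            return None
        return dist_a, ratio
    if dist_a > tolerance_bp or dist_b > tolerance_bp:
        return None
    if a.sv_type == "translocation_inter":
        return max(dist_a, dist_b), 1.0
    overlap = _reciprocal_overlap(_interval(a.bp_a, a.bp_b), _interval(b.bp_a, b.bp_b))
    if overlap < reciprocal_overlap:
        return None
    return max(dist_a, dist_b), overlap


def match_pairs(de_novo: list, rare_variant: list, config: Optional[AnalysisConfig] = None) -> list:
    """Greedy one-to-one matching between the two callsets.

    Candidate pairs (see :func:`match_distance`) are taken in order of
    ascending breakpoint distance, ties broken by larger overlap score and
    then by lexical call-id order; each call matches at most once.  Returns
    ``(i, j)`` index pairs into the two lists.
    """
    config = config or AnalysisConfig()
    candidates = []
    for i, a in enumerate(de_novo):
        for j, b in enumerate(rare_variant):
            scored = match_distance(
                a, b, config.merge_bp_tolerance_bp, config.merge_reciprocal_overlap
            )
            if scored is not None:
                dist, overlap = scored
                candidates.append((dist, -overlap, a.call_id, b.call_id, i, j))
    candidates.sort()
    used_dn: set = set()
    used_rv: set = set()
    pairs = []
    for _, _, _, _, i, j in candidates:
        if i in used_dn or j in used_rv:
            continue
        used_dn.add(i)
        used_rv.add(j)
        pairs.append((i, j))
    return pairs


def merge_pipelines(
    de_novo: Iterable[SVCall],
    rare_variant: Iterable[SVCall],
    config: Optional[AnalysisConfig] = None,
) -> list:
    """Merge one sample's de novo and rare-variant callsets.

    Matched pairs are unified into a single call with provenance = union and
    VAF / molecule support (and coordinates) taken from the rare-variant
    member, the pipeline with direct molecule-level support at low allele
    fractions.  Matching is greedy by ascending breakpoint distance, ties
    broken by larger reciprocal overlap, then lexical call ids; each call
    matches at most once.  Unmatched calls pass through with single-source
    provenance.  All outputs carry ``pipeline="merged"``.
    """
    config = config or AnalysisConfig()
    dn = list(de_novo)
    rv = list(rare_variant)
    samples = {c.sample_id for c in dn} | {c.sample_id for c in rv}
    if len(samples) > 1:
        raise ValueError(f"merge_pipelines expects one sample, got {sorted(samples)}")

    pairs = match_pairs(dn, rv, config)
    used_dn = {i for i, _ in pairs}
    used_rv = {j for _, j in pairs}
    merged: list[SVCall] = []
    for i, j in pairs:
        a, b = dn[i], rv[j]
        merged.append(
            replace(
                b,
                pipeline="merged",
                provenance=effective_provenance(a) | effective_provenance(b),
            )
        )
    for i, a in enumerate(dn):
        if i not in used_dn:
            merged.append(replace(a, pipeline="merged", provenance=effective_provenance(a)))
    for j, b in enumerate(rv):
        if j not in used_rv:
            merged.append(replace(b, pipeline="merged", provenance=effective_provenance(b)))
    return sort_calls(merged)


def apply_region_masks(calls: Iterable[SVCall], masks: Iterable) -> list:
    """Drop calls with either breakpoint inside a mask interval (inclusive).

    ``masks`` is an iterable of ``(chrom, start, end)`` 1-based inclusive
    intervals (e.g. ``GenePanel.genes`` entries also work).  Order of the
    surviving calls is preserved.
    """
    intervals: dict = {}
    for mask in masks:
        chrom, start, end = mask[0], int(mask[1]), int(mask[2])
        intervals.setdefault(str(chrom), []).append((start, end))

    def hit(bp: GenomicBreakpoint) -> bool:
        return any(lo <= bp.pos <= hi for lo, hi in intervals.get(bp.chrom, ()))

    return [c for c in calls if not (hit(c.bp_a) or hit(c.bp_b))]


def filter_somatic(
    calls: Iterable[SVCall],
    control_db: ControlSVDatabase,
    config: Optional[AnalysisConfig] = None,
) -> list:
    """Remove calls matching the control-genome database (polymorphisms).

    A call is polymorphic iff the database holds a record of the same type
    with both breakpoints within ``control_match_tolerance_bp`` (and
    reciprocal overlap / size ratio at least ``merge_reciprocal_overlap`` for
    sized types).  Survivors are labelled ``somatic_like``.
    """
    config = config or AnalysisConfig()
    controls = [
        SVCall(
            call_id=f"ctrl_{k}",
            sample_id="__control__",
            pipeline="merged",
            sv_type=r.sv_type,
            bp_a=r.bp_a,
            bp_b=r.bp_b,
            size_bp=r.size_bp,
        )
        for k, r in enumerate(control_db.records)
    ]
    kept = []
    for call in calls:
        polymorphic = any(
            match_distance(call, ctrl, config.control_match_tolerance_bp, config.merge_reciprocal_overlap)
            is not None
            for ctrl in controls
        )
        if not polymorphic:
            kept.append(replace(call, somatic_status="somatic_like"))
    return kept


def filter_quality(calls: Iterable[SVCall], config: Optional[AnalysisConfig] = None) -> list:
    """Keep calls with VAF strictly above the floor and enough molecules."""
    config = config or AnalysisConfig()
    return [
        c
        for c in calls
        if c.vaf_pct is not None
        and c.vaf_pct > config.min_vaf_pct
        and c.n_molecules >= config.min_molecules
    ]


def run_stage1(
    de_novo: Iterable[SVCall],
    rare_variant: Iterable[SVCall],
    masks: Iterable,
    control_db: ControlSVDatabase,
    config: Optional[AnalysisConfig] = None,
) -> list:
    """Merge one sample's callsets, then mask, somatic and quality filter."""
    config = config or AnalysisConfig()
    merged = merge_pipelines(de_novo, rare_variant, config)
    masked = apply_region_masks(merged, masks)
    somatic = filter_somatic(masked, control_db, config)
    return filter_quality(somatic, config)
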