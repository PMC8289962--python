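"""Summary statistics of the packaged chromosome-1 cohort table.

Every quantity is recomputed from the fixture records at call time through
the pipeline's own classification and counting operations (nothing is
hard-coded beyond the fixture itself): chromosome-1 rearrangement burden per
group, the flagship EMM1/EMM2 rearrangements with their affected-gene
counts, the subclonality of the EMM rearrangements, and the MM per-patient
chromosome-1 deletion and insertion+duplication medians.
"""

from __future__ import annotations

from typing import Optional

from .classify import classify_clonality
from .cohort_stats import group_median_range, per_sample_counts
from .datamodel import AnalysisConfig
from .io_formats import load_chr1_cohort_fixture

__all__ = ["compute_fixture_report"]


def compute_fixture_report(config: Optional[AnalysisConfig] = None) -> dict:
    """Recompute the published chromosome-1 cohort statistics.

    Returns a mapping of statistic name to ``{"value": number, "n": size}``
    where ``n`` is the number of records (or samples) the statistic is
    computed over.
    """
    config = config or AnalysisConfig()
    calls, meta = load_chr1_cohort_fixture()
    emm_samples = [m.sample_id for m in meta if m.group == "EMM"]
    mm_samples = [m.sample_id for m in meta if m.group == "MM"]
    summary = per_sample_counts(calls, meta, config)

    intra_counts = summary.counts(sv_types=("intra_rearrangement",), chrom="1")
    emm_intra = [c for c in calls if c.sv_type == "intra_rearrangement" and c.sample_id in emm_samples]
    emm1_intra = [c for c in emm_intra if c.sample_id == "EMM1"]
    emm2_intra = [c for c in emm_intra if c.sample_id == "EMM2"]
    subclonal = [c for c in emm_intra if classify_clonality(c, config) == "subclonal"]

    del_stats = group_median_range(summary, "chr1_deletions", meta)
    insdup_stats = group_median_range(summary, "chr1_insertions_duplications", meta)

    n_records = len(calls)
    report = {
        "emm_patients_n": {"value": len(emm_samples), "n": len(meta)},
        "mm_patients_n": {"value": len(mm_samples), "n": len(meta)},
        "pct_emm_with_chr1_intra_rearrangement": {
            "value": 100.0 * sum(intra_counts[s] > 0 for s in emm_samples) / len(emm_samples),
            "n": len(emm_samples),
        },
        "pct_mm_with_chr1_intra_rearrangement": {
            "value": 100.0 * sum(intra_counts[s] > 0 for s in mm_samples) / len(mm_samples),
            "n": len(mm_samples),
        },
        "emm_chr1_intra_rearrangements_total": {
            "value": int(sum(intra_counts[s] for s in emm_samples)),
            "n": n_records,
        },
        "emm1_chr1_intra_size_kbp": {
            "value": emm1_intra[0].size_bp / 1000 if len(emm1_intra) == 1 else float("nan"),
            "n": len(emm1_intra),
        },
        "emm1_chr1_intra_affected_genes": {
            "value": sum(c.n_genes or 0 for c in emm1_intra),
            "n": len(emm1_intra),
        },
        "emm2_chr1_intra_affected_genes": {
            "value": sum(c.n_genes or 0 for c in emm2_intra),
            "n": len(emm2_intra),
        },
        "emm_chr1_intra_max_vaf_pct": {
            "value": max(c.vaf_pct for c in emm_intra),
            "n": len(emm_intra),
        },
        "pct_emm_chr1_intra_subclonal": {
            "value": 100.0 * len(subclonal) / len(emm_intra),
            "n": len(emm_intra),
        },
        "mm_chr1_deletions_median": {"value": del_stats["MM"][0], "n": len(mm_samples)},
        "mm_chr1_deletions_max": {"value": del_stats["MM"][2], "n": len(mm_samples)},
        "mm_chr1_insertions_duplications_median": {
            "value": insdup_stats["MM"][0],
            "n": len(mm_samples),
        },
        "mm_chr1_insertions_duplications_max": {
            "value": insdup_stats["MM"][2],
            "n": len(mm_samples),
        },
    }
    return report
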