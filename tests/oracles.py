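"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a result from first principles (plain double loops,
exhaustive enumeration, repeated-min greedy selection, set closure) without
importing the implementation's matching, interval-tree or rank machinery.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _reciprocal_overlap(lo1, hi1, lo2, hi2) -> float:
    ov = min(hi1, hi2) - max(lo1, lo2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (hi1 - lo1 + 1), ov / (hi2 - lo2 + 1))


def oracle_merge_pairs(de_novo, rare_variant, tolerance_bp, min_overlap):
    """All-pairs greedy matcher: returns the set of (dn call_id, rv call_id)
    pairs selected by ascending breakpoint distance with the declared
    tie-breaking (larger overlap score, then lexical ids)."""
    candidates = []
    for a in de_novo:
        for b in rare_variant:
            if a.sv_type != b.sv_type:
                continue
            if (a.bp_a.chrom, a.bp_b.chrom) != (b.bp_a.chrom, b.bp_b.chrom):
                continue
            da = abs(a.bp_a.pos - b.bp_a.pos)
            db = abs(a.bp_b.pos - b.bp_b.pos)
            if a.sv_type == "insertion":
                if da > tolerance_bp:
                    continue
                sa, sb = a.size_bp or 0, b.size_bp or 0
                score = 1.0 if not sa or not sb else min(sa, sb) / max(sa, sb)
                if score < min_overlap:
                    continue
                candidates.append((da, -score, a.call_id, b.call_id))
            elif a.sv_type == "translocation_inter":
                if da > tolerance_bp or db > tolerance_bp:
                    continue
                candidates.append((max(da, db), -1.0, a.call_id, b.call_id))
            else:
                if da > tolerance_bp or db > tolerance_bp:
                    continue
                lo1, hi1 = sorted((a.bp_a.pos, a.bp_b.pos))
                lo2, hi2 = sorted((b.bp_a.pos, b.bp_b.pos))
                score = _reciprocal_overlap(lo1, hi1, lo2, hi2)
                if score < min_overlap:
                    continue
                candidates.append((max(da, db), -score, a.call_id, b.call_id))
    pairs = set()
    used_a: set = set()
    used_b: set = set()
    while candidates:
        best = min(candidates)
        candidates.remove(best)
        _, _, id_a, id_b = best
        if id_a in used_a or id_b in used_b:
            continue
        used_a.add(id_a)
        used_b.add(id_b)
        pairs.add((id_a, id_b))
    return pairs


def oracle_gene_counts(calls, panel) -> list:
    """Per-call affected-gene counts by vectorised linear scan of the panel."""
    by_chrom: dict = {}
    for chrom, start, end, _ in panel.genes:
        by_chrom.setdefault(chrom, []).append((start, end))
    arrays = {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }
    counts = []
    for call in calls:
        if call.bp_a.chrom == call.bp_b.chrom:
            chrom, lo, hi = call.interval()
            if chrom in arrays:
                starts, ends = arrays[chrom]
                counts.append(int(((starts <= hi) & (ends >= lo)).sum()))
            else:
                counts.append(0)
        else:
            total = 0
            for bp in (call.bp_a, call.bp_b):
                if bp.chrom in arrays:
                    starts, ends = arrays[bp.chrom]
                    total += int(((starts <= bp.pos) & (ends >= bp.pos)).sum())
            counts.append(total)
    return counts


def oracle_mask_survivors(calls, masks) -> list:
    """Per-call linear scan of all mask intervals (breakpoint-inclusive)."""
    survivors = []
    for call in calls:
        removed = False
        for chrom, lo, hi in masks:
            for bp in (call.bp_a, call.bp_b):
                if bp.chrom == str(chrom) and lo <= bp.pos <= hi:
                    removed = True
        if not removed:
            survivors.append(call.call_id)
    return survivors


def oracle_exact_mann_whitney_p(x, y, sided: str = "one") -> float:
    """Exact permutation p-value by direct pair counting over all labellings.

    The statistic is computed as the count of (x_i, y_j) pairs with
    x_i > y_j plus half the ties — a different route than rank sums.
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    n = len(x)

    def u_of(xs, ys):
        u = 0.0
        for xi in xs:
            for yj in ys:
                u += 1.0 if xi > yj else 0.5 if xi == yj else 0.0
        return u

    u_obs = u_of(x, y)
    mu = len(x) * len(y) / 2
    hits = total = 0
    indices = range(len(pooled))
    for combo in combinations(indices, n):
        chosen = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in indices if i not in chosen]
        u = u_of(xs, ys)
        total += 1
        if sided == "one":
            hits += u >= u_obs - 1e-9
        else:
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return hits / total


def oracle_complex_components(translocations, window_bp) -> set:
    """Connected components by repeated set merging (no graph library).

    Returns the set of frozensets of member call_ids that have >= 2 members
    and touch >= 3 chromosomes, over all samples.
    """
    by_sample: dict = {}
    for c in translocations:
        by_sample.setdefault(c.sample_id, []).append(c)
    result = set()
    for sample, nodes in by_sample.items():
        components = [{i} for i in range(len(nodes))]

        def linked(a, b):
            return any(
                p.chrom == q.chrom and abs(p.pos - q.pos) <= window_bp
                for p in (a.bp_a, a.bp_b)
                for q in (b.bp_a, b.bp_b)
            )

        changed = True
        while changed:
            changed = False
            for i in range(len(components)):
                for j in range(i + 1, len(components)):
                    if any(
                        linked(nodes[a], nodes[b])
                        for a in components[i]
                        for b in components[j]
                    ):
                        components[i] |= components[j]
                        del components[j]
                        changed = True
                        break
                if changed:
                    break
        for comp in components:
            chroms = set()
            for k in comp:
                chroms.update((nodes[k].bp_a.chrom, nodes[k].bp_b.chrom))
            if len(comp) >= 2 and len(chroms) >= 3:
                result.add(frozenset(nodes[k].call_id for k in comp))
    return result
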