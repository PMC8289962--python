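# Methods

## Coordinates, formats and the data model

All coordinates are 1-based inclusive internally, matching the SMAP-style
tables OGM callers emit; BED input/output converts to and from 0-based
half-open at the boundary, and chromosome names are normalised to bare
`1`..`22`, `X`, `Y`. The canonical exchange format is a tab-separated SV
table whose ten roles (sample, pipeline, type, two breakpoints, size, VAF,
molecule support) are bound by a *dialect* object; a preset maps Bionano
SMAP-like column names onto the same roles so real exports can be ingested
without code changes. Sizes in kbp dialects are converted exactly to bp;
thousands separators are accepted.

For insertions the size is the inserted length and may exceed the breakpoint
span, because optical-map insertions are anchored between labels. For the
other sized types the printed size is treated as authoritative but is
checked against the span only loosely (flagged when exceeding the span by
more than max(1 kbp, 5 %)): label-anchored breakpoints routinely delimit a
wider interval than the event itself, as the packaged cohort table shows
(e.g. a 0.7 kbp deletion across a 3.1 kbp label interval).

### The packaged chromosome-1 cohort table

The per-patient chromosome-1 SV table of the 11-patient cohort (4 EMM, 7 MM)
is shipped as a TSV fixture, transcribed record-for-record from the
published table: type, size (kbp), cytobands, both breakpoints, VAF (%) and
the published affected-gene count (stored as an annotation, `n_genes`).
Molecule support is not printed; records carry 10, the minimum consistent
with the molecule filter every published call passed. Three rows print
VAF = 5 although the callset was filtered at VAF > 5 (presumably rounding);
they are stored verbatim and the fixture report does not re-apply the
quality filter. Known internal inconsistencies of the published
table/prose (size-vs-span mismatches, per-patient gene totals) are stored
as printed, not reconciled.

## Thresholds

All thresholds live in `AnalysisConfig`; the defaults are the published
procedure:

| parameter | default | semantics |
|---|---|---|
| `min_vaf_pct` | 5 | quality filter, strict `>` |
| `min_molecules` | 10 | quality filter, inclusive `>=` |
| `clonal_cutoff_pct` | 25 | subclonal iff VAF `<=` cutoff |
| `sv_min_size_bp` | 500 | detection floor; smaller events rejected with a warning |
| `small_max_bp` | 50,000 | small bin: [500 bp, 50 kbp] |
| `medium_max_bp` | 5,000,000 | medium bin: (50 kbp, 5 Mbp] |
| `intra_span_bp` | 5,000,000 | intrachromosomal re-typing, inclusive `>=` |
| `merge_bp_tolerance_bp` | 10,000 | breakpoint agreement between pipelines |
| `merge_reciprocal_overlap` | 0.5 | reciprocal overlap (sized types) / size ratio (insertions) |
| `control_match_tolerance_bp` | 10,000 | somatic filter match tolerance |
| `complex_link_window_bp` | 1,000,000 | translocation chaining window |
| `cnv_support_flank_bp` | 50,000 | span trimming before CN majority vote |

The first seven are published values with the boundary semantics stated in
the source; the remaining tolerances are this package's own declared
defaults (the published procedure does not state its merge or control-match
criteria) and are configuration-exposed rather than inferred.

## Stage 1: merge and filters

Merging is greedy one-to-one matching by ascending breakpoint distance
(max over the two breakpoints), ties broken by larger reciprocal overlap and
then lexical call ids — deterministic and oracle-checkable. Candidate pairs
must share type and chromosome pair, agree within the tolerance, and (sized
types) overlap reciprocally ≥ 0.5; insertions are matched on the anchor
breakpoint plus size ratio, since interval overlap is meaningless for them;
translocations on both breakpoints, orientation ignored. The merged record
takes VAF, molecule support and coordinates from the rare-variant member
(the pipeline with direct molecule-level support at low allele fractions);
unmatched calls pass through. Merging a merged set with an empty set is the
identity.

Region masks remove a call when **either breakpoint** falls inside a mask
interval (inclusive at both edges) — masks target unreliable breakpoint
regions, so span overlap is deliberately not used. The somatic filter
removes calls matching a control-genome record under the same pair criteria
at `control_match_tolerance_bp`; survivors are labelled somatic-like. All
stage-1 filters are pure per-call predicates given a fixed configuration and
database, hence commute.

## Stage 2: classification

Intrachromosomal re-typing is conservative: only `sv_type` and
`cnv_support` change (the pre-typing class is kept in `original_type`).
Copy-number support is the length-weighted majority state (loss CN < 2,
gain CN > 2, neutral otherwise) of CNV segments over the span trimmed by
`cnv_support_flank_bp` at each end, to avoid breakpoint-edge segment noise;
uncovered bases count as diploid, ties resolve to neutral, and samples
without any CNV profile are `unassessed`.

Complex rearrangements are connected components of the graph whose nodes are
one sample's translocations, with an edge whenever two translocations share
a chromosome with breakpoints within `complex_link_window_bp`; components
with ≥ 2 members touching ≥ 3 chromosomes are reported. The default
high-risk loci are hg38 cytoband-level intervals for 17p13, 13q14, 8q24,
1q21, 1p32, 14q32, 2p11 and 22q11, packaged as BED and overridable; the
flag matrix is monotone — adding calls or segments never clears a flag.

## Stage 3: annotation

A gene is affected by a call when its interval overlaps the call span by at
least 1 bp (strandless; panels are collapsed to one interval per symbol on
load, so a gene counts once per call). Translocations have no span; each
breakpoint is a zero-length window, counting the genes containing it.
Panel fractions are **gene-wise**: |affected genes in panel| / |affected
genes in any panel| — the union convention was an open choice and is
documented here; panels overlap, so fractions need not sum to one.

## Stage 4: group comparison

Counts are compared with the Mann–Whitney *U* test. For pooled sizes ≤ 12
every labelling is enumerated (ties by mid-ranks, so ties are exact); the
4-vs-7 design is therefore always exact, with smallest attainable one-sided
p = 1/C(11,4) ≈ 0.003. Larger samples use the normal approximation with tie
correction (scipy). The default is one-sided in the direction of each
metric's hypothesis — deletion-type metrics: EMM greater; translocation
metrics: MM greater — with two-sided available; the source reports p-values
without naming the test or sidedness, so this is a declared choice, not a
claim of equivalence. No multiple-testing correction is applied by default;
Benjamini–Hochberg is available by flag.

## The synthetic cohort generator

The generator emulates the study conditions: 4 EMM + 7 MM samples; per-type
somatic Poisson means (deletions 45/34 for EMM/MM with small-deletion shares
37/45 and 24/34 — the published medians; insertions 18, inversions 3,
duplications 3); 1–4 chromosome-1 rearrangements per EMM sample (spans
log-uniform 6–60 Mbp, beta-skewed towards 1p), typed
deletion/insertion/inversion with matching CN = 1 / CN = 3 / copy-neutral
segments; translocation means 1.25 (EMM) vs 3 (MM) with a three-chromosome
complex chain in MM at probability 4/7; VAF mixed 50:50 between subclonal
(5.5–25) and clonal (25.5–49); 30 germline-like polymorphisms shared by all
samples and present verbatim in the control database. Where the source
states no value (jitter, sensitivities, false-call rates, caller VAF floor
of the assembly pipeline, polymorphism count) the defaults are declared
once here: breakpoint jitter N(0, 500 bp) / N(0, 300 bp), sensitivity 0.95
per caller, 5 false calls per caller per sample, de novo VAF floor 20 %.
Event positions are uniform (length-weighted) outside 1 Mbp subtelomeric
masks with a 100 kbp minimum gap, which keeps distinct events from matching
each other at the merge/control tolerances. Counts are Poisson and sizes
log-uniform per type; everything is deterministic given the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: molecule-level noise and coverage variation,
breakpoint-correlated VAF error, segmented (partial) CNV support under a
rearrangement, clonal phylogenies, orientation/zygosity, and realistic gene
density (panels are uniform non-overlapping intervals). The caller model is
a detection-floor-plus-Bernoulli abstraction, not a re-implementation of
the callers.

Two structural consequences are deliberate: (i) small subclonal events
below both callers' floors (< 5 kbp and < 20 % VAF) are invisible to the
simulated callsets, so pipeline counts under the default caller model sit
below the planted Poisson means; the count-recovery test therefore uses the
noiseless caller model (jitter 0, sensitivity 1, no false calls, no VAF
floor), under which the stage-1 chain provably returns exactly the planted
somatic events. (ii) jitter at the 500 bp size floor removes a further
sliver of the smallest deletions.

## Numerical and degenerate-input choices

Exact Mann–Whitney p-values use an epsilon of 1e-9 when comparing permuted
statistics to the observed one, so mid-rank halves never flip on float
error. Empty groups, missing VAF at clonality, unknown sample ids, and
overlapping CNV segments are errors; sub-threshold sizes warn and are
excluded from binning; an empty affected-gene union yields absent (not
zero) panel fractions; `validate_call` is total and returns violations
instead of raising. Spans shorter than twice the CNV flank are assessed
untrimmed.

## Problem sizes used in tests and the acceptance script

Oracle checks run at 200 events (merge), 10,000 calls × 2,000 genes
(annotation), all pooled sizes ≤ 10 (exact test) and ≤ 50 translocations
(complex events); power and null calibration use 200 simulated count
cohorts each; the count-recovery check uses 40 samples per group. These
sizes give stable statistics while keeping the whole suite fast; they are
the package's own choices.

## Known limitations

The fixture covers chromosome 1 only (that is all the source prints per
patient), so genome-wide medians are exercised on synthetic data alone.
High-risk locus coordinates are cytoband-level approximations, not gene
boundaries. VAF is treated as an opaque percentage from the caller
(whether it is molecule-fraction or coverage-normalised is not specified
upstream). The vendor's internal logic for calling "intrachromosomal
translocations" is not reproduced; this package re-types by span and CNV
context and keeps the original type alongside.
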