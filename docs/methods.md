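# Methods

This note documents the models and procedures implemented in
`dtctrace`, the defaults and why they were chosen, and what the
synthetic validation does and does not demonstrate.

## Single-cell copy-number profiling

**logR.** For one cell with bin counts c₁…c_B, logRᵢ = log2(cᵢ / c̄).
Zero-count bins are floored to 0.5 reads before the log so the track
stays finite; an all-zero cell is rejected as an empty library. The
track has coverage-weighted mean 2^logR ≈ 1 by construction and carries
no absolute scale — a perfectly flat genome-doubled cell is
indistinguishable from a diploid one from read depth alone.

**GC correction.** Amplified single-cell libraries show a smooth
coverage dependence on bin GC content. We fit logR on GC with a
quadratic least-squares curve, with one round of outlier trimming at
3 MADs so large CNAs do not drag the fit, subtract the curve, and
re-center. A constant GC track makes the fit degenerate; the correction
is then a warned no-op. The synthetic generator injects a quadratic
multiplicative curve, so correction is exactly the model inverse there;
on real data residual non-quadratic GC structure would remain.

**Segmentation (PCF).** Per chromosome, we compute the exact minimizer
of Σ_segments Σᵢ (yᵢ − ȳ_seg)² + γ·(number of breakpoints) by O(n²)
dynamic programming over all breakpoint placements — not a heuristic.
Cost ties are broken toward fewer breakpoints, then toward longer final
segments, making the output deterministic. The penalty default is
γ = 25. Reference PCF implementations apply γ after scaling the data by
an estimated noise SD; whether the conventional γ = 25 refers to that
normalized scale or to raw RSS is ambiguous, so `segment_pcf` exposes
`normalize`: the pipeline uses the normalized interpretation (effective
raw-scale penalty γ·σ̂², σ̂ from MAPD), while `normalize=False` applies
γ to raw RSS — the form the unit oracle tests use. Chromosome
boundaries always break segments.

**Ploidy and copy number.** Segment copy number is cn = 2^logR · Ψ,
integer state = round(cn) floored at 0. Ψ is not observable from logR
alone; we grid-search Ψ ∈ [1.5, 5.0] (step 0.05) minimizing the
bin-length-weighted absolute distance of segment cn values to the
nearest non-negative integers, ties to the smallest Ψ. This pins Ψ
whenever the genome contains segments at ≥ 2 distinct states and
resolves flat genomes to the smallest consistent ploidy (documented
ambiguity; a tetraploid flat cell reads as diploid).

**MAPD QC.** MAPD = median |logRᵢ₊₁ − logRᵢ| over consecutive
within-chromosome pairs; for i.i.d. Gaussian noise of SD σ it equals
σ·√2·Φ⁻¹(0.75) ≈ 0.954σ, so it measures bin-level noise robustly to
genuine CNA steps (which affect few pairs). Cells pass at MAPD ≤ 0.45
(configurable). The threshold was calibrated on the generator: cells at
the default dispersion land near MAPD ≈ 0.29 and pass; cells at 4× the
default dispersion land near 0.55 and fail. Aberrant cells failing QC
are reported as QC_FAIL rather than forced into DTC/AU, since noise can
fabricate CNAs.

## Classification against the bulk architecture

Cell events are maximal runs of segments whose integer state differs
from the rounded cell ploidy, ≥ 5 Mb (smaller events are indistinguishable
from segmentation noise at this coverage; the same 5 Mb floor is used in
matching, rarefaction and everywhere else for internal consistency).
Total copy number cannot reveal copy-neutral LOH in a single cell, so
cell-side events are gains/losses only and bulk cnLOH events are
excluded from the clonal-match denominator.

Two events match iff they overlap, have the same direction, and every
breakpoint pair in which **both** breakpoints are identifiable lies
within 5 Mb; breakpoints at centromeres or telomeres are treated as
unidentifiable and skipped (`annotate_breakpoints` flags them from a
sidecar annotation; `toy_arms`/`toy_chrom_lengths` cover the bundled
toy genome). The matching relation is symmetric; classification is
invariant to cell and event order.

The DTC rule requires ≥ 80% of bulk clonal events matched
(`share_fraction`). A cell that is tumor-derived can miss one clonal
event to dropout or a segmentation hiccup; 0.8 tolerates one miss out
of five while still never letting an event-free cell be a DTC (no
events ⇒ N by construction). Raising the threshold can only demote
DTC → AU, never the reverse (monotonicity, tested).

Doublet isolation artifacts (two cells in one well) are not classified —
in the source workflow they are recognized from micrographs. A mixed
profile puts much of the genome near half-integer copy number; when
≥ 20% of bins sit within 0.15 of x.5 the label carries an advisory
`doublet_suspect` flag only.

Cohort-level summaries: per-arm AU recurrence (fraction of AU cells
with an event of a given kind covering ≥ half an arm), OLS regression
of aberrant-cell fraction on patient age (slope t-test; per-point
proportion SE √(f(1−f)/n); a zero-residual fit degenerates the
t-statistic and is reported as p = 1 for a flat line), and
sequencing-vs-morphology concordance with binomial SEs.

## Genotyping error model and lineage tests

Per cell, from gold-standard germline SNPs (selection criteria: array
BAF ∈ [0.3, 0.7] plus het in blood and tumor exomes at ≥ 10× for the het
set; BAF ≤ 0.1 or ≥ 0.9, hom in both exomes, and 1+1 or 2+2 bulk copy
number for the hom set):

* p̂_fp = (covered hom-ref gold with ≥ 1 alt read) / (covered hom-ref gold)
* p̂_fn = (covered het gold with 0 alt reads) / (covered het gold)
* locus dropout = (het gold with no reads) / (het gold)
* var(p̂) = p̂(1−p̂)/n; zero observed errors trigger the worst-case
  pseudocall p̂ = 1/(n+1) (one error added to the numerator, one trial
  to the denominator), keeping downstream tests conservative.

A locus counts as a detection with ≥ 1 alt read — no base-quality
weighting, matching how sparse 1–2× WGA data is actually usable.

For n covered somatic loci with k detections, the **false positive
model** (cell unrelated; detections are artifacts) reports
P(X ≥ k), X ~ BetaBinomial(n, a, b) with (a, b) matched to
(p̂_fp, var p̂_fp) via a = μ(μ(1−μ)/σ² − 1), b = (1−μ)(·); the **false
negative model** (cell tumor-derived; misses are dropouts) reports
P(Y ≥ n−k) with the FN moments. The tails are one-sided by design:
only these directions discriminate lineages. Cells whose variance
estimate admits no Beta (σ² ≥ μ(1−μ), tiny n) fall back to the plain
binomial and are flagged; n = 0 returns p = 1 for both models.

The beta-binomial tail is computed by exact log-space summation of
pmf(j) = C(n,j)·a^(j)·b^(n−j)/(a+b)^(n) (rising factorials). This form
is numerically stable for arbitrarily large a, b: it matches an exact
rational-arithmetic oracle to ~1e−14 relative and converges to the
binomial tail to < 1e−10 absolute as σ² → 0. Beta-function
formulations (including scipy's) lose several digits in exactly these
regimes, which is why the tail is computed in-package; scipy's
beta-binomial serves as an independent cross-check on bulk tails. Note
the overdispersed tail dominates the binomial tail only beyond a
single crossing point slightly above the mean, not immediately at
k > nμ.

Somatic-call filtering (upstream of genotyping) discards candidates
seen in any panel of normals, in centromere/intergenic/repeat regions,
with allelic fraction < 0.15, or with complete strand bias (all alt
reads on one strand); variants with missing annotations are held out
and reported, never silently passed.

## Rarefaction

Events < 5 Mb are removed; two overlapping same-chromosome events are
the *same* CNA iff both breakpoints agree within 5 Mb **and** their
total copy-number states are equal — the reading of the uniqueness rule
under which an identical event shared by many cells is never counted
twice (the disjunctive reading would split it). Pairwise sameness is
not transitive, so events are grouped by transitive closure with
deterministic union-find before counting. The curve reports, per
number of cells k, the mean and SD over random orderings of the
cumulative count of distinct classes; the value at k = n is a set union
and exactly order-free. Default 100,000 permutations (tests and the
pipeline demo use fewer; the estimate is a mean over exchangeable
permutations, so only its MC error changes). A final-step mean
increment < 0.5 flags the curve as saturated.

## Clone-tree reconstruction

Subclonal units carry a label, a CCF, and a sample of origin. The
pigeonhole principle is applied in its generalized form — CCF₁ + CCF₂ > 1
forces co-occurrence, hence collinearity with the lower CCF nested
under the higher — rather than only when both exceed 0.5; this yields
strictly more inferences from the same logic, and a strict mode is
available. CCFs within 0.02 are treated as tied (measurement noise)
and never ordered by CCF alone. Cross-sample pairs are never
pigeonhole-ordered (their CCFs share no denominator); they resolve only
through cell evidence.

Single-cell refinement: a cell carrying two unordered events proves
collinearity; direction comes from CCFs, or, at a tie, from subset
evidence (a cell with A but not B places A above B). Contradictions —
a cell carrying a nested event without its forced ancestor, subset
evidence in both directions, or cyclic orders after closure — are
emitted as conflict records (convergent evolution or CCF error) and the
pair left unordered. After transitive closure, each subclone's parent
is its lowest-CCF resolved ancestor (the MRCA, CCF 1, holding the
clonal events, if none); unordered sibling pairs are recorded as
unresolved sets.

DTC placement walks to the deepest node whose own events are all
present in the cell with a supported parent; the root only requires
sharing ≥ 1 clonal event, since dropout can hide individual clonal
events in a cell that classification already accepted as a DTC. A cell
sharing no clonal event is refused (it should have been classified AU).
Remaining cell events are private. Whole-genome doubling in a single
cell appears as Ψ ≈ 2× the tree baseline and stays a per-cell
annotation, not a tree node.

Serialization is labeled Newick (via dendropy) plus a node side table
(parent, CCF, sample, events, placed cells); write → read → write is
byte-identical.

## Synthetic cohorts — what they emulate

`SimConfig` defaults define the validation conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 6 chromosomes × 100 bins × 500 kb | large enough for multi-event karyotypes, small enough for fast tests |
| base_depth | 300 reads/bin | deep bins as in mappable-position binning of ~1–2× genomes |
| overdispersion α | 0.04 (NB var = μ(1+αμ)) | WGA noise giving MAPD ≈ 0.29, the regime where QC passes but noise is visible; α → 0 is Poisson |
| GC curve | 0.35 + 3.0·gc − 3.4·gc² | ±10% smooth multiplicative bias, invertible by the correction |
| clone tree | MRCA (5 events) → S1 (CCF 0.5) → S2 (CCF 0.3) | a linear two-subclone tumor with whole-arm-scale events |
| locus dropout | 0.6907 | measured rate in GenomePlex single-cell data |
| allelic dropout | 0.4405 | idem (false negative rate) |
| false positives | 0.0017 per covered locus | idem |
| somatic SNVs | 35 (≈ 60% truncal) | per-patient exome scale |
| gold SNPs | 200 het, 500 hom | enough covered loci for per-cell rate estimates |

Counts are negative-binomial because WGA overdispersion is precisely
the phenomenon MAPD QC exists for. Dropout, allelic dropout and false
positives are modeled at locus level, not per read: the estimators only
observe locus-level outcomes, so a per-read model would add parameters
the analysis cannot identify. Doublets are the bin-wise average of a
tumor and a normal cell's expected coverage — enough to exercise the
mixed-profile flag, not a model of real co-isolation. DTC cells carry
exactly the CNA/SNV path of their assigned clone; AU cells draw 1–2
whole-chromosome-scale events disjoint from the tree; N cells are flat.
Bulk CCFs are written from the generating truth, not estimated.

What passing these tests shows: the pipeline inverts its own generative
assumptions — segmentation recovers the true karyotype, classification
recovers the true classes (≥ 95% across seeds), rate estimators recover
the generative rates within sampling error, and tree reconstruction
recovers random topologies whenever ordering evidence exists. What it
does not show: robustness to real-data pathologies absent from the
generator — wave artifacts and non-quadratic GC structure, segmental
WGA amplicons correlated across bins, subclonal cells within one
"clone", CCF estimation error in the bulk input, or mis-specified
gold-standard SNP sets.

## Numerical and edge-case conventions

* Zero-count bins floored to 0.5 reads; zero-mappability bins are
  expected to be masked upstream of binning.
* PCF cost ties (within 1e−9) resolve toward fewer breakpoints.
* Ploidy grid ties resolve to the smallest Ψ.
* Integer copy-number state uses floor(cn + 0.5), clipped at 0.
* Beta-binomial tails: exact log-space summation; binomial fallback
  (flagged) when σ² ≥ μ(1−μ); P(X ≥ 0) = 1 short-circuit.
* Rarefaction SD is the population SD over permutations; a cohort with
  no sizeable events returns a flat zero curve with a warning.
* All pipeline randomness derives from one master seed via
  SeedSequence; identical seeds give byte-identical outputs (config
  hashes cover scientific parameters only, not paths).

## Problem sizes used in the validation suite

The bundled tests and the acceptance script run the full method on
cohorts of 18 cells × 600 bins (10 seeds), 200–500 brute-force PCF
oracle series (n ≤ 12), 10⁶-draw Monte-Carlo beta-binomial checks, 20
random trees, and 10³–10⁴-permutation rarefaction curves — sizes chosen
so the whole suite completes in well under a minute while keeping every
estimate's Monte-Carlo error far below the tested tolerances.

## Known limitations

* Single-sample CCF scales: cross-sample subclones are ordered only by
  cell evidence; a full multi-sample junction (sample-B-clonal events
  anchoring under a sample-A subclone) is reported via conflicts and
  sample labels rather than resolved automatically.
* cnLOH is invisible to the cell-side profiles (total copy number
  only); allele-aware single-cell input would be needed.
* Ploidy inference from logR alone is inherently ambiguous for flat or
  symmetric karyotypes; Ψ defaults to the smallest consistent value.
* The AU/DTC decision depends on the bulk profile being complete; an
  unsampled true subclone would misdirect cells sharing only its
  private events to AU.
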