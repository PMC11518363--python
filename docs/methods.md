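# Methods

## The analysis model

The pipeline treats a two-condition qPCR miRNome contrast as four coupled
problems: (i) turning per-well fluorescence traces into quantification
cycles, (ii) turning Cq into comparable relative expression, (iii) ranking
miRNAs by differential expression, and (iv) asking whether curated miRNA
sets concentrate at either end of that ranking. Set-level inference is the
point: no per-miRNA hypothesis tests are performed.

## Synthetic panel data

The generator emulates a commercial 384-well LNA miRNome panel: 372 human
miRNA assays, three interplate calibrators, three reference-gene assays,
five RNA spike-in controls, one blank. Per-well signal is a four-parameter
logistic, `f(c) = baseline + f_max / (1 + exp(−k (c − m)))`, with additive
i.i.d. Gaussian noise on fluorescence only. The logistic was chosen because
its second-derivative maximum has the closed form `m − ln(2+√3)/k`
(the maximum of `L''` falls at `L = (3−√3)/6`), so the generator can place
`m` such that the true SDM Cq is known exactly — every downstream stage
then has an exact oracle.

Study conditions and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_samples_per_condition` | 3 | replicate panels per condition; the original profiling does not state a replicate count, so the field-typical minimum for a two-group contrast is used |
| `de_effect_size` | 2.0 Cq | planted shift; one cycle = one doubling on the 2^−ΔCq scale |
| `noise_sd` | 0.1 | fluorescence noise SD (≈1% of the 10-unit plateau), yielding ≈0.03-cycle Cq error |
| `interplate_offset_sd` | 0.3 Cq | per-sample plate offset (each sample runs on its own plate); what calibration must remove |
| `base_cq_mean`, `base_cq_sd` | 25.0, 2.5 | per-assay baseline Cq, clipped to [20, 33] so curves plateau within 45 cycles |
| `n_cycles` | 45 | standard qPCR run length |

Direction convention is standard qPCR semantics: "up-regulated in condition
2" = condition-2 Cq lowered by the effect size. Planted sets shift all
members coherently; a member assigned conflicting directions by overlapping
sets is a configuration error. Reference genes, calibrators and spike-ins
are condition-invariant by construction; the blank yields a flat trace.

What the generator does **not** emulate: PCR efficiency differences and
chemistry, melt curves, correlated (plate-layout or batch) noise beyond the
single interplate offset, partially amplifying wells, and the heavy
right tail of low-expressed miRNAs near the detection limit. Passing tests
therefore demonstrate correctness of the algorithms under a clean
generative model, not robustness to every artifact of real panel data.

## Cq calling

The quantification cycle is the SDM of the amplification curve. Local
estimators (moving-average or Savitzky–Golay smoothing followed by discrete
second differences and quadratic interpolation) were evaluated first and
rejected on measurement: at slope k = 2 the second-derivative peak has
width ≈ 1/k cycles, under-resolved at the one-cycle sampling interval, and
the best local variant had worst-case error ≈ 0.27 cycles on noiseless
curves — far outside the 0.05-cycle accuracy the pipeline targets. The
caller therefore fits the four-parameter logistic directly
(Levenberg–Marquardt, analytic Jacobian, initialized from the half-rise
crossing of a centered moving average) and evaluates the SDM analytically
from the fitted `(k, m)`. On noiseless curves the worst-case error over
k ∈ [0.5, 2], Cq ∈ [15, 33] is ≈ 1e−14 cycles; at the default noise it is
≈ 0.03 cycles (mean), ≈ 0.4 ms per well.

Detection gate: a well is undetermined when the smoothed amplitude rise is
below `detection_snr` (default 5) times the residual noise estimate
`std(raw − smoothed)`. This makes blanks undetermined by construction while
the ≥ 5-unit rise of true amplification passes easily. Fits that fail to
converge, or whose SDM leaves the cycle range, are also undetermined.

## Preprocessing

- **Interplate calibration** subtracts (plate-mean calibrator Cq − global
  mean calibrator Cq) per plate; idempotent by construction. A plate with
  all calibrators undetermined is a QC failure.
- **Spike-in QC** compares each sample's spike-in Cq, per assay, against
  the leave-one-out mean and SD of the remaining samples. Leave-one-out is
  used because a pooled SD masks the very outlier being sought (with n ≤ 6
  samples a 10-SD shift cannot exceed a pooled z of ≈ 2). The SD enters
  through `max(SD, 0.125)` cycles: with few samples the leave-one-out z is
  t-distributed with few degrees of freedom, and spike QC is meant to catch
  gross technical failures, so sub-0.375-cycle deviations (at the default
  3-SD tolerance) never flag a sample. The report is advisory; it does not
  gate the pipeline.
- **ΔCq normalization** uses the arithmetic mean of reference-gene Cq
  (standard ΔCq practice; configurable), `expression = 2^{−ΔCq}`.
  Undetermined Cq propagates to missing values — never zero. miRNAs
  undetermined in more than half the samples of either condition (threshold
  configurable) are dropped before ranking.

## Ranking

Default score: log2 fold change of condition means on the expression scale,
equivalently −ΔΔCq. A signal-to-noise option `(μ₂−μ₁)/(σ₁+σ₂)` is provided
for consistency with the GSEA lineage. Ties break lexicographically so the
ranking is a deterministic function of the matrix. Degenerate scores (a
zero condition mean) are capped at ±(max finite |score| + 1) with a
warning, keeping the list total and finite.

## Enrichment statistic

Classic unweighted (Kolmogorov–Smirnov-style) increments: +1/G at members,
−1/(N−G) at non-members; the description of the procedure is pure
enhance/reduce cumulative summation, so no score-weighting is applied. ES
is the signed value at the maximum |running sum|; on an exact tie the
positive peak wins, then the earlier rank (a 1e−12 tolerance absorbs
floating-point accumulation differences). The trace starts at the first
increment and telescopes to zero; |ES| ≤ 1 always.

The null permutes set labels — B random G-subsets of the ranked universe —
rather than sample labels, because the statistic operates on a single
differential ranking (with 3 samples per condition a sample-permutation
null would also be far too coarse). B defaults to 1000; when C(N, G) ≤
10,000 every subset is enumerated instead. Null scores for equal G are
shared across sets, since the null distribution depends only on G. A
closed-form vectorized evaluator (extremes of the running sum from sorted
hit positions) computes null batches and is tested for exact agreement with
the cumulative-sum walk.

NES = ES / mean(|same-sign null ES|); with no same-sign null values the
full null's magnitudes are used, with a warning. The nominal p is the
add-one estimator `(1 + #{|null| ≥ |ES|, same sign}) / (1 + #same-sign)`,
which can never reach zero (floor 1/(B+1) — consistent with reference
p-values that floor at 0.05, i.e. B = 19-scale resolution). FDR follows the
GSEA convention: pooled null NES tail fraction over observed NES tail
fraction, same sign, clipped to [0, 1], then made monotone non-decreasing
in the nominal p within each sign class. FDR pools within each category by
default because the reference figures analyze one category at a time; a
global option exists.

Report filters: significance keeps `p ≤ 0.05`; the ES filter keeps
`|ES| ≥ 0.25` inclusive (the reference functional table itself retains a
set at ES = −0.25). Candidate annotation operates on the union.

## Set collections and names

GMT dialect: `set name TAB category[;tsi=x] TAB members…` — a standard GMT
file whose description field carries the six-way category and, for tissue
sets, the tissue-specificity index (filtered at ≥ 0.7 inclusive). Names
normalize to lowercase `hsa-mir-*` (species prefix added when missing,
`hs-` typo corrected). Base-name matching strips `-3p/-5p` arms and
trailing paralog letters; it is ON by default in candidate annotation
because the reference analysis itself links hairpin-level set members
(hsa-mir-182) to mature-level prediction evidence (miR-182-5p). Sets are
restricted to the ranked universe before scoring (minimum surviving size 2,
matching the smallest reference set).

The packaged reference tables include two recorded inconsistencies that the
package preserves rather than resolves: the per-category enriched-set
counts sum to 147 while the reported total is 144; and the published
candidate annotation strings list sets ("DNA Repair" for mir-182, "AKT
Pathway" for mir-214) that do not contain those miRNAs in the published set
memberships. `annotate_candidates` derives annotations from membership, so
its output differs from the published strings at exactly those points.

## Problem sizes and determinism

The validation experiments use the full 372-assay panel. Planted-set
recovery runs the complete curve-to-enrichment pipeline 100 times in the
test suite (50 in the acceptance script) with G = 5, Δ = 2, noise 0.1;
null-calibration uses 1000 replicates per set size G ∈ {2,…,8} at B = 1000.
These sizes give rate estimates with ≈ 3-percentage-point standard errors
while keeping a full run in minutes on one core. All randomness flows
through seeded `numpy` generators; the pipeline manifest records SHA-256
digests of every artifact, and identical config + seed reproduce them
byte-identically.

## Known limitations

- Exact reproduction of the reference ES/NES tables is impossible in
  principle: the underlying expression data were never deposited. The
  reference tables function as filter fixtures and planted ground truth,
  not as recomputation targets.
- The NES normalization, permutation scheme and FDR of the original
  set-enrichment tool are not published in detail; the conventions here
  follow the GSEA lineage it cites and are documented above as assumptions.
- The Cq caller assumes a sigmoid-shaped curve; exotic amplification
  artifacts (double rises, drifting baselines) are outside its model and
  will surface as undetermined wells or poor fits rather than being
  corrected.
- With 3 samples per condition the ranking metric estimates condition
  means with little averaging; the enrichment inference conditions on the
  observed ranking and does not propagate between-replicate uncertainty.
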