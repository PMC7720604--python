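# Methods

## Scope and data model

`bloompheno` operates downstream of an object detector. Its inputs are
per-image detection records — bounding boxes in pixel coordinates (origin
top-left, corner form, inclusive extents), a class label, and a confidence
score — grouped by plant, scan date (days after planting, DAP) and viewing
angle (up to 4 views per plant per date). Two label taxonomies are
supported: the 5-class set {target_plant, emerging_bloom, opened_boll,
specular_region, other} and its 3-class reduction that collapses the last
three into non_bloom; the reduction preserves every plant and bloom record
exactly. Calendar dates in input files are converted to DAP from a
configured planting date (default 13 June 2018). Missing views are
tolerated (aggregation uses the views present) but logged; duplicate view
indices in one scan are an error, not a warning, because they make counts
ambiguous.

## Counting

Confidence filtering keeps detections with score ≥ threshold (default 0.7;
equality kept, so only strictly lower scores are removed). Plant-based
counting selects the highest-confidence target-plant box (several plant
boxes in one image are flagged; none at all yields count 0 with a flag
rather than silently falling back to whole-image counting, which would
change the strategy's semantics per image) and counts emerging-bloom
detections whose box centroid lies inside it. Centroids exactly on the
boundary count as inside — a measure-zero case that still needs a
deterministic rule. Per-date aggregation defaults to the maximum over
views; sum and mean are implemented for ablations (mean divides by the
number of views actually present). Structural consequences, enforced by
tests: plant-based ≤ whole-image ≤ total detections per image; max ≤ sum
per scan; raising the threshold never increases any count.

## Curves and characteristics

The cumulative flowering curve is P_k = Σ_{i≤k} C_i / Σ_{i≤N} C_i on scan
dates, extended between scans by previous-value (step) interpolation and 0
before the first scan — counts are observations on discrete days, so no
smoothing or parametric fit is applied. The numerator and denominator
always use the same counting method (imaging curves normalize by imaging
totals, manual curves by manual totals). A plant with zero total blooms
has no curve; such plants are excluded and reported, not dropped. Group
curves are pointwise means with sample standard deviation (ddof = 1,
configurable) over step-interpolated member curves.

FBD is the first scan date with a nonzero count (computed from the count
series, so it exists even before 5% is reached); FSD and FED are the first
scan dates with P ≥ 0.05 and P ≥ 0.95 (thresholds attained exactly count
as attained; no between-date interpolation); FD = FED − FSD. All four are
invariant to rescaling counts by a positive constant.

## Statistics

*Regression through the origin.* Imaging counts are regressed on manual
counts with no intercept: slope b = Σxy/Σx², RMSE from the residuals, and
the uncentered R² = 1 − Σ(y−bx)²/Σy² (the centered definition can be
negative without an intercept and is not standard there).

*Error analysis.* Signed errors (imaging − manual) are binned on integers.
Relative errors e/manual are computed for the subset with |e| ≤ 1 and
manual > 0: "absolute error less than one bloom" is not satisfiable by a
nonzero integer error, so the boundary is included — the inclusive reading
is what makes the relative-error histogram nondegenerate. Samples with
manual = 0 but imaging > 0 form their own labeled bin, excluded from
relative errors. Mean signed error is reported per manual bloom load 0–12
(higher loads clipped into the top group) and mean cumulative-percentage
error per manual-cumulative decile (0–10% … 90–100%).

*ANOVA.* The genotype × transplant-batch factorial uses Type-II sums of
squares, appropriate for the unbalanced design (unequal survivors per
batch). One-way analyses use Tukey's HSD for pairwise comparisons
(pairwise t with Holm correction available behind a switch). The compact
letter display is built from the maximal cliques of the non-significance
graph, which guarantees that any two groups sharing a letter have adjusted
p ≥ α; groups are ordered by ascending mean before letters are assigned.
The coarser +/− display marks a group that is significantly higher
(respectively lower) than every group it differs from.

*Effect size and replicate estimation.* Cohen's f = √(η²/(1−η²)) with
η² = SS_between/SS_total, the convention used when deriving the effect
size from observed variances. The minimum replicates per group is the
smallest n ≥ 2 (n = 2 is the floor — error df must be positive) such that
a balanced fixed-effects one-way ANOVA with k groups reaches the target
power: power = P(F′ > F_crit) with F′ noncentral F(df1 = k−1,
df2 = k(n−1), λ = f²·n·k) and F_crit the central-F upper-α quantile. The
search is a short upward integer scan; power is monotone in n, so the
first hit is minimal. The implementation reproduces the published
replicate table for the three flowering traits exactly
(f = 1.18, 1.52, 0.88; k = 22 and 200; α = 0.05; power 0.95 → n = 2, 2,
2, 2, 3, 2).

*Power formula cross-check.* The analytic power is validated in the test
suite against a Monte-Carlo oracle (4000 simulated one-way F tests at
f = 0.5, k = 3, n = 10) to within 3 percentage points.

## Frequency study

Scan dates are partitioned into weeks relative to the first date
((dap − first) // 7) and the first m dates of each week are kept (m = 2 or
1), starting at a configurable offset; a seed-controlled random-thinning
variant exists for sensitivity checks. Which dates the original study kept
when thinning is not documented; the deterministic first-of-week rule was
chosen for reproducibility.

Curve fidelity is the mean absolute difference between two curves on the
union of their scan dates (step interpolation), in percentage points. The
full-schedule manual group curve is the fixed reference at every
frequency; only the imaging counts are thinned. This choice is deliberate:
blooms open for a single day, so a bloom opening on a dropped scan date is
lost from the thinned curve entirely, and the gap to the dense reference
grows as the schedule coarsens (~2% → ~3.5% → ~5% per category on the
default synthetic study). Thinning the reference alongside the imaging
data would instead coarsen both curves in step and leave the difference
nearly flat, which would make the frequency comparison uninformative.
Characteristics are re-extracted from each thinned count table
(renormalized to its own total), and group letter displays can be rerun on
them.

## The simulator

The generator emulates the study design the pipeline targets: 23 genotypes
in 3 genetic categories (10 elite upland, 12 diverse exotic accessions, 1
long-window extra-long-staple genotype), 5 replicate plants per genotype,
26 scan dates from DAP 68 at 2/2/3-day spacing (three per week), 4 views
per plant per date. Replicates split 3/2 into two transplant batches;
batch-2 plants flower 6 days later. Daily emergence is Poisson with a
genotype-specific intensity (Gaussian bump or Beta(2,2) density over the
flowering window) normalized so the pre-dip expected season total equals
the genotype's mean bloom production; two weather events (DAP 95 and 103)
multiply the intensity by 0.3–0.4 for three days in most genotypes.

Blooms are countable only on their opening day — the central modeling
choice. It is what couples observation to the scan schedule (blooms
opening between scans are unobserved by any method, which is exactly why
collection frequency matters) and it makes the manual reference counts,
modeled as exact truth on scan days, per-scan-date quantities like the
imaging counts.

Detector noise is modeled at the level of its net effect. Each true bloom
is visible from each view independently with probability p_vis = 0.85
(occlusion; per-bloom-per-view Bernoulli, shared bloom identities across
views, so the max-over-views count can never exceed the true count).
Each visible bloom is detected with p_det = 0.9, defined as the
probability of producing a detection that *survives* the confidence
filter; accordingly true-detection scores are drawn above the operating
threshold (truncated normal, mean 0.9) — modeling sub-threshold true
scores separately would double-count the same miss mechanism. False
positives are Poisson per image (rate 0.3), half with centroids outside
the plant box, with scores straddling the threshold (truncated normal,
mean 0.6, sd 0.15 on [0,1]), so the 0.7 filter is exercised. p_vis and
p_det are not field-calibrated constants; they were chosen once to
reproduce the qualitative error structure (undercount growing with bloom
load, cumulative-percentage errors far smaller than count errors), not any
particular published error bar.

What the simulator deliberately does not model: duplicate-bloom identity
across views (the pipeline's max aggregation makes this unnecessary),
pixel appearance and illumination failure modes (only their net
miss/false-positive effect), within-genotype phenology variance beyond
Poisson noise, and detector localization error (boxes are placed exactly
where blooms are). Passing tests therefore demonstrate correctness of the
analysis pipeline under the stated noise model, not field accuracy of any
particular detector.

## Ground truth for parameter recovery

Recovery tests compare pipeline-extracted characteristics against
characteristics computed directly from the simulated true emergence
restricted to scan days, via an independent partial-sum path that never
touches the detection pipeline. Scan-day truth (rather than the full daily
grid) is the honest reference under the opening-day model: a single bloom
opening between two scans is invisible to *any* per-scan-date method, and
daily-grid characteristics can legitimately differ from scan-day ones by
more than a scan interval for sparse bloomers. With a perfect detector
(p_vis = p_det = 1, no false positives) the pipeline recovers scan-day
truth exactly for all 115 plants; the acceptance tolerance of one scan
interval is an upper bound, not the observed error.

## Problem sizes and numerical choices

The default study (115 plants × 26 dates × 4 views ≈ 12k images, ~100k
detections) simulates in a few seconds; the full test suite runs in about
half a minute and the acceptance script in under a minute. Threshold
comparisons on cumulative fractions use a 1e-12 float tolerance so exactly
attained 5%/95% thresholds are never missed to rounding; the final curve
value is pinned to exactly 1. The replicate search caps at n = 10⁴ and
raises beyond it. All randomness flows from a single integer seed through
`numpy.random.default_rng`; fixed seed implies byte-identical simulator
output files.

## Known limitations

- Max-over-views counting saturates at high bloom loads (no single view
  shows every bloom); absolute count curves are therefore qualitative.
  Cumulative curves mitigate this because the shortfall enters numerator
  and denominator alike — the property the error analysis quantifies.
- Compact letter displays are not unique in general; the maximal-clique
  construction guarantees correctness (shared letter ⇔ some mutually
  non-different set) but not minimal letter count.
- The COCO-style reader expects the documented plant/date/view image table
  inside the JSON; arbitrary third-party COCO files need that table added.
- Week partitioning for thinning is relative to the first scan date, not
  ISO calendar weeks; with the default schedule these coincide up to an
  offset.
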