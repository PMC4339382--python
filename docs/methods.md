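# Methods

## Event model and the minimum event distance

Profiles are integer copy numbers of the two parental alleles over a
shared segmentation (1-based inclusive coordinates; chromosomes in
natural order 1–22, X, with Y accepted and carried through). An event
adds +1 (amplification) or −1 (deletion) to a contiguous run of segments
on one haplotype. Zero is absorbing: a segment at 0 is unaffected by any
event spanning it — a deletion removing material around an already-lost
region counts once — and can never be regained. Haplotypes evolve
independently; a pair's distance is the sum of its two haplotype
distances. Whole-genome doubling is deliberately not modelled as an
atomic event.

`med_asym` solves the directed problem exactly with a dynamic program
over segment positions. Any optimal event sequence can be normalised to
run all deletions before all amplifications once a *slack* channel is
allowed: a deletion run may overshoot a surviving segment by *s* copies
provided *s* later amplification passes repay it. The DP state is the
pair (open deletion runs, open amplification runs) at the current
boundary; opening a run costs one event, closing is free, and per
segment the admissible states are

* `u_i = 0` — transparent, no constraint (runs bridge for free);
* `v_i = 0 < u_i` — deletion coverage ≥ `u_i` (passes beyond the loss
  are free), amplification coverage free (the segment is gone before the
  amplification phase);
* `u_i, v_i > 0` — coverage `(max(0, u_i − v_i) + s, max(0, v_i − u_i) + s)`
  for slack `s ≤ min(u_i, v_i) − 1`, the bound being survival through
  the deletion phase.

The slack channel is not cosmetic: `[1,1,2,3] → [2,0,2,2]` costs 2 (one
deletion run spanning segments 2–4, one amplification run spanning 1–3
across the newly lost segment), which no phase-separated decomposition
without slack finds. Correctness is defined operationally: the DP agrees
with an exhaustive breadth-first search over event sequences on every
random instance the suite draws (several thousand, lengths ≤ 5, copies
≤ 4), and the zero-free case reduces to the closed-form skyline count.
The inner loop is jitted with numba; the source is plain Python and runs
identically without it.

Symmetrization takes the cheaper feasible direction; when each profile
has lost a segment the other retains, both directions are infeasible and
the distance is routed through the component-wise maximum as a minimal
common ancestor, `d(m,u) + d(m,v)`. This preserves finiteness and
reduces to the directed value whenever one direction is feasible.

## Phasing

The flip decision is per segment and shared across samples, which keeps
haplotypes comparable patient-wide; the objective is the total pairwise
distance including the diploid pseudo-sample. Exhaustive enumeration is
used up to 12 ambiguous segments (4,096 assignments); beyond that a
greedy left-to-right pass on the prefix objective is refined by
single-segment flip hill climbing to a local optimum. On 200 small
simulated instances the heuristic matches the exhaustive optimum in
≈ 90% of cases and is never better (it cannot be) nor more than a few
events worse. Repeated pair evaluations are memoized, which is what
makes the exhaustive search affordable.

## Trees, support, and tree-shape tests

Neighbour joining runs on the full matrix including the diploid; the
tree is re-rooted at the diploid leaf so root-to-leaf paths measure
divergence from the normal genome. Negative NJ branch lengths are
clamped to zero. Support values are segment-bootstrap frequencies
(resample segment indices with replacement, recompute distances and the
tree; default 100 replicates, seeded); the method is a pragmatic default
— segment counts are modest, so supports should be read comparatively,
not as calibrated probabilities.

The star test fits E[d_ij] = b_i + b_j with b ≥ 0 by NNLS over all taxa
including the diploid (which is what makes three-sample patients
testable, df = n(n−1)/2 − n ≥ 1 needs a fourth taxon) and refers
Σ (d−ê)²/max(ê, ε) with ε = 1 event to χ² on those df. The χ² reference
is approximate; on simulated star cohorts with integer noise the
empirical size at α = 0.05 is well below 0.15 (measured ≈ 0.0–0.05), and
two-clade cohorts separated by a 30-event internal edge are rejected in
≥ 90% of seeds. The clock test refers the dispersion index
Σ (ℓ_i − ℓ̄)²/ℓ̄ of root-to-leaf path lengths (diploid excluded — it *is*
the root) to χ² with n−1 df. Both p-value families are BH-corrected
across patients.

## Landscape, TH, and CE

Classical MDS double-centers the squared distance matrix and keeps
dimensions with eigenvalue > 10⁻⁸ × the largest; signs are fixed by
making each dimension's largest-magnitude loading positive, so
coordinates are deterministic. The diploid is excluded from the
landscape: the indices describe the tumour samples.

The robust centre of mass is the geometric median (Weiszfeld iteration
with the Vardi–Zhang step when an iterate lands on a data point;
tolerance 10⁻⁹, ≤ 1,000 iterations). TH is the distance between the
biopsy and surgery centres in raw event units (no normalisation), and is
missing when either timepoint is unsampled.

CE is −log₁₀ of a Monte-Carlo p-value: observed statistic W = mean
nearest-neighbour distance; null = `n_null` (default 10,000) draws of
the same number of points uniform in the axis-aligned bounding box of
the observed coordinates; p = (1 + #{W_null ≤ W_obs})/(n_null + 1).
Conditioning the null on the observed bounding box makes the test
**conservative**: the observed configuration spans its own box, so under
uniform truth the null draws look slightly more clustered and the null
CE concentrates near 0 (measured median ≈ 0.03) rather than at
−log₁₀ 0.5. This is acceptable for the index's purpose — separating
clustered from diffuse cohorts, which it does by ≈ 2.5–3 CE units in
simulation — but CE values should be compared within an analysis, not
read as calibrated −log₁₀ p. A fully degenerate configuration (all
samples identical) is maximally clustered and reports the maximum
attainable CE.

Dichotomization uses the lower median (inverse empirical CDF at 0.5,
i.e. the ⌈n/2⌉-th order statistic), with CE-high meaning strictly
greater; quartiles use the same convention. The interpolated-median
convention is also provided because the two summaries commonly reported
for this kind of cohort (median 0.73, IQR 0.65–1.24 vs median 0.74, IQR
0.66–1.15) differ exactly by this choice; lower-median is the default.

## Survival

Durations are days; medians are Kaplan–Meier medians divided by 30 and
rounded to one decimal — the 30-day month is the convention under which
the packaged cohort's four group medians (12.7/10.1 and 42.6/23.5
months) are exact. The packaged summary table carries no censoring
flags, so its event indicators default to "observed"; medians are
unaffected, but log-rank and Cox p-values computed from the fixture are
illustrative. Cox models use Efron tie handling (lifelines);
non-convergence and separation are flagged and reported as missing
rather than raised. The spline check fits a natural cubic basis (knots
at quantiles, L2 penalty) for the marker in the Cox linear predictor and
reports the centred log relative hazard with pointwise Wald bands over
the inner 95% marker range; it is a shape diagnostic, not a test.

The robustness bootstrap resamples patients with replacement and redoes
the whole dichotomize-and-test procedure per replicate. Replicates that
collapse to one group are counted and excluded from the denominator.
Because resampling duplicates subjects and the split is re-derived per
replicate, the significant fraction under a true null is inflated above
the nominal 5% (measured ≈ 0.15–0.2 averaged over null cohorts); the
fraction is informative as a robustness measure relative to the strongly
separated regime (> 0.9), not as a size-α test.

## Synthetic cohorts

The generator emulates clonal evolution directly in the event model the
distance counts: a near-diploid founder (heterozygous fraction 0.5 of
segments at (2,1), the rest (1,1)), a per-patient clone tree (star, or
random bifurcating via sequential attachment, or k tight clusters), and
Poisson(events_per_branch) events per branch with geometric run lengths
(mean 3 segments — long enough that events overlap and stress MED
optimality), uniform haplotype and sign, applied with zero absorption.
Defaults (6 samples, 40 segments, 6 events per branch) give per-patient
divergences of tens of events, the scale seen in multi-sample HGSOC
cohorts. Clusters shrink within-cluster branch rates by the tightness
factor (default 0.05); the long-internal-edge regime used to benchmark
the star test sets the hub-branch rate to 30 events, matching the
magnitude at which branched topologies become unambiguous. Survival
times are exponential with hazard scaled by exp(group log-HR), censored
administratively at the (1 − censoring fraction) quantile of the
baseline distribution.

What the simulator does **not** model: array noise and segmentation
error, tumour-cell admixture within a sample (each sample is one clone;
cellularity labels exist only to exercise QC), whole-genome doubling,
and breakpoint-level rearrangement structure. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
event model, not robustness to measurement noise in real arrays.

## Problem sizes and determinism

The validation studies use deliberately modest sizes chosen to exercise
each contract: 1,000 random MED instances against the BFS oracle, 200
phasing instances against exhaustive search, 50 six-leaf cohorts for
topology recovery (exact recovery ≈ 75%), 200 seeds per condition for
star-test discrimination, 20 per condition for CE separation, n = 500
for Cox recovery and 100 replicates of 200-per-arm for log-rank power.
All randomness flows from explicit seeds; the pipeline writes
byte-identical bundles when re-run with the same seed and inputs.

## Known limitations

The MED normal-form argument (deletions before amplifications, with the
slack channel) is validated exhaustively on small instances rather than
proved; the star and clock χ² references are approximate; CE is
conservative and scale-dependent through its bounding-box null; the
segment bootstrap treats segments as exchangeable units, ignoring their
genomic lengths; and the phasing heuristic is a local optimum beyond the
exhaustive threshold.
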