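# cnevol

Evolutionary analysis of multi-sample tumour copy number profiles:
minimum-event-distance phylogenetics on allele-specific integer copy
numbers, quantitative intra-tumour heterogeneity indices, and survival
analysis of the resulting patient groups.

The package targets copy-number-driven cancers sampled at multiple
anatomical sites and timepoints — the motivating setting is high-grade
serous ovarian cancer (HGSOC), where each patient contributes several
spatially and temporally separated biopsies profiled as segmented integer
copy numbers of the two parental alleles. It is aimed at computational
biologists who want to reconstruct each patient's clonal history from
such profiles and relate summary measures of that history to clinical
outcome.

## The model

**Minimum event distance (MED).** The elementary somatic event is a
segmental amplification or deletion: it selects a contiguous run of
segments on one haplotype and adds ±1 to every selected segment. A
segment at copy number 0 is absorbing — it is unaffected by events
spanning it and can never be regained. The directed distance
`med_asym(u, v)` is the minimum number of events transforming profile *u*
into profile *v* (infeasible when *v* needs copies where *u* has lost
both). Away from zero it reduces to the two-sided skyline count

&nbsp;&nbsp;d(u, v) = Σᵢ max(0, pᵢ − pᵢ₋₁) + Σᵢ max(0, nᵢ − nᵢ₋₁),

with *p*/*n* the positive/negative parts of *v − u*; with zeros it is
computed by an exact dynamic program whose correctness is pinned to an
exhaustive breadth-first-search oracle in the test suite. Distances are
symmetrized by taking the cheaper direction, falling back to a
component-wise-maximum ancestor when neither direction is feasible.

**Phasing.** Arrays report the unordered (major, minor) copy-number pair
per segment. Per segment, one global flip decides which haplotype takes
the major allele; the flip vector is chosen to minimise the summed
pairwise MED over all samples plus an implicit diploid pseudo-sample
(exhaustively for ≤ 12 ambiguous segments, greedily with hill climbing
beyond).

**Trees and tree-shape tests.** Neighbour joining on the per-patient MED
matrix (diploid included), re-rooted at the diploid, gives a tree with
branch lengths in event units; split confidence comes from a segment
bootstrap. A star-topology goodness-of-fit test (E[d_ij] = b_i + b_j by
non-negative least squares, χ² statistic) asks whether all samples
radiate independently from the ancestor; a dispersion test on
root-to-leaf path lengths asks whether evolution is clock-like. Both are
Benjamini–Hochberg corrected across patients.

**Heterogeneity indices.** Classical multidimensional scaling embeds each
patient's samples into a Euclidean "mutational landscape". The **TH
index** (temporal heterogeneity) is the distance between the geometric
medians of pre-chemotherapy biopsy and interval-debulking surgery
samples, in event units. The **CE index** (clonal expansion) is
−log₁₀ p for a Monte-Carlo test of local clustering: the observed mean
nearest-neighbour distance is compared with draws of the same number of
points uniform in the bounding box of the observed coordinates. The
cohort is dichotomized at the lower-median CE (CE-high ⇔ CE strictly
above it) and the groups compared by Kaplan–Meier/log-rank, Cox
regression, and a patient-level bootstrap.

## Worked example

The packaged per-patient summary table of the 17-patient HGSOC cohort
(14 evaluable with ≥ 3 post-QC samples) drives the cohort-statistics
stages directly:

```
$ cnevol survive --n-boot 200 --seed 1
```

prints, among other fields,

```
"PFS": { "median_low_months": 12.7, "median_high_months": 10.1,
         "logrank_p": 0.00906, ... },
"OS":  { "median_low_months": 42.6, "median_high_months": 23.5,
         "logrank_p": 0.00283, ... }
```

i.e. the 14 evaluable patients split 7/7 at the lower-median CE of 0.73
(quartiles 0.65–1.24), and the CE-high group progresses earlier (10.1 vs
12.7 months) and dies earlier (23.5 vs 42.6 months). The log-rank
p-values shown assume every endpoint event was observed, since the
summary table does not carry censoring flags. Bootstrap summaries
(`frac_significant`, `median_hr`) quantify how robust the group contrast
is to patient resampling.

A fully synthetic end-to-end run with known ground truth:

```
$ cnevol simulate --seed 3 --n-patients 6 --out sim/
$ cnevol run --segments sim/segments.tsv --metadata sim/metadata.tsv \
             --clinical sim/clinical.tsv --out results/ --seed 3
```

which writes per-patient Newick trees and distance matrices,
`cohort_indices.tsv` (TH/CE, star and clock tests per patient), and
`survival.json`.

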