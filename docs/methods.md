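# Methods

## Problem setting

A PDX bank maintains lineages: one patient tumor (PT) and its serial mouse
passages P1…Pn. Three QC questions recur: (i) how much has a passage drifted
genetically from its PT, (ii) is a given sample really from the lineage it
claims, and (iii) has a graft been overtaken by mouse lymphoproliferative
tissue. All three are answered here from one measurement: genotype calls over
a fixed signature of common biallelic SNPs.

## Concordance and drift

Calls are encoded 0/1/2 (major-homozygote, heterozygote, minor-homozygote)
with missing as NA. For two aligned vectors, concordance is the fraction of
markers *called in both samples* at which the states are identical;
comparison is pairwise-complete and the number of co-called markers is
always reported, so a low-call-rate sample cannot hide behind a fraction
computed on ten markers. A pair with zero co-called markers is an error, not
a concordance of zero. The alteration rate 1 − concordance is the drift
measure; "alteration" is a symmetric state mismatch — no directionality is
assumed, since a genotyping assay cannot distinguish gain from loss at a
single site.

Per lineage, two trajectories are computed and labelled explicitly, because
a per-passage drift profile can legitimately mean either comparison:
*cumulative* (PT vs Pn) and *incremental* (Pn−1 vs Pn), with
incremental[1] ≡ cumulative[1]. Pooling across lineages reports mean ± SEM
per passage index (SEM with ddof = 1; a passage contributed by one lineage
reports SEM 0 and carries a `single_lineage` flag rather than NaN, so
downstream tables stay numeric).

Lineages are classified UNSTABLE when PT-vs-P1 concordance falls below a
threshold, default 0.95 — the midpoint between the stable-class (98.2%) and
unstable-class (90.0%) initiation concordances the design targets. The
comparison is inclusive (exactly 0.95 is STABLE). A threshold classifier is
used rather than a multiple-comparison test against the cohort because the
decision is per-lineage and the two classes are separated by ~8 points,
several times the sampling error of a 300-marker concordance.

## Panel selection

MAF is estimated from reference genotypes as min(f_B, 1 − f_B) with
f_B = (2·n_BB + n_AB)/(2·n_called); markers with zero called genotypes are
flagged NaN. Selection keeps markers with MAF ≥ 0.40 (inclusive) and, when
call rates are supplied, call rate ≥ 0.95 (standard array QC, applied before
ranking). Among qualifiers the top 300 by descending MAF are taken —
maximizing discriminating power — with (chromosome, position) as a
deterministic tie-break; the final panel is stored in genomic order. Both
population-MAF and cohort-estimated-MAF paths are supported (`select_panel`
accepts either the catalog MAFs or `compute_maf` output). No
linkage-disequilibrium pruning is done; for identity fingerprinting,
residual LD only makes markers slightly redundant, not misleading.

## Authentication rule

Thresholds: MATCHED at concordance ≥ 0.80, CONTAMINATED below 0.30,
UNRELATED between, INDETERMINATE when fewer than 50 markers are co-called,
and a call-rate gate: either sample below 0.50 call rate ⇒ CONTAMINATED
regardless of concordance, checked first — mouse DNA on a human-specific
array primarily *fails to genotype*, so a collapsed call rate is the
stronger contamination signal. The 0.80/0.30 cutoffs sit in the wide empty
margins between the three concordance regimes (~0.94+ matched, ~0.39
unrelated, ~0.21 contaminated); all four numbers are configurable. The
50-marker floor bounds the standard error of the fraction (≈ 0.07 at
concordance 0.5) below the narrowest margin between cutoffs.

## Synthetic cohort generator

The generator produces data with the statistical properties the analysis
assumes, at the study's scale, so that every estimator can be tested for
parameter recovery.

* **Markers.** MAFs from a three-part mixture (45% rare U(0.001, 0.05), 35%
  intermediate, 20% common over the configured MAF window), positions
  strictly increasing per autosome. The mixture shape only needs to supply
  enough common markers for selection; the rare excess mimics an exonic
  catalog.
* **Patients.** Per marker with MAF q: HOM_A with (1−q)², HET with 2q(1−q),
  HOM_B with q²; base missingness 1%.
* **Passages.** Each called site is altered with probability d; HET becomes
  a random homozygote (loss of heterozygosity, the dominant mode in
  genomically unstable serous carcinoma) and a homozygote becomes HET. Every
  alteration is a detectable state change, so the measured alteration rate
  is an unbiased estimate of d. Defaults: initiation drift 0.018
  (stable class) / 0.100 (unstable, 8 of 17 lineages), 0.006 per passage
  P2–P6, 0.037 at P7.
* **Stroma.** Mouse stromal admixture (fraction drawn U(0.27, 0.55) per
  sample) does not change genotype identity — human-specific probes are
  assumed not to cross-hybridize — but adds missingness of
  0.2 × fraction (so 27–55% stroma costs ~5–11% call rate). The 0.2 scale is
  a modelling constant: admixture mainly dilutes intensity rather than
  failing probes outright, so only a minority of affected probes drop below
  calling confidence.
* **Contamination.** A lymphoma sample is modelled phenomenologically, not
  mechanistically: call rate collapses to 0.40, and each called marker
  copies the reference (the lineage's PT in cohort simulation) with
  probability 0.21, otherwise lands uniformly on one of the two other
  states. Expected concordance against the reference therefore equals the
  configured match rate exactly. A probe-level mechanism for mouse DNA on a
  human array is not identifiable from concordance summaries alone, and
  reference-free genotype draws cannot reach 21% against a MAF ≥ 0.40 panel
  (the floor is ≈ q̄² ≈ 20% only at a degenerate all-minor-homozygote
  profile, and 0% is unreachable); the reference-aware rule makes the
  calibration target a model parameter instead.
* **Duplicates.** A copy of the PT re-run with assay noise (default 0),
  exercising the 100%-concordance identity check.
* **Seeding.** One master seed; each sample's stream is
  `SeedSequence(seed, spawn_key=(namespace, lineage, passage))`, so any
  sample regenerates independently and cohorts are byte-identical across
  runs. Contaminated passages are injected as per-passage assay
  replacements — propagation continues from the underlying (clean) tumor —
  so the ground-truth manifest controls exactly which samples are
  contaminated; a multi-passage takeover is configured by listing several
  passages.

The manifest records the generating parameters per lineage (class, drift
per passage, stromal fractions, contaminated/duplicate sample ids) for
recovery tests, and round-trips through YAML/JSON.

**What the generator does not emulate:** linkage disequilibrium and
population structure (markers are independent), copy-number events, shared
ancestry between "unrelated" samples, batch effects, and any probe-level
intensity behaviour. Passing recovery tests therefore shows the estimators
are correct under the stated model, not that real cohorts satisfy the
model; in particular real unrelated-pair concordance runs ~1 point above
the independent-markers expectation.

## Clinical statistics

Fisher's exact test (two-sided) uses the point-probability convention: the
sum over tables with the observed margins whose hypergeometric probability
is ≤ the observed one, with a ~1e-7 relative tie tolerance; implemented via
scipy and verified in tests against an exhaustive enumeration for all
margins ≤ 15. Take rates are reported as integer percentages
(round-half-up), matching how cohort tables print them. Tumor volume is
½·L·W² (L the larger caliper axis by convention; the formula is evaluated
as given). Platinum sensitivity is PFS ≥ 6 months, boundary inclusive. The
T/C ratio returns 100 × mean(treated)/mean(control) and leaves any
responsiveness cutoff to the caller, since such cutoffs are
protocol-specific. The engraftment-cohort constants shipped with the
package include a recurrence 2×2 of [[24, 3], [5, 4]]
(engrafted/failed × recurrence <12/>12 months): the published table's cell
counts for that row are internally inconsistent (its failed column sums to
one more than the failed total), and these counts are the unique
reconstruction consistent with the table's own margins and percentages.
Per-patient continuous covariates (age, recurrence months, survival) are
not reproducible from printed summaries, so no t-test wrapper is provided.

## Problem sizes and numerical choices

Recovery tests use 500–2000 replicate lineages/pairs over 300-marker
panels and assert within 3 Monte-Carlo standard errors; Hardy–Weinberg
fidelity uses ≥ 10⁴ individuals within 4 SE; the three-regime separation
check uses 10³ triplets. These sizes put Monte-Carlo error well below every
margin being tested while keeping the default suite and the acceptance
script in the seconds-to-a-minute range. Concordance arithmetic is exact
integer counting; no floating-point tolerance is needed anywhere except
Fisher tie-breaking, noted above.

## Known limitations

* The authentication thresholds assume a MAF ≥ 0.40 panel; a low-MAF panel
  narrows the matched/unrelated margin and the defaults would need
  re-deriving.
* The drift kernel is single-step: drifting a site twice can restore the
  original state across passages, so very long chains under-count
  cumulative drift slightly relative to the sum of per-passage rates.
* Mixed samples (partial human contamination, sample mixtures) produce
  intermediate heterozygote excess that the three-way verdict does not
  model; they surface as UNRELATED or INDETERMINATE rather than a
  dedicated class.
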