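# Methods

## The labeling scheme and what is being estimated

Two peptide samples are compared by processing one in H₂¹⁸O and one in
H₂¹⁶O. Two enzymatic reactions deposit the label: immobilized trypsin
exchanges both C-terminal carboxyl oxygens (+2 × 2.0042 Da), and PNGase-F
removes N-glycans while converting the glycosylated Asn to Asp, fixing one
water oxygen in the new carboxyl (+0.9840 Da in light water, +2.9883 Da in
heavy water). A mono-glycosylated peptide therefore carries three ¹⁸O in the
heavy channel and its pair shows a 6-Da shift; a non-glycopeptide carries
two and shifts 4 Da. The quantity of interest is the heavy/light abundance
ratio per peptide, rolled up to protein × lectin-subgroup medians.

Because peptide natural isotope envelopes span several Da, the light
species' M2/M4/M6 isotopologues land under the heavy species' peaks. The
measured even-offset channel intensities I0, I2, I4, I6 (nominal offsets
from the light monoisotopic peak) are therefore a mixture, unmixed as
follows.

## Overlap correction

With r_k = M_k/M_0 the theoretical envelope ratios of the peptide
(nominal-mass binned, computed by convolving per-element isotope abundance
vectors from an embedded IUPAC table), sequential stripping recovers the
monoisotopic-equivalent abundance of each label-count species:

    S0 = I0
    S2 = I2 − r2·S0
    S4 = I4 − r4·S0 − r2·S2
    S6 = I6 − r6·S0 − r4·S2 − r2·S4

Negative intermediates (noise) are clamped to zero *before* propagation and
flagged. Expanding the recursion yields the closed forms used for manual
calculation of the light/heavy ratio — I0/(S2+S4+S6) for a glycopeptide and
I0/(S2+S4) for a non-glycopeptide — and the test suite asserts this
algebraic identity on 10⁴ random envelopes rather than assuming it.

The reported ratio is the grouped form

    ratio(¹⁸O/¹⁶O) = (S6 + S4) / S0

whose numerator contains the fully site-labeled species with two (Group A)
or one (Group B) C-terminal label. Back-exchange of a single C-terminal
oxygen and incomplete C-terminal labeling only move abundance between S6 and
S4, so the grouped ratio is invariant to them by construction; loss of
*both* C-terminal labels (an S2 species) is excluded by default and can be
counted via `include_single_label=True`. The closed-form labeled total
includes S2 while the grouped numerator does not; the switch makes the two
conventions reconcilable and defaults to the grouped definition.

## Reagent purity

The labeling water is nominally 97% ¹⁸O. Each nominal label position
independently carries ¹⁸O with probability p, so an n-label species is
observed across k ≤ n labels with binomial weights. `purity_correct`
inverts this triangular mixing exactly (a 4×4 linear solve; generalized
size for multi-site peptides). The correction is applied to species
abundances after stripping, not folded into the theoretical envelope —
keeping the envelope a property of the composition and the purity a
property of the reaction.

## Envelope extraction

At 100k resolving power the +2k channels contain two partially resolved
positions: the natural ladder of a lighter species (k × 1.00335/z) and the
monoisotopic peak of the k/2-label species (k/2 × 2.00425/z). Extraction
sums every centroid within the ppm tolerance (default 10 ppm) of either
position, counting each centroid once, over all MS1 scans within ±30 s of
the identification's retention time. Both window parameters are
configurable and recorded in the measurement metadata together with the
scan ids, so every results row is traceable. Odd-offset channels I1/I3/I5
are extracted for envelope-shape diagnostics but never enter the ratio
algebra. RT-window summation (rather than apex picking) was chosen for
robustness on centroid data; single-scan extraction is a special case of a
narrow window.

## Significance calling

The method's dispersion is calibrated empirically from seven repeated
analyses of a 1:1 standard mixture. The sample SD (n−1; conservative at
n = 7) of the replicate ratios sets symmetric bands: significant beyond
1 ± 3·SD (~99% confidence under normality), minor between 1 and 3 SD.
Upper bounds are rounded half-up at two decimals; lower bounds are the
rounded reciprocals of the *unrounded* upper expressions, which keeps the
bands reciprocal-symmetric before rounding. With the published calibration
SDs (0.216 protein-level maximum, 0.186 peptide-level maximum) this
convention reproduces the published 1.65/1.22/0.82 protein bounds and the
1.19/0.84 peptide bounds; the published 1.57/0.63/0.60 edges differ from
the convention by one unit in the last decimal (1.56/0.64/0.61 computed) —
the published rounding is internally inconsistent, so both the computed
and the published values are available (`reference.PUBLISHED_BOUNDS`).
Boundary ratios are assigned to the less extreme band. A peptide uses its
own calibrated SD when available, else the level-wide maximum SD — the
conservative choice implied by global thresholds.

Protein ratios are medians of their quantifiable glycopeptide ratios per
lectin subgroup, flagged when supported by a single peptide. Proteins whose
subgroups move in opposite directions are listed as discordant — the
signature of a glycoform shift rather than an abundance change. No
multiple-testing correction is applied.

## Sequon logic

A peptide is a glycopeptide when at least one deamidation sits on an Asn in
a valid N-X-S/T motif (X ≠ P). Deamidation on a non-motif Asn is likely
spontaneous; such peptides are classified `inconsistent`, excluded from
glycopeptide ratios, and reported.

## The simulator

`simulate_pair`/`simulate_cohort` generate centroid MS1 stick spectra with
exact ground truth. Species populations are *expected* fractions — the
C-terminal label distribution (p0, p1, p2), per-site labeling efficiency q
and binomial purity thinning are composed analytically — so a noise-free
run is exactly invertible by the quantitation chain, which is the basis of
the end-to-end recovery tests (error < 1e-6 over the 0.1–10 mixing grid,
the dynamic range of the original validation design). Stochasticity enters
only as per-centroid multiplicative log-normal noise of a given CV (chosen
to keep intensities positive), seeded everywhere; identical seeds give
bit-identical spectra. Defaults are the bench conditions of the workflow:
97% purity, complete C-terminal and site labeling, a handful of MS1 scans
per peptide, peptides spaced 120 s apart in RT.

What the simulator does **not** emulate: chromatographic peak shapes,
coelution and interference from unrelated species, detector saturation,
profile-mode peak shapes, or missed/ambiguous identifications. Passing
recovery tests therefore demonstrates the correctness of the algebra and
the pipeline plumbing, not robustness to real-matrix interference.

## Numerical choices and edge cases

- Envelopes are computed to 12 offset bins and renormalized; a warning
  fires if the truncated tail exceeds 1e-6 of the distribution.
- ¹⁸O is carried as a distinct, isotopically pure element in compositions;
  substituting it leaves the envelope shape unchanged and displaces the
  cluster by +2 per label (purity handled separately, as above).
- Ratios with a labeled total below 1% of I0 (configurable) are flagged
  `denominator-small` and withheld rather than reported, since the closed
  forms diverge as the heavy signal vanishes; a non-positive labeled total
  or I0 = 0 yields a not-quantifiable record with a reason, not an
  exception.
- Canonical orientation is heavy/light (the grouped form); closed-form
  results are produced light/heavy and inverted exactly on demand.
- Peptides with ≥ 2 glycosites shift more than 6 Da; the stripping
  generalizes to +8/+10 channels behind the `allow_multisite` flag, and the
  default configuration raises an explicit error instead of misapplying the
  mono-site formulas.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic or
embedded printed data: single-peptide pairs of 5–10 scans, cohorts of a few
peptides, 10⁴-sample algebraic property checks, and a 1000-replicate noise
study — sizes chosen so the full validation executes in seconds while still
exercising every code path at the study's design conditions (mixing grid
0.1–10, CV 5%, 97% purity, seven-replicate calibration).
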