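# Methods

This note documents the statistical procedure implemented by `rdeep`,
the conventions chosen where the underlying experimental practice leaves
the analysis under-determined, and what the synthetic screens do and do
not establish.

## Data model

A screen is a protein × condition (CTRL / RNASE) × replicate (typically
3) × fraction (1..25) table of non-negative intensities, as exported
from reporter-ion quantification. Fractions are 1-based integers
everywhere; peak positions are continuous (a peak may sit between
fractions). Proteins missing a whole condition or quantified in fewer
than `min_replicates` (default 2) complete replicate channels are
excluded from shift calling and reported with a reason, never silently
dropped — real MS tables are ragged.

## Normalization

**Between replicates.** Each measurement channel (condition ×
replicate) is rescaled within every fraction so that all channel totals
at that fraction agree. In the multiplexed design each fraction is one
labelled run, so per-fraction per-channel loading and labelling biases
are the dominant technical artefact. The factor for channel *ch* at
fraction *f* is

```
gamma(f, ch) = target(f) · G / T(f, ch)
```

where `T(f, ch)` is the channel's total intensity over all proteins at
that fraction, `target(f)` is the across-channel mean of the channels'
*fraction-share* profiles `T(f, ch) / Σ_f T(f, ch)`, and `G` is the
geometric mean of the channel depths `Σ_f T(f, ch)`. This equalizes
totals within each fraction while preserving the gradient's
fraction-to-fraction load profile, changes no relative proportion
within a channel, is exactly idempotent, and makes the final profiles
exactly invariant to rescaling any one replicate channel by a positive
constant (the constant cancels inside `T`, and the residual global
factor `c^(1/n)` via `G` is removed by the per-protein scaling below).
A median-of-ratios variant (`between_replicate_method="median_ratio"`)
is available for screens where a few dominant proteins distort channel
totals. Channels with zero total are flagged and left unscaled.

**Per protein.** For every protein × condition the replicate-mean curve
is scaled to sum to exactly 100 ("percent of the protein per
fraction"); the replicate curves carry the same factor, so replicate
variability at each fraction is preserved for the significance test and
control and RNase profiles integrate to the same total.

## Gaussian mixture fitting

The fit target is the replicate-mean curve. Candidate peak positions
are local maxima (boundaries included) of the curve smoothed with a
Gaussian kernel (σ = 0.75 fractions), kept when they reach
`rel_height` = 5% of the global maximum, at most `max_peaks` = 5. For
each component count k = 1..n_candidates, the k highest candidates seed
a bounded trust-region least-squares fit (amplitude ≥ 0; position μ ∈
[0.5, 25.5] so boundary peaks are representable; width σ ∈ [0.3, 6] to
exclude one-point spikes and structureless plateaus); the best k is
chosen by BIC with 3k parameters over the 25 grid points. Components
with fitted amplitude below `min_amplitude` = 1 (on the sum-100 scale)
are pruned and components closer than `merge_distance` = 0.5 fractions
merged, refitting after each simplification until stable. The optimizer
and the multi-start order are deterministic; there are no stochastic
restarts.

**Quality control.** A fit passes QC iff its coefficient of
determination against the mean curve reaches `qc_threshold` = 0.8 *and*
the fitted grid area stays within `max_area_deviation` = 5% of the data
curve's total (a mixture that cannot carry the protein's amount is not
an interpretable profile). Zero-variance curves have undefined r² and
never pass. QC failures are excluded from shift calling and counted.

## Shift calling

Control and RNase peaks are matched by optimal one-to-one assignment
(Hungarian algorithm) minimizing total |Δμ|, with pairs farther apart
than `max_match_distance` = 10 fractions forbidden and ties broken
toward the assignment with larger combined peak area. Unmatched peaks
become one-sided pairings (peaks lost or gained upon RNase); when a
lost control peak and a gained RNase peak are mutually nearest orphans
they are fused into a single pairing — one physical move larger than
the matching limit (precipitation typically moves a peak by 10–20
fractions), not two events.

A pairing is a **significant shift** iff |distance| > 1 fraction
(strict, on the continuous fitted maxima) and a two-sided Welch t-test
of the replicate amounts at the integer fraction nearest either maximum
gives p < α = 0.05. Direction follows the sign of the distance; a
significant shift whose RNase-side peak lies beyond fraction 23 is
**precipitation**, and a gained RNase peak beyond fraction 23 is
precipitation on the amplitude test alone. One-sided pairings take
their distance from the nearest fitted peak of the other condition;
with no partner peak at all the distance is undefined and no shift is
called. No multiple-testing correction is applied in the default
calling; Benjamini–Hochberg q-values over all tested pairings are
emitted as an additional column.

**Shifting coefficient.** For a pairing anchored at a control peak,

```
SC = (grid area of the control peak / 100) ×
     max(0, F_ctrl(μ_c) − F_rnase(μ_c)) / F_ctrl(μ_c)
```

where `F_cond` is the fitted mixture of that condition evaluated at the
control maximum; gained RNase peaks use the symmetric gain form with
the RNase peak's area. SC is clipped to [0, 1] and undefined when the
anchoring mixture is zero at the anchor. On noiseless single-peak data
SC equals the moved amount. A protein with no significant shift is
RNA-independent; max SC ≥ `complete_threshold` = 0.75 over its
significant shifts makes it completely RNA-dependent, anything between
partially. The 0.75 cutoff is a convention of this implementation — the
partial/complete distinction is qualitative in the experimental
literature.

## Molecular-weight calibration

`log10(MW/kDa) = a·fraction + b` is fitted by least squares through ≥ 2
reference proteins of known complex mass at distinct fractions; the
slope must be positive (heavier complexes sediment farther). The
log-linear law is a convention supported by the decade-spanning MW
range of sucrose gradients; reference peak fractions are
gradient-specific and must be supplied by the user. Post-RNase species
are classified by the ratio r of apparent MW at the protein's main
(largest-area) RNase peak to its annotated monomer mass: r < 1/tol →
smaller than monomer, r ≤ tol → monomeric, r > tol → in complex, with
tol = 2 defining "roughly monomeric"; peaks beyond fraction 23 are
precipitated regardless of mass. Positions outside [1, 25] are
evaluated with an extrapolation flag.

## Property comparisons

Shifting vs non-shifting proteins are compared per annotation property
with the two-sided Wilcoxon rank-sum test: exact null distribution for
min(n₁, n₂) ≤ 20 without ties, otherwise mid-ranks with the normal
approximation and continuity correction. Box summaries use
linear-interpolation quartiles and 1.5×IQR whiskers. By default only
proteins whose fits passed QC enter the comparison
(`properties_qc_passing_only`); a flag includes every detected protein.

## Synthetic screens

The generator emulates the triplicate 25-fraction two-condition design:
each protein draws a scenario (defaults: 60% no shift, 25% complete
left shift of 3–8 fractions, 5% right shift of 3–6 fractions, 5%
precipitation into fractions 23.5–25, 5% partial left shift moving
30–60% of the protein), peak widths σ ∈ [1.0, 2.2] fractions, total
abundance 10^5–10^6.5. Measurements receive a per-channel (fraction ×
condition × replicate) loading bias drawn uniformly in ±20% and
multiplicative lognormal noise with σ_log = 0.15 and expectation 1 —
reporter-ion intensities are positive with roughly proportional error.
The noise magnitudes are conventions of this package chosen to be
realistic for TMT-style quantification, not measured values; all
randomness flows from a single seed and identical seeds give bitwise
identical tables.

What the simulation does **not** model: peptide-level effects
(missing-value structure, shared peptides, isotope impurity),
correlated noise across fractions, co-eluting complex partners,
non-Gaussian (skewed) sedimentation shapes, and inter-screen batch
effects. Passing tests on synthetic screens therefore establish the
correctness and operating characteristics of the *statistical
pipeline* under its own model class, not the biological accuracy of
any particular real screen.

At the default conditions (500 proteins, seeded), the pipeline recovers
essentially all complete shifts of ≥ 3 fractions and keeps false calls
among no-shift proteins at the level of the nominal α; single-peak
positions are recovered within 0.2 fractions for ≥ 95% of proteins
under replicate noise. `scripts/acceptance.py` recomputes these
numbers from scratch. Problem sizes there (200-protein recovery set,
500-protein screen, 5 enumeration oracles) are chosen so the whole
script completes in well under a minute on a single core while keeping
binomial uncertainty on the rates a few percent.

## Numerical notes and degenerate inputs

- All-zero curves yield no candidates and a QC-failing empty fit.
- Zero variance in both replicate groups at a test position gives p = 1
  for equal means and p = 1e-12 otherwise (a measured-certain
  difference); fewer than 2 replicates makes a position untestable.
- Welch p-values are floored at the smallest positive float so reported
  values stay in (0, 1].
- BIC uses an SS floor of 1e-12 so perfect fits do not produce −∞.
- Swapping the condition labels inverts every left/right direction and
  preserves significance; the precipitation class is deliberately
  asymmetric (it is defined on the RNase side only).
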