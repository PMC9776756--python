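# rdeep

Quantitative analysis of **R-DeeP screens**: proteome-wide detection of
RNA-dependent proteins by comparing protein sedimentation in sucrose
density gradients with and without RNase treatment.

In an R-DeeP experiment, cell lysate is treated (or not) with RNase,
separated by ultracentrifugation into 25 gradient fractions, and every
protein is quantified per fraction by multiplexed mass spectrometry in
triplicate. A protein embedded in an RNA-dependent complex loses mass
when RNA is degraded and its sedimentation profile *shifts* — usually
toward lighter fractions. `rdeep` turns fraction-wise abundance tables
into statistically called shifts with effect sizes and size classes.

## The model

Each protein × condition profile (normalized so its 25-fraction total is
100) is modelled as a sum of Gaussians

```
y(f) = Σₖ Aₖ · exp(−(f − μₖ)² / 2σₖ²),   f = 1 … 25
```

fitted by bounded nonlinear least squares with BIC model selection over
the component count. Control and RNase peaks are matched by optimal
assignment on |Δμ|, and a shift is called when

1. the matched maxima are **more than one fraction apart** (|μ_RNase −
   μ_Ctrl| > 1), and
2. the replicate amounts **differ significantly at one of the two
   maxima** (Welch t-test, α = 0.05).

Shifts into fractions > 23 are classified as **precipitation**. Each
shift carries a **shifting coefficient** SC ∈ [0, 1],

```
SC = (area of the control peak / 100) × relative amplitude loss at its maximum,
```

the fraction of the protein population that changed complex; proteins
are classified RNA-independent / partially / completely RNA-dependent
(SC ≥ 0.75). A log-linear calibration `log₁₀(MW/kDa) = a·fraction + b`
through reference proteins (RNase A 14 kDa … Ferritin 480 kDa) maps each
post-RNase peak to an apparent molecular weight and a size class
(smaller-than-monomer / monomeric / in-complex / precipitated, within a
factor 2 of the annotated monomer mass). Shifting and non-shifting
proteins are finally compared on RNA-binding hallmarks (RBP2GO score,
RBD content, IDR fraction, pI, MW) with two-sided Wilcoxon rank-sum
tests.

Because deposited screen data require raw-spectra processing, the
package ships a first-class synthetic screen generator
(`rdeep.simulate`) with known ground truth — Gaussian peak scenarios
(no shift, partial/complete left, right, precipitation), per-channel
loading biases and mean-1 lognormal replicate noise — so every stage is
testable end to end.

## Worked example

```python
from rdeep import simulate_screen, RnaDependenceScreen
from rdeep.calibration import ReferencePoint

refs = [ReferencePoint("RNase A", 14, 1.5), ReferencePoint("BSA", 60, 5.0),
        ReferencePoint("Aldolase", 160, 7.4), ReferencePoint("Catalase", 240, 8.4),
        ReferencePoint("Ferritin", 480, 10.1)]
table, truth = simulate_screen(100, seed=7)
results = RnaDependenceScreen.from_dataframe(table, calibration_points=refs).fit()
print(results.summary())
```

```
RNA-dependence screen summary
=============================
proteins analysed               100
  failed fit QC / incomplete      0
proteins with >=1 shift          37
  left shifts (calls)            26
  right shifts (calls)            7
  precipitations (calls)          4
RNA-independent proteins         63
partially RNA-dependent           4
completely RNA-dependent         33
MW calibration: log10(kDa) = 0.1785 x fraction + 0.8815
post-RNase size classes: precipitated 11%, unknown 89%
```

37 of 100 simulated proteins are called RNA-dependent; most shifts go
left (lighter complexes after RNA loss), matching the simulated mix.
Size classes other than "precipitated" are `unknown` here because no
annotation table with monomer masses was supplied. The significant
calls carry positions, p-/q-values and shifting coefficients:

```python
results.shift_table.query("significant")[["protein_id", "ctrl_mu", "rnase_mu",
    "distance", "direction", "p_min", "q_value", "shifting_coefficient"]].head()
```

```
protein_id  ctrl_mu  rnase_mu  distance direction  p_min  q_value  shifting_coefficient
      P001  13.3619    7.8295   -5.5324      left 0.0022   0.0110                1.0000
      P002   6.2530   11.4516    5.1986     right 0.0017   0.0098                0.9754
      P003  13.7408    8.9364   -4.8044      left 0.0032   0.0152                1.0000
      P006   4.2525    9.8507    5.5982     right 0.0015   0.0096                0.9905
      P008  21.7699   16.3111   -5.4589      left 0.0038   0.0161                1.0000
```

P001 sediments around fraction 13.4 in the control gradient and around
7.8 after RNase — a complete left shift (SC = 1.0): essentially the
whole population of the protein left its RNA-dependent complex.
`results.plot_profile("P001")` shows the curves and fits;
`results.compare_properties()` runs the shifting-vs-non-shifting
property tests when annotations are provided.

The same pipeline runs from the shell:

```bash
rdeep simulate --n 500 --seed 7 --out run/
rdeep run-all --screen run/screen.tsv --out run/results/
# or stage-wise: rdeep normalize / fit / call-shifts / calibrate / compare-properties
```

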