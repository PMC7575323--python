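# Methods

## The analysis problem

Immunoprecipitating an epitope-tagged organelle drags along non-specific
background: metabolites that stick to beads, buffer components, ambient
contamination. Deciding what is *inside* the organelle therefore needs two
orthogonal filters. Enrichment against a control IP (same protocol, no
tag) removes bead- and buffer-borne signal; for synaptic vesicles, a
pharmacological arm adds a mechanistic filter — BafilomycinA inhibits the
vATPase, collapsing the proton gradient that powers neurotransmitter
import, so genuine luminal cargo is depleted while contaminants are not.
The pipeline implements both filters on top of standard LC-MS
quantification, for a targeted panel and for untargeted MS1 features.

## Targeted extraction

Each library entry carries a molecular formula (or monoisotopic mass), an
adduct, a polarity and an expected retention time. The theoretical m/z is
`(M + shift) / |z|` with the proton mass fixed at 1.00727646 Da; the
electron mass is ignored for protonation/deprotonation (sub-ppb residual)
and included in the Na⁺/K⁺ adduct shifts. Extraction is two-pass:

1. **Study apex.** Across all non-blank runs, the extracted-ion
   chromatogram (±5 ppm, closed window) is scanned inside
   `expected_rt ± 0.5 min`; the RT of the single highest point is the
   study apex. Blanks are excluded so carry-over cannot define the RT.
2. **Per-sample height.** Every run (blanks included) reports the maximum
   XIC point within `apex ± 7.5 s`. Height means apex intensity, not
   integrated area. No match ⇒ an explicit not-detected sentinel; the
   matrix always keeps one row per library entry.

The two-pass reading makes both printed tolerances meaningful: the wide
window locates the peak once per study, the tight window enforces
chromatographic agreement across samples. A config switch
(`apex_reference = study | library`) restores the alternative reading that
anchors directly on the library RT. Isobaric peaks inside the ppm window
of one scan are summed. Matching is binary search on per-run m/z-sorted
peak indexes; tests prove exact equivalence with an exhaustive scan.

Internal-standard normalization (for absolute-quantification workflows,
e.g. dopamine against ¹³C₉-¹⁵N-phenylalanine) divides every cell by the
sample's standard height and fails loudly, naming the samples, if the
standard is missing anywhere.

## Untargeted feature discovery

Candidates are MS1 peaks from non-blank runs with intensity ≥ 1e5 and
≥ 10× the within-spectrum noise. The noise proxy is the spectrum's median
peak intensity (config-switchable to the mean of the lowest decile);
the median is robust when a handful of real peaks sit on a floor of
chemical noise. Candidates are visited in strictly decreasing intensity
(ties broken by m/z, then RT, then sample id — a total order, so the pass
is deterministic). Each candidate joins the nearest existing same-polarity
feature within 25 ppm *and* 0.5 min of that feature's founder values, or
founds a new feature. Founder m/z/RT are never re-averaged: the
highest-intensity member defines the feature, which keeps the greedy pass
order-stable. Eligible features are located by bisection on an m/z-sorted
index; an O(n²) reference implementation backs the equivalence tests.

Feature intensities are then extracted across all samples (blanks
included) with the targeted engine at the *feature-definition* tolerances:
25 ppm in m/z and the binning RT delta (0.5 min) around the feature's
representative RT. A feature is defined by its m/z at a retention-time
window, so quantification deliberately does not apply the targeted panel's
±7.5 s apex gate, which describes a library-grade chromatographic
agreement claim rather than a feature boundary.

The 0.5 min RT delta follows the processing description; the results-level
feature definition quotes ±0.25 min. The discrepancy is preserved as a
configuration choice (`bin_rt_delta`, default 0.5 min).

## Detection and statistics

Per feature, one threshold shared by all samples:
`max(3 × mean(blank signals), 10,000)`, with not-found blanks counted as
zero (aggregation switchable to max). Cells at or above the threshold are
detected (inclusive boundary); all other cells are annotated not-detected
and the threshold is imputed so a fold-change estimate remains defined.
Imputation can only shrink |log2FC| toward zero — a conservative bias,
verified by test.

Per contrast: a single-pass two-sided Grubbs test (α = 0.05) within each
group removes at most one outlier, using the closed-form critical value
`G = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{α/(2n), n−2}`; then values are
log2-transformed, and

* log2FC = mean(log2 a) − mean(log2 b),
* SEM = √(SEM_a² + SEM_b²) on the log2 scale,
* p from a two-sided Welch t-test on the log2 values.

Welch is the default because replicate variances are not assumed equal;
`ttest = student` and `test_scale = linear` are available for
reproducing either historical reading. Zero-variance identical groups get
p = 1; a row with no detected cell in either group is classed
`undetected` (its fold change is 0 by construction of imputation). No
multiple-testing correction gates anything — the screening criterion is
the plain p < 0.05 — but a Benjamini–Hochberg q column is emitted.

The screen: pass ⇔ (log2FC_SV ≥ log2 2 ∧ p_SV < α) ∧ (log2FC_BafA ≤
−log2 2 ∧ p_BafA < α), inclusive boundaries on the log2 scale. Requiring
significance on the depletion arm is the default
(`require_depletion_significance`); switching it off restores the looser
reading in which only enrichment carries a significance requirement.
Annotation matches surviving features to the library by accurate mass
(±5 ppm) and RT (±7.5 s), nearest-ppm first, name-order tie-break with an
ambiguity flag.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study *design*: arms
{tagged IP, control IP, inhibitor, vehicle} with 3–4 replicates, blank
IPs, a 153-entry polar panel, 2,724 untargeted background features, and
planted effects on designated true positives (the presets plant glutamate,
GABA and a potassium-associated cation at ≥ |2.3| log2 in both screen
arms; the potassium species is modelled as a synthetic low-mass cationic
library entry, not a chemically asserted ion). Quantitative choices, made
once:

| parameter | default | rationale |
|---|---|---|
| replicate CV | 0.15 | typical LC-MS replicate scatter; log-normal heights, σ = √ln(1+cv²), so planted log2FC is the exact expectation |
| m/z error | 1.0 ppm (per scan) | high-resolution Orbitrap mass accuracy; 5σ inside the 5 ppm targeted gate |
| RT jitter | 0.75 s sd (per run) | consistent with a method that asserts ±7.5 s study-wide apex agreement: run-to-run apex differences (√2·σ ≈ 1.1 s) sit ~7σ inside the gate |
| blank carry-over | 1 % | keeps true signals above the 3× blank rule while exercising it |
| elution profile | Gaussian, FWHM 6 s, scans every 0.2 min in ±0.5 min | one scan lands exactly on the (jittered) apex, so height extraction is exact in the noiseless limit |
| chemical noise | 4 peaks/spectrum, 10²–10⁴ units | below the 1e5 candidate floor; supplies the within-spectrum median that real peaks must exceed 10-fold |
| background features | m/z ~ U(70, 1000), RT ~ U(1, 28 min) | instrument scan range 67–1000 m/z, 30-min method |

Background features are rejection-sampled so every same-polarity pair is
separated by > 3× the binning tolerance in m/z or RT — merges are
impossible by construction, which is what lets tests assert exact feature
counts and exact survivor sets. Real data offer no such guarantee:
passing tests demonstrate correctness of the algorithms under the declared
noise model, not robustness to co-eluting isomers, isotopologue/adduct
degeneracy, RT drift or batch effects, none of which are modelled.
Isotope envelopes are deliberately absent from LC-MS fixtures (isotope
math is exercised in the correction module).

Calibration invariants (type-I rate of the null design pooled over 200
seeds; fold-change bias at cv = 0.1 over 100 seeds) are measured through
the generator's matrix-level path, which draws the same replicate heights
the chromatographic path would render and skips scan rendering. The two
paths agree exactly in the noiseless limit and the rendered path is
oracle-verified separately, so the shortcut changes nothing but runtime.
Measured on this design, the t-test stage (with Grubbs active) holds a
5% nominal rate within [0.04, 0.06].

## Isotope correction

For a fragment formula and tracer element, column j of the correction
matrix is the natural-abundance envelope of the species with j labeled
atoms (those atoms leave the natural pool), truncated to k+1 rows and
shifted down by j. Envelopes come from convolving per-element shift
distributions built from an embedded constants table (CODATA/IUPAC
monoisotopic masses, representative natural abundances), so results are
bit-reproducible. Only elements whose principal isotope is the lightest
are tabulated for abundances (H C N O F Na Mg Si P S Cl K Ca Zn Br I);
elements with lighter-than-principal isotopes would need negative mass
shifts, outside the M+0..M+k model. Inversion solves the triangular
system directly when that already yields a non-negative solution and
falls back to non-negative least squares otherwise; the output is
renormalized to a fractional distribution. Resolution-dependent
corrections (skipping isotopologues that high resolution separates) are
not implemented.

## Numerical and interface choices

* All m/z windows are closed on both ends: a "± tolerance" should match
  boundary peaks.
* RT is minutes everywhere internally; the 7.5 s apex tolerance converts
  to 0.125 min at config load.
* Polarity is a hard partition at every stage.
* Not-detected is NaN in memory and `ND` in TSV output; it is never
  silently zero.
* Every stochastic step flows from one integer seed
  (`numpy.random.default_rng`); rerunning any pipeline with the same seed
  and config produces byte-identical output tables.
* Problem sizes in the test suite: the full 2,724-feature screen runs at
  20 seeds; the sensitivity/false-discovery sweep uses a 300-feature
  background at 50 seeds; calibration pools 200 seeds of the 500-feature
  null design at the matrix level.

## Known limitations

No RT alignment or warping across runs; no chromatographic peak
deconvolution or shape scoring; no isotopologue/adduct clustering of
features; no batch or covariate correction (an external count-model
package is the appropriate tool when covariates matter); no MS/MS identity
confirmation — annotation is accurate-mass/RT only, and the screen's
"potassium" entry is a placeholder for an ion whose exact formula is not
asserted. mzML and vendor formats are out of scope (mzXML and the
peak-table TSV are the supported inputs).
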