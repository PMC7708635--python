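# Methods

This note documents the models, estimators and numerical choices behind
`hdxdiff`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and units

The unit of observation is the **ion**: one peptide in one charge state,
one condition (state), one exposure time and one replicate, with an MS
intensity and a deuterium uptake in Da measured against the undeuterated
(exposure 0) centroid of the same ion. Coordinates are 1-based and
inclusive throughout; exposure 0 defines the reference and is forced to
zero uptake on read. Mildly negative uptake (≥ −0.15 Da) is treated as
centroid noise around the reference and clamped to zero with a warning;
anything more negative rejects the row, since T0-subtraction noise does
not plausibly reach that magnitude.

Relative deuterium uptake (RDU) is stored internally as a fraction in
[0, 1]; reports and thresholds quote percent. There is exactly one
conversion boundary (at reporting), which avoids silent factor-of-100
errors.

## Theoretical maximum and RDU

A peptide's theoretical maximum uptake counts its exchangeable backbone
amides: every residue except prolines (no amide hydrogen) and the
peptide's **first** residue, whose amide deuterium is lost too quickly
to survive quench and separation. Some laboratories exclude the first
two residues; here the count excludes one, with
`n_term_exclusions` exposed for users who prefer the stricter
convention.

Per peptide/condition/exposure/replicate, the charge states are
collapsed by an intensity-weighted mean before normalization:

    RDU = Σᵢ Iᵢ uᵢ / Σᵢ Iᵢ / (N_exch · f_D)

This estimator is invariant under uniform intensity rescaling and
reduces to the plain mean for equal intensities. `f_D` (the D₂O
fraction of the labelling buffer) defaults to 1.0: RDU is then relative
to the all-exchanged theoretical maximum, uncorrected for either the
deuterium fraction or back exchange, which matches how uptake tables
are usually reported and keeps values comparable across conditions.
The parameter exists so simulator round-trips can recover absolute
fractional uptake. RDU above 1 by at most 5% is clamped with a warning
(replicate noise near saturation); above that it is an error, because
it indicates an inconsistent amide count rather than noise.

Replicate dispersion uses the sample SD (n−1 denominator); the designs
this package targets run n = 3.

## Differential statistics

**Model.** For each peptide shared between two conditions, replicate
RDU values at the non-zero exposures enter a two-factor linear model —
condition + exposure (categorical) + condition×exposure, sum-to-zero
contrasts — and the **type-III p-value of the condition main effect**
is the peptide's raw p. On the balanced complete design this equals the
classical two-way ANOVA partition, and the package uses a closed-form
vectorized computation for that case (statsmodels OLS with Sum
contrasts handles unbalanced fallbacks, tolerating rank deficiency by
pseudo-inverse, i.e. aliased terms are absorbed rather than fatal).
T0 cells are excluded: RDU there is identically zero with zero
variance, a degenerate cell that would corrupt the fit. Zero residual
variance (noise-free data) degenerates cleanly: p = 0 when the
condition sum-of-squares is positive, else p = 1.

The factor structure is one deliberate reconstruction among several
defensible ones (an interaction-focused test is a reasonable
alternative); it is isolated behind `anova_condition_effect` so it can
be swapped without touching the caller.

**Multiplicity.** Raw p-values are Benjamini–Hochberg adjusted once per
condition-pair comparison, pooled across all peptides of all proteins
in that comparison (`statsmodels.multipletests`, standard step-up with
cumulative-minimum tie handling — deterministic). Untestable peptides
carry NaN and do not count toward the number of tests.

**Effect size and persistence.** The effect threshold is data driven:
`multiplier` (default 4) × the dataset-wide mean replicate dispersion
of RDU over all (peptide, condition, exposure > 0) groups with ≥ 2
replicates. Two dispersion estimators are provided: the mean replicate
sample SD (default) and the mean pairwise absolute difference; for
n = 3 Gaussian replicates they differ by a fixed factor (for the
symmetric triplet {c−d, c, c+d} the pairwise mean is 4d/3), and the run
report prints both so the choice is auditable.

A peptide is **regulated** iff corrected p ≤ α (0.01, inclusive) AND
|ΔRDU| > threshold (strict) at `k` (default 3) successive non-zero
exposures, where ΔRDU is the difference of replicate means,
treatment − reference. The window must additionally be sign-consistent
(`require_same_sign=True` by default): a region is either protected or
deprotected, and mixed-sign windows are almost always noise. This
tightening is configurable off. The earliest qualifying window
determines the reported sign (up/down).

The persistence rule makes the procedure conservative relative to the
nominal α; under a complete null the fraction of called peptides is far
below 1% (the null-calibration test measures it at the residue level).

## Consolidation and export

Each covered residue takes the value of the **shortest** covering
peptide — shorter peptides localize their signal better. Among
equal-length covering peptides the smallest start wins; the tie-break is
arbitrary but deterministic, and provenance (which peptide supplied each
residue) is recorded so ties are auditable. A brute-force per-residue
scan (enumerate covering peptides, pick min(length, start)) serves as
the test oracle.

In differential mode the shortest-peptide rule runs over **regulated
peptides only**: a regulated peptide beats any overlapping
not-regulated one regardless of length, because "not regulated" is a
verdict about evidence, not a measured zero. Residues covered only by
tested-but-not-regulated peptides are `not-significant` (grey);
residues without tested coverage — including peptides observed in a
single condition — are `no-data` (black). Status can only improve
(no-data → not-significant → value) as peptides are added.

ChimeraX `defattr` export writes one numeric attribute per residue
(`match mode: 1-to-1`, lines `/<chain>:<resnum>\t<value>`); `no-data`
residues are omitted and `not-significant` residues carry a sentinel
value placed outside the data range and recorded in the header, because
viewers have no native "grey" channel. Multi-copy subunits receive
identical attributes on every chain mapped to them. Heatmap grids are
residue × exposure with NaN (not zero) for missing cells.

## Synthetic data generator

The generator emulates the acquisition design the pipeline targets:
6 exposures (0, 0.5, 1, 5, 10, 30 min), triplicates, two conditions,
several ~230-residue (~25 kDa) subunits, overlapping pepsin-like
peptides (random layout with mean length 12 and ~2.5× redundancy, or a
deterministic nested tiling for exact tests).

Exchange follows the Linderstrøm-Lang form in the EX2 limit. Per
residue, an intrinsic rate k_int is drawn log-uniformly over
[10⁻², 10¹] min⁻¹ — three orders of magnitude, placed so the kinetics
actually move inside the 0.5–30 min window (slower residues would be
indistinguishable from non-exchangers at these exposures, faster ones
saturate before the first timepoint). Protection factors are 1 except
in designated effect regions, where one condition's PF is multiplied by
`fold` (default 20): `protected` slows the treatment condition
(ΔRDU < 0), `deprotected` slows the reference instead, so PF ≥ 1 always
holds. True peptide uptake is the closed form

    u(t) = β · f_D · (1/N) Σⱼ [1 − exp(−(k_int,j / PF_j) t)]

with f_D = 0.95 (the labelling-buffer D₂O fraction) and β a uniform
back-exchange retention factor (default 1.0, i.e. none).

Noise is added at the peptide-RDU level (Gaussian, σ_rep = 0.4% RDU by
default), because that is the level the statistics operate on and it
keeps the generator's ground truth analytic. The default σ_rep puts the
×4 effect threshold near 1.6%, a realistic operating point for
triplicate HDX data. Per-ion centroid jitter (SD 0.02 Da) is layered on
top to exercise the intensity-weighted averaging; intensities are split
across 2–3 charge states by a Dirichlet draw with a log-normal total.
Identical (config, seed) yields byte-identical CSV.

**What the simulator does not emulate:** isotope envelopes or spectral
shapes, EX1 bimodality (multiple conformational states), correlated or
heteroscedastic replicate noise, sequence-dependent intrinsic rates
(rates are drawn, not predicted), peptide dropout between conditions,
or back-exchange that varies by residue. Passing benchmarks therefore
demonstrate that the statistics and consolidation behave correctly for
well-behaved EX2 kinetics with exchangeable Gaussian noise — not that
the pipeline is robust to pathological spectra, which are assumed to
have been curated upstream.

## Benchmarks and their scoring

The residue-level benchmark (`benchmark_recovery`) compares regulated
calls against the designed effect regions, over residues with testable
coverage. One scoring subtlety is inherent to peptide-level HDX: a
peptide overlapping a region by even one exchangeable residue carries a
genuinely non-zero ΔRDU, and once called it paints its entire extent —
so "false positives" concentrate in a shoulder of up to one peptide
length around each region edge. `boundary_margin` excludes that
shoulder from the negative set; the power and noiseless suites score
with margin = max peptide length (region recovery), while edge
resolution remains visible at margin 0. The null suite has no regions
and is unaffected.

Suite problem sizes, chosen to exercise the asymptotics while staying
desk-scale: null calibration uses 2,000 peptides (10 subunits × 200
peptides, 250 residues each, ~180k ion rows; raw p uniformity by KS
test plus the ≤ 1% flagged-residue bound); the power suite uses 8
30-residue regions at fold 30 across 4 subunits, where every region's
true |ΔRDU| exceeds 3× the measured threshold at ≥ 4 exposures; the
noiseless limit (σ_rep = 0, jitter = 0) must recover regions with
sensitivity and specificity exactly 1.0, exercising the degenerate
zero-variance paths end to end.

## Known limitations

* The ANOVA treats exposures as exchangeable categories; it does not
  model the kinetic ordering, so slowly accumulating differences spread
  over many exposures are detected less efficiently than a time-course
  model would allow.
* BH correction controls FDR across peptides, not residues; the
  residue-level false-positive rate inherits conservatism from the
  persistence rule rather than from an explicit residue-level
  guarantee.
* The shortest-peptide rule is a heuristic spatial deconvolution;
  subtraction-based resolution enhancement (overlapping-peptide
  differencing) is deliberately out of scope.
* No back-exchange correction: reported RDU underestimates true uptake
  by an unknown peptide-dependent factor, which cancels in differential
  comparisons only to first order.
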