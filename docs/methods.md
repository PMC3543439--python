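# Methods

## The problem

Methylation-sensitive high-resolution melting (MS-HRM) amplifies
bisulfite-converted DNA with methylation-independent primers and records
fluorescence of a saturating dye while the amplicon is melted on a fine
temperature ramp. Methylated template retains its CpG cytosines through
bisulfite conversion, so its amplicon is GC-richer and melts at a higher
temperature than the unmethylated amplicon. Conventionally MS-HRM is read
out by eye against a dilution series of standards, giving a *range* of
methylation rather than a number. `meltquant` implements a calibration
procedure that turns each melt curve into a single methylation percentage,
plus the Net Temperature Shift (NTS) alternative, a detector for
heterogeneous-methylation melt profiles, and the Pearson / Bland–Altman
machinery used to validate melt-based estimates against a quantitative
reference assay such as pyrosequencing.

## Curve normalization

Raw fluorescence differs between wells in amplitude and baseline drift.
We use the standard two-window HRM normalization: a straight line is
least-squares-fitted to the pre-melt window (fully double-stranded
plateau; upper baseline `U(T)`) and to the post-melt window (fully melted;
lower baseline `L(T)`), and the trace is rescaled to

    F_norm(T) = 100 · (F(T) − L(T)) / (U(T) − L(T)),

so every well reads ≈100 before and ≈0 after the melt. The transform is
invariant under positive affine rescaling of the raw trace. Defaults put
the baseline windows at `[window_lo − 4, window_lo − 2]` and
`[window_hi + 2, window_hi + 4]` °C — a full degree clear of the melt
window, so that transitions sitting slightly outside the window (as in
heterogeneous samples) do not contaminate the baseline fits. If the
fitted upper baseline does not exceed the lower baseline everywhere on
the grid, the well is rejected with a degenerate-baseline error rather
than silently producing nonsense.

## The standard curve

Per assay, a window of temperatures spanning the melt transition is fixed
(74–80 °C for the APC-like default, 76–84 °C for the CDKN2A-like one),
and the *windowed mean RFU* — the arithmetic mean of the normalized trace
over all grid points in the closed window — summarizes each well. The
standards (0, 12.5, 25, 50, 75, 100% methylated mixtures, replicates of a
level averaged) define n points `(mean_rfu_i, pct_i)` through which the
unique degree-(n−1) interpolating polynomial `pct = P(rfu)` is passed.
Evaluation uses a barycentric Lagrange representation, which is exact at
the nodes and numerically stable; a degree-(n−1) least-squares fit is the
same polynomial and supplies the power-basis coefficients written to the
calibration audit YAML. A sample's methylation estimate is `P(mean_rfu)`,
clamped to [0, 100]; an RFU outside the standards' range sets an
`extrapolated` flag instead of raising, because real plates contain
samples at and beyond the extreme standards.

Design points:

- The polynomial maps RFU → % directly; the inverse parameterization
  (fit RFU as a function of %, invert numerically) is not implemented.
- Degree is fixed at n−1 (exact interpolation). Runge-type
  non-monotonicity on the calibration range is detected on a 1000-point
  grid and surfaced as `monotone_ok = False` with a warning, never
  silently corrected.
- Standards whose RFU ordering disagrees with their methylation ordering
  indicate a failed run and raise a calibration error.
- Replicates of a sample are quantified individually and reported as
  mean ± SD of percentages (an honest spread estimate); `pool_rfu=True`
  averages RFU first. The two coincide exactly on noiseless data and
  differ only through polynomial curvature across replicate scatter.

## Net Temperature Shift

NTS compares a sample's normalized curve to the fully methylated
control's: both are linearly resampled to a 0.1 °C grid over a 10 °C
range centered on the assay window midpoint (101 points, endpoints
included), and NTS = Σ(sample − control) / 100. A fully methylated
sample scores 0; less methylated samples melt earlier and score
increasingly negative. Since NTS is a relative measure, an ordinary
least-squares line fitted on the standards' (percent, NTS) pairs maps it
to a percentage (clamped to [0, 100]). The NTS channel is filled whenever
a methylated-control well — or, failing that, a 100% standard — is on the
plate.

## Heterogeneous-methylation detection

Samples whose molecules carry different methylation patterns melt in
transitions outside the assay's two intrinsic melting points and show
"unusual" multi-peak profiles. The detector computes the
Savitzky–Golay-smoothed negative derivative −dF/dT (default window 11
points ≈ 2.2 °C, polynomial order 3), searches the melt region (assay
window ± 2.5 °C) for local maxima with prominence at least 10% of the
trace's own maximum derivative, and merges peaks closer than a minimum
separation (default 3.5 °C). A sample is flagged when ≥2 transitions
survive. The separation rule is essential: a homogeneous
intermediate-methylation sample is a mixture of fully methylated and
fully unmethylated amplicons whose components melt ~3 °C apart and
legitimately resolve into two derivative peaks — only transitions
*beyond* the assay's intrinsic Tm span are evidence of heterogeneity.
With the defaults, bimodal profiles with component separation ≥ 4 °C are
flagged while ordinary mixtures and sub-resolution pairs (≤ 1 °C) are
not. Flagged samples keep their methylation estimate; the flag marks
them for follow-up with a pattern-resolving assay. Standards are
optionally sanity-checked (≤ 2 transitions each) with a logged warning.

Limitation: at instrument noise around 1 RFU the 10% prominence default
occasionally admits noise peaks or noise-shifted intrinsic secondary
peaks on borderline samples; raising `het_prominence_frac` to 0.2–0.3
trades sensitivity for specificity. Both threshold and smoothing are
per-assay configuration.

## Concordance analysis

Two paired methylation vectors (melt estimates vs reference) are
compared with (i) the sample Pearson correlation, its 95% confidence
interval by the Fisher z-transform with the 1.96 normal quantile, and a
two-sided p-value from `t = r·√((n−2)/(1−r²))`; and (ii) Bland–Altman
analysis: per sample the abscissa is the mean of the two measurements and
the ordinate their difference, the limits of agreement are
`mean difference ± 1.96 × SD` (sample SD, n−1 denominator), and samples
outside the limits are listed as outliers — reported, never removed.

## The simulator

The synthetic-data module exists so every stage, including the full
comparison study, runs without instrument exports. Melting is two-state
logistic: the double-stranded fraction is

    S(T) = m·σ((Tm_meth − T)/s) + (1 − m)·σ((Tm_unmeth − T)/s),

and the raw trace is `F(T) = L(T) + (U(T) − L(T))·S(T) + ε` with linear
upper/lower baselines and i.i.d. Gaussian noise `ε`. Defaults: Tm 79 /
76 °C (3 °C separation, typical for MS-HRM assays), transition width
0.5 °C, amplitude 100 RFU, baseline drifts −0.8 / −0.2 RFU/°C, ramp
70–90 °C at 0.2 °C per acquisition, noise off unless requested.
Standards are simulated in triplicate; samples default to one well each
with a `sample_replicates` option. Heterogeneous samples are mixtures of
logistic components at Tm offsets from the sample's nominal melting
point (weights summing to 1); their mean methylation is drawn mid-range
(U[0.3, 0.7]) since an equal-weight bimodal mixture is intermediate by
construction. The matched reference channel adds Gaussian per-CpG noise
(default SD 3 percentage points, 7 CpGs) to the true per-CpG methylation
and averages across CpGs, mimicking how a mean pyrosequencing value is
formed. All randomness flows from one seed through `numpy.random`
SeedSequence spawning; identical seeds give bit-identical plates.

Because normalization exactly removes linear baselines and `S(T)` is
affine in m, the windowed mean RFU of a simulated two-state curve is
affine in the methylated fraction; the interpolating polynomial then
degenerates to that line and noiseless recovery is exact to numerical
precision. Real amplicons deviate from this ideal (non-two-state melting
domains, PCR bias toward methylated template, temperature-shift effects),
so passing simulated recovery does not bound real-world accuracy; the
simulation validates the *estimator*, not the assay chemistry. PCR
amplification bias is deliberately not modeled.

## Problem sizes and numerical choices

Default study conditions used by the test suite: plates of 6 standard
levels × 3 replicates; 50-sample plates at RFU noise SD 1 with
triplicate samples for recovery error (RMSE < 5 percentage points); a
90-sample study (noise SD 1, reference per-CpG SD 3) for the concordance
analysis; 10⁴ pairs for the limits-of-agreement coverage property.
Temperature-grid uniformity is enforced to 1e-6 °C; window membership
uses a 1e-9 °C closed-interval tolerance; interpolation must reproduce
the standards to 1e-6 or the calibration aborts. Ingest never resamples;
the only resampling is the NTS 0.1 °C linear interpolation.
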