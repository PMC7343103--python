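# Methods

## The measurement being modelled

Dielectrophoresis (DEP) moves polarisable particles in a non-uniform AC
field. For a spherical cell of complex permittivity ε*_p suspended in a
medium of complex permittivity ε*_m, the direction and strength of the
force at frequency f follow the real part of the Clausius–Mossotti
factor

    CM(f) = (ε*_p − ε*_m) / (ε*_p + 2 ε*_m),      ε* = ε ε₀ − j σ/ω,

with Re[CM] ∈ [−0.5, 1]. A well-plate DEP cytometer reads out a light-
intensity change per well that is proportional to Re[CM] at that well's
frequency, yielding one 20-point spectrum per run over 10 kHz–45 MHz.
The proportionality (instrument gain) is not calibrated absolutely; the
package treats it as a free scalar.

## Single-shell cell model

A cell is a conductive cytoplasm sphere (relative permittivity ε_cyt,
conductivity σ_cyt) wrapped in a thin, poorly conducting membrane. The
membrane enters through its specific capacitance C_mem (F/m²) and
specific conductance G_mem (S/m²) — the quantities DEP experiments can
actually constrain — combined as a complex specific capacitance
C*_mem = C_mem − j G_mem/ω. The thin-shell limit of the two-layer
shelled-sphere mixing formula gives the effective homogeneous-particle
permittivity as a series combination:

    ε*_p = (r C*_mem/ε₀) ε*_cyt / (r C*_mem/ε₀ + ε*_cyt).

Assumptions: shell thickness ≪ radius (for d ≤ 10 nm and r ≥ 5 µm the
thin-shell and explicit finite-thickness computations agree to well
under 1%, verified in the tests); no membrane permittivity dispersion
beyond G_mem (not identifiable from a 20-point Re[CM] curve); no
multi-shell (nuclear) structure; ε₀ = 8.854×10⁻¹² F/m.

The crossover frequency (Re[CM] sign change) is located by scanning the
band on a log grid and refining the lowest-frequency sign change with
Brent's method; additional sign changes are flagged on the result. In
the insulating-membrane regime (G_mem = 0, σ_cyt ≫ σ_m) the root agrees
with the closed form f_xo = √2 σ_m / (2π r C_mem) to a few percent; the
agreement degrades as σ_cyt approaches σ_m, which is why the oracle
checks use σ_cyt = 1 S/m against the 43 mS/m medium.

Spectrum fitting minimises Σ(observed − gain·Re[CM])² over a named
subset of {radius, C_mem, G_mem, ε_cyt, σ_cyt, gain} by
Levenberg–Marquardt in log-parameter space, which enforces positivity
without explicit bounds and equalises parameter scales spanning nine
orders of magnitude. Masked points are dropped; non-convergence is
returned as a flag, never silently.

## Synthetic cohort

The generator reproduces the structure of a small two-arm voided-urine
screening study; its defaults are the study conditions every test and
the acceptance script run under.

| parameter | default | why |
|---|---|---|
| arm sizes | 8 cancer + 8 control | pilot-cohort structure |
| technical repeats | 3–5 per sample, uniform | "at least three, four or five if cells sufficed" |
| frequency grid | 20 log-spaced points, 10 kHz–45 MHz | 20-well plate, stated band |
| medium | ε_r 78, σ 43 mS/m | the DEP buffer's measured conductivity |
| control cells | r 10 µm, C_mem 0.01 F/m², G_mem 2000 S/m², ε_cyt 60, σ_cyt 0.25 S/m | typical urothelial-scale cell |
| cancer cells | as control but G_mem 200 S/m², σ_cyt 0.5 S/m | the two-state contrast: low membrane conductance, high cytoplasm conductivity |
| biological variation | log-normal, CV 0.15 per parameter | positivity-preserving; plausible inter-donor spread |
| noise | iid Gaussian, SD 0.05 per point per repeat | simplest model of "substantial" instrument noise |
| gain | 2.0 | see below |
| dead points | probability 0.05 per point, shared across a sample's repeats | one failed well in twenty; a dead connection affects the whole acquisition |
| low-cell samples | 3, forced into the cancer arm | the deterministic analogue of the study's three failed samples |

Gain 2.0 places simulated spectra on a dynamic range (≈ −1 to +1.6)
where the fixed SD-based exclusion cut of 0.4 sits far from both real
curves (spectrum SD ≈ 0.6–1.0) and the low-cell noise floor (≈ 0.03),
matching the scale on which that cut was originally chosen.

What the generator does **not** emulate: mixed cell populations within
a sample (e.g. squamous contamination), sex- or age-dependent spectra,
correlated noise between repeats sharing a well-plate loading, and
instrument drift. Passing tests therefore demonstrate that the
analysis behaves correctly under its own stated noise model, not that
the classifier's operating point transfers to real clinical spectra.

## Processing and the MDV statistic

Per sample, the summary curve is the per-frequency **median** across
repeats (numpy midpoint rule for even counts). Dead connections are
masked automatically: a point whose median absolute reading across
repeats falls below 0.02 while the spectrum's overall median absolute
level is at least 0.04 is a near-zero outlier relative to a real
curve. The 0.02 cut was set from the operating characteristics on
default cohorts: it detects essentially every injected dead point while
mis-masking < 0.3% of good points, whereas a cut at the noise SD (0.05)
also swallows legitimate near-crossover readings. Uniformly near-zero
spectra fail the overall-level guard and are left to the sample-level
exclusion filter. Masking never alters stored values.

The **Mean Difference Value** of a spectrum is

    MDV = mean(9 lowest-frequency valid points) − mean(9 highest),

i.e. low plateau minus high plateau. Because cancer-like spectra are
more negative below the crossover and more positive above it, their
MDV is smaller, and the decision rule is *cancer iff MDV < threshold*
(strict; ties go to control). "Lowest points" is read by frequency
position, the reading consistent with plateaus relative to the
crossover; a by-value mode is provided since the phrase is ambiguous.
The alternative sign convention is one config switch. When dead-point
masking leaves fewer than 18 valid points the pipeline lets the two
9-point bands share mid-band points rather than refusing the sample;
the strict non-overlapping requirement remains the default for direct
calls. The rolling-average (window 2) trendline is for plots only and
never feeds the MDV.

**Exclusion filter**: a sample is excluded when the SD of its median
spectrum across frequencies is below sd_min = 0.4 (strict). Low cell
counts leave pure noise with no low/high plateau spread, so the SD
collapses by an order of magnitude — the filter separates the two
regimes with a wide margin under the default conditions.

## Diagnostics

Cancer is the positive class; sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP). The arm comparison uses the classical pooled-variance
two-tailed t-test on per-sample MDVs (Welch available as an option).
The threshold sweep evaluates every distinct operating point: each gap
between consecutive sorted MDVs yields one candidate (its midpoint),
plus one candidate outside each extreme. The optimum maximises the
Youden index (sensitivity + specificity − 1); the full gap attaining
it is reported as the optimal-threshold interval and its midpoint is
the threshold used. If several disjoint gaps tie, the lowest-threshold
gap wins (deterministic, favouring the more sensitive rule for this
sign convention).

`run_full_analysis` produces paired reports: exclusion off, then on.
By default the threshold is calibrated once — the Youden optimum of
the *unfiltered* analysis — and reused for the filtered re-analysis,
so the two reports differ only in which samples enter the statistics;
this mirrors re-analysing a fixed discriminator after removing failed
samples. The sweep is calibration on the data in hand, not validated
inference: no confidence intervals, multiple-testing control or
cross-validation are attempted, and reported operating points are
optimistic in the usual resubstitution sense.

## Numerical and design choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed reproduce
  byte-identical cohort files and reports (floats serialised via
  `repr`).
- Degenerate t-test input (zero variance, equal means) returns
  (t, p) = (0, 1) instead of NaN.
- Spectrum values are never modified by masking; every masked decision
  is recoverable from the mask column of the written CSVs.
- Problem sizes: the operating-characteristics checks use 100 cohorts
  of 16 samples and the fit-recovery study 100 noisy replicates of a
  20-point spectrum — large enough for stable proportions at the
  precision reported, and the whole suite runs in seconds.

## Known limitations

- The instrument gain, and hence the absolute MDV scale and threshold,
  is synthetic-data-specific; on real spectra the threshold must be
  re-calibrated by the sweep. The classification *structure* (bands,
  sign, exclusion) is scale-invariant up to positive gain.
- The single-shell model ignores the nucleus and membrane dispersion;
  fitted parameters are effective values, adequate for the two-state
  qualitative contrast the classifier relies on.
- With 8 + 8 samples the operating characteristics are coarse (steps
  of 1/8); reported sensitivities and specificities should be read as
  counts, not precise rates.
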