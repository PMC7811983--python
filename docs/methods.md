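# Methods

## Spectral biomarker pipeline

The analysis operates on 19-channel scalp EEG (10-20 montage, 128 Hz).
Channels are bandpassed 0.5–40 Hz with a 2nd-order Butterworth filter.
The filter is applied forward and backward (`sosfiltfilt`), standard EEG
practice that preserves waveform timing; the effective magnitude response is
therefore the square of the designed 2nd-order response, and the design
order — not the application mode — is the configurable parameter.

The recording is partitioned into consecutive non-overlapping 10 s epochs.
An epoch is rejected if any channel exceeds ±100 µV (movement/electrode
transients) or if any channel's standard deviation falls below 0.1 µV
(flatline). Both thresholds are configuration options; the defaults follow
common clinical QEEG practice, since "artifact-free" admits no single
canonical criterion. The first 12 passing epochs are concatenated into the
120 s analysis segment. The segment need not be contiguous in original
time: each 10 s tract is windowed independently downstream, so boundary
discontinuities do not leak across tract spectra. Selection is
deterministic, first-fit, order-preserving; a recording with fewer than 12
clean epochs raises an explicit error naming the shortfall.

The PSD is Welch's estimate: the mean of Hann-tapered modified periodograms
over the twelve 10 s tracts (0.1 Hz resolution, 0% overlap — the natural
reading of a 120 s segment averaged in 10 s tracts; overlap is exposed only
through the tract length parameter). Density scaling with window-power
compensation is used so that the integral of the PSD over frequency
approximates the signal variance; the test suite asserts this Parseval
property within 5% on broadband noise.

Absolute band powers integrate the PSD by the rectangular rule over bins
whose centre frequency lies in the band. The canonical bands delta [1, 4),
theta [4, 8), alpha [8, 13), beta [13, 30) Hz share endpoints, so bins are
assigned half-open on their centres: the four bands then tile the 1–30 Hz
normalisation range with no gap or double counting, relative powers are
exact fractions of the total, and the four fractions sum to one on every
channel to 1e-9. (A `BandDefinition.include_upper` flag provides a
closed-upper-edge variant; it is off by default because it breaks the exact
tiling at finite resolution by one bin.)

DAR = delta/alpha and DTABR = (delta+theta)/(alpha+beta) are computed per
channel; because the 1–30 Hz normalisation cancels in both ratios, absolute
and relative powers give identical values (asserted as a property test).
Scalp averaging is the arithmetic mean of each of the six parameters over
all electrodes. For the ratios this is deliberately the **mean of
per-channel ratios**, not the ratio of scalp-mean powers: the parameters are
averaged, not the underlying powers. The alternative convention changes the
result (e.g. channels with (delta, alpha) = (0.5, 0.25) and (0.2, 0.4) give
1.25 vs 1.077) and is available as `scalp_average(..., method="ratio_of_means")`.

## Outcome statistics

Spearman's rho is the product-moment correlation of midranks (average ranks
for ties — NIHSS and mRS are heavily tied integer scales). For n ≤ 9 the
two-sided p-value is exact, computed by enumerating all n! pairings of the
rank vectors; beyond that the Student-t approximation with n − 2 df is used
(a 20-patient cohort sits firmly in the approximation regime, and exactness
is cheap where it matters). The test suite checks rho and the exact p
against brute-force enumeration for all n ≤ 8.

Each outcome (NIHSS at admission, 7 days, 12 months; final infarct volume)
is tested against the six EEG parameters; Bonferroni control is applied per
outcome family with m = 6 by default (configurable), flagging significance
at p < 0.05/m.

Good 12-month outcome is mRS ≤ 2. The boundary category mRS = 3 is assigned
to the bad class by default, giving a two-class partition of the cohort; a
literal mode (`mrs3_is_bad=False`) leaves mRS = 3 unassigned and drops those
patients from the logistic stage. Logistic regression of good-vs-bad on
intercept + ln(feature) is fitted by IRLS (binomial GLM, statsmodels); the
odds ratio per unit ln-increase is reported with a 95% Wald interval, the
presentation convention for this analysis. Complete separation is detected
before fitting (a threshold on the ln-feature splitting the classes
perfectly) and reported as a non-converged result rather than an error.
Coverage of the Wald CI is verified empirically: over 200 simulated cohorts
of n = 200 with a known coefficient, the interval covers the truth within
95 ± 4 percentage points.

## Lesion imaging

Region growing uses a fixed intensity window and 6-connectivity:
breadth-first growth from the seed over neighbours whose intensity lies in
[low, high], terminating when the frontier is empty. This is the simplest
deterministic member of the region-growing family — equivalently, the
6-connected component of the in-window voxel set containing the seed, which
is exactly how an independent test cross-checks it (scipy.ndimage labeling).
The homogeneity window and connectivity are configuration options since no
single canonical choice exists. Mask volume is voxel count × voxel volume
(mm³) / 1000 ml.

Perfusion classification thresholds each voxel against its mirror across
the midline axis (voxel-wise, no registration — adequate for the symmetric
synthetic maps; real-data registration is out of scope): hypoperfused where
MTT > 1.45 × contralateral, necrotic core where additionally
CBV < 2.0 mL/100 g, salvageable penumbra otherwise. The boundary
CBV = 2.0 is assigned to penumbra — conservative toward salvageable tissue.
Mismatch is penumbra/total hypoperfused, in [0, 1]; it is NaN (not 0) when
nothing is hypoperfused, because the ratio is then undefined.

## Synthetic cohort

The generator provides known ground truth for every stage; all generators
are pure functions of their arguments including the seed.

**EEG.** Each channel is 1/f^γ background noise (γ = 1, 5 µV RMS) plus four
band-limited Gaussian-noise oscillators (5 µV RMS per unit gain) centred on
the four bands. Band-limited noise rather than pure sinusoids keeps every
Welch bin within a band populated and avoids knife-edge bin-alignment
artifacts. Oscillator gains interpolate linearly between a healthy
alpha-dominant vector (delta 0.7, theta 0.8, alpha 2.0, beta 0.7) and a
stroke delta-dominant vector (2.2, 1.2, 0.6, 0.4), so DAR and relative
delta are increasing, and relative alpha decreasing, functions of severity
by construction — the property the downstream correlation stage must
recover. At severity 0 the spectrum is alpha-dominant (downstream relative
alpha ≈ 0.63 vs delta ≈ 0.10); at severity 1, DAR reaches ≈ 9.

**Artifacts.** A configurable fraction of 10 s epochs receives either a
0.2 s biphasic transient at 10× the channel SD (at least 150 µV, above the
100 µV rejection threshold) or a full-epoch flatline on one channel. Both
failure modes are exactly the ones the rejection rule tests, so every
contaminated epoch is guaranteed to be caught.

**Outcomes.** The severity→NIHSS mean curve is logistic-shaped (steepness 6,
midpoint 0.7), rescaled to pass through 0 at severity 0 and 42 (the scale
maximum) at severity 1 — a bounded scale with floor and ceiling effects. A
uniform-severity cohort then has median admission NIHSS ≈ 10. Recovery
factors 0.4 and 0.25 produce the 7-day and 12-month scores (medians ≈ 4 and
≈ 2–3 across a uniform cohort); truncated Gaussian noise (default SD 1) is
added before integer rounding and clipping. The 12-month mRS is a monotone
step function of 12-month NIHSS (cuts 1, 2, 4, 6, 8, 10), placing about
55% of a uniform cohort at mRS ≤ 2. Final infarct volume is
116 ml · severity^4.5 with lognormal noise (σ = 0.4), giving a strongly
right-skewed distribution with median ≈ 5 ml and maximum ≈ 116 ml. These
constants were chosen once to match the descriptive scale of a typical
thrombolysis-treated anterior-stroke cohort and are configuration fields,
not tuning knobs.

**Lesions.** The lesion is the set of the N voxel centres closest to a
random centre under a random mildly anisotropic (axis ratios 0.8–1.2)
ellipsoidal metric, with N matching the requested volume exactly; ground
truth is therefore exact bookkeeping, not an approximation. Intensities are
80 ± 2 (lesion) on a 40 ± 2 background, so the default growing window
[70, 90] separates the tissues by > 5 SD; the lesion is confined to one
side of the midline, and volumes that cannot fit off-midline are rejected.
Perfusion maps are mirror-symmetric outside the lesion (baseline MTT 4.0,
CBV 4.0, shared symmetric noise), MTT is raised to 180% of the mirrored
baseline inside the lesion, and CBV drops to 1.0 on the innermost
`core_fraction` of lesion voxels (by distance to the lesion centroid) and
stays at 3.0 elsewhere, so the classifier's recovered core fraction equals
the requested one up to a single voxel.

**What the generator does not emulate.** No volume conduction or dipole
forward model, no topographic/hemispheric asymmetry (the analysis averages
over all 19 electrodes, so laterality is never consumed), no real artifact
morphologies beyond the two rejection failure modes, no CTP acquisition
physics or contrast kinetics, and outcome noise that is independent across
time points rather than longitudinally correlated. Passing tests therefore
demonstrate correctness of the computational pipeline under its stated
model, not clinical performance on real recordings — the cohort
correlations reported for real patients are not reproducible from
simulation and are not targets of this package.

## Problem sizes and numerical choices

The default simulated cohort is 20 patients × 300 s × 19 channels at
128 Hz; tests use 3–20 patients and 130–300 s recordings, sizes at which
the full pipeline runs in tens of seconds. Exact Spearman inference
enumerates up to 9! permutations vectorised; the logistic coverage check
uses 200 replicates of n = 200. Lesion recovery is exercised from 1 to
100 ml on 1 mm isotropic grids. EDF export quantises to 16 bits over each
channel's physical range (error < range/65535, ≈ 0.006 µV for typical
amplitudes); features recomputed after an EDF round trip agree with the
in-memory values to 0.1%. CSV outputs use a fixed float format so reruns
with an identical configuration are byte-identical.

Known limitations: Wald (not profile-likelihood) intervals are reported,
which undercover near separation — flagged via `converged`/`separated`
instead of being patched; the t-approximation for Spearman p at n > 9 is
standard but approximate under heavy ties; region growing assumes the
lesion is 6-connected at the acquisition resolution; the perfusion midline
mirror assumes head symmetry and no registration error.
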