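# Methods

`glomquant` quantifies two complementary properties of olfactory-bulb
dopaminergic (DA) interneurons — the anatomy of their presynaptic release
sites and their capacity for GABAergic self-inhibition — and ships a
synthetic-data generator for each, so that every estimator in the package can
be validated against known ground truth. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## 1. Synthetic imaging scenes

### Geometry

Dendrites are represented as polylines in physical micrometres, generated by
a correlated random walk with fixed 0.5 µm steps inside the voxel grid
(heading jitter SD 0.35 rad; z drift a few percent of the axial extent per
step, reflected at the boundaries). A filament set is one main polyline plus
optional branches rooted on it; because segment lengths are fixed, total
length is controlled to within a few percent of the target. Coordinates use
(x, y, z) order with the origin at the centre of voxel (0, 0, 0); arrays are
stored (z, y, x).

Puncta are scattered along the filaments as a Poisson process in arclength
(default linear density 0.19 µm⁻¹, the measured dendritic bouton density of
anaxonic DA cells), displaced by uniform jitter in a 0.1 µm ball, and each
receives an independent Bernoulli co-localisation label (default fraction
0.74, the measured fraction of presynaptic-marker puncta that carry the
vesicular GABA transporter, vGAT).

### Optics

The default voxel grid matches high-NA confocal acquisition: 0.033 µm in xy
and 0.37 µm z steps. Co-localisation scenes are thin (4 planes, ≈1.1 µm), as
used when antibody penetration limits usable depth; density scenes use
16-plane (≈5.9 µm) stacks. Each punctum renders as an anisotropic 3D
Gaussian with σ = diameter/2.355 (0.5 µm default diameter) convolved in
quadrature with a Gaussian PSF (σ_xy 0.10 µm, σ_z 0.30 µm). The blob peak is
the punctum amplitude (150 photons default over a background of 10). The
"GFP" channel renders filament tubes (0.15 µm radius, peak 100); the "vGAT"
channel renders blobs at co-localised puncta (placement offset SD 0.05 µm)
plus off-filament distractor blobs at 0.05 µm⁻³, at least 0.5 µm from any
dendrite. Noise is applied last: Poisson photon noise on signal plus
background, then Gaussian read noise (SD 2). Every stochastic stage takes an
explicit seed; a scene is bit-reproducible from one integer.

What the generator deliberately omits: optical sectioning beyond the
Gaussian PSF, spectral bleed-through, depth-dependent aberration, uneven
labelling, and tissue autofluorescence structure. Passing tests on these
scenes therefore show that the estimators are correct *given* the stated
image-formation model, not that they are robust to every real-world
artefact.

## 2. Imaging analysis

### Detection

Puncta are detected by a scale-matched, anisotropy-corrected
Laplacian-of-Gaussian filter: per-axis sigmas equal the expected punctum
sigma in voxel units (the axial sigma floored at half a voxel), the response
negated and normalised by σ_xy²/3. "Quality" is the peak filter response —
a portable stand-in for proprietary spot-quality scores. The default
threshold (300) was calibrated once on default-SNR scenes, where true-blob
responses fall at 800–2700 units and noise-only maxima stay below ~50.
Local maxima use a suppression footprint of half the blob sigma so that
pairs down to the two-Gaussian resolvability limit (≈2σ) retain separate
maxima; centroids are refined by centre-of-mass of the response over a
one-sigma neighbourhood, and refined centroids closer than half the expected
diameter are deduplicated (higher quality wins).

Two true puncta closer than ≈0.47 µm laterally (≈0.94 µm axially) produce a
single intensity mode and cannot be split by any local-maximum method.
Detection benchmarks therefore use neighbourhood confusion counts: a true
punctum counts as recalled if *any* detection lies within the 0.5 µm match
radius. Density estimates, which count detections, inherit a small (~10%)
downward bias from such mergers at the default density; this mirrors the
behaviour of any spot-counting workflow at these separations.

### Co-localisation rule

For each punctum, at its (y, z) centroid voxel row: find the punctum-channel
x-profile maximum within the punctum's x-extent (centroid ± diameter/2);
average the target channel over a 1 µm window centred there; compare against
the mean + 1 SD of target intensity in 1 µm windows immediately flanking the
x-extent on *both* sides, pooled. The call is positive on strict inequality.
Pooling both flanks removes an arbitrary side choice and reduces background
variance; the SD is the sample SD (n−1) of the pooled background voxels.
Sub-voxel centroids are rounded half-away-from-zero for profile extraction.
The criterion is scale-equivariant — rescaling both channels leaves every
call unchanged — and puncta whose background windows fall entirely outside
the volume are excluded from the percentage and logged.

In crowded fields, a neighbouring punctum's target-channel blob can fall in
a background window (deflating calls) or, more rarely, in the centre window
(inflating them); at the default density these effects stay within a few
percentage points, which is why fraction-recovery checks are run at the
study's own density rather than artificially dense fixtures.

### Density and soma area

Dendritic puncta density is the number of detected puncta whose centroid
lies within a match radius (default 0.5 µm) of any filament, divided by
total filament length. Soma area is the absolute shoelace area of the
drawn polygon on a maximum-intensity projection.

## 3. Synthetic electrophysiology

### Passive model

The clamped cell is a single RC compartment: series resistance R_s, membrane
resistance R_m, capacitance C_m. A command step ΔV produces
I(t) = ΔV/(R_s+R_m) + (ΔV/R_s − ΔV/(R_s+R_m))·e^(−t/τ), τ = C_m·R_s‖R_m.
Units are pA / mV / MΩ / pF, so R·C is in microseconds. All sweep responses
are exact superpositions of this closed form at step on/off edges, which the
analysis-side tests exploit as machine-precision oracles.

### Evoked and spontaneous currents

The depolarisation-evoked GABA-A current is a difference of exponentials
(rise 1 ms, decay rate k, default 0.03 ms⁻¹) starting at each step's end.
The calcium tail current is a 20 ms mono-exponential. Both are inward
(negative) and are scaled so that their integral over the standard analysis
window — 10 ms to 510 ms after the step end — equals the archetype's
ground-truth charge. The window convention matters: with k = 0.03 ms⁻¹ only
~74% of the kernel's infinite-time integral falls inside the window, and
experimental charge values are themselves window integrals, so defining
ground truth on the window keeps generator and estimator commensurable for
any decay rate. Gabazine removes the GABA component and suppresses
spontaneous IPSCs; cadmium removes the tail.

Spontaneous IPSCs arrive as a Poisson process (default 2 Hz, biexponential
0.5/10 ms, peak ≈30 pA). Event, component, and noise randomness are drawn
from separate seed substreams, so two conditions simulated with the same
seed share event times and noise exactly — the pharmacological subtraction
identity (pre − gabazine = GABA + sIPSC components, exactly, at zero noise)
holds by construction and is asserted in tests. "Noise-free" recovery
conditions mean Gaussian noise SD 0 *and* sIPSC rate 0: spontaneous events
are biological noise that survives subtraction by design.

Archetype presets anchor the two DA subtypes: anaxonic cells with large
self-inhibition charge (44.11 pC), high input resistance (684 MΩ), no tail;
axon-bearing cells with near-absent self-inhibition (3.8 pC), lower input
resistance (324 MΩ), and a 15.33 pC cadmium-sensitive tail.

### Action potentials

Spikes are phenomenological, not conductance-based — only the phase-plane
topology is specified. Monophasic (anaxonic): one logistic upstroke (85 mV,
0.10 ms rise scale). Biphasic (axon-bearing): a small fast
initial-segment component (20 mV, 0.05 ms) followed 0.45 ms later by the
dominant somatic component (70 mV, 0.07 ms); repolarisation is a slow
logistic (2 ms), emulating caesium-loaded recordings. The somatic dV/dt peak
exceeds the initial-segment bump, matching the physiological ordering.
Traces are sampled at 200 kHz (5 µs).

### Cohorts

`make_cohort` draws per-cell parameters from subtype presets with a shared
animal-level lognormal effect (SD 0.2 on the log scale by default) and
per-parameter cell-level lognormal effects (CVs approximating the measured
between-cell spread, e.g. 0.7 for AEI charge), both mean-corrected so the
arithmetic mean equals the preset. Animals are nested within subtype and
cells are dealt round-robin, giving balanced designs for the nested
statistics.

## 4. Electrophysiology analysis

**Membrane test.** The two polarity responses of the double test pulse
(±10 mV, 5 ms, from −60 mV) are sign-corrected and averaged; baseline is the
pre-step mean. A three-parameter exponential A·e^(−kt) + C is fitted from
the peak sample onward (log-linear initialisation, then least squares). The
fit supplies everything: steady state I_ss = C (the tail mean alone is
biased when τ is slow relative to the 5 ms pulse), peak back-extrapolated to
the step onset I_0 = A + C (the sampled peak undershoots ΔV/R_s by up to one
sample's decay), R_S = ΔV/I_0, R_I = ΔV/I_ss (total input resistance),
and C_M = A·τ·(R_S+R_m)²/(ΔV·R_m²) with R_m = R_I − R_S, which inverts the
RC relation between transient charge and capacitance. Estimates are
invariant to step polarity, step size, and holding current.

**Series-resistance QC.** A recording fails if any R_S value exceeds 30 MΩ
or the spread (max − min) exceeds 30% of the first value.

**Charge.** Conditions are compared as pre − post averaged traces, with the
mean over the 50 ms before the first step removed from the difference.
Charge is the trapezoidal integral over 10–510 ms after the (last) step end,
reported as the positive magnitude of the inward integral, in pC. For
paired-pulse protocols the window anchors to the second pulse; a per-pulse
breakdown (windows truncated at the next pulse) is also available.

**Decay.** A·e^(−kt) + C fitted to the sign-corrected trace from the
within-window peak onward, k bounded in (10⁻⁴, 1) ms⁻¹, log-linear
initialisation; non-convergence, k at the lower bound, or a constant input
raise a fit-failure error.

**Spontaneous IPSCs.** Inward deviations from the trace median crossing a
threshold (default 15 pA), with refractory merging (default 5 ms); event
times are estimated onsets (walk-back to 5% of peak height), since the
biexponential kernel peaks ≈1.6 ms after onset.

**Phase plane.** Voltage is smoothed with a 20-point sliding mean (100 µs at
5 µs sampling; windows shrink symmetrically at the edges), then
differentiated by central differences. The attenuation of this chain is
analytic (Dirichlet kernel × sinc) and is verified against a closed form in
tests.

**Classification.** The upstroke is the contiguous run of dV/dt above
10 V/s ending at the global dV/dt maximum. After light smoothing (5-point),
local maxima of dV/dt along the upstroke are counted; the waveform is
biphasic iff two maxima are separated by a trough at least 10% below the
smaller one. Both thresholds are exposed as configuration, since the
original discrimination was visual; the defaults give 100% agreement with
generator labels noise-free and ≳97% at 0.3 mV voltage noise. The rule is
invariant to voltage offsets and uniform time rescaling.

## 5. Statistics

`summarize` reports mean ± SEM (sample SD/√n; SEM undefined at n = 1).
`format_proportion` rounds half-away-from-zero at the requested precision.

`choose_and_compare` reproduces normality-driven test selection: per-group
normality via D'Agostino–Pearson for n ≥ 8 (the test's minimum usable
sample) and Shapiro–Wilk below; both-normal unpaired data get a t-test, with
Welch's correction when a two-tailed F-ratio test rejects variance equality
at α = 0.05 (or always, by configuration); non-normal unpaired data get
Mann–Whitney (exact null distribution for tie-free groups of ≤8); paired
data get paired t or exact Wilcoxon signed-rank. Every result carries a
decision trace recording which branch fired. No multiple-testing correction
is applied by default.

`repeated_measures_check` is the classic one-way within-subject
decomposition (F = MS_time/MS_error); the degenerate all-identical-columns
case returns F = 0, p = 1. It is cross-checked against an independent
implementation in tests.

`nested_compare` addresses cells-within-animal pseudoreplication. Primary
route: a linear mixed model (REML) with animal random intercept; the
fixed-effect p-value uses a t reference with n_animals − 2 degrees of
freedom rather than the asymptotic normal, because Wald-z inference with few
clusters is anticonservative. Fallback (on singular or non-converged fits,
or by request): a seeded permutation test that shuffles group labels at the
animal level (cell-level mean difference statistic). In null simulations
with a strong animal effect (8 animals per group, 5 cells each), both
routes hold the 5% level while the naive cell-level t-test rejects ~30% of
the time. With 5 or fewer animals per group both routes are structurally
conservative (permutation granularity, small between-cluster df) — a safe
direction, but worth knowing when interpreting marginal p-values.

## 6. Problem sizes and tolerances used in validation

Recovery checks run at: a 3×3×3 grid of R_S/R_m/C_M (noise-free < 2%,
achieved < 0.01%; 5 pA noise, 100 seeds, median < 10%, achieved ≈0.5%);
charge 5/25/45 pC × decay 0.02/0.03/0.05 ms⁻¹ (noise-free < 5%; 5 pA median
< 10%); decay k within 1% noise-free; 200 spikes at 0.3 mV noise (≥90%
agreement); co-localisation fractions 0/0.5/0.75/1 on three 33.8 µm-field
scenes each at default SNR (±10 percentage points); detection on three
default-SNR scenes (recall and precision ≥ 0.9 at 0.5 µm); density on a
200 µm, 16-plane noise-free scene (within the Poisson 95% interval of the
target); 1000 null cohorts for nested-test calibration. These sizes were
chosen to make sampling noise small relative to each tolerance while keeping
the full validation suite runnable in minutes on one CPU.

## 7. Known limitations

- The imaging model has no deconvolution and no object-overlap
  co-localisation alternative; the intensity-window rule is the only
  criterion implemented, by design.
- Density and recall inherit the resolvability-merge bias described above;
  at densities well beyond ~0.3 µm⁻¹ the intensity-window co-localisation
  call also degrades from background-window contamination.
- The ephys generator is linear: no voltage-dependent conductances, no
  series-resistance error correction, no liquid-junction handling; the
  2.9 kHz hardware filter is not emulated by default.
- Spike waveforms are shape templates; they validate the classifier's
  topology handling, not biophysical realism.
- The mixed-model route reports a variance decomposition but its p-value
  rests on the t(n_animals − 2) approximation; for designs with very few
  animals prefer the permutation route.
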