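# Methods

## Stimuli and timing

Four protocols are modelled on a square visual-field grid covering
±5.5 degrees (samples at pixel centres; default 101×101 for rendering,
51×51 for fitting, where the coarser grid changes predictions by less than
the optimiser tolerance at the pRF sizes involved). Timing is fixed by the
acquisition design: bowtie 186 volumes (first 6 discarded, 15 rotation
cycles of 24 s), ring 174/6 (12 expansion cycles of 28 s), full-field
flash 124/4 (12 cycles of 4 s ON / 16 s OFF), bar 200/0 (8 sweeps of 40 s
— four orientations 0°, 45°, 90°, 115°, two directions each — with four
20 s blanks after every second sweep), all at TR 2 s. Quantities the
design does not fix are conventional defaults, configurable: 45° wedge
width per bowtie lobe, ring annulus width 25 % of the display radius, bar
width 1/8 of the 11° display. Polar angle is measured counterclockwise
from the upper vertical meridian in [0, 360), so the left visual hemifield
is (0, 180).

The chequerboard carrier, colour flicker and fixation task are not
modelled: only the binary aperture enters the forward model.

## Haemodynamics

The HRF is a double gamma with unit scale: gamma densities with modes at
the peak delay (5 s) and undershoot delay (15 s), undershoot ratio 1/6,
kernel length 32 s, normalised to unit peak, h(0) = 0. Convolution of a
volume-level regressor is done at dt = 0.1 s with zero-order hold and
resampled at volume onsets. This choice is load-bearing: it makes the
cycle-averaged 4 s-ON block response peak at 8 s after stimulus onset on
the 2 s grid, the latency positive voxels show empirically; naive
discrete convolution on the TR grid mis-places the peak at 6 s because it
integrates only two samples of the ON block. An exactly sign-inverted
voxel population necessarily peaks (negatively) at the same latency, so
the generator cannot reproduce a genuine latency difference between
positive and inverted populations; none is asserted anywhere.

The full-field reference waveform is the HRF-convolved ON/OFF boxcar,
zero-meaned. Pearson correlation is invariant to the zero-meaning and to
kernel amplitude rescaling, so the positive/inverted classification is
scale-free.

## pRF model and fitting

A voxel's neural drive is the fraction of its unit-mass Gaussian pRF
covered by the aperture each volume; predictions are that drive convolved
with the HRF, scaled by an amplitude beta and offset by a baseline. The
convolved aperture matrix is precomputed once per (movie, HRF) pair, so a
prediction is one matrix–vector product.

Fitting is two-stage. Stage 1 evaluates an 11×11 lattice of centres over
±5.5° crossed with sigmas {0.25, 0.5, 1, 2, 4}°, solving (beta, baseline)
per candidate in closed form, vectorised over voxels. Stage 2 runs
Nelder–Mead over (x0, y0, sigma) from the grid winner — beta and baseline
profiled out at every evaluation — with bound penalties at twice the
display extent, relative RSS tolerance 1e-6 and a 500-evaluation cap; the
result never has higher RSS than its start. Multi-run series (bowtie,
ring, bar) are fitted jointly after per-run mean removal of both data and
predictions; per-run fitting remains available by passing a single movie.
Bowtie and ring apertures are symmetric under 180° rotation, so joint
fitting without the bar leaves the antipodal position degenerate — the bar
breaks it.

Amplitude is constrained nonnegative by default, as in standard
retinotopy fitting. This is the mechanism by which venous artefact
corrupts maps here: a sign-inverted voxel cannot be fitted at its true
position with a positive amplitude, so it lands elsewhere (often in the
ipsilateral hemifield) or fits poorly and falls below the
variance-explained floor (default 0.1) that gates voxels out of coverage
and smoothness analyses. A signed mode is provided; under it, noiseless
inverted voxels are recovered exactly with negative beta.

Travelling-wave analysis: per-voxel discrete Fourier phase and coherence
at the stimulus frequency bin, coherence defined as the amplitude at that
bin over the root-sum-square amplitude of all non-DC bins. A double-wedge
bowtie stimulates each voxel twice per rotation, so its response
fundamental sits at twice the rotation frequency and the phase there
encodes polar angle modulo 180°.

## Voxel classes and the correction

The normalised mean map is each voxel's time-average divided by the
maximum such average. Venous eclipses are either supplied as manual ROIs
(the reference workflow) or detected automatically as a stated surrogate:
voxels below the 0.15 intensity quantile, grouped into 4-connected
components, kept when at least 20 voxels large and elongated
(major/minor axis ratio ≥ 2, the shape signature of a vessel shadow).

The flip correction reflects every voxel with r < −threshold (strict;
default threshold 0) about its own temporal mean. This is the unique
pointwise correction that exactly negates r while leaving the voxel's
mean — hence the mean map — unchanged, and it is an involution. Ties at
r = 0 are classed positive: flipping a zero-correlation voxel is a no-op
in expectation. A −0.1 threshold variant (flip only r < −0.1) is exposed
because flipping weak, noise-driven negative correlations can make maps
worse rather than better.

Negative voxels beyond the stimulated 5.5° are classified NBR, within it
inverted; voxels without an eccentricity estimate are flagged
unclassifiable. Inverted-voxel prevalence is reported as the plain
within-region percentage of negatively correlated voxels.

## Coverage and smoothness

Visual-field coverage renders the usable fits (variance explained above
the floor, non-degenerate) as unit-height Gaussian profiles on a 201×201
field grid. The default map is the profile *envelope* (pointwise
maximum), binarised at 0.8; the sum-of-profiles map normalised by its
maximum is available as an option. The envelope was chosen as the default
after the sum reading proved unusable for completeness classification at
desk scale: with max-normalisation the binarisation threshold couples to
the local crowding of pRF centres, and even a perfect full-hemifield map
classifies "incomplete" in the meridian sectors. Under the envelope a
complete map covers essentially every sector and the 20 % cutoff
discriminates exactly the failure mode of interest. Sector percentages
are computed on grid points within 5.5°; completeness uses round-half-up
(the boundary behaviour is exact: 19.4 % is incomplete, 19.5 % complete).

For smoothness, the ROI's polar angles are mapped linearly to luminance,
the lattice is rotated so the least-squares angle gradient runs along the
image x-axis, voxels are re-binned at unit spacing, and the per-column
mean of included pixels is min–max normalised across columns. The
statistic is the total variation of that profile: a clean monotone ramp
spanning the range scores exactly 1, disturbances raise it, and a
constant image is degenerate (score 0, warned). The literal per-column
RMS contrast of a horizontal ramp would be 0 in every column and could
never score 1; the column-mean reading is the one under which the
ideal-map calibration holds. `percent_smoother(before, after)` is
100·(s_before − s_after)/s_before, positive when the correction smooths.

## Synthetic cortical patches

The generator lays out a rows×cols voxel lattice (default 30×30) whose
columns split into strips for V1, V2, V3, hV4 (23/23/24/20 % of columns)
and a 10 % periphery strip just beyond the stimulus (eccentricities
5.75–7°). Polar angle runs 5°–175° down the rows in every strip — hV4
therefore carries a full contralateral hemifield — and eccentricity runs
0.25°–5.25° across each strip's columns with a deterministic golden-ratio
stagger across rows, emulating pRF-centre scatter; without it the centres
sit on iso-eccentricity arcs and density maps are degenerate. pRF size
grows linearly with eccentricity (0.3° + 0.2·ecc).

Three depth layers are simulated (2.5 mm and 1 mm above the grey/white
boundary, and the boundary), with an elongated eclipse band near the
lower hV4 border whose per-layer intensity drop (0.45/0.30/0.10 of
baseline) and inversion probability (0.8/0.5/0.2) decay toward the
grey/white boundary; the depth-integrated series is the unweighted layer
mean, and a voxel's integrated class is inverted when a majority of its
layers are. Baseline EPI intensity is 100 with spatial heterogeneity
(sd 8, shared across layers — a property of the anatomy, not the noise);
response amplitude beta = 2 (≈1.2 % peak signal change), Gaussian noise
sd 1 per layer. NBR voxels respond with the negated HRF-convolved
whole-display coverage at amplitude 1.5 and noise sd 0.5 — brighter,
stronger-correlated and cleaner than inverted voxels, which is the
signature separating suppression from artefact. Responses modulate about
the baseline (the drive is zero-meaned), so the mean map carries vascular
intensity information only. All randomness derives from the single spec
seed; identical seeds give bit-identical bundles, and patch geometry is
seed-independent.

Scenarios: `default` (the conditions above), `missing_lower` (lower-sector
hV4 pRFs silenced, no eclipse — the incomplete-without-artefact control),
and `subject10` (24×24; every lower-sector hV4 voxel inverted at all
depths, constructed so the lower quadrant classifies incomplete before
correction and complete after). In the subject-10 scenario the artefact
block is compact rather than elongated, so the detector does not report
an eclipse and the run pairs "incomplete, eclipse absent" — an
incongruent pairing, as in the real case it emulates.

What passing tests on these phantoms do *not* show: performance on folded
cortical geometry, physiological (non-white) noise spectra, genuine
latency shifts in inverted responses, partial-volume mixtures, or
hand-drawn ROI variability. The depth phenomenology is injected, so the
depth tests validate the measurement chain, not the physiology. Because
both the superficial and the integrated eclipse contrasts sit far above
the detection floor under the default conditions, superficial-layer
detection ties, rather than strictly beats, detection on the integrated
map; the integrated intensity contrast itself is strictly weaker, and
detection does collapse at the grey/white boundary.

## Pipeline and reproducibility

`run_pipeline` chains mean map → correlation → eclipse ROI (manual file or
detection) → flip → pRF fits of original and corrected series (hV4 ROI) →
coverage, smoothness, inverted fractions, and the congruence label
("incongruent" when lower-quadrant completeness contradicts eclipse
presence). Stage failures raise a stage-named error; outputs (config echo,
report JSON, fits and class tables, ROI) are written next to each run.
NBR-class voxels sit outside the visual-area ROIs and therefore never
enter area-level analyses. Real 4-D NIfTI series are ingested through a
masked extraction with a documented stable voxel ordering (x fastest) and
a header-TR fallback to the configured value.

Problem sizes used by the shipped checks — 20–30 voxel lattices, 41–51
aperture grids, single runs per protocol — are the package's test-scale
defaults; all are configurable upward.
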