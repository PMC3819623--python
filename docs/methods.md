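# Methods

This note documents the models, algorithms and numerical choices behind
`cardiogate`, what the synthetic data does and does not emulate, and the
known limitations.

## Synthetic heart model

The contracting ventricle is an ellipse (aspect ratio 1.4) whose projected
area oscillates sinusoidally between the diastolic area A_d and the systolic
area A_s = A_d(1 − EF/100):

    A(φ) = A_d − (A_d − A_s)(1 − cos φ)/2,    φ = 0 at end-diastole.

Making the *area* (not the radius) sinusoidal means the true EF maps
linearly onto the area envelope, so EF recovery is analytically checkable.
A pure area oscillation is mirror-symmetric in phase — A(φ) = A(−φ) — and no
image-matching method could tell systolic filling from emptying. Real hearts
are not symmetric: the ventricle translates and shears as it contracts. The
generator therefore translates the ellipse centre by 6 µm · sin φ, an odd
term that breaks the symmetry without changing the projected area. Frames
are rasterised with a ~1-pixel anti-aliased edge whose half-intensity
contour is the exact ellipse, so thresholded areas are accurate to well
under 1%.

Phase over time is piecewise linear: rate 2π/period before injury, zero
during a pause (the image freezes at the pause-onset phase), and
2π/post-pause-period afterwards — emulating the observed injury response of
a 2–4 s pause followed by bradycardia. Ground truth (per-frame phase and
area, target-phase crossing times) is exact and computed before noise.
Noise is additive Gaussian on intensity, clipped to [0, 1].

Defaults are the healthy 72 hpf operating point: 400 ms period (150 bpm),
30 fps, A_d = 10.1·10³ µm², EF 20%, 2 µm pixels, noise σ = 0.05 of the unit
dynamic range.

What the generator does *not* emulate: myocardial texture, optical PSF and
depth blur, illumination drift, atrial motion in the field of view, and
beat-to-beat period variability. Passing tests therefore demonstrate
correctness of the algorithms under controlled conditions, not robustness
to every property of real microscope video.

## Gating

* **Similarity metric** — zero-normalized cross-correlation (ZNCC) of whole
  frames: invariant to global intensity gain and offset. Reference frames
  are pre-normalized once, so a frame is scored against all references with
  a single matrix–vector product.
* **Period estimation** — mean ZNCC between frames i and i+L for each
  candidate lag L; integer multiples of the true period score as well as
  the period itself, so the smallest-lag local maximum within 0.25 of the
  peak prominence is selected, then refined by quadratic interpolation.
  A video whose score curve has prominence below 0.02, or whose frames are
  identical, raises an aperiodic-input error.
* **Phase refinement** — quadratic interpolation through the best-matching
  reference and its two circular neighbours; skipped for a bit-exact match
  so exact reference frames return exact phases.
* **Confidence** — margin between the best match and the best
  non-neighbouring match, scaled by 0.05 and clipped to [0, 1]. The scale
  was calibrated on the generator: frames of a default-noise video have
  margins ≥ 0.034 while pure-noise frames stay ≤ 0.013, so the 0.5
  confidence floor separates the two populations with headroom on both
  sides.
* **Prediction** — the last 8 above-floor estimates are circularly
  unwrapped and fitted with a least-squares line; the trigger time solves
  ωt + φ₀ ≡ φ_target (mod 2π) in closed form (verified against a 0.01 ms
  brute-force scan). Latency compensation subtracts a configured scalar,
  since real trigger-to-emission latency is hardware-specific.
* **Withhold paths** — slope below 2π/3000 rad/ms (period > 3 s: pause or
  asystole), fit RMS residual above 0.35 rad (arrhythmia), or confidence
  below floor. Withheld events are recorded once per contiguous episode.
* **Pause safety** — prospective prediction cannot know that a pause will
  begin inside the commit horizon (one inter-frame interval). Because this
  tool gates recorded video and the laser is mocked behind a trigger-event
  sink, a committed trigger is additionally verified against the frames in
  a guard window (default one period) after the predicted crossing: if the
  phase estimates stop following the fitted line — a frozen heart stops
  advancing — the trigger is withheld. This makes the no-fire-during-pause
  rule absolute at the cost of being a post-hoc check that a real-time
  system could not perform; a hardware deployment would accept a one-frame
  risk window instead.
* **Refractory interval** — 60 s default between fires, matching the
  multi-pulse injury protocol (up to 5 pulses at 1-minute intervals);
  configurable, and tests use shorter intervals to keep video lengths
  practical.

## Heart function

Segmentation is a deliberately simple deterministic rule — Otsu threshold,
largest connected component, hole filling — chosen over manual ImageJ-style
outlining so results are reproducible and testable. Diastolic peaks are
detected on the area signal with a minimum peak distance of 0.6 × the
dominant FFT period and prominence 0.2 × the signal range; per-beat extrema
are refined by three-point parabolic interpolation, which removes the
sampling bias (up to ~3% of the pulse amplitude at 9–12 frames per cycle)
that discrete extrema would otherwise introduce into EF. EF uses per-beat
extrema averaged across beats, robust to slow drift. A video whose area
varies by less than 1% of its maximum is treated as having no detectable
beat (degenerate input) rather than returning meaningless extrema.

## Blood-flow velocimetry

Cells are detected as bright blobs (absolute threshold 0.3, area-filtered)
with intensity-weighted centroids (sub-pixel). Frame-to-frame linking is
minimum-total-displacement bipartite assignment with links beyond the gating
distance forbidden; joint assignment is used because greedy closest-pair
matching provably mis-links when inter-cell spacing is comparable to the
per-frame displacement (a trailing cell's next position can be nearer to its
neighbour's current position than that neighbour's own continuation). The
gating distance defaults to 1.5 × the median observed step. Track velocity
is the net displacement between the first and last linked positions divided
by the elapsed frames — equal to the path speed for straight constant-speed
motion, and unbiased under centroid noise, unlike summed step lengths whose
noise contribution is strictly positive. The mean is taken over the 4
longest tracks with ≥ 10 positions (the standard manual protocol).

## Nucleus and puncta counting

The myocardial mask is the largest 3-D 26-connected component of the
thresholded GFP channel, morphologically closed with a 3 µm anisotropic
ellipsoid and hole-filled; the largest-component rule stands in for the
manual exclusion of atrium and bulbus. DAPI nuclei are labelled in 3-D with
26-connectivity (one count per nucleus regardless of z-extent) and filtered
to a volume window of the configured radius ± 50%, computed in µm³ so counts
are invariant to z-sampling density; over-sized (merged) components are
logged and rejected. Watershed splitting of touching nuclei is off by
default — the generator guarantees separation — and nuclei closer than
their diameter plus one z-step are genuinely unresolvable by connected
components at 3 µm slicing, which is why the generator's minimum separation
defaults to 9 µm (5 µm diameter + 3 µm z-step + 1 µm margin). VCm counts
DAPI components whose mean PHH3 intensity exceeds 0.25. TUNEL puncta are
local maxima of the in-plane-smoothed (σ = 0.7 px) TUNEL channel above 0.4
within the mask dilated by 3 µm; puncta (r = 1.2 µm) span roughly one
z-slice, so smoothing is applied in-plane only, and the generator snaps
punctum z-positions to slice planes because a punctum smaller than half the
z-step that falls between planes would simply not be imaged.

## Statistics

Summaries are mean ± SEM (sample sd, n − 1) with n; a single-value group
reports SEM as missing. One-way ANOVA uses scipy; the two-way
repeated-measures design (group between subjects, timepoint within) is
delegated to pingouin's mixed ANOVA and requires every subject at every
timepoint, raising an explicit error otherwise. Pairwise post-hoc t-tests
are Bonferroni-adjusted (raw p × number of comparisons, capped at 1; the
family is all pairwise comparisons within a timepoint) with the usual star
convention (p < 0.05/0.01/0.001).

## Problem sizes

Validation uses problem sizes a desk check can finish in about a minute:
150-frame videos (5 s at 30 fps) for gating and function recovery, 100
seeded noisy gating runs, 25 pause and 25 noisy-stack replicates,
(36, 160, 160)-voxel stacks with 238 + 40 nuclei, 15 flow runs spanning
50–400 µm/s, 2000 null ANOVA simulations, and 1000 random fits for the
trigger-time oracle. All quantities are recomputed from scratch at run time
by `scripts/acceptance.py`.

## Known limitations

* The ellipse-with-translation heart is a stand-in: no published geometry
  underlies area-based EF for this preparation, and volumetric EF is out of
  scope.
* Phase is modelled as locally linear; strong beat-to-beat rate variability
  would inflate the fit residual and suppress triggers (by design) rather
  than track the variability.
* The pause-safety guard inspects frames after the predicted crossing and
  is thus specific to gating recorded video; it is not a claim about
  real-time hardware behaviour.
* Velocimetry assumes quasi-straight motion over the tracked span;
  pulsatile waveform analysis is out of scope.
* Counting assumes nuclei separated beyond the connected-component
  resolution limit; densely packed tissue would need the optional watershed
  path and would no longer be exact.
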