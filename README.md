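# cardiogate

Prospective cardiac-cycle gating and heart-function quantification for the
embryonic zebrafish heart, from 2-D video and 3-D confocal z-stacks.

At 72 hours post-fertilisation the zebrafish heart beats at 2–3 Hz, and the
ventricle and atrium overlap in a lateral view. Delivering a laser pulse to
the mid-ventricle without collateral damage therefore requires *prospective
optical gating*: estimating the cardiac phase from live imagery and firing
exactly when the heart next reaches a chosen phase (typically end-diastole,
the frame of maximal ventricular area). This package implements that gating
loop together with the downstream measurements used to characterise injury
and recovery — heart rate (HR), area-based ejection fraction (EF),
ventricular diastolic area (VDA), caudal-vein blood-flow velocity by
erythrocyte tracking (CVBF), and 3-D counts of total (VCt) and mitotic (VCm)
ventricular cardiomyocyte nuclei and apoptotic (TUNEL) puncta in confocal
stacks. A synthetic-data module generates every input with exact ground
truth, so the whole pipeline installs and validates with zero downloads.

## The method

**Gating.** One recorded cardiac cycle becomes a reference dictionary: frames
with phases φ ∈ [0, 2π) assigned uniformly by time, φ = 0 at the anchor
(end-diastole). Each incoming frame is matched to the dictionary by
zero-normalized cross-correlation; the best match is refined to sub-frame
resolution by quadratic interpolation of the circular similarity curve. The
last few phase estimates (default 8) are circularly unwrapped and fitted with
a least-squares line φ(t) = ωt + φ₀ (locally constant heart rate), and the
trigger time is the next solution of ωt + φ₀ ≡ φ_target (mod 2π), minus the
configured system latency. Triggers are withheld when the match confidence is
low, when ω falls below an asystole floor (cardiac pause), when the fit
residual indicates arrhythmia, or inside a refractory interval (default 60 s,
matching a multi-pulse injury protocol of up to 5 pulses at 1-minute
intervals). A pulse of energy E over duration τ delivers average power
P = E/τ (0.9 mJ over 3 ms → 300 mW).

**Quantification.** EF is area-based: EF = (A_d − A_s)/A_d × 100, with
per-beat diastolic/systolic extrema of the segmented ventricle area
(automatic Otsu threshold, largest connected component, holes filled).
HR is 60000 / mean inter-diastolic-peak interval (ms). CVBF is the mean
velocity of 4 erythrocytes tracked over 10 frames at 30 fps, linked
frame-to-frame by gated minimum-displacement assignment. VCt counts DAPI
nuclei inside the GFP⁺ myocardial mask by 3-D 26-connected labelling with a
physical volume filter (one count per nucleus regardless of how many
z-slices it spans); VCm is the PHH3-positive subset; TUNEL puncta are 3-D
local maxima inside the (dilated) heart region.

## Worked example

```python
import cardiogate as cg

# a healthy 72 hpf embryo: 400 ms period (150 bpm), EF 20%, 30 fps video
video, truth = cg.generate_heart_video(cg.HeartSimParams())

period = cg.estimate_period(video)                        # 400.02 ms
refs = cg.build_reference(video, period, 0, "end-diastole")
events = cg.gate_stream(video, refs, cg.GateConfig(n_pulses=1))
print(events[0].fire_time_ms)                             # 400.01 ms

rep = cg.analyze_heart_video(video)
print(rep.hr_bpm, rep.ef_pct, rep.vda_um2)                # 150.0 20.25 10112.0
```

The first trigger fires 400.01 ms into the recording — within 0.02 ms of the
true end-diastole crossing at 400 ms — and the recovered HR (150.0 bpm),
EF (20.25%) and VDA (10112 µm²) match the generator's ground truth
(150 bpm, 20%, 10100 µm²) to well within segmentation precision.

The same pipelines are exposed on the command line:

```bash
cardiogate simulate heart --out heart.tif --seed 1
cardiogate gate --video heart.tif --target end-diastole --out triggers.csv
cardiogate quantify --video heart.tif --out report.csv
```

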