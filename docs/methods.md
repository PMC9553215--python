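# Methods

## Measurement model

The bladder in a fluoroscopic projection is treated as a prolate
spheroid: the segmented outline is reduced to its equivalent ellipse (the
ellipse with the same normalized second central moments as the binary
mask), giving in-plane semi-axes *a* ≥ *b* in mm, and

    V_ves = (4/3) π a b²   (1 mm³ = 1 µl),

i.e. the out-of-plane semi-axis is taken equal to the short in-plane
axis. No out-of-plane orientation is inferred; calibration is a single
isotropic pixel size (mm/pixel) supplied by the user. Moment-based axes
are rotation invariant and deterministic, which matters because the
animal — and therefore the bladder's pose — moves freely.

Derived quantities follow standard cystometry usage: urethral flow rate
UFR = −dV_ves/dt (positive during voiding), urethral flow conductance
UFC = UFR / p_ves (the only dimensionally consistent reading of "flow
conductance"), bladder capacity BC = V at void onset, residual volume
RV = V at void end, voiding efficiency E_voiding = 100·(BC−RV)/BC, void
duration t20–80 = time for V to fall from 20% to 80% of the voided
volume, and the intercontractile interval ICI measured onset-to-onset.

## Segmentation

The reference operator is classical and deliberately simple: per-frame
robust contrast normalization (0.1–99.5 percentile rescale), dark-object
thresholding, morphological closing (disk radius 2 px) with hole filling
("one closed object"), removal of components touching the image border,
and retention of the single largest 8-connected component above a minimum
area. The default minimum area is the projected disk area of a 4 µl
sphere at the configured pixel size — the practical detection floor of
the approach; smaller bladders read as "no object".

Two design points deserve explanation:

* **Threshold choice.** The automatic threshold is the lowest cut of a
  three-class Otsu split, which separates the contrast-opaque bladder
  from mid-gray bones and bright background. When the bladder is small
  its intensity class carries too little mass to anchor the split, and
  the three-class solution degenerates to bones-vs-background; a second
  Otsu split **inside** the dark class then recovers the truly opaque
  object. A manual threshold overrides both.
* **Border clearing.** Skeletal structures ("bones") cross the whole
  field of view; any thresholded component touching the image border is
  discarded before the largest-object rule. Without this, an empty
  bladder would let a bone win the largest-object contest. The bladder
  itself never touches the border in valid acquisitions.

Frames are pre-smoothed with a centered 15-frame rolling average (window
shrinking symmetrically at the edges) before segmentation. Any external
per-frame predictor with the `frame -> (mask, valid)` contract can
replace the reference operator.

## Trace processing and events

Per-frame volumes are repaired across runs of at most 2 invalid frames by
linear interpolation (typical brief segmentation failures); longer runs
stay invalid. A Savitzky–Golay filter (default window 31 samples ≈ 1 s at
30 frames/s, polynomial order 3, edges by boundary-polynomial evaluation)
smooths the trace **only for differentiation**; BC, RV and t20–80 are
read from the unsmoothed repaired trace, because smoothing rounds off the
volume peak at void onset and biases BC low on short voids.

Void detection thresholds the flow trace (default 2 µl/s), merges
candidates closer than 3 s, widens each event to where UFR crosses 5% of
its peak and then to the flow reversal, and finally anchors onset/end at
the pre-void volume maximum and post-void volume minimum around the flow
peak. The extremum anchoring makes onsets robust to brief artifacts swept
up by merging and keeps ICI errors well below the inter-void spacing.
Candidates moving less than 10 µl are dropped.

Residuals at the detection limit are censored: when the bladder becomes
undetectable around the void end, or the in-void minimum volume is at or
below the ~4 µl segmentation floor, RV is reported as 0 — mirroring what
an annotation-based readout reports for complete voids (an empty bladder
is simply not visible).

Pressure (independently sampled, nominally 50 Hz) is linearly
interpolated onto the image timebase, endpoint-clamped. UFC is undefined
below a 3 cmH₂O pressure floor to avoid division blow-ups between
contractions. Nonvoiding contractions in the 80 s window before each void
are pressure excursions above a rolling-median baseline (15 s window),
detected with a dual threshold — the excursion spans the region above
half the amplitude criterion (default 5 cmH₂O) but must peak above the
full criterion — lasting at least 1 s, and moving no more than 2 µl of
volume (larger drops are leaks/voids, not NVCs). Without pressure
(noninvasive mode) UFC, p_max and NVC counts are simply absent.

## Synthetic ground truth

The simulator emulates the two experimental regimes: a catheterized
session (pump infusion, default 20 µl/min, capacity ~100 µl) and a
noninvasive session (diuresis-driven filling, default 7.3 µl/min,
capacity ~360 µl, pressure typically discarded). Filling is linear; when
volume reaches the capacity threshold a void begins: pressure rises by a
raised-cosine pulse (default 30 cmH₂O over a 10 cmH₂O baseline) and the
urethral conductance opens with the same raised-cosine profile (peaking
mid-void), outflow being conductance × pressure. The pulse width is
solved analytically so the void drains to residual_fraction × capacity;
the volume record is the cumulative trapezoid of the same outflow, so
volume conservation holds by construction. NVCs are raised-cosine
pressure pulses (default 8 cmH₂O, 2 s) at seeded Poisson times during
filling; they move no volume. Filling phases are handled analytically
and voids on a 600 Hz grid (a common multiple of the 30 frames/s and
50 Hz acquisition rates), so runtime is independent of session length.

Rendering projects the spheroid at a configured aspect ratio (default
1.5): attenuation follows the X-ray chord length through the spheroid
(Beer–Lambert, 6 mm⁻¹ — a strong contrast agent, so the silhouette is
nearly saturated with a thin soft rim), composited over a bright
background crossed by 2–3 rigid dark bars ("bones") that translate and
rotate with a drift process independent of the bladder's own
mean-reverting drift (default stationary s.d. 2 px), plus additive
Gaussian sensor noise (default s.d. 0.03 on a 0–1 intensity scale). The
ground-truth mask is the exact ellipse support. All randomness derives
from one seed sequence; identical configurations are bit-identical.

What the simulator does **not** emulate: beam hardening and scatter,
non-elliptical bladder deformation, ureters/reflux, motion blur within a
frame, exposure drift, and genuinely textured anatomy. Passing tests
therefore demonstrate the correctness of the analysis chain and its
robustness to noise, pose, background motion and fill state — not
segmentation performance on real fluoroscopy, which depends on the
chosen per-frame predictor.

## Validation protocols and problem sizes

Desk-scale sessions compress time so that several full filling/voiding
cycles render in minutes on one CPU: supraphysiological fill rates
(refills in ~8–15 s), voids of ~4 s, frame stacks of a few hundred to a
few thousand 224×224 frames. Image-formation settings (noise, background
motion, pixel size 0.1 mm, 30 frames/s) stay at their defaults.

* **Segmentation benchmark** (`cystoflow.protocols.dice_benchmark`):
  four sessions at capacities 50/150/280/400 µl (residual fraction 0.25,
  ~1460 frames total), default segmentation, seeded 20% frame holdout,
  per-frame Dice vs ground truth. Frames where both masks are empty are
  excluded (the Dice formula is 0/0 there).
* **Parameter recovery** (`cystoflow.protocols.recovery_batch`): five
  sessions spanning capacities 50–400 µl and residual fractions
  0/0.25/0.5, two voids each, through the full imaging pipeline.
  Complete-voiding sessions are paired with the lower-capacity (hence
  lower-fill) conditions so the post-void empty period stays longer than
  the rolling-average span; at faster compressed refills the 15-frame
  average bridges the brief empty interval with a ghost image — an
  artifact impossible at real time scales, where the empty period lasts
  tens of seconds.
* **Flow consistency** is checked at real time scales on ground-truth
  traces (20 µl/min, two cycles, no rendering needed).

## Known limitations

* Thresholds (flow onset, NVC amplitude/duration, pressure floor) are
  config-exposed defaults chosen for the simulated regimes; real
  recordings may need adjustment, and every effective value is echoed
  into the run log for provenance.
* Onset timing from a smoothed flow trace carries an intrinsic delay of
  a fraction of the smoothing window when filling is fast relative to
  the void; at physiological fill rates the bias is small (≲0.3 s).
* The prolate assumption understates volume when the long axis points
  out of plane; this is a property of single-view volumetry itself.
* AVI input is out of scope; convert recordings to multi-page TIFF or a
  PNG sequence first (e.g. `ffmpeg -i rec.avi frames/f%06d.png`).
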