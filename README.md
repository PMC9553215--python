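# cystoflow

Fluoroscopic bladder volumetry and cystometry analysis for time-lapse
X-ray imaging of the lower urinary tract (LUT) in freely moving rodents.

In videocystometry and noninvasive fluoroscopic volumetry, a
contrast-filled bladder is imaged at video rate (nominally 30 frames/s)
while intravesical pressure is optionally recorded (nominally 50 Hz).
Because the animal moves, background subtraction is impossible; the
bladder must be delineated in every frame. `cystoflow` provides the full
analysis chain:

1. **Segmentation** — per-frame binary bladder masks from the image
   sequence (15-frame rolling average, dark-object thresholding,
   morphological closing and hole filling, largest-closed-object
   selection). A classical reference operator is built in; any external
   per-frame predictor with the same contract can be plugged in.
2. **Volumetry** — each mask is reduced to its equivalent ellipse
   (normalized second central moments) with long semi-axis *a* and short
   semi-axis *b* (mm), and volume follows the prolate-spheroid
   approximation

   V_ves = (4/3) π · a · b²   (mm³ = µl),

   with linear repair of brief (1–2 frame) segmentation failures.
3. **Signals** — Savitzky–Golay smoothing before differentiation; the
   urethral flow rate UFR = −dV_ves/dt (µl/s, positive during voiding);
   pressure resampled onto the image timebase; urethral flow conductance
   UFC = UFR / p_ves (µl·s⁻¹·cmH₂O⁻¹) where pressure exceeds a floor.
4. **Events** — void detection on the flow trace and per-void
   urodynamics: bladder capacity BC, residual volume RV, voiding
   efficiency E_voiding = 100·(BC−RV)/BC, void duration t20–80 (time for
   the volume to fall from 20% to 80% of the voided volume), UFR/UFC/p
   maxima, intercontractile interval (ICI), and nonvoiding-contraction
   (NVC) counts in the 80 s window preceding each void.
5. **Benchmarking** — Dice similarity index DISI = 2|X∩Y| / (|X|+|Y|)
   against ground-truth masks on a seeded 20% holdout.
6. **Simulator** — a synthetic fluoroscopy generator (filling/voiding
   dynamics, pressure with voiding and nonvoiding contractions, rendered
   prolate-spheroid bladder over a moving high-contrast background with
   sensor noise, plus exact ground-truth masks and event logs) so the
   entire pipeline is verifiable without animal data.

## Worked example

Simulate a short session (100 µl capacity, one voiding cycle with a 25%
residual), then analyze it end to end:

```sh
cystoflow simulate --out sim --seed 3 --config examples/session.yaml
cystoflow analyze --frames sim/frames.tif --pressure sim/pressure.csv --out run
cystoflow benchmark --pred run/masks.tif --truth sim/masks.tif --seed 0
```

with `examples/session.yaml` holding, e.g.:

```yaml
fill_rate: 400.0          # µl/min (compressed session)
capacity_threshold: 100.0
residual_fraction: 0.25
void_conductance: 2.0
initial_volume: 80.0
duration: 22.0
```

The `analyze` step prints `analyzed 661 frames: 2 voids -> run` (the
compressed fill rate refills the bladder fast enough for a second cycle),
and `run/voids.csv` contains the per-void table (values truncated here):

```
void_id,onset_s,end_s,BC_ul, RV_ul, voided_ul,efficiency_pct,t20_80_s,ufr_max_ul_s,ufc_max,p_max_cmH2O,ici_s,nvc_count
0,      3.5,  5.23, 100.089,25.029,75.060,   74.993,        0.676,   71.713,      1.825,  39.989,     ,     0
1,      16.8, 18.7, 99.743, 24.679,75.064,   75.257,        0.670,   72.719,      1.827,  40.000,     13.3, 0
```

read as: the first void started 3.5 s into the recording at a bladder
capacity of 100.1 µl, expelled 75.1 µl (75.0% efficiency; the simulated
truth is 75%), fell from 20% to 80% of the voided volume in 0.68 s, and
peaked at 71.7 µl/s flow, 1.82 µl·s⁻¹·cmH₂O⁻¹ conductance and
40.0 cmH₂O pressure; the second void followed 13.3 s later (ICI).
`run/trace.csv` holds the per-frame volume/flow/pressure/conductance
trace, and `run/run.log` echoes every effective parameter.  The final
`benchmark` step reports the mask agreement of this run:

```
Dice on 133 held-out frames: median 0.989, mean 0.987 ± 0.008
```

The same pipeline is available as a library (`cystoflow.analyze_sequence`,
`cystoflow.simulate`, …) for in-memory use.

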