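# sonoquant

Quantification pipeline for small-animal high-frequency ultrasound, with a
synthetic phantom generator so every estimator is validated against exact
ground truth — no image downloads required.

What it computes:

- **Vessel B-mode** (`sonoquant.vessel`): instantaneous diameter waveform from
  longitudinal cine loops by per-scanline wall-band detection with sub-pixel
  gradient-peak refinement, temporal continuity constraints, and beat
  segmentation (ECG-anchored or periodicity-based) with ensemble averaging.
- **PW-Doppler** (`sonoquant.doppler`): velocity envelope by per-column
  cumulative-power percentile (default 0.95) with median smoothing; PSV, EDV
  (pre-upstroke window minimum), cycle-mean MV; renal RI = (PSV−EDV)/PSV and
  PI = (PSV−EDV)/MV; transmitral E/A with fusion handling.
- **Hemodynamics** (`sonoquant.hemodynamics`): relative distension
  100·(Ds−Dd)/Dd; local pulse wave velocity from the diameter–velocity loop
  (V regressed on ln D over the reflection-free early-systolic limb,
  PWV = slope/2); pulse pressure by inverting the Bramwell–Hill relation
  (ρ = 1059 kg/m³); wall shear rate 4·Vmean/Dd.
- **Cardiac** (`sonoquant.cardiac`): LV mass/volumes (monoplane area–length,
  V = 8A²/(3πL)), SV/EF/FS/CO; speckle tracking by normalized
  cross-correlation block matching with sub-pixel refinement and frame-0
  drift control; 6-segment Lagrangian strain and strain rate with global
  peaks as the mean of segmental peaks.
- **Steatosis** (`sonoquant.steatosis`): liver/kidney mean gray-level ratio
  on a single B-mode image (rectangle or polygon ROIs).
- **Cohort** (`sonoquant.cohort`): per-animal biomarker table, median [IQR]
  group summaries, and two-sided Mann–Whitney comparisons (exact enumeration
  for small tie-free samples, Edgeworth-corrected normal approximation
  otherwise).
- **Phantoms** (`sonoquant.phantom`): deterministic speckle phantoms for all
  of the above — pulsating vessels, loop-coupled Doppler spectrograms,
  deforming LV loops with closed-form strain, parametric renal/mitral
  waveforms, liver/kidney textures, impulse-train ECG — plus a two-group
  cohort generator with planted effect directions.

## Pulse-pressure conventions

Inverting the Bramwell–Hill relation requires a *fractional distension*, and
whether that distension is a diameter strain or a cross-sectional-area strain
changes the answer by roughly a factor of two. Both readings are implemented
and the choice is explicit:

| convention        | formula (x = relD/100)      | at PWV 1.80 m/s, relD 20.77% |
|-------------------|-----------------------------|------------------------------|
| `literal`         | PWV²·ρ·x                    | 5.35 mmHg                    |
| `linearized_area` | PWV²·ρ·2x                   | 10.69 mmHg                   |
| `exact_area`      | PWV²·ρ·((1+x)²−1)           | 11.80 mmHg                   |

Published pulse-pressure medians from the model cohort this pipeline targets
are consistent with the area-based reading (≈10.6 mmHg) even where the
diameter-strain equation is printed; since the intended reading is not
stated, `literal` is the default and the flag
(`--pp-convention {literal,linearized_area,exact_area}`) must be chosen
deliberately. The acceptance suite asserts both computed values.

## CLI

```sh
# generate synthetic data (vessel | coupled | lv | renal | mitral | liver | cohort)
sonoquant phantom --kind coupled --seed 3 --out data/
sonoquant phantom --kind cohort --n-per-group 8 --seed 11 --out cohort/

# analyze single acquisitions
sonoquant vessel --cine data/vessel.tif --doppler data/doppler.tif \
    --pp-convention literal --out vascular.csv
sonoquant renal --spectrogram data/renal.tif --out renal.csv
sonoquant cardiac --contours lv.csv --hr 400 --out metrics.csv
sonoquant steatosis --image liver.tif --rois rois.json --out steatosis.csv

# full two-group pipeline: animals.csv, summary.csv (median [IQR]),
# comparison.csv (Mann-Whitney), manifest.json
sonoquant cohort --config cohort/cohort_config.json --out results/ --seed 11
```

Images travel as multi-frame TIFF with a JSON sidecar (pixel spacing, frame
rate, PRF, axes, view); traces/contours as CSV. All writers round-trip
through the package readers.

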