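# cine5d

Cardiorespiratory-resolved 3D cine cardiac MRI ("5D": x–y–z–cardiac phase–
respiratory phase) as a fully testable Python pipeline.

Free-breathing cardiac MRI usually collapses respiration: images are gated
to one respiratory position, or breathing is averaged away, hiding the
respirophasic changes in ventricular filling that matter in pulmonary
hypertension, constrictive pericarditis or congenital heart disease. This
package implements the alternative: acquire continuously for a couple of
minutes, measure the heart's absolute 3D displacement once per heartbeat,
cluster heartbeats into respiratory phases, and reconstruct a separate
cardiac cine for each phase, so ESV/EDV/SV/EF can be read out at
end-expiration and end-inspiration separately.

The chain, per heartbeat and phase:

- **CIRCUS sampling** — interleaved pseudo-random variable-density
  Cartesian undersampling of the ky–kz plane on concentric square rings
  (spiral parameter c = 1.5, 75 % partial Fourier per axis); any contiguous
  acquisition window is a valid undersampling pattern.
- **Per-beat imaging** — lines sorted by ECG triggers; each beat
  reconstructed at ~4×4×4 mm from the central k-space band (per-beat
  acceleration R ≈ 17 at protocol parameters).
- **3D motion tracking** — deformable registration of each beat volume to
  a reference beat; the field averaged over a central 1/4-FOV box gives
  the heart's displacement (dx, dy, dz) in mm. Positive x = heart moves up
  = towards end-expiration.
- **Respiratory binning** — k-means (k = 4, 10 restarts) on the 3-vectors;
  extreme x centroids are end-expiration (EE) and end-inspiration (EI);
  respiratory depth Δd = ‖c_EE − c_EI‖₂.
- **k-t SPARSE-SENSE** — per respiratory phase, solve
  argmin_x ½‖Ex − y‖² + λ_t·TV_cardiac(x), with multicoil SENSE encoding E
  and cyclic temporal total variation, by a monotone proximal-gradient
  iteration.
- **Function analysis** — Hough-initialised, elliptically refined level-set
  segmentation of LV and RV; EF = (EDV − ESV)/EDV × 100 per ventricle and
  respiratory phase, plus respiration metrics (rate, Δd, data portions,
  EE:EI ratio, per-phase heart rate) and paired statistics.

Everything is validated against a built-in digital cardiorespiratory
phantom: a beating two-ventricle heart with analytic cavity volumes,
quasi-periodic asymmetric breathing, respiratory sinus arrhythmia (heart
slowest at end-expiration), optional thoracoabdominal asynchrony, and
multi-coil k-space simulation checked line-by-line against a brute-force
DFT. No external data are required anywhere.

## Worked example

```python
import numpy as np
from cine5d import run_supplement_b, run_end_to_end

# Tracking accuracy: 1 mm phantom, 4 mm tracking, small and large motion
print(run_supplement_b(n_beats=30, seed=0))
```

```
{'depth_mm': [4.0, 16.0],
 'rmse_mm': [0.77, 0.80],
 'correlation': [0.9994, 0.9998]}
```

Per-beat displacement is recovered to 0.8 mm RMSE for both ±2 mm and
±8 mm motion — well under half a tracking voxel, which is what
makes k-means binning on the trace reliable.

```python
r = run_end_to_end(seed=1, duration_s=60.0)   # ~4 min on one CPU
m = r.report.measurements
print(m["LV"]["EE"]["EF_pct"], r.truth["lv_ef_pct"])
print(r.report.resp_metrics["Heart Rate (bpm)"])
print(r.report.resp_metrics["Data Portion (%)"])
```

```
54.8 53.63
{'EE': 57.8, 'mid-expiration': 61.2, 'mid-inspiration': 60.5, 'EI': 60.9}
{'EE': 44.1, 'mid-expiration': 18.6, 'mid-inspiration': 8.5, 'EI': 28.8}
```

From 60 seconds of simulated free-breathing acquisition the full chain
(simulate → gate → track → bin → reconstruct → segment) returns the LV
ejection fraction of the end-expiration cine within ~1 point of the
phantom's analytic 53.6 %; the per-phase heart rates show the built-in
respiratory sinus arrhythmia (slowest at EE), and end-expiration holds the
largest share of heartbeats, as expected for an asymmetric breathing
waveform.

## Command line

```bash
cine5d simulate --out run/ --seed 1 --duration-s 60   # k-space bundle + logs
cine5d gate run/                                      # beats, volumes, 1D trace
cine5d track run/                                     # 3D motion trace (CSV)
cine5d bin run/ --seed 1                              # clusters + metrics JSON
cine5d e2e --out run/ --seed 1                        # full pipeline + report
cine5d bench-a                                        # 1D vs 3D binning study
cine5d bench-b                                        # tracking accuracy study
```

Outputs are plain CSV/JSON plus NIfTI volumes with voxel spacing in the
header.

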