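# echogate

Ultrasound-guided respiratory motion tracking and gating for 4D PET, at desk
scale.

Respiratory motion smears small lesions over several centimetres in PET
images of the abdomen. Diagnostic ultrasound (US) can watch the moving
anatomy directly — without dose and in real time — but to be useful for a
scanner or a treatment room the tracked image coordinates must be expressed
in absolute room coordinates, even when the probe itself rides on the
breathing patient. `echogate` implements that whole workflow for
physicists building or validating such a system:

* **Rigid transform chain.** A pixel `p_US` of the image plane maps to the
  room ("world") frame through
  `p_W = T_{S→W} · T_{T→S} · T_{US→T} · p_US`, where `T_{T→S}` is the
  streamed optical pose of the marker tool on the probe, `T_{US→T}` (rigid
  pose + isotropic mm/px scale) and `T_{S→W}` come from calibration.
* **Freehand calibration.** A multi-cross wire phantom (29 wires between
  plates 80 mm apart) is imaged from 64 diverse probe poses; every bright
  wire cross-section constrains the chain. The 13 unknown parameters are
  solved by Levenberg–Marquardt on point-to-wire residuals in world space,
  with accuracy / precision evaluation protocols. The sensor-to-room block
  can also be fixed from a table-position calibration (closed-form absolute
  orientation).
* **Condensation contour tracking.** A contour snapped to the target's
  brightness edge is propagated by a particle filter over the 5-parameter
  similarity state (translation x/y, rotation, scale x/y); the axial
  displacement column is the respiration signal.
* **Respiratory gating.** Inhale peaks (Gaussian-refined), clock-offset
  estimation between acquisition computers, gate-tag replacement in the
  list-mode stream, phase sorting into equal per-cycle time bins,
  per-phase reconstruction, axial registration to the first phase after the
  inhale peak, averaging, and FWHM quantification of the axial profile
  (`FWHM = 2√(2 ln 2) σ` from a 1D Gaussian fit at the transverse maximum).
* **Simulators** for every input: Lujan-type trajectories
  (`z(t) = A cos⁴(πt/T)`, sinusoids, recorded tables), Poisson list-mode
  events smeared by the scanner point-spread function (5.2 mm FWHM static
  resolution), surrogate belt signals, optical pose streams at 10 Hz,
  speckled ball-in-water-tank US frames, and labeled wire-phantom
  calibration sessions.

## Worked example

Gate a simulated point-source acquisition (cos⁴ motion, 30 mm peak-to-peak,
4 s period, 600 s at 1000 events/s):

```python
from echogate import (MotionTrajectory, SimConfig, simulate_listmode,
                      simulate_surrogate, gated_fwhm_pipeline)

traj = MotionTrajectory(kind="cos4", amplitude_mm=30.0, period_ms=4000.0)
lm = simulate_listmode(traj, SimConfig(event_rate_hz=1000.0, psf_fwhm_mm=5.2,
                                       duration_ms=600_000.0, seed=11))
sig = simulate_surrogate(traj, sample_rate_hz=25.0, duration_ms=600_000.0,
                         noise_sd=1.5, seed=12)
fit, report = gated_fwhm_pipeline(lm, sig, n_phases=8)
print(f"gated FWHM  {fit.fwhm_mm:.2f} mm")
print(f"ungated FWHM {report['ungated_fwhm_mm']:.2f} mm "
      f"(extent at 10% max {report['ungated_extent_10pct_mm']:.1f} mm)")
```

prints

```
gated FWHM  7.88 mm
ungated FWHM 31.29 mm (extent at 10% max 37.6 mm)
```

Without gating the point source is smeared over the full 30 mm motion
amplitude; 8-phase gating recovers a near-Gaussian profile close to the
static 5.2 mm resolution, widened only by the residual motion inside each
phase. The same pipeline is exposed on the command line
(`echogate simulate | calibrate | track | gate | report`), each subcommand
writing its artifacts plus a `metrics.json` with a provenance block.

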