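# vitalmag

Video magnification for revealing sub-pixel breathing motion — a toolkit
for detecting vital signs in video of people who cannot be approached
(disaster scenes, hazardous environments), using nothing but an ordinary
stable camera.

An adult breathes 12–18 times per minute (0.2–0.3 Hz).  The chest motion
this produces in a video shot from several meters away is a small fraction
of a pixel — invisible to the eye, but present in the data.  `vitalmag`
implements the two classic Eulerian approaches to make it visible:

- **ELVM** (Eulerian Linear Video Magnification).  Each frame is
  decomposed into a Laplacian pyramid; the per-pixel time series of every
  band is bandpass-filtered (Butterworth, zero-phase) to isolate the
  breathing band; the filtered signal is scaled by a magnification factor
  α and added back.  For a scene translating by δ(t), to first order
  `I(x,t) = f(x + δ(t)) ≈ f(x) + δ(t) f'(x)`, so the synthesized video
  moves by `(1+α) δ(t)`.  The linearization holds only while
  `(1+α) δ ≤ λ/8` for a band of wavelength λ, which caps how far an
  intensity method can push — and its noise grows linearly with α.

- **PBVM** (Phase-Based Video Magnification).  Each frame is decomposed
  into a complex steerable pyramid whose oriented bands are analytic
  signals `S_ω = A_ω e^{iω(x+δ(t))}`.  By the Fourier shift theorem,
  translation lives in the local phase.  Phase differences against frame 0
  are bandpass-filtered to get `B_ω ≈ ω δ(t)`, then each coefficient is
  rotated by `e^{iαB_ω}` — amplitudes untouched — and the frames are
  reconstructed.  Phase magnification tolerates much larger α (up to
  `α δ < π/(2ω)` per band for the 4-orientation pyramid, double that for
  the 8-orientation variant) at a higher computational cost.

Quality is compared with `PSNR = 10 log10(255² / MSE)`, the MSE averaged
over the R, G, B channels.  A synthetic scene generator renders
ground-truthed sub-pixel breathing motion analytically (no interpolation),
and a phase-correlation displacement oracle measures the motion a pipeline
actually produced, independently of the pipeline itself.

## Worked example

```python
from vitalmag import (SceneSpec, generate_breathing_video, magnify_phase,
                      PbvmConfig, measure_displacement,
                      fit_sinusoid_amplitude, quality_report,
                      estimate_breath_rate)

# 96x96 px, 10 fps, 60 s: a blob translating 0.05 px at 0.25 Hz (15 bpm)
spec = SceneSpec()
video, truth = generate_breathing_video(spec)

out = magnify_phase(video, PbvmConfig(alpha=30.0, scales=4))

trace_in, trace_out = measure_displacement(video), measure_displacement(out)
print(fit_sinusoid_amplitude(trace_in, spec.freq))   # 0.0505  (px, invisible)
print(fit_sinusoid_amplitude(trace_out, spec.freq))  # 1.2209  (px, visible)
report = quality_report(video, out)
print(report.mse, report.psnr)                       # 1.229  47.23 dB
print(estimate_breath_rate(trace_out))               # 15.0 breaths/min (0.250 Hz)
```

The measured input motion matches the generator's ground truth (0.05 px);
after phase magnification at α=30 the same scene moves ~1.2 px — the
0.84 × (1+α) realized gain reflects the Butterworth passband and the
finite pyramid depth — and the breathing rate reads straight off the
magnified displacement trace.

## Command line

```bash
vitalmag synth --spec scene.json -o scene/            # render a test scene
vitalmag magnify --method pbvm --alpha 30 --fl 0.2 --fh 0.3 \
    --levels 4 -i scene/ -o magnified/
vitalmag evaluate --original scene/ --magnified magnified/   # MSE/PSNR JSON
vitalmag trace -i magnified/ --x 48 --y 48 --channel gray --breath-rate
```

Videos are exchanged as lossless PNG frame sequences with an `fps.json`
sidecar (bit-exact round trips); MP4/AVI containers work when an
ffmpeg-capable imageio plugin is installed.

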