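# caspike

Detection and quantification of nuclear Ca²⁺ spikes in plant-root
fluorescence recordings.

Growing *Arabidopsis* root meristems produce brief nuclear-localised Ca²⁺
transients — single asymmetric spikes of roughly 40 s, released first in
the nucleus and only then spreading to the cytosol — whose frequency and
shape track meristem activity and primary-root growth. `caspike` is a
tested, reusable implementation of the analysis such experiments need:
per-cell spike-shape quantification, nuclear-vs-cytosolic origin
classification from a dual-localised sensor, and cohort-level statistics,
together with a seeded simulator that produces realistic recordings with
exact ground truth for validation. It is aimed at plant cell biologists
and imaging analysts working with GECO/GCaMP-type indicator time series
sampled every 2–3 s over ~1–1.5 h.

## The method

For each cell and channel, raw fluorescence F(t) is normalised to
ΔF/F = (F − F₀)/F₀ with F₀ the mean of the first 20 baseline frames, then
detrended by subtracting an ordinary-least-squares cubic polynomial in
time. A spike is located at the maximum of the detrended signal; its
onset and offset are the first points before and after the peak at which
both the detrended signal and the magnitude of its gradient fall below
thresholds expressed as multiples of a robust per-trace noise scale
(1.4826 × median absolute deviation). The shape statistics are

    rise = t_peak − t_on,   fall = t_off − t_peak,   duration = rise + fall,

with the amplitude taken as the detrended ΔF/F value at the peak.
Detection operates on a Savitzky–Golay-smoothed copy of the detrended
signal and refines the scan boundaries by limb-line extrapolation (exact
for piecewise-linear transients); `docs/methods.md` details the estimator
and its calibration. Signal origin is classified per cell from the onset
lag t_on(cytosolic) − t_on(nuclear); cohort summaries cover responder
fractions, spike rates per plant-hour within a 200 µm meristem window,
meristem/elongation partitions, shape means and the growth-rate
regression.

## Worked example

Simulate one recording with a known injected spike and detect it:

```python
from caspike import SimulationConfig, SpikeSpec, simulate_trace, detect_spikes

cfg = SimulationConfig(seed=7)          # 2 s frames, 5400 s, SNR 5, cubic drift
trace, truth = simulate_trace(
    cfg, [SpikeSpec(t_on=1000.0, rise_s=15.0, fall_s=24.0, amplitude_dff=0.5)]
)
for rec in detect_spikes(trace):
    c = rec.call
    print(f"onset {c.t_on:7.1f} s   peak {c.t_peak:7.1f} s   offset {c.t_off:7.1f} s")
    print(f"rise  {c.rise_s:5.1f} s   fall {c.fall_s:5.1f} s   "
          f"duration {c.duration_s:5.1f} s   amplitude {c.amplitude_dff:.2f} dF/F")
```

prints

    onset  1001.5 s   peak  1014.9 s   offset  1040.0 s
    rise   13.4 s   fall  25.1 s   duration  38.5 s   amplitude 0.45 dF/F

The injected spike ran from 1000 s to 1039 s with a 15 s rise and 24 s
fall; at a peak signal-to-noise ratio of five and 2 s sampling the
boundaries are recovered to within about a frame and the shape statistics
to within ~2 s, with the amplitude slightly attenuated by noise at the
peak frame.

The same pipeline is available from the shell:

    caspike simulate --out-dir run/ --seed 7
    caspike detect    --in run/traces.csv --out run/spikes.csv
    caspike origin    --spikes run/spikes.csv --out run/origin.csv --tolerance 2
    caspike summarize --spikes run/spikes.csv --traces run/traces.csv \
                      --meta run/plants.csv --out run/summary.csv

`caspike roi-extract` additionally turns a multi-page grayscale TIFF plus
an ROI table into the trace CSV the pipeline consumes.

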