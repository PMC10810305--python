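# myoexo

Proportional myoelectric ankle-exoskeleton control and gait adaptation
analysis on synthetic walking data.

Portable ankle exoskeletons under proportional myoelectric control scale
their assistance continuously with the user's own soleus activity: the
surface EMG is high-pass filtered (2nd-order Butterworth, 50 Hz),
full-wave rectified and low-pass filtered (2nd-order Butterworth, 8 Hz);
the resulting envelope *e(t)* commands a motor current

    i(t) = clip(g · e(t), 0, i_max),    i_max = 7.6 A (q-axis)

with a subject-specific static gain *g* set during unpowered walking and a
deadband that keeps the device transparent during swing. A transmission
ratio *r* (Nm/A, constant or a function of the device's ankle angle) turns
current into a plantarflexion-only torque τ(t) = r·i(t).

The scientific questions around such a device are: does the user's
triceps surae activity down-regulate as they adapt to the assistance, and
how much of the ankle's mechanical output does the device actually
provide? `myoexo` implements the full measurement chain for both — stride
segmentation from vertical GRF, 101-point gait-cycle normalization,
EMG normalization to the Boots-Only condition, stance/swing RMS, percent
change and standardized mean difference, the ankle decomposition
(biological moment = total − exoskeleton; shares of peak moment, peak
power and positive work), one-way ANOVA with Tukey post-hocs, and 1-D
statistical parametric mapping with permutation family-wise control —
driven by a synthetic multi-subject gait/EMG generator that emulates the
session protocol (Boots Only → Unpowered → Powered → Deadaptation, 50
minutes of walking) with known ground truth, so every stage is verifiable
without human data. Real recordings can enter through CSV trial files
with the same schema.

It is intended for researchers in rehabilitation robotics and
neuromechanics who want a tested, reproducible reference implementation
of this controller/analysis stack, or a calibrated synthetic testbed for
developing new ones.

## Worked example

Run the default study conditions — 12 synthetic subjects, 50 minutes of
walking each, adaptation effects of −12% (soleus), −5% (medial
gastrocnemius), −17% (lateral gastrocnemius) and +9% (tibialis anterior):

```python
from myoexo import GeneratorConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(generator=GeneratorConfig(seed=1))
report = run_pipeline(cfg)

g = report["group"]
for m in ("sol", "mg", "lg", "ta"):
    print(f"{m:3s} RMS change BootsOnly -> PoweredEnd: "
          f"{g['percent_change'][m]['mean']:+6.1f}%")
dec = g["decomposition"]["PoweredEnd"]
print(f"exo share of peak ankle power : {dec['peak_power_share']:.3f}")
print(f"exo share of peak ankle moment: {dec['peak_moment_share']:.3f}")
print(f"exo share of positive work    : {dec['positive_work_share']:.3f}")
print(f"exo peak power                : {dec['peak_exo_power_w_per_kg']:.2f} W/kg")
```

prints (about 25 s on one CPU):

```
sol RMS change BootsOnly -> PoweredEnd:  -12.3%
mg  RMS change BootsOnly -> PoweredEnd:   -6.3%
lg  RMS change BootsOnly -> PoweredEnd:  -15.3%
ta  RMS change BootsOnly -> PoweredEnd:   +9.1%
exo share of peak ankle power : 0.284
exo share of peak ankle moment: 0.168
exo share of positive work    : 0.353
exo peak power                : 0.63 W/kg
```

The measured percent changes recover the generator's configured
adaptation to within ±3 percentage points, and the device's contribution
shares match the noise-free model-implied values
(`myoexo.nominal_decomposition`) to within ±0.03 — the device supplies
roughly 28% of peak ankle power, 17% of peak ankle moment and a third of
the positive ankle work at a peak of ~0.63 W/kg, while commanded torque
stays within [0, 7.6 A]·r and is exactly zero during swing.

The same pipeline is available from the shell:

```bash
myoexo run --seed 1 --out report.json        # full pipeline
myoexo simulate --out data/                  # trial CSVs + sidecars
myoexo control --input data/S00_Powered.csv \
       --calibrate-from data/S00_Unpowered.csv --out control.csv
myoexo stats --input rms.csv --out stats.json
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

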