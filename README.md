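# swimresp

Analysis pipeline for swim-tunnel respirometry with simultaneous cardiac
recordings: the kind of experiment in which a fish, instrumented with a
ventral-aortic flow probe, swims in a Blazka-type tunnel through stepwise
velocity increments to exhaustion while water oxygen and blood flow are
recorded.  The package is written for comparative ecophysiologists who need
to turn those raw traces into the standard cardiorespiratory traits — and for
anyone who wants to validate such a pipeline without access to raw traces,
via the bundled synthetic-trial generator with known ground truth.

## What it computes

**Oxygen consumption.** During each closed (intermittent) respirometry phase,
water PO2 (% air saturation) declines linearly; after a 2-min wait period an
ordinary least-squares slope gives

    MO2 = |slope| / 100 · β(T, S) · V_eff / M        [mg O2 kg⁻¹ h⁻¹]

with β the oxygen solubility at 100% air saturation (García–Gordon fit of the
Benson–Krause data), V_eff the tunnel volume minus fish volume, and M body
mass.  Fits with r² < 0.80 are flagged, never dropped; background (microbial)
respiration is subtracted only when it reaches 1% of the fish's rate.

**Critical swim speed.** With velocity increments Vi every ti,

    Ucrit = V + tf · Vi / ti,

prorating the partially completed final step, then corrected for the solid
blocking effect of the fish in the flume:

    Ucrit,corr = Ucrit · (1 + ε),   ε = τ λ (A0/AT)^1.5,

with A0 = 0.25 G²/π from the maximum girth G and AT = π r² the tunnel
cross-section (τ = 0.8, λ = 0.5 for a streamlined fish).

**Metabolic traits.** SMR by back-extrapolating log10(MO2) on swim speed to
zero speed; RMR from the 0.08 bL s⁻¹ baseline; MMR as the maximum per-step
MO2; absolute and factorial aerobic scopes AAS = MMR − SMR, FAS = MMR/SMR and
their "realistic" variants using RMR.

**Cardiac traits.** Heart rate by counting systolic peaks in two 30-s windows
of the closed phase (adaptive threshold plus refractory period); cardiac
output Q̇ as the time-averaged flow per kg; stroke volume VS = Q̇/fH; tissue
oxygen extraction MO2/Q̇ with the explicit per-hour/per-minute factor of 60;
relative ventricular mass RVM = ventricle/body mass × 100; thermal
sensitivity Q10 = (R2/R1)^(10/(T2−T1)).

**Group statistics.** Welch's two-sample t between temperature groups, paired
t for rest vs 2-h recovery, Grubbs and Rosner (generalized ESD) outlier
screens, and mean ± SEM tables with significance letters.

## Worked example

```python
import swimresp as sr

# a synthetic 22 °C trial with known ground truth, noise switched off
import dataclasses
truth = dataclasses.replace(sr.default_truth(22.0), ucrit_true=0.725,
                            noise_sd_po2=0.0, noise_sd_flow=0.0)
fish = sr.generate_fish(seed=1)
trial = sr.simulate_trial(truth, fish, seed=3)
s = sr.summarize_traits(trial)
print(f"SMR {s.smr:.2f}  MMR {s.mmr:.2f}  Ucrit {s.ucrit_raw:.3f} "
      f"(corrected {s.ucrit_corrected:.3f})  fH max {s.fh_max:.0f}")
```

prints

```
SMR 44.08  MMR 244.33  Ucrit 0.725 (corrected 0.741)  fH max 62
```

i.e. the pipeline recovers the generator's standard metabolic rate
(44.08 mg O2 kg⁻¹ h⁻¹) and Ucrit (0.725 bL s⁻¹) exactly; MMR is the model
MO2 at Ucrit; the blocking correction for this fish's girth adds ~2.2%; and
maximum heart rate lands within the ±2 beats min⁻¹ quantization of 30-s peak
counting (truth 62.4).

The same workflow from a shell:

```bash
swimresp simulate --n-fish 9 --temp 22 --seed 7 --out trials/
swimresp simulate --n-fish 9 --temp 30 --seed 8 --out trials/
swimresp analyze --trials trials/ --out analysis/
swimresp report --analysis analysis/ --format md
```

which writes per-fish trait tables plus group and recovery tables
(mean ± SEM, Welch letters, paired-t annotations).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults and
units, what the synthetic generator does and does not emulate, numerical
conventions, and known limitations.
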