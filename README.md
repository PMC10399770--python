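# cavesong

Automated analysis of click sounds produced by blind Mexican cavefish
(*Astyanax mexicanus*) in hydrophone recordings, and of the population-level
"accents" those sounds carry.

Cavefish from different caves produce Single Clicks (short broadband pulses,
≈2 kHz dominant frequency, ≈5 ms) and Serial Clicks (trains of ≈8 pulses at
≈15 ms intervals). Whether each cave population carries a distinctive
multivariate acoustic signature is a question about both *signal
measurement* (can clicks be found and parameterized reliably in noisy cave
recordings?) and *statistics* (do the parameter distributions separate the
populations?). `cavesong` implements the full workflow:

1. **Detection** — a reference-signal matched filter. One click `s`, chosen
   by ear, is slid across the recording `x`; at every lag `i` the detector
   computes the zero-mean, energy-normalized correlation

   r(i) = Σₖ (x[i+k] − x̄ᵢ)(s[k] − s̄) / (‖x ᵢ− x̄ᵢ‖‖s − s̄‖),

   and correlation maxima above a threshold mark candidate click onsets.
   The threshold is *supervised*: on an annotated segment the sweep over all
   achievable operating points returns the threshold at which ≥ 95% of the
   reported signals are true (precision ≥ 0.95; a recall criterion is also
   available).
2. **Segmentation** — pulses are delimited on the noise-floor-corrected
   amplitude envelope (analytic-signal magnitude in the 500–10,000 Hz band)
   at −20 dB of the local peak, then grouped: an isolated (> 1 s) pulse
   shorter than 20 ms is a Single Click; pulses with close onsets form a
   Serial Click.
3. **Features** — duration (ms), dominant frequency (Hz) and SNR for Single
   Clicks; pulse number, mean pulse duration, mean interpulse duration,
   pulse rate and total duration for Serial Clicks.
4. **Signatures** — Kolmogorov–Smirnov (Lilliefors) and Bartlett assumption
   checks; Kruskal–Wallis tests with Dunn's post hoc z-tests; PCA acoustic
   space with 95% confidence ellipses; permuted discriminant function
   analysis (pDFA: leave-one-out LDA reclassification whose p-value comes
   from a label-permutation null); and hierarchical clustering of per-cave
   acoustic medians, projectable onto cave coordinates.

Field audio of this kind is not publicly deposited, so the package ships a
first-class synthetic-soundscape generator (`cavesong.synthgen`) that
renders clicks and click trains with exact ground truth in white or pink
noise at controllable signal-to-noise ratio; every stage of the pipeline is
validated against it.

## Worked example

Two synthetic "caves" whose clicks differ in dominant frequency
(1900 vs 2100 Hz, within-cave SD 0 here), each analyzed exactly like a field
recording — template chosen from the recording, threshold tuned on the
annotated segment, events segmented, features extracted — then compared:

```python
import numpy as np
import pandas as pd
import cavesong as cs
from cavesong.detection import ClickTemplate, tune_threshold, score_detections
from cavesong.segmentation import segment_recording
from cavesong.features import FeatureTable, build_feature_table
from cavesong.signatures import acoustic_space, compare_groups, pdfa

frames = []
for cave, freq, seed in [("Pachon", 1900.0, 1), ("Tinaja", 2100.0, 2)]:
    rec, truth = cs.random_soundscape(
        n_singles=40, duration=90.0,
        click=cs.ClickSpec(dominant_freq=freq, amplitude=0.5),
        noise_model="pink", noise_rms=0.1, seed=seed, min_gap=1.6, label=cave)
    template = ClickTemplate.from_recording(rec, truth.entries[0].time, 0.005)
    detector = tune_threshold(rec, template, truth, target=0.95)
    m = score_detections(detector.detect(rec), truth)
    print(f"{cave}: threshold {detector.threshold:.3f}, "
          f"precision {m.precision:.3f}, recall {m.recall:.3f}")
    events = segment_recording(rec, detector.detect(rec))
    frames.append(build_feature_table(events, rec, cave, "single").df)

table = FeatureTable(df=pd.concat(frames, ignore_index=True),
                     event_type="single",
                     feature_names=["duration_ms", "dominant_frequency_hz", "snr"])
print(table.df.groupby("group")[table.feature_names].mean().round(2))

cmp = compare_groups(table, "dominant_frequency_hz")
print(f"Kruskal-Wallis H = {cmp.h_statistic:.1f}, p = {cmp.p_value:.3g}")

space = acoustic_space(table, n_axes=2)
res = pdfa(space.coordinates(), table.df["group"].to_numpy(),
           n_permutations=999, seed=0)
print(res.summary())
```

Output:

```
Pachon: threshold 0.515, precision 0.952, recall 1.000
Tinaja: threshold 0.503, precision 0.952, recall 1.000
        duration_ms  dominant_frequency_hz   snr
group
Pachon         5.53                1899.50  3.94
Tinaja         5.52                2100.32  3.77
Kruskal-Wallis H = 60.8, p = 6.36e-15
Permuted discriminant function analysis
  overall reclassification: 100.0%
  Pachon: 100.0%
  Tinaja: 100.0%
  p = 0.001 (999 permutations, null mean 46.4%)
```

The tuned detectors each report ≥ 95% true signals and miss none; the
recovered dominant frequencies sit within a few tenths of a hertz of their
cave's generating mean; the rank test separates the caves decisively; and
the pDFA reclassifies every click to its cave, far above the ≈46% chance
level of its permutation null (p = 0.001, the smallest value 999
permutations can resolve).

## Command line

The same pipeline is scriptable via the `cavesong` command:

```bash
cavesong synth --spec spec.json --out rec.wav --truth truth.csv
cavesong detect rec.wav --template tmpl.wav --tune truth.csv --out dets.csv
cavesong validate dets.csv truth.csv --tol 0.01
cavesong segment rec.wav dets.csv --out events.json
cavesong features events.json --rec rec.wav --group Pachon --out features.csv
cavesong signatures features.csv --coords coords.csv --nperm 1000 --seed 7 --out report/
```

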