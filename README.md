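# endostress

Objective stress measurement from autonomic biosignals recorded during
colonoscopy — and a fully synthetic test bed for it.

Music is a cheap, safe intervention against procedural anxiety, but most
evidence for it is questionnaire-based. A stress level can instead be read
directly off the autonomic nervous system: facial electromyography (fEMG)
over the *corrugator supercilii* and *zygomaticus major*, the ECG, skin
conductance level (SCL), and fingertip skin temperature (TMP), recorded at
2,048 Hz throughout the procedure. `endostress` implements that analysis as
a reusable, tested pipeline:

1. **Conditioning** — decimation to 512 Hz; fEMG: Butterworth 20–250 Hz
   band-pass → Hilbert magnitude |x + iH(x)| → 4 Hz low-pass (a slow
   amplitude envelope in µV); SCL: 8 Hz low-pass; ECG: n = 67 moving
   average + linear detrend; TMP: n = 513 moving average. All filters are
   order-4 zero-phase (forward–backward).
2. **Cardiac** — Hamilton–Tompkins R-peak detection (QRS-band energy,
   adaptive signal/noise thresholds, 200 ms refractory, search-back) and
   heart rate in beats/min per window.
3. **Windowing** — three event-anchored 60 s windows per session: the
   first minute of the examination, ±30 s around reaching the cecum, and
   the last minute; automated artifact screening
   (keep / correct / discard) with explicit criteria.
4. **Features** — the mean of each conditioned window (µV, µS, °C) plus
   BPM, assembled into a long-format cohort table.
5. **Group statistics** — per (channel, anchor, stratum) cell: group
   means, SDs, Ns and a one-sided Mann–Whitney U test
   (H₁: the music arm is lower on the stress markers, declared a priori),
   significance at p ≤ 0.05; Pearson χ², Fisher's exact and t tests for
   cohort characteristics.
6. **Simulation** — because the patient recordings are not publicly
   deposited, a synthetic-session generator reproduces the statistical
   structure the analysis assumes (amplitude-modulated band-limited fEMG
   noise, template ECG with RR jitter, tonic+phasic SCL, drifting TMP,
   event marks, saturation artifacts) *with ground truth attached*, so
   every stage is testable against a known answer.

## Worked example

Simulate a cohort at the study's group sizes with a 40 % music-arm
reduction of the fEMG envelope means, run the full pipeline, and read off
the headline cell (about a minute of single-core compute for 149 ten-minute
sessions at 2,048 Hz — the cohort streams, so memory stays flat):

```python
from endostress import (CohortSpec, SessionSpec, EventMarks,
                        iter_cohort, run_pipeline)

base = SessionSpec(duration_s=600.0, fs=2048.0,
                   anchors=EventMarks(60.0, 540.0, cecum=300.0))
cohort = CohortSpec(n_control=65, n_music=84, base=base,
                    music_femg_scale=0.6, seed=42)
features, comparison, qc = run_pipeline(iter_cohort(cohort))
cell = comparison.query("channel == 'femg_zygomaticus' and anchor == 'start'"
                        " and stratum == 'all'").iloc[0]
print(f"zygomaticus @ start: control {cell.mean_control:.2f} uV (n={cell.n_control}), "
      f"music {cell.mean_music:.2f} uV (n={cell.n_music}), one-sided p = {cell.p_one_sided:.4f}")
```

```
zygomaticus @ start: control 7.02 uV (n=65), music 6.06 uV (n=82), one-sided p = 0.0497
```

The control arm sits near the generator's 7.70 µV start-anchor envelope
mean. The music arm's *parameter* is 0.6 × that (4.62 µV), but its observed
mean is higher: per-patient envelope means are drawn from a zero-truncated
normal with the study's large between-patient SD (5.56 µV), which biases
the low-mean arm upward — so the realised group contrast is weaker than
the nominal scale and the one-sided U test lands just under the 0.05 line
at these group sizes. Two music-arm windows were trimmed by the automated
artifact screening (n = 82 < 84), mirroring the per-cell N attrition in
real cohorts. With `music_femg_scale=1.0` the same cell's p-value is
uniform on [0, 1].

A command-line interface wraps the same pipeline:

```bash
endostress simulate --n-control 10 --n-music 10 --music-scale 0.6 --out sessions/
endostress process --in sessions/ --out results/
endostress calibrate --replicates 200 --n-per-group 30
```

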