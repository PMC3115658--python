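# cracklekit

Multichannel lung-sound **crackle** analysis: simulation, detection,
waveform feature extraction, crackle-family transmission analysis, and
disease classification by hierarchical majority voting.

Crackles — short explosive transients superimposed on the breath sound —
are a hallmark of interstitial pulmonary fibrosis (IPF), but at the bedside
they are easily mistaken for the crackles of congestive heart failure (CHF)
or pneumonia (PN), with real therapeutic consequences.  Recorded over the
chest with a multichannel microphone array, however, the three diseases
differ systematically: IPF crackles are numerous, high-pitched, short, and
heard on essentially one microphone at a time; CHF crackles are lower
pitched, accentuated toward the lung bases, and transmit widely across the
ipsilateral chest; PN crackles resemble CHF's but cluster in one focal
region.  `cracklekit` implements this analysis end to end for researchers
in computational lung-sound analysis — and, because no public multichannel
crackle datasets exist, ships a fully annotated synthetic-recording
generator so every stage is testable.

## The method

**Per-crackle features** (from the waveform around the highest peak).  The
waveform is decomposed at its baseline crossings into half-periods
T₁, T₂, …, Tₙ with amplitudes A₁, A₂, …, Aₙ (T₁ carries the highest peak;
enumeration stops below 10 % of the peak amplitude):

- pitch = 2 / (T₁+T₂+T₃+T₄)  (≈ 2000/ΣT for T in ms)
- ZXS = number of baseline crossings (= n + 1)
- T₂/T₁, A₂/A₁, A₃/A₁, amplitude, polarity (sign of the highest peak)
- duration and amplitude variability = SD/mean × 100 %
- timing code 1–6 (early/mid/late third of inspiration or expiration)

**Crackle transmission coefficient (CTC).**  Simultaneous detections of one
event on the N ipsilateral microphones form a *crackle family* whose
largest-amplitude member is the *mother crackle*:

    CTC = 100/(N−1) · Σ_children min(A_child / A_mother, 1)   [%]

0 % when no other channel hears the event, 100 % at equal transmission
everywhere.  Sources are localized inside the chest by least squares on
arrival-time differences (delay = distance / sound speed).

**Aggregate features per breath**: crackle count, counts per chest
quadrant, the 6 pairwise quadrant percentage differences, and maximum
inter-crackle distances (x, y, z, overall; on sources and on microphones).

**Classification.**  Per-crackle features feed an RBF-kernel SVM or a
16-unit backpropagation network; held-out crackle labels are majority-voted
into breath labels, and breath labels into the patient label, under
five-fold cross-validation split at the patient level.  Sensitivity,
specificity and accuracy are reported with IPF as the positive class for
the two tasks IPF-vs-CHF and IPF-vs-PN.

## Worked example

```python
import cracklekit as ck
from cracklekit.pipeline import analyze_recording

profile = ck.builtin_profile("CHF")          # basal pattern, CTC ~23%
geometry = ck.default_geometry()             # 16 channels, 14 posterior
signal, truth = ck.synthesize_recording(profile, geometry, seed=2)

result = analyze_recording(signal, 8000, geometry,
                           breath_boundaries=truth.breath_boundaries())
ck_df = result.crackles                       # one row per crackle family
print(f"{len(ck_df)} crackles in {len(result.breaths)} breaths")
print(f"median pitch {ck_df.pitch.median():.0f} Hz, "
      f"median T1 {ck_df.t1.median():.2f} ms, "
      f"mean CTC {ck_df.ctc.mean():.1f} %")
```

prints

```
35 crackles in 3 breaths
median pitch 269 Hz, median T1 1.52 ms, mean CTC 28.9 %
```

i.e. this synthetic CHF patient produced ~12 crackles per breath with the
low pitch (≈ 270 Hz vs ≈ 420 Hz for IPF), long first half-period, and high
ipsilateral transmission characteristic of heart-failure crackles (this
patient's latent transmission drew above the 23 % group mean).  A cohort
study is one call — `build_cohort({...}, geometry, seed=0)` returns pooled
crackle, breath, and per-patient summary tables ready for
`compare_groups` (Welch t-tests per feature) and `cross_validate`
(crackle → breath → patient voting metrics).

The same stages are available from the shell:

```bash
cracklekit simulate --profile IPF --seed 1 --n-recordings 10 --out data/
cracklekit extract  --in data/IPF-1-000.wav \
                    --annotation data/IPF-1-000.annotation.jsonl --out feats/
cracklekit run      --config run.yaml        # full simulate→classify→report
```

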