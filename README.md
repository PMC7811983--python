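# strokeqeeg

Quantitative-EEG biomarkers for hyper-acute ischemic stroke, with the
statistical and imaging procedures used to relate them to clinical outcome.

In the first hours after stroke onset, cortical hypoperfusion slows the EEG:
delta power rises and alpha power falls. Summarised as scalp-averaged
relative band powers and the two slowing ratios

- **DAR** = delta / alpha power,
- **DTABR** = (delta + theta) / (alpha + beta) power,

these spectral parameters carry prognostic information about short- and
long-term neurological outcome (NIHSS, modified Rankin scale) and the final
infarct volume. This package implements that analysis end to end for
researchers in clinical neurophysiology:

- **`synthetic`** — a seeded cohort generator: 19-channel 10-20 EEG whose
  spectrum shifts from alpha- to delta-dominant with a severity parameter,
  outcomes monotonically coupled to the same severity, follow-up CT volumes
  containing lesions of exactly known volume, and MTT/CBV perfusion maps.
- **`preprocess`** — 0.5–40 Hz 2nd-order Butterworth bandpass (zero-phase)
  and first-fit selection of a 120 s artifact-free segment from 10 s epochs
  (±100 µV amplitude and 0.1 µV flatline criteria).
- **`spectral`** — Welch PSD on non-overlapping Hann-tapered 10 s tracts;
  absolute and relative band powers (delta 1–4, theta 4–8, alpha 8–13,
  beta 13–30 Hz, normalised by total 1–30 Hz power); DAR and DTABR;
  arithmetic scalp averaging over the 19 electrodes.
- **`stats`** — Spearman correlation (exact permutation p for n ≤ 9,
  t-approximation beyond) of the six EEG parameters against NIHSS at three
  time points and final infarct volume, with Bonferroni control (family
  m = 6); univariate binary logistic regression of good 12-month outcome
  (mRS ≤ 2) on ln-transformed features with Wald 95% CIs.
- **`imaging`** — seed-based region-growing segmentation of the final
  infarct and its volume in ml; CT-perfusion core/penumbra classification
  (hypoperfused: MTT > 145% of the mirrored contralateral side; core:
  CBV < 2.0 mL/100 g; mismatch = penumbra / total hypoperfused).
- **`pipeline` / CLI** — one reproducible run (`simulate → preprocess →
  features → associate → segment`) from a single YAML config, with persisted
  intermediates and byte-identical reruns.

## Worked example

```python
import numpy as np
import strokeqeeg as sq

# a severe synthetic patient (severity 0.8 on the 0–1 scale)
profile = sq.SeverityProfile.from_severity(0.8)
rec = sq.generate_eeg(profile, duration_s=130.0, fs=128.0, n_channels=19, seed=3)
seg = sq.select_clean_segment(sq.bandpass_filter(rec))   # first clean 120 s
scalp = sq.scalp_average(sq.extract_features(seg))
for k, v in scalp.as_dict().items():
    print(f"{k:>10}: {v:.3f}")

out = sq.generate_outcomes(0.8, noise_sd=0.5, volume_scale=116.0, seed=3)
vol = sq.generate_lesion_volume(out.final_volume_ml, seed=3)
seed_pt = tuple(np.argwhere(vol.mask).mean(axis=0).astype(int))
mask = sq.region_grow(vol, seed_pt, (70.0, 90.0))
print(f"segmented volume: {sq.mask_volume_ml(mask, vol.spacing):.2f} ml")
```

prints

```
 rel_delta: 0.552
 rel_theta: 0.253
 rel_alpha: 0.141
  rel_beta: 0.053
       dar: 3.933
     dtabr: 4.157
segmented volume: 35.46 ml
```

A delta-dominant spectrum (relative delta 0.55 vs alpha 0.14) yields
DAR ≈ 3.9 and DTABR ≈ 4.2 — marked slowing, in the range seen in
bad-outcome patients — and region growing recovers this patient's simulated
35.46 ml infarct exactly (the generator records the inserted voxel count as
ground truth).

The same run is available from the shell:

```sh
strokeqeeg config init --out study.yaml
strokeqeeg run --config study.yaml
```

which simulates a 20-patient cohort, extracts features per patient, and
writes the feature table, the 6 × 4 Spearman correlation grid, the logistic
table, cohort descriptives (median and range per outcome), segmentation and
perfusion summaries, exclusion log and provenance block into the output
directory.

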