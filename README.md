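# lfpkit

Computational core of a chronic multianimal video-LFP monitoring platform:
binary session file formats, LFP-packet ↔ video-frame synchronization with
offline frame interpolation, two seizure-detection algorithms, cross-animal
signal-independence QC, a seizure scoring/annotation data model, and a
synthetic session generator that exercises the whole pipeline without any
recorded data.

## Layout

| module | what it does |
| --- | --- |
| `lfpkit.io_formats` | 16-bit unsigned amplifier binaries (packet-blocked or sample-interleaved), JSON session config, µV scaling (0.195 µV/bit), session directory discovery |
| `lfpkit.sync` | 32-bit timestamp files, packet→frame sync map, linear frame interpolation, unassigned-frame gap statistics, segment continuity checking, packet sample/ms arithmetic |
| `lfpkit.detect` | amplitude detector (downsample 500 Hz → 3–50 Hz bandpass → mean + N·SD peaks → ≥3 Hz burst grouping → 2.5 s merging → duration filter) and spectral detector (128-point sliding FFT, 4–40 Hz mean power, same back end) |
| `lfpkit.qc_stats` | pairwise Pearson correlations in three comparison categories, ECDFs, one-way ANOVA, Tukey HSD |
| `lfpkit.synth` | seeded synthetic sessions: 1/f background noise, interictal spikes, seizure spike trains, movement artifacts, asynchronous packet/frame assignment, full on-disk footprint with ground-truth sidecar |
| `lfpkit.events_scoring` | questionnaire annotations (TP/FP, hemisphere, subclinical/Racine I–V), per-scorer JSON files, summaries, inter-scorer agreement, detection-vs-truth matching |
| `lfpkit.cli` | `lfpkit simulate / detect / sync-report / qc / summarize / agreement` |

## CLI

```bash
# generate a synthetic 2-animal session
cat > spec.json <<'EOF'
{"seed": 1, "duration_s": 120.0, "n_animals": 2,
 "seizures": [{"animal": 0, "start_s": 30.0, "duration_s": 6.0, "amplitude_uv": 600.0}]}
EOF
lfpkit simulate spec.json --out session/

# run the amplitude detector on channel 0 (threshold mean + 5 SD, >= 3 s)
lfpkit detect session/ --channel 0 --n-sd 5 --min-duration 3 --out events.csv

# continuity + frame-gap report, and cross-animal independence QC
lfpkit sync-report session/ --out report/
lfpkit qc session/ --out qc/
```

Every command prints a JSON settings snapshot to stderr before writing
results, so a run can be reproduced from its log.

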