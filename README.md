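# lungsound

Respiratory-sound asthma classification pipeline: MFCC + TQWT feature
extraction from 3-second lung-sound segments, ReliefF feature selection,
and quadratic-kernel SVM / narrow neural-network classifiers evaluated
with participant-level stratified 10-fold cross-validation.

Because clinical recordings of this kind are rarely shareable, the package
ships a seeded synthetic-cohort generator that reproduces the study
design's structure — 120 participants (60 asthma / 60 healthy), six
15-second posterior-thorax recordings each, 3600 three-second segments in
total — with asthma modelled as narrowband expiratory wheeze components
superimposed on breathing-modulated band-limited noise. Every stage of the
pipeline is testable offline against this cohort.

## Layout

| module | purpose |
| --- | --- |
| `lungsound.synth` | seeded synthetic cohort generation (WAV + manifest CSV, or in memory) |
| `lungsound.audio_io` | WAV reading, 3-s segmentation, spectral quality control |
| `lungsound.mfcc` | framing, FFT, Mel filterbank, log energies, DCT, frame averaging (14 coefficients) |
| `lungsound.tqwt` | tunable Q-factor wavelet transform (perfect reconstruction) + sub-band descriptors |
| `lungsound.features` | combined 15-feature matrix, standardization, ReliefF, top-k selection, sweeps |
| `lungsound.models` | quadratic SVM, narrow NN, participant-level CV, metrics panel, ROC/PR |
| `lungsound.cli` | `lungsound` command with generate / extract / select / train / evaluate / run-all |

## CLI

All stages are driven by one optional YAML config (unknown keys rejected;
defaults reproduce the reference design: 3-s segments, 15 features, k=10
selection, 10 folds). Flags override config keys.

```sh
# end to end on the default synthetic cohort
lungsound --seed 1 run-all --out runs/demo

# or stage by stage
lungsound --seed 1 generate --out runs/demo/data
lungsound --seed 1 extract  --data runs/demo/data --out runs/demo
lungsound --seed 1 select   --features runs/demo/features.csv --out runs/demo
lungsound --seed 1 --model nnn evaluate --features runs/demo/features.csv --out runs/demo
```

Artifacts: cohort WAVs + `manifest.csv`, `features.csv` (segments x
features with identifiers), `segments.csv` (QC log), `relieff_weights.csv`,
`model.joblib`, `evalreport.json` (fold-aggregated confusion matrix,
percent metric panel, ROC/PR AUCs) and per-stage logs carrying the config
hash and seed. `evaluate --plot` additionally writes ROC/PR curves as PNG.

Label convention: asthma = 1 (positive class), healthy = 2.

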