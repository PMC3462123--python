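# sleepdhmm

Automatic sleep staging with a transition-constrained discrete hidden
Markov model (DHMM). The pipeline conditions three-channel PSG
(EEG/EOG/EMG), extracts 13 spectral and temporal features per 30-s
epoch, vector-quantizes them through a k-means codebook, and decodes the
stage sequence with a Viterbi path that can never traverse a disallowed
stage transition (e.g. Wake → SWS). A synthetic PSG generator produces
stage-labeled recordings whose band content follows the standard visual
scoring criteria, so the whole pipeline is exercisable end to end
without clinical data.

## Layout

| module | role |
| --- | --- |
| `sleepdhmm.synth` | stage-labeled synthetic PSG: masked Markov hypnograms, per-stage EEG/EOG/EMG signal models |
| `sleepdhmm.preprocess` | resampling to 256 Hz, order-8 Butterworth band-passes, 30-s epoch segmentation, averaged 512-point spectra, >200 μV movement detection |
| `sleepdhmm.features` | the 13 features: total powers, band power ratios, mean spectral frequencies, alpha/spindle/SWS duration ratios, EMG mean amplitude |
| `sleepdhmm.codebook` | subinterval-initialized k-means vector quantization |
| `sleepdhmm.dhmm` | constrained DHMM: brute-force oracle, scaled forward, log-space Viterbi, count-based training with masked transitions pinned to zero |
| `sleepdhmm.evaluate` | confusion matrix, per-stage sensitivity, overall agreement (M_SSRR), Cohen's kappa + Landis–Koch bands, repeated 2-fold cross-validation |
| `sleepdhmm.io` / `cli` / `config` / `pipeline` | minimal EDF codec, TSV/JSON formats, declarative config, end-to-end orchestration |

The default allowed-transition diagram lives in
`src/sleepdhmm/data/default_mask.json` and is shared by the generator
and the decoder; edit it (or pass `--mask`) to change the constraint
set.

## CLI

```sh
sleepdhmm synth --subjects 4 --epochs 200 --seed 1 --out data/
sleepdhmm featurize --signals data/subject_00.signals.tsv --out data/subject_00.features.tsv
sleepdhmm train-codebook --features data/ --m 50 --out cb.json
sleepdhmm train --features data/ --hypnograms data/ --codebook cb.json --out model.json
sleepdhmm score --model model.json --codebook cb.json \
    --features data/subject_00.features.tsv --out decoded.tsv
sleepdhmm evaluate --reference data/subject_00.hypnogram.tsv --predicted decoded.tsv
sleepdhmm crossval --data data/ --m 50 --repeats 5 --seed 0 --out cv.json
```

Signals are exchanged as headered TSV (one column per channel) or EDF
(`--edf` on `synth`); hypnograms as `epoch_index<TAB>stage` TSV with
stages spelled Wake/S1/S2/SWS/REM/Mov; codebooks and models as JSON with
bit-exact round-trips.

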