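# dfnc — dynamic functional network connectivity brain-state analysis

A tested pipeline for time-resolved functional network connectivity (dFNC):
tapered sliding-window correlation among component/ROI time series,
Manhattan-distance k-means brain-state clustering with elbow model-order
selection, state dwell-time/transition metrics, and group + brain-behavior
inference — together with a synthetic multi-subject, two-task cohort
generator that plants known state structure, task signal, motion, and
behavior, so every stage can be validated against ground truth.

## Stages

| module            | role |
|-------------------|------|
| `dfnc.cohort`     | synthetic cohort: block paradigm (8 s fixation, 8 × 36 s task blocks interleaved with 8 × 12 s rest, TR 2 s, 201 volumes), Markov regime switching over planted covariance states, HRF-convolved task signal, AR(1) motion scaled to a target mean FD, signal-detection behavior coupled to state dwell time |
| `dfnc.prep`       | nuisance regression (HRF-convolved paradigm + 6 motion parameters + derivatives + intercept), linear detrend, zero-phase 5th-order Butterworth low-pass (0.1 Hz), Power framewise displacement |
| `dfnc.ica`        | two-stage PCA (per-subject n1=27, group n2=18), repeated-run fixed-point ICA with a stability index (Iq) from greedy cross-run clustering, dual-regression back-reconstruction, component selection |
| `dfnc.windows`    | taper (rectangle ⊛ Gaussian, w=20 TRs, σ=3), weighted Pearson correlation per sliding window (197 volumes → 178 windows at step 1), edge vectorization |
| `dfnc.states`     | L1 k-means (median centroids, k-means++-style seeding, best of 20 replicates, max 150 iterations), within/between validity ratio over k=2..10, elbow selection, transition counts and fractional dwell times |
| `dfnc.inference`  | permutation test on group mean differences (B=10,000), edgewise paired t with Benjamini–Hochberg FDR, d′ with log-linear correction, FD-adjusted partial Pearson correlation |
| `dfnc.pipeline`   | orchestration, provenance, markdown/JSON reporting |

## CLI

```sh
dfnc simulate --out sim/ --seed 1                 # write the synthetic cohort (TSV/JSON)
dfnc prep     --in sim/ --out clean/ --seed 1     # nuisance regression + filtering
dfnc fnc      --in clean/ --out fnc/ --seed 1     # windowed correlations
dfnc states   --in fnc/ --out states/ --seed 1    # brain-state clustering + metrics
dfnc infer    --run-dir run/ --out inf/ --seed 1  # group / behavior inference
dfnc run      --out run/ --seed 1                 # full pipeline end to end
dfnc report   --run-dir run/                      # print the JSON summary
```

All commands accept `--config cohort.yaml` (YAML or JSON; see
`dfnc.config.RunConfig` for every parameter) and `--log-level`. Reruns with
the same config and seed are numerically identical.

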