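# bcistim

A tested, reusable pipeline for desk-scale motor-imagery BCI stimulation
studies: synthetic sensorimotor EEG generation, preprocessing, online-style
(CSP+FLDA) and offline (Riemannian minimum-distance-to-mean) BCI scoring,
closed-loop alpha-falling-phase stimulation simulation, pre-stimulus band
power, global phase-locking-value (PLV) connectivity, and pre/post group
statistics.

Because no raw study data are publicly deposited, the package ships a
first-class synthetic generator (`bcistim.synthetic`) that emulates the
study's recording and trial structure — 19-channel 10–20 montage at 300 Hz in
µV, 1.5 s fixation / 4 s imagery / 1.5 s blank trials, 40 trials per block,
2 offline + 2 online blocks, pre and post sessions — with controllable
contralateral ERD depth, pre-stimulus alpha amplitude, inter-channel phase
coupling, and artifact rate. Every downstream stage is tested against this
generator's ground truth.

## Layout

| module | contents |
|---|---|
| `bcistim.synthetic` | `SyntheticConfig`, `generate_subject`, `make_phase_coupled_signals`, `inject_artifacts` |
| `bcistim.io` | `RawRecording`/`EventTable`/`EpochSet`, EDF+TSV read/write, zero-phase Butterworth filtering, epoching, ±100 µV trial rejection, >30% bad-trial subject rule |
| `bcistim.edf` | minimal 16-bit EDF writer/reader (µV, 1 s records) |
| `bcistim.bci` | trial covariances, affine-invariant distance, Karcher mean, MDM fit/predict, CSP+FLDA (both study hyper-parameter variants), adjusted-Wald chance threshold, low/high performer split |
| `bcistim.phase_stim` | streaming 500 ms / 50 ms-step phase estimation (order-10 elliptic IIR + FFT-seeded sine fit), falling-phase prediction, 100 ms stim / 100 ms ISI closed-loop simulator, coverage & targeting metrics |
| `bcistim.spectral` | band power in dB (Hann periodogram), pre-stimulus power (C3/C4 mean + 9-channel ROI), ERD% time courses |
| `bcistim.connectivity` | Hilbert phases, across-trial PLV time courses, global (36-pair ROI mean) PLV |
| `bcistim.stats` | paired t-test, Bonferroni, arm × group contrast tables, end-to-end cohort pipeline |
| `bcistim.reference` | published group-level summary accuracies (pre/post deltas) |

## CLI

```sh
bcistim simulate --seed 1 --out subj01/            # EDF + events.tsv + ground_truth.json
bcistim preprocess --in subj01/ --out prep.json    # filter/epoch/reject summary
bcistim score --in subj01/ --session pre --report scores.json
bcistim stimulate --in subj01/ --session pre --log stim_log.json
bcistim bandpower --in subj01/ --bands alpha --out power.json
bcistim plv --in subj01/ --bands alpha,low_beta,high_beta --out plv.json
bcistim report --config study.yaml --out report/   # full synthetic-cohort study
```

`simulate --config cfg.yaml` accepts any `SyntheticConfig` field as YAML.
`report` consumes a study YAML (seed, arms with subject counts and post-session
effects, subject overrides, measure toggles) and writes `report.json` +
`report.md` with per-group "mean (min ~ max)" accuracy strings and paired
pre/post contrasts (Bonferroni over the 9 ROI channels where applicable).

## Conventions worth knowing

- Time windows are half-open `[start_ms, end_ms)` relative to stimulus onset;
  sample index = `round(ms * fs / 1000)`.
- Phases use the cosine convention; "falling" means phase in (0, π).
- The ±100 µV rejection rule is strict (`>`), applied after filtering, and
  exempts Fp1/Fp2; the >30% bad-trial subject rule is also strict.
- Offline MDM on the 9-channel ROI (F3 Fz F4 C3 Cz C4 P3 Pz P4), trained on
  blocks 1–2 and tested on blocks 3–4, is the canonical performance metric;
  CSP+FLDA exists to emulate the online protocol only.
- dB values are `10*log10(power / 1 µV²)`; C3/C4 averaging happens in the dB
  domain (configurable).
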