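# eogsacc

Saccade classification from electrooculography (EOG) registers, aimed at
screening for slowed-saccade neurodegenerative conditions. A *register*
is the set of saccades recorded from one subject and carries a single
diagnosis — control (C), presymptomatic (P) or sick (S) — which every
saccade inherits. Presymptomatic registers are mostly filled with
healthy-looking saccades, so those inherited training labels are noisy.

The package implements a hybrid unsupervised/supervised pipeline:

1. **SOM relabeling** — a self-organizing map groups training saccades by
   shape; each map cell's label counts (nC, nP, nS) decide a corrected
   *working label* for the saccades it holds: S on strict sick plurality,
   C when no P label is present, otherwise P iff nC/nP falls below a
   ratio threshold.
2. **CNN-LSTM classifier** — two 1-D conv blocks (kernel 3, ReLU, max
   pool 2) feeding an LSTM, dropout and a 3-way softmax, implemented in
   pure NumPy with explicit backprop (no deep-learning framework
   required). Checkpoints are selected by the *recall compromise*
   min(recall_C, recall_P) computed on validation registers.
3. **Register voting** — predicted saccade labels are aggregated per
   register by majority vote (ties to the severer class).
4. **Threshold sweep** — the ratio threshold is swept over
   {2, 3, 4, 4.5} plus a no-relabel baseline (threshold 0), with repeated
   seeded runs on one fixed register split; the threshold with the best
   validation recall compromise is selected.

A synthetic generator (`eogsacc.synthetic`) produces registers with the
same bag-level label-noise structure (logistic-step saccades, slower rise
for affected classes, a configurable fraction of control-shaped saccades
inside presymptomatic registers) and keeps per-saccade ground truth, so
every stage is testable without clinical data. `eogsacc.preprocess`
segments raw 200 Hz traces (2-means on |velocity|), cuts 192-sample
windows from saccade centers, scales each stimulus angle to a nominal
30° amplitude and flips right-to-left saccades.

## CLI

```sh
eogsacc --seed 1 generate data.csv --registers 14 6 10 --contamination 0.6
eogsacc --seed 1 relabel data.csv relabeled.csv --threshold 4
eogsacc --seed 1 segment trace.csv windows.json
eogsacc --seed 1 --out-dir runs/demo pipeline        # sweep + select + report
eogsacc --seed 1 sweep                               # per-threshold scores
eogsacc evaluate true.csv pred.csv
```

`--config file.yaml` overrides any pipeline parameter (data path or
generator settings, split fractions/seed, SOM hyperparameters, sweep
values, model and training settings, repeats).

Data travel as a plain CSV: `saccade_id, register_id, angle, given_label,
working_label[, true_shape_label], s000..s191`. A headerless 192-column
matrix plus a row-aligned metadata CSV is also accepted
(`read_saccade_table(path, format="matrix", metadata_path=...)`).

## Notes

- All randomness flows from explicit seeds (`numpy.random.SeedSequence`
  substreams); identical seeds give identical datasets, maps, models and
  reports within one environment.
- Run-averaged metrics are always recomputed from the mean confusion
  matrix, not averaged per run.
- The scaled-down end-to-end demonstration (30 synthetic registers,
  small model, ≤15 epochs, 2 repeats per threshold) lives in
  `eogsacc.fixtures` and runs in under a minute on one CPU.
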