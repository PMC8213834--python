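# mlpcm

A machine-learning correction layer for polarizable-continuum solvation
free energies.

Continuum solvation models (PCM, CPCM and relatives) estimate the free
energy of transferring a solute from gas phase into a solvent treated as
a dielectric continuum.  They are fast — seconds per molecule — but on
large benchmarks of neutral solutes their mean unsigned error (MUE)
against experiment sits near 3 kcal/mol.  The intermediate quantities of
the underlying self-consistent reaction-field (SCRF) calculation,
however, carry far more information than the single ΔG the model prints:
gas- and solution-phase expectation values ⟨Ψ|H|Ψ⟩ and ⟨Ψ|H+V/2|Ψ⟩,
solute–solvent interaction and polarization energies, cavity surface
area and volume, kinetic and potential energy totals.  `mlpcm` maps
those 15 components, together with the solvent dielectric constant ε
(and optionally a COSMO-RS ΔG), onto the experimental solvation free
energy with small feed-forward neural networks — recovering roughly an
order of magnitude in accuracy at essentially zero added cost over the
SCRF run itself.

The package is aimed at computational chemists who already run
continuum-solvation calculations and want calibrated ΔG_solv predictions
plus an honest protocol for deciding whether a fitted model can be
trusted.

## Method

* **Inputs.** Per solute/solvent record: the 15 SCRF energy/geometry
  components, ε, optionally a COSMO-RS ΔG, and the experimental ΔG
  (kcal/mol).  Exchanged as plain CSV.
* **Dielectric scalings.** The conductor-like screening factor
  f(ε) = (ε−1)/(ε+x) and the effective dielectric ε̃ = (ε+x)/(x+1)
  satisfying f(ε̃, 0) = f(ε, x), so an x = 0 code can emulate any x.
* **Feature screening.** Minimum-redundancy maximum-relevance (MRMR)
  selection on equal-frequency-discretized variables, maximizing
  I(f; ΔG_exp) while penalizing mean I(f; selected), under a 25-setting
  grid (quantization level × difference/quotient scheme ×
  forward/backward direction × Laplace pseudo-count smoothing).
* **Regression.** One hidden layer (logsig or tansig), linear output,
  min-max normalization to [−1, 1] fitted on the training split only;
  trained by Levenberg–Marquardt or gradient-descent backpropagation
  with validation early stopping.
* **Protocol.** Demanding 60/15/25 train/validation/test splits that
  must contain a solvent or solute element unseen in training; a grid
  search over feature sets × architectures trained on many resplits and
  initializations; a 22% mean-absolute-percentage-error gate; and a
  post-validation screen that warm-starts the recorded weights under 100
  fresh resplits and requires the train and test error samples to be
  statistically indistinguishable (two-sample t-test, 5% level) in at
  least 80 of them.  The unweighted mean of the retained models'
  predictions is the reported ensemble.
* **Extrapolation audits.** Leave-one-solvent-out and
  leave-one-element-out experiments compare the error on a group of
  records when the group is available to training versus when it is
  banished to the test set.

Because the real inputs require a quantum-chemistry package and a
curated experimental database, `mlpcm` ships a first-class synthetic
benchmark generator with the same schema: correlated SCRF-like
components, a known nonlinear ground truth, realistic noise, and a
continuum baseline with a deliberate ~3 kcal/mol systematic error.  See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

```
$ mlpcm generate --n 400 --seed 1 --out data.csv
wrote 400 records to data.csv

$ mlpcm screen --data data.csv --out selections.json --k 8
2 distinct feature subsets -> selections.json

$ cat > protocol.yaml <<EOF
n_splits: 3
n_inits: 2
hidden_sizes: [10]
max_epochs: 150
EOF

$ mlpcm train --data data.csv --selections selections.json \
      --out run --seed 1 --config protocol.yaml
2 candidates, 2 passed the 22.0% MAPE gate

$ mlpcm postvalidate --data data.csv --candidates run/candidates.json \
      --out postval.json --seed 1 --iterations 100
candidate 0: pass 93/100 verdict=True ensemble MUE=0.3174 kcal/mol
candidate 1: pass 97/100 verdict=True ensemble MUE=0.3059 kcal/mol
```

The generated benchmark's continuum baseline (`dg_model` vs `dg_exp`)
has MUE 3.15 kcal/mol.  The MRMR screen kept, among others, the baseline
ΔG itself, the interaction and polarization energies and ε — the inputs
that genuinely drive the ground truth.  Both candidates passed the MAPE
gate; post-validation retained them (93 and 97 of 100 resplits
statistically indistinguishable), and their ensembles predict the
held-out chemistry with MUE ≈ 0.31 kcal/mol — a tenfold improvement over
the continuum baseline.  A model trained on permuted targets is rejected
by the same screen (pass counts near 0/100).

`mlpcm predict --model run/best_model.json --data new.csv --out pred.csv`
applies a saved model to records without experimental values, and
`mlpcm loso` runs the leave-one-group-out audit.

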