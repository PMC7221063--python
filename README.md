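# emgforce

Estimation of end-effector force from high-density surface EMG (HD-sEMG)
during multi-muscle isometric contraction, with a perturbation-based index
that ranks which muscle matters most.

When several muscles act on a joint — say biceps brachii, brachialis,
triceps, brachioradialis and the finger extensors during elbow flexion — a
practical question for prosthetics control and biomechanics is whether the
force at the hand is best decoded from the *dominant* muscle alone or from
the whole muscle group. `emgforce` implements a complete pipeline to study
that question: four 4×8 electrode grids (128 monopolar channels at 1 kHz)
are reduced to one representative activation signal per muscle, a deep
belief network maps those signals to instantaneous force, and a mean impact
value (MIV) analysis ranks the muscles by their influence on the estimate.

Because public HD-sEMG + force recordings of this protocol do not exist,
the package ships a first-class synthetic session generator with known
ground truth (dominant muscle, per-grid gains, bad channels), so every
stage — and the pipeline's ability to recover the dominant muscle — is
testable end to end.

## Method

1. **Envelope preprocessing** (per contraction cycle): bad-channel repair
   (amplitude bounds + MAD variance rule, 4-neighbor mean replacement) →
   zero-phase 20 Hz Hann-window FIR high-pass (order 80) → full-wave
   rectification → 100 ms moving average → force normalized by its cycle
   maximum, envelopes by the single maximum over all 128 channels.
2. **Representative signals**: each grid's mean-removed envelope matrix
   X (32 × T) is decomposed by PCA, Y = A X, where the rows of A are
   eigenvectors of the channel covariance. Components are kept until the
   cumulative variance-explained fraction reaches 0.85 (on clean data the
   first component suffices). Across training cycles the component count is
   harmonized to the minimum, and one global min–max pair scales all
   selected components to [0, 1].
3. **DBN regression**: a four-layer network — (1, 80, 80, 1) for a single
   muscle input, (4, 100, 100, 1) for all four — built from stacked
   restricted Boltzmann machines. Layer-wise CD-1 pre-training (Gaussian
   then Bernoulli visible units) initializes the weights; backpropagation
   with momentum fine-tunes them on mean-squared force error with
   early stopping on held-out validation cycles. Pure numpy, bit-reproducible
   under a fixed seed.
4. **Muscle priority (MIV)**: with the trained all-muscles model and the
   cycle's input matrix P (m × n), each input row is scaled by ±10 % in
   turn and MIV_k = mean(f(P′) − f(P″)) over the n samples. Inputs are
   ranked by |MIV|; a grid's priority is the max |MIV| of its inputs.
5. **Evaluation**: RMSD and R² between normalized measured and estimated
   force; per-grid activation level I_j = Σ_i RMS_j(i)² over the grid's 32
   normalized channels identifies the dominant muscle; leave-one-out
   cross-validation over the non-validation cycles at each force level
   (20/40/60 %MVC, sinusoidal 6 s cycles).

## Worked example

One synthetic session (grid gains 1.0/0.45/0.35/0.25, so grid E1 is
dominant), leave-one-out CV at 60 %MVC:

```python
from emgforce import run_recovery_benchmark

[res] = run_recovery_benchmark([42], reps_per_level=5, top_level=0.6)
print(f"ground-truth dominant grid : E{res.dominant_grid_truth + 1}")
print(f"PC1 variance fraction      : {res.pc1_variance_fractions.mean():.3f}")
print(f"dominant-grid test RMSD    : {res.dominant_rmsd:.4f}  (R2 {res.dominant_r2:.4f})")
print(f"all-grids test RMSD        : {res.all_rmsd:.4f}  (R2 {res.all_r2:.4f})")
print(f"MIV top-ranked grid        : E{res.miv_top_grid + 1}")
```

prints

```
ground-truth dominant grid : E1
PC1 variance fraction      : 0.980
dominant-grid test RMSD    : 0.0291  (R2 0.9930)
all-grids test RMSD        : 0.0397  (R2 0.9872)
MIV top-ranked grid        : E1
```

The first principal component of every grid carries ~98 % of its envelope
variance; the dominant muscle alone tracks force slightly *better* than the
four-muscle combination (RMSD 0.029 vs 0.040 of normalized force), and the
MIV ranking recovers the generator's dominant grid.

The same stages are available as a shell tool:

```bash
emgforce simulate --config sim.yaml --out session/ --seed 1
emgforce preprocess --in session/ --out stage/
emgforce extract --in stage/ --out stage/ --threshold 0.85
emgforce train --in stage/ --grids all --out model.h5 --seed 1
emgforce run --config experiment.yaml --out results/   # full experiment
```

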