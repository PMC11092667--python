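# gaitsig

Individual-specific **gait signatures** from the latent dynamics of a
recurrent neural network, with the full downstream analysis chain: subject
identification across walking speeds, low-dimensional gait maps, and
linear speed-modulation models.

## The problem

People walk in recognizably individual ways, yet most gait analyses reduce a
trial to discrete summary numbers (peak joint angles, cadence, step length)
that discard how the joints coordinate *over time*. A gait signature
captures that temporal structure: a single-layer LSTM is trained on
continuous multi-joint gait time series ``x_t`` (joint angles, ground
reaction forces, moments, powers) to predict the next sample,

    x̂_{t+1} = g(h_t),    h_t = LSTM(x_t, h_{t-1}, c_{t-1}),

and the hidden-state trajectory ``h_1..h_T`` — the model's internal estimate
of the gait dynamics — is reduced with PCA, resampled onto a common
percent-gait-cycle axis (phase 0 at right heel strike), and averaged across
strides. The resulting loop, flattened to a vector, is the signature of one
trial. Signatures support:

- **identification** — a linear SVM classifies which subject produced a
  trial, trained on a subset of each subject's speed conditions and tested
  on the held-out speeds;
- **gait maps** — classical multidimensional scaling of pairwise signature
  distances into 3D, where intra- vs inter-individual distance structure is
  quantified with pooled z-scores and Mann-Whitney U tests;
- **speed models** — per-subject linear regressions and a random-intercept
  linear mixed-effects model per map coordinate,
  ``coord ~ β₀ + β₁·speed + (1|subject) + ε``,
  with a leave-one-subject-out hierarchical bootstrap;
- **correlates** — Pearson tests relating speed-induced signature shifts to
  balance ability, self-selected speed, and spatiotemporal changes, with
  Bonferroni correction (α = 0.05/10 = 0.005 for the ten spatiotemporal
  tests per condition pair).

Because real motion-capture cohorts are not redistributable, the package
ships a first-class synthetic cohort generator with known ground truth for
every structure the pipeline estimates: subject-specific Fourier waveform
shape, linear speed modulation of amplitude and cadence, stride-to-stride
jitter, and a stance-only vertical ground reaction force for event
detection. See `docs/methods.md` for the generative model and all defaults.

## Worked example

```python
from gaitsig.cohort import CohortConfig
from gaitsig.dynamics import RNNConfig
from gaitsig.pipeline import RunConfig, run_study

config = RunConfig(
    cohort=CohortConfig(n_subjects=8, speeds_per_subject=6,
                        speed_min=0.3, speed_max=2.0,
                        duration_s=20.0, data_type="kin3d", seed=11),
    rnn=RNNConfig(hidden_units=64, learning_rate=5e-3, epochs=100,
                  l2_strength=1e-4, seed=12, early_stopping_patience=30),
    k_range=(1, 4), n_runs=20, required_trials=6,
    run_bootstrap=False, master_seed=11,
)
study = run_study(config, verbose=True)
for r in study.classification:
    print(f"k={r.k_train}: accuracy {r.mean_accuracy:.3f}  CI {r.ci}")
print("retained PCs:", study.n_pcs)
print("intra/inter MWU p:", study.distance_stats.mwu_p)
```

Output on the seeds above:

```
k=1: accuracy 0.596  CI (0.525, 0.7)
k=4: accuracy 1.000  CI (1.0, 1.0)
retained PCs: 3
intra/inter MWU p: 8.8e-14
```

With four of six speed trials per subject in training, the SVM identifies
every held-out trial's subject; with a single training trial it is still
far above the 1/8 chance level. Three latent PCs explain over 80% of the
variance of the original 18 kinematic channels, and intra-individual map
distances are far smaller than inter-individual ones.

A command-line interface mirrors the stages:

```bash
gaitsig all --seed 11 --out runs/demo        # full pipeline + manifest
gaitsig simulate --seed 3 --out runs/cohort  # cohort CSVs only
gaitsig validate --config cfg.yaml           # config report
```

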