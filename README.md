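# erpkit

Classification of event-related potentials (ERP) from N-back
working-memory paradigms, for researchers studying cognitive impairment
with EEG. The package implements a complete, tested analysis chain:

1. **Synthetic cohort generation** — multichannel recordings with
   P300-like target responses, stimulus-locked theta bursts, blink
   artifacts, and pink-noise background, with configurable patient vs.
   control effect sizes (prolonged latency, reduced amplitude, reduced
   theta power). Every downstream stage is testable without clinical
   data.
2. **ICA-OEMD cleaning** — extended Infomax ICA
   (`dW = [I - K tanh(u)u' - uu']W`, with the diagonal switching matrix
   K choosing the super-/sub-Gaussian nonlinearity from
   `k_i = sign(E[u_i^4]/E[u_i^2]^2 - 3)`) removes EOG-correlated
   sources; orthogonal empirical mode decomposition
   (`g_j = g_oj - sum_{k<j} beta_jk g_k`,
   `beta_jk = <g_k, g_oj>/<g_k, g_k>`) reduces each source to its
   task-relevant intrinsic mode function — theta-band dominant with a
   peak 200-450 ms after target onset — before back-projection to the
   scalp channels.
3. **Four ERP features** per scalp channel on the target-locked
   average: P300 peak latency, P300 peak amplitude, RMS, and theta
   (4-8 Hz) band power from a depth-5 db4 wavelet-packet energy
   spectrum.
4. **EMK-SVM** — a multiple-kernel SVM whose kernel is a
   genetic-programming-evolved expression tree over
   `{+, x, exp}` and `{K_Poly, K_RBF, alpha}` with
   `K_Poly(x,y) = <x,y>+1`, `K_RBF(x,y) = exp(-||x-y||^2/2)`,
   `alpha in [-1,1]`; fitness is inner-cross-validated SVM accuracy.
   Evaluated with subject-grouped stratified 5-fold CV against LDA and
   QDA baselines.

See `docs/methods.md` for the model details, parameter defaults, and
limitations.

## Worked example

```python
from erpkit import synth, pipeline
from erpkit.emk import GPConfig

paradigm = synth.ParadigmSpec(n_sessions=2, trials_per_session=20)
effects = synth.GroupEffectSpec()      # default group effect sizes
cohort = synth.generate_cohort(paradigm, effects,
                               n_patients=6, n_controls=6, seed=7)
config = pipeline.PipelineConfig(
    ica=pipeline.ICAConfig(max_iter=100),
    gp=GPConfig(pop_size=20, max_gen=10, seed=0),
    cv_folds=5, seed=0)
report = pipeline.run_pipeline(cohort, config)
print(report.accuracy.round(3))
```

which prints (about two minutes on one core):

```
classifier    emk_svm    lda    qda
feature
latency_ms      0.683  0.583  0.533
amplitude_uv    0.917  0.683  0.917
rms_uv          0.883  0.467  0.833
theta_power     0.650  0.433  0.717
```

Each cell is the mean held-out accuracy over grouped 5-fold CV for one
feature type and one classifier: with only 6 subjects per group the
amplitude and RMS contrasts are already recovered well above chance,
and the evolved kernel beats the linear baseline on every feature. The
accompanying statistics table gives the per-feature group contrasts at
the most discriminative channel (here e.g. amplitude at Cz: Welch
t = 5.14, p = 0.0001), and `report.kernels` lists each fold's best
evolved kernel with the generation it appeared in, e.g.

```
(* K_RBF (exp (* (* K_RBF K_Poly) K_Poly)))   generation 10
```

At the full study scale (13+13 subjects x 3 sessions x 40 trials) the
same pipeline reaches mean accuracies of roughly 0.85-0.95 across the
four features, seed-dependent (see `results/acceptance.json` after
running the script below).

## Command line

```sh
erpkit synth --n-patients 13 --n-controls 13 --seed 1 --out cohort/
erpkit run-all --cohort cohort/ --config config.yaml --out results/
```

Subcommands `clean`, `features`, and `classify` expose the
intermediate stages; recordings are delimited text matrices with event
sidecars and a cohort manifest, so everything is inspectable.

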