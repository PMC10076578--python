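# voxscreen

Speech-based depression screening with speaker embeddings and a multi-task
stacked ensemble.

Depressed speech differs measurably from healthy speech: reduced fundamental-
frequency (F0) variability, more and longer pauses, and a slower speaking
rate. `voxscreen` implements a screening pipeline that turns those
paralinguistic differences into a subject-level classifier, for researchers in
computational psychiatry and speech pathology who want a reproducible,
end-to-end reference implementation that runs on a laptop.

## The method

1. **Acoustic front end.** Each utterance becomes a T×60 matrix of frame-level
   features — MFCC, PLP, or FBANK — with 25 ms Hamming windows and a 10 ms
   shift, energy-based voice activity detection, and per-utterance cepstral
   mean normalization.
2. **Speaker-embedding extractors**, pre-trained on a many-speaker corpus and
   then frozen:
   - **i-vector**: a diagonal-covariance GMM-UBM plus the total-variability
     model M = m + Tw; the MAP estimate of the latent factor w is the
     embedding (default rank 256, 256 Gaussians).
   - **TDNN x-vector**: a time-delay network whose spliced contexts
     {−2..2}, {−2,0,2}, {−3,0,3} give one top-level frame a 15-frame receptive
     field, followed by statistics pooling (mean ‖ std over time) and a
     segment-level affine tap (256-d).
   - **ResNet34 x-vector**: a residual encoder over the 60×T feature map —
     7×7 stride-1 stem, stages of (3,4,6,3) basic blocks with (32,64,128,256)
     channels and stride-2 downsampling, statistics pooling over time, 256-d
     segment affine.
3. **Multi-task stacked ensemble.** Each subject performs nine speech tasks.
   Per (task, embedding type), an RBF-kernel SVM emits the probability
   p_i(j) that subject i is depressed given task j; the 9·k probabilities
   (k = number of fused embedding types, e.g. R_m + R_p) form a meta-feature
   vector classified by an MLP. Meta-features for training subjects are
   produced out-of-fold so no subject is scored by a model trained on itself.
4. **Evaluation.** Stratified 10-fold cross-validation at the subject level,
   repeated with fresh shuffles; accuracy, F1-D (depressed positive) and
   F1-H (healthy positive) from the fold confusion matrices.

Because clinical speech corpora are private, the package ships a seeded
synthetic-corpus module: a harmonic source-filter synthesizer whose
"depressed" group has reduced F0 variability, raised pause probability and
reduced syllable rate, each shifted by `effect_size` population standard
deviations. `effect_size = 0` is an exact null (labels independent of
acoustics), so the whole pipeline can be validated for both power and
calibration without external data.

The neural layers (time-delay splicing, 2-D convolutions with ceil-mode
striding, statistics pooling, AdamW) are implemented in NumPy with explicit
backpropagation, sized for desk-scale experiments.

## Worked example

```python
from voxscreen.encoders import EncoderSpec
from voxscreen.ensemble import EnsemblePipeline
from voxscreen.evaluation import repeated_cv
from voxscreen.pretrain import TrainingConfig, featurize_manifest, train_extractor
from voxscreen.synth import CohortConfig, generate_cohort, generate_pretrain_corpus
from voxscreen.workflow import extract_cohort_table

pre = generate_pretrain_corpus(24, 8, seed=101, out_dir="scratch/pre")
ext = train_extractor(pre, "mfcc", EncoderSpec.tiny_tdnn(),
                      TrainingConfig(epochs=40, batch_size=32, seed=100),
                      features=featurize_manifest(pre, "mfcc"))
coh = generate_cohort(CohortConfig(n_depressed=60, n_healthy=60,
                                   effect_size=2.0, seed=102),
                      out_dir="scratch/cohort")
table = extract_cohort_table([ext], coh)
report = repeated_cv(lambda s: EnsemblePipeline(seed=s), table,
                     repetitions=5, k=10, base_seed=200)
print(report.aggregate)
```

On this seeded study the run prints

```
{'accuracy': 0.91, 'f1_d': 0.905, 'f1_h': 0.914}
```

i.e. with a two-SD group separation the ensemble recovers the group label for
about 91% of held-out subjects, with balanced per-class F1. Rerunning with
`effect_size=0.0` gives accuracy ≈ 0.46 — chance level, confirming the
pipeline does not manufacture signal where none exists.

The same experiment is available as a CLI:

```bash
voxscreen run --config experiment.yaml     # simulate → featurize → pretrain →
                                           # extract → ensemble → evaluate
```

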