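# harfusion

Human activity recognition (HAR) from a chest-worn tri-axial accelerometer,
for researchers and engineers building fall-detection and activity-monitoring
pipelines.  Instead of feeding raw 1-D signals to a network or hand-crafting
features, each 10 s window x ∈ ℝ^{2500×3} (250 Hz) is re-expressed as three
64×64×3 images that expose complementary structure, and a three-branch CNN
fuses their features:

* **Spectrogram** — squared STFT magnitude per axis,
  `S(m, ω) = |Σₙ x[n] w[n−m] e^{−jωn}|²`, decibel-scaled, tri-axial matrices
  stacked horizontally, colormapped;
* **Modified recurrence plot** — the unthresholded distance matrix
  `D_ij = |v_i − v_j|` per axis (the Heaviside binarisation of classical
  recurrence plots is omitted), axes → RGB channels;
* **Modified multi-channel plot** — every value min–max scaled into
  [0, 255] and split digit-wise into one RGB pixel:
  R = ⌊v⌋, G = ⌊100·frac(v)⌋, B = ⌊10⁴·frac(v)⌋ mod 100, so
  R + G/100 + B/10⁴ ≈ v.

Each image passes through its own 5-block CNN (3×3 conv + ReLU + 2×2 max
pool; 64→32→16→8→4→2 spatial, final 2×2×64 map → 256 → dense 1024); the three
1024-d features are concatenated (3072) and classified through dense layers
of 256 and `n_classes` units with softmax.  Training: categorical
cross-entropy, Adam (lr 0.005, batch 8), reduce-on-plateau (×0.7 after >3
stagnant epochs on validation loss), validation-based model selection.
Evaluation is always subject-independent: no person appears in both training
and test data.  A 1-D convolutional mirror over the raw window serves as the
baseline, and a synthetic subject-grouped activity simulator (periodic gait,
posture transitions, six fall types, per-subject random effects) makes the
whole pipeline testable without access to clinical recordings.

The CNN engine is a compact, self-contained numpy implementation (im2col +
GEMM convolutions, float32), bit-reproducible for a fixed seed.

## Worked example

```python
import numpy as np
from harfusion import (four_class_config, simulate_dataset, split_by_subject,
                       reconstruct_all, FusionImageClassifier)
from harfusion.evaluation import encode_split, compute_metrics

# 4 activity classes (walking, jump rope, sitting down, forward fall),
# 40 subjects, 2 repetitions each -> 320 ten-second segments
segments = simulate_dataset(four_class_config(n_subjects=40, reps_per_class=2,
                                              seed=0))
split = split_by_subject(segments, test_fraction=0.2, val_fraction=0.2, seed=0)

def triples(part):
    imgs = encode_split(part)  # dict: method -> (n, 64, 64, 3) uint8
    return np.stack([imgs[m] for m in ("spectrogram", "rp", "mp")], axis=1)

labels = lambda part: np.array([s.label for s in part])
clf = FusionImageClassifier(epochs=10, seed=0)
clf.fit(triples(split.train), labels(split.train),
        validation_data=(triples(split.validation), labels(split.validation)))
probs = clf.predict_proba(triples(split.test))
idx = np.searchsorted(clf.classes_, labels(split.test))
report = compute_metrics(idx, probs)
print(f"top-1 {report.top1_accuracy:.3f}  top-3 {report.top3_accuracy:.3f}  "
      f"macro AUC {report.roc_auc:.3f}")
```

Output on one CPU (~3 min):

```
top-1 0.891  top-3 1.000  macro AUC 0.995
```

i.e. the fusion model labels 89 % of segments from eight never-seen subjects
correctly, the true activity is always within the top three candidates, and
class separation (one-vs-rest AUC) is near-perfect.  Replicate means over
several seeds are reported by the sweep harnesses
(`harfusion.evaluation.method_comparison`, `window_size_sweep`,
`noise_sweep`), which mirror the study protocols: single-encoding ablations
vs fusion, spectrogram window sizes 1/2/5/10 s, and Gaussian noise injected
into the raw test signals at fractions of the pooled signal sigma.

A command-line interface wraps the same pipeline:

```bash
harfusion simulate --classes WK,JR,SC,FF --subjects 40 --reps 2 --seed 0 --out data/
harfusion reconstruct --data data/segments.npz --out images/
harfusion train --data data/segments.npz --model fusion --epochs 10 --seed 0 --out run/
harfusion evaluate --model run/model.npz --data data/segments.npz --seed 0 --out eval/
harfusion sweep --data data/segments.npz --kind noise --seed 0 --out sweeps/
```

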