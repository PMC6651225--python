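# capsmi

Capsule networks for two-class motor-imagery EEG decoding.

When a person imagines moving their left or right hand, the sensorimotor
mu (8–12 Hz) and beta (16–31 Hz) rhythms recorded over the opposite
hemisphere are attenuated — event-related desynchronization (ERD). A
brain–computer interface can decode the imagined hand from three
electrodes (C3, Cz, C4) by detecting which hemisphere desynchronized.
`capsmi` implements a capsule-network classifier for this task, together
with the full preprocessing chain and a synthetic ERD trial generator so
the whole pipeline can be developed and validated without any recordings.

## The method

1. **Preprocessing** — each 3-channel trial is band-pass filtered 4–38 Hz
   (zero-phase 4th-order Butterworth) and the 0.5–2.5 s post-cue segment
   is extracted: 500 samples per channel at 250 Hz.
2. **Time–frequency imaging** — a magnitude STFT (Hann window 128,
   overlap 100) maps each channel to 65 bins × 14 frames; the 14 bins
   covering 7.81–33.20 Hz (mu + beta) are kept and min–max scaled, giving
   a 3×14×14 image per trial.
3. **Capsule network** — a SELU convolution (4 kernels 3×3) feeds a
   PrimaryCaps layer (128 channels of 4-dimensional capsules on a 5×5
   grid → 3200 capsules), routed by agreement into one 8-dimensional
   capsule per class. With prediction vectors û<sub>j|i</sub> = W<sub>ij</sub>u<sub>i</sub>,
   couplings c<sub>ij</sub> = softmax(b<sub>ij</sub>), s<sub>j</sub> = Σ<sub>i</sub> c<sub>ij</sub>û<sub>j|i</sub>
   and v<sub>j</sub> = squash(s<sub>j</sub>), the logits update by the agreement
   b<sub>ij</sub> ← b<sub>ij</sub> + û<sub>j|i</sub>·v<sub>j</sub>. The capsule norm ‖v<sub>j</sub>‖
   encodes class probability. Training minimizes the margin loss
   L<sub>k</sub> = T<sub>k</sub> max(0, m⁺−‖v<sub>k</sub>‖)² + λ(1−T<sub>k</sub>) max(0, ‖v<sub>k</sub>‖−m⁻)²
   (m⁺ = 0.9, m⁻ = 0.1, λ = 0.5) plus 0.0005 × the squared error of a
   3-layer decoder (512, 1024, 588 units) that reconstructs the input
   from the masked class capsule.
4. **Training** — classical momentum SGD (batch 50, lr 0.01, momentum
   0.7), optional early stopping on validation loss, plus a
   hyperparameter grid runner. A ShallowNet baseline (temporal/spatial
   convolutions, squaring, average pooling, log) trains on the raw
   epochs under the same loop.

Both networks are implemented in NumPy with exact hand-written
backpropagation — including through the unrolled routing iterations —
verified against central finite differences.

## Worked example

```python
import numpy as np
import capsmi as cm

# 100 synthetic trials/class with strong contralateral ERD
cfg = cm.SynthConfig(erd_depth=0.8, noise_sd=0.3)
train = cm.build_epochset(cm.synthesize_dataset(cfg, 100, seed=11))
test  = cm.build_epochset(cm.synthesize_dataset(cfg, 100, seed=12))

Xtr = cm.epochs_to_images(train.data).astype(np.float32)
Xte = cm.epochs_to_images(test.data).astype(np.float32)

model, hist = cm.train_model(Xtr, train.labels,
                             train_cfg=cm.TrainConfig(epochs=100, seed=7))
print(f"train loss {hist.train_loss[0]:.4f} -> {hist.train_loss[-1]:.4f}")
print(f"test accuracy {cm.evaluate(model, Xte, test.labels):.3f}")
```

prints

```
train loss 0.3236 -> 0.0451
test accuracy 1.000
```

The loss falls from the chance-level margin loss (~0.32) to near zero,
and the held-out accuracy reaches 1.0: with an 80% contralateral power
drop at moderate noise, the lateralized mu/beta pattern is fully
decodable. With `erd_depth=0` the same run stays at chance (~0.5).

scikit-learn users can compose the same pipeline as estimators:

```python
from sklearn.pipeline import Pipeline
pipe = Pipeline([("images", cm.SpectrogramImager()),
                 ("capsnet", cm.CapsNetClassifier(epochs=100, random_state=7))])
pipe.fit(train.data, train.labels)
```

A CLI covers the same flow: `capsmi simulate`, `capsmi prepare`,
`capsmi train`, `capsmi eval`, `capsmi grid`.

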