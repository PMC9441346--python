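# sadgan — adversarial retinal-vessel segmentation

`sadgan` segments the blood-vessel tree in retinal fundus photographs with a
generative-adversarial pair of convolutional networks:

- a **U-shaped generator** whose convolution blocks are SE-ResNet blocks
  (residual blocks channel-gated by squeeze-and-excitation, reduction
  r = 2) producing a per-pixel two-class softmax `S(x)`;
- a **discriminator** built from dilated-inception blocks (parallel 3×3
  branches at dilation rates 1/2/4, residual-fused), average-pooling
  down-sampling and CBAM attention (channel then spatial), ending in a
  fully connected softmax that scores a segmentation map's probability of
  being an expert ground truth, `D(·)`.

Training alternates the two networks at batch size 1.  The discriminator
minimizes the real/fake cross entropy

    L_D = −(1−q)·log(1 − D(S(x))) − q·log D(y),      q ∈ {0, 1},

and the generator minimizes the weighted segmentation loss

    L_seg = L_ce + λ_adv · L_adv,
    L_ce  = −Σ_{h,w} Σ_c y_{h,w,c} · log S(x)_{h,w,c},
    L_adv = −log D(S(x)),                             λ_adv = 0.1.

Both networks use Adam (generator lr 2.5·10⁻⁴, weight decay 10⁻⁴;
discriminator lr 10⁻⁴).  The package also implements the standard fundus
preprocessing chain (green channel → normalization → CLAHE → gamma),
rotation/flip augmentation, the 90/10 train/validation split, pixel-level
ACC/SE/SP/ROC_AUC/PR_AUC evaluation inside the field of view, and a
procedural **vessel-phantom generator** so the entire pipeline runs and is
tested without downloading the DRIVE / CHASE_DB1 datasets.  The networks run
on a small, fully tested NumPy autodiff engine (`sadgan.nn`) — no deep
learning framework is required.

It is intended for researchers working on fundus-image analysis who want a
transparent, dependency-light reference implementation of adversarial
segmentation training.

## Worked example

Train on synthetic phantoms and evaluate on held-out ones:

```python
from sadgan import VesselSegmenter, PhantomSpec, generate_dataset

samples = generate_dataset(PhantomSpec(height=96, width=96), 12, seed=1)
train, test = samples[:8], samples[8:]

est = VesselSegmenter(iterations=300, random_state=1).fit(train)
report = est.evaluate(test)
print(f"ACC={report.acc:.4f} SE={report.se:.4f} SP={report.sp:.4f} "
      f"ROC_AUC={report.roc_auc:.4f} PR_AUC={report.pr_auc:.4f}")
```

A run of this size (a few minutes on one CPU core) prints

```
ACC=0.9896 SE=0.9722 SP=0.9929 ROC_AUC=0.9975 PR_AUC=0.9900
```

ACC is the fraction of FOV pixels labeled correctly at threshold 0.5, SE the
fraction of true vessel pixels recovered, SP the fraction of background
pixels kept clean, and the two areas summarize the full threshold sweep of
the probability map (1.0 = perfect ranking).  On phantoms the task is much
easier than on real fundus images; these numbers validate the pipeline, not
clinical performance.

The same workflow is available from the shell:

```bash
sadgan phantom --n 12 --out data/ --seed 1 --height 96 --width 96
sadgan train --data data/ --out run/ --iterations 300 --seed 1
sadgan eval  --checkpoint run/checkpoint_last.npz --data data/ --out eval/
sadgan predict --checkpoint run/checkpoint_last.npz --data data/ --out pred/
```

Users with a local copy of DRIVE or CHASE_DB1 can launch the full published
recipe (20 000 iterations) with `scripts/reproduce_benchmarks.py`.

## Layout

| module | contents |
| --- | --- |
| `sadgan.nn` | NumPy reverse-mode autodiff: tensors, conv/pool/upsample, BN, Adam |
| `sadgan.preprocess` | green channel, normalization, CLAHE, gamma, augment, split, padding |
| `sadgan.generator` | SE-ResNet U-Net generator |
| `sadgan.discriminator` | dilated-inception + CBAM realness discriminator |
| `sadgan.losses` | discriminator, cross-entropy, adversarial and combined losses |
| `sadgan.training` | alternating loop, checkpoints, validation, JSONL logs |
| `sadgan.evaluate` | confusion counts, ACC/SE/SP, ROC/PR curves and areas, Dice |
| `sadgan.phantom` | synthetic branching-vessel phantom generator |
| `sadgan.estimator` | sklearn-style `VesselSegmenter` facade |
| `sadgan.cli` / `sadgan.config` | `sadgan` command-line interface and YAML configs |

Design notes, parameter conventions and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
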