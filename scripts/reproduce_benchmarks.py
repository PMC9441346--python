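#!/usr/bin/env python
"""Full-scale benchmark reproduction for users who have the public datasets.

This script is NOT part of the automated checks: it expects a local copy of
DRIVE and/or CHASE_DB1 in the loader layout (images/, labels/, masks/ — or
train/ and test/ subdirectories with that structure) and runs the complete
recipe: 20000 iterations at batch size 1, generator lr 2.5e-4 with weight
decay 1e-4, discriminator lr 1e-4, lambda_adv 0.1, with CLAHE/gamma
preprocessing and rotation/flip augmentation.  Expect a long run on CPU.

    python scripts/reproduce_benchmarks.py --data /path/to/DRIVE --out runs/drive
"""

from __future__ import annotations

import argparse
from pathlib import Path

from sadgan.config import load_config
from sadgan.data import load_split_dataset
from sadgan.evaluate import evaluate_samples
from sadgan.preprocess import split_train_val
from sadgan.training import fit, predict_sample


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--config", type=Path, default=None,
                    help="optional YAML overriding the published recipe")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--label-suffix", default=None,
                    help="e.g. '1stHO' to pick CHASE_DB1's first observer")
    args = ap.parse_args()

    cfgs = load_config(args.config, overrides={"training.seed": args.seed,
                                               "preprocess.seed": args.seed})
    train_all, test = load_split_dataset(args.data, args.label_suffix)
    train, val = split_train_val(train_all, cfgs.preprocess)
    gen, _, _ = fit(train, val, cfgs.generator, cfgs.discriminator,
                    cfgs.training, cfgs.preprocess, out_dir=args.out)

    held_out = test if test else val
    probs = [predict_sample(gen, s, cfgs.preprocess) for s in held_out]
    rep = evaluate_samples(probs, [s.vessel_mask for s in held_out],
                           [s.fov_mask for s in held_out])
    print(f"ACC={rep.acc:.4f} SE={rep.se:.4f} SP={rep.sp:.4f} "
          f"ROC_AUC={rep.roc_auc:.4f} PR_AUC={rep.pr_auc:.4f}")


if __name__ == "__main__":
    main()
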