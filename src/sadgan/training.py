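"""Alternating adversarial training.

Each iteration processes one image (batch size 1): the discriminator is
updated first on a ground-truth mask (q=1) and a detached generator output
(q=0); the generator is then updated on the combined segmentation loss
L_ce + lambda_adv * L_adv with gradients flowing through the (frozen)
discriminator.  Both networks use Adam; defaults follow the training recipe
this implementation reproduces: generator lr 2.5e-4 with weight decay 1e-4,
discriminator lr 1e-4, lambda_adv 0.1, 20000 iterations.

``fit`` adds on-the-fly augmentation, periodic validation (pooled ROC AUC on
the validation split, used to retain a best checkpoint) and JSONL loss
logging.  Runs are deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .data import RetinalSample
from .discriminator import Discriminator, DiscConfig
from .evaluate import evaluate_samples
from .generator import Generator, GenConfig
from .losses import LossConfig, adversarial_loss, cross_entropy_loss, discriminator_loss
from .preprocess import PreprocConfig, augment, pad_to_multiple, preprocess_image

__all__ = ["TrainConfig", "TrainingAbort", "prepare_pair", "train_step",
           "discriminator_half_step", "generator_half_step", "fit",
           "save_checkpoint", "load_checkpoint", "predict_sample"]


@dataclass
class TrainConfig:
    lr_generator: float = 2.5e-4
    lr_discriminator: float = 1e-4
    weight_decay: float = 1e-4
    lambda_adv: float = 0.1
    iterations: int = 20000
    batch_size: int = 1
    seed: int = 0
    val_every: int = 500
    checkpoint_every: int = 1000
    augment_data: bool = True
    decay_discriminator: bool = False   # weight decay on D too, if wanted
    loss_reduction: str = "mean"

    def validate(self) -> "TrainConfig":
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")
        if self.weight_decay < 0 or self.lambda_adv < 0:
            raise ValueError("weight_decay and lambda_adv must be nonnegative")
        if self.batch_size != 1:
            raise ValueError("training operates at batch size 1")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")
        return self


class TrainingAbort(RuntimeError):
    """Raised when a loss goes non-finite; carries the diagnostic record."""

    def __init__(self, record: dict):
        super().__init__(f"non-finite loss at iteration {record.get('iteration')}: {record}")
        self.record = record


def prepare_pair(sample: RetinalSample, pre_cfg: PreprocConfig, multiple: int
                 ) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]]:
    """Preprocess and pad one sample into a (image, truth, crop) training pair."""
    img = preprocess_image(sample, pre_cfg).astype(nn.DTYPE)
    img_p, crop = pad_to_multiple(img, multiple)
    truth_p, _ = pad_to_multiple(sample.vessel_mask.astype(np.uint8), multiple)
    return img_p, truth_p, crop


def discriminator_half_step(gen: Generator, disc: Discriminator, d_opt: nn.Adam,
                            x: Tensor, truth: np.ndarray,
                            loss_cfg: LossConfig) -> dict:
    """Update D on the ground truth (q=1) and a detached generator output (q=0).

    The generator's parameters receive no gradient (its forward pass runs
    with the graph disabled).
    """
    with nn.no_grad():
        fake_detached = gen(x).data[:, 1:2]           # positive-class plane
    d_opt.zero_grad()
    d_real = disc(Tensor(truth.astype(nn.DTYPE)[None, None]))
    d_fake = disc(Tensor(fake_detached))
    loss_d = discriminator_loss(d_on_real=d_real, q=1, epsilon=loss_cfg.epsilon) \
        + discriminator_loss(d_on_fake=d_fake, q=0, epsilon=loss_cfg.epsilon)
    loss_d.backward()
    d_opt.step()
    return {"loss_d": loss_d.item(),
            "d_real": float(np.mean(d_real.data)),
            "d_fake": float(np.mean(d_fake.data))}


def generator_half_step(gen: Generator, disc: Discriminator, g_opt: nn.Adam,
                        x: Tensor, truth: np.ndarray,
                        loss_cfg: LossConfig) -> dict:
    """Update G on L_ce + lambda_adv * L_adv with D frozen.

    Gradients of the adversarial term flow *through* the discriminator to
    the generator, but the discriminator's parameters are left untouched.
    """
    g_opt.zero_grad()
    prob = gen(x)                                     # (1,2,H,W)
    ce = cross_entropy_loss(prob, truth, reduction=loss_cfg.reduction,
                            epsilon=loss_cfg.epsilon)
    if loss_cfg.lambda_adv > 0:
        disc.requires_grad_(False)
        d_on_fake = disc(prob[:, 1:2, :, :])
        adv = adversarial_loss(d_on_fake, epsilon=loss_cfg.epsilon)
        loss_g = ce + loss_cfg.lambda_adv * adv
    else:
        adv = None
        loss_g = ce
    loss_g.backward()
    if loss_cfg.lambda_adv > 0:
        disc.requires_grad_(True)
        disc.zero_grad()                              # drop pass-through grads
    g_opt.step()
    return {"loss_ce": ce.item(),
            "loss_adv": adv.item() if adv is not None else 0.0,
            "loss_seg": loss_g.item()}


def train_step(gen: Generator, disc: Discriminator, g_opt: nn.Adam, d_opt: nn.Adam,
               image: np.ndarray, truth: np.ndarray, loss_cfg: LossConfig,
               iteration: int = 0) -> dict:
    """One alternating update (D half-step then G half-step) on one pair.

    ``image``: preprocessed, padded H×W float array; ``truth``: matching
    binary mask.  Returns the four logged losses.  Raises
    :class:`TrainingAbort` on a non-finite loss.
    """
    x = Tensor(image.astype(nn.DTYPE)[None, None])
    record = {"iteration": iteration}
    record.update(discriminator_half_step(gen, disc, d_opt, x, truth, loss_cfg))
    record.update(generator_half_step(gen, disc, g_opt, x, truth, loss_cfg))
    if not all(np.isfinite(v) for v in record.values() if isinstance(v, float)):
        raise TrainingAbort(record)
    return record


def predict_sample(gen: Generator, sample: RetinalSample,
                   pre_cfg: PreprocConfig) -> np.ndarray:
    """Positive-class probability map for one sample (H×W, original size)."""
    img = preprocess_image(sample, pre_cfg)
    return gen.predict_proba(img)[..., 1]


def _validate(gen: Generator, val: list[RetinalSample], pre_cfg: PreprocConfig):
    probs = [predict_sample(gen, s, pre_cfg) for s in val]
    truths = [s.vessel_mask for s in val]
    fovs = [s.fov_mask for s in val]
    return evaluate_samples(probs, truths, fovs)


def fit(train_samples: list[RetinalSample], val_samples: list[RetinalSample] | None = None,
        gen_cfg: GenConfig | None = None, disc_cfg: DiscConfig | None = None,
        train_cfg: TrainConfig | None = None, pre_cfg: PreprocConfig | None = None,
        out_dir: str | Path | None = None,
        resume_from: str | Path | None = None,
        ) -> tuple[Generator, Discriminator, list[dict]]:
    """Run the full adversarial loop; returns (generator, discriminator, log).

    When ``out_dir`` is given it receives a config snapshot, a JSONL loss
    log, periodic checkpoints, the final checkpoint and — when a validation
    split with improving pooled ROC AUC exists — a best checkpoint.

    ``resume_from`` restarts from a saved checkpoint: network weights and the
    iteration counter are restored, and iterations continue up to
    ``train_cfg.iterations`` with the same numbering a straight run would use
    (optimizer moments restart, so the continued loss values are not bitwise
    those of an uninterrupted run).
    """
    if not train_samples:
        raise ValueError("empty training set")
    train_cfg = (train_cfg or TrainConfig()).validate()
    gen_cfg = (gen_cfg or GenConfig(seed=train_cfg.seed)).validate()
    disc_cfg = (disc_cfg or DiscConfig(seed=train_cfg.seed + 1)).validate()
    pre_cfg = (pre_cfg or PreprocConfig(seed=train_cfg.seed)).validate()
    loss_cfg = LossConfig(lambda_adv=train_cfg.lambda_adv,
                          reduction=train_cfg.loss_reduction).validate()

    start_iteration = 0
    if resume_from is not None:
        gen, disc, start_iteration = load_checkpoint(resume_from)
        gen_cfg, disc_cfg = gen.cfg, disc.cfg if disc is not None else disc_cfg
        if disc is None:
            disc = Discriminator(disc_cfg)
    else:
        gen = Generator(gen_cfg)
        disc = Discriminator(disc_cfg)
    g_opt = nn.Adam(gen.parameters(), lr=train_cfg.lr_generator,
                    weight_decay=train_cfg.weight_decay)
    d_opt = nn.Adam(disc.parameters(), lr=train_cfg.lr_discriminator,
                    weight_decay=train_cfg.weight_decay if train_cfg.decay_discriminator else 0.0)

    rng = np.random.default_rng(train_cfg.seed)
    multiple = 2 ** max(gen_cfg.depth, disc_cfg.stages)
    out = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps({
            "generator": asdict(gen_cfg), "discriminator": asdict(disc_cfg),
            "training": asdict(train_cfg), "preprocess": asdict(pre_cfg),
        }, indent=2, default=list))
        log_fh = (out / "train_log.jsonl").open("w")

    log: list[dict] = []
    best_auc = -np.inf
    val_rows = []
    try:
        for it in range(start_iteration + 1, train_cfg.iterations + 1):
            sample = train_samples[int(rng.integers(len(train_samples)))]
            if train_cfg.augment_data:
                sample = augment(sample, pre_cfg, rng)
            image, truth, _ = prepare_pair(sample, pre_cfg, multiple)
            record = train_step(gen, disc, g_opt, d_opt, image, truth,
                                loss_cfg, iteration=it)
            log.append(record)
            if log_fh is not None:
                log_fh.write(json.dumps(record) + "\n")

            if val_samples and it % train_cfg.val_every == 0:
                rep = _validate(gen, val_samples, pre_cfg)
                val_rows.append({"iteration": it, **rep.__dict__})
                if out is not None and np.isfinite(rep.roc_auc) and rep.roc_auc > best_auc:
                    best_auc = rep.roc_auc
                    save_checkpoint(out / "checkpoint_best.npz", gen, disc, it,
                                    gen_cfg, disc_cfg)
            if out is not None and it % train_cfg.checkpoint_every == 0:
                save_checkpoint(out / f"checkpoint_{it:06d}.npz", gen, disc, it,
                                gen_cfg, disc_cfg)
    finally:
        if log_fh is not None:
            log_fh.close()

    if out is not None:
        save_checkpoint(out / "checkpoint_last.npz", gen, disc,
                        train_cfg.iterations, gen_cfg, disc_cfg)
        if val_rows:
            import csv
            with (out / "validation.csv").open("w", newline="") as fh:
                wr = csv.DictWriter(fh, fieldnames=list(val_rows[0]))
                wr.writeheader()
                wr.writerows(val_rows)
    return gen, disc, log


# ------------------------------------------------------------- checkpoints

def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator | None,
                    iteration: int, gen_cfg: GenConfig, disc_cfg: DiscConfig | None):
    arrays = {"gen." + k: v for k, v in gen.state_dict().items()}
    if disc is not None:
        arrays.update({"disc." + k: v for k, v in disc.state_dict().items()})
    meta = {"iteration": iteration, "gen_cfg": asdict(gen_cfg),
            "disc_cfg": asdict(disc_cfg) if disc_cfg else None}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[Generator, Discriminator | None, int]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        gcd = meta["gen_cfg"]
        gcd["plain_blocks"] = tuple(gcd["plain_blocks"])
        gen = Generator(GenConfig(**gcd))
        gen.load_state_dict({k[4:]: z[k] for k in z.files if k.startswith("gen.")})
        disc = None
        if meta["disc_cfg"] is not None:
            dcd = meta["disc_cfg"]
            dcd["dilation_rates"] = tuple(dcd["dilation_rates"])
            disc = Discriminator(DiscConfig(**dcd))
            dkeys = {k[5:]: z[k] for k in z.files if k.startswith("disc.")}
            if dkeys:
                disc.load_state_dict(dkeys)
    return gen, disc, int(meta["iteration"])
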