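"""Scikit-learn style estimator facade over the adversarial pipeline.

:class:`VesselSegmenter` bundles preprocessing, the generator/discriminator
pair, the adversarial training loop and the evaluation metrics behind the
familiar ``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface, so
the whole method composes with sklearn model-selection tooling.  The X of
``fit`` is a list of :class:`~sadgan.data.RetinalSample`; labels travel
inside the samples, so ``y`` is accepted and ignored.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import RetinalSample
from .discriminator import DiscConfig
from .evaluate import evaluate_samples
from .generator import GenConfig
from .preprocess import PreprocConfig, split_train_val
from .training import TrainConfig, fit as _fit, predict_sample

__all__ = ["VesselSegmenter"]


class VesselSegmenter(BaseEstimator):
    """Adversarially trained retinal-vessel segmenter.

    Parameters mirror the module configs: generator width/SE reduction,
    discriminator stages/attention, learning rates, adversarial weight and
    iteration count.  After ``fit`` the trained networks are available as
    ``generator_`` and ``discriminator_`` and the loss log as ``history_``.
    """

    def __init__(self, base_channels: int = 16, se_reduction: int = 2,
                 disc_stages: int = 4, disc_base_channels: int = 32,
                 attn_reduction: int = 8, spatial_kernel: int = 7,
                 lr_generator: float = 2.5e-4, lr_discriminator: float = 1e-4,
                 weight_decay: float = 1e-4, lambda_adv: float = 0.1,
                 iterations: int = 20000, val_fraction: float = 0.1,
                 gamma: float = 1.2, clahe_clip_limit: float = 0.01,
                 augment_data: bool = True, random_state: int = 0):
        self.base_channels = base_channels
        self.se_reduction = se_reduction
        self.disc_stages = disc_stages
        self.disc_base_channels = disc_base_channels
        self.attn_reduction = attn_reduction
        self.spatial_kernel = spatial_kernel
        self.lr_generator = lr_generator
        self.lr_discriminator = lr_discriminator
        self.weight_decay = weight_decay
        self.lambda_adv = lambda_adv
        self.iterations = iterations
        self.val_fraction = val_fraction
        self.gamma = gamma
        self.clahe_clip_limit = clahe_clip_limit
        self.augment_data = augment_data
        self.random_state = random_state

    # ------------------------------------------------------------------ api
    def _configs(self):
        pre = PreprocConfig(gamma=self.gamma, clahe_clip_limit=self.clahe_clip_limit,
                            val_fraction=self.val_fraction, seed=self.random_state)
        gen = GenConfig(base_channels=self.base_channels,
                        se_reduction=self.se_reduction, seed=self.random_state)
        disc = DiscConfig(stages=self.disc_stages,
                          base_channels=self.disc_base_channels,
                          attn_reduction=self.attn_reduction,
                          spatial_kernel=self.spatial_kernel,
                          seed=self.random_state + 1)
        train = TrainConfig(lr_generator=self.lr_generator,
                            lr_discriminator=self.lr_discriminator,
                            weight_decay=self.weight_decay,
                            lambda_adv=self.lambda_adv,
                            iterations=self.iterations,
                            seed=self.random_state,
                            augment_data=self.augment_data)
        return pre, gen, disc, train

    def fit(self, X: list[RetinalSample], y=None, out_dir=None):
        if not X:
            raise ValueError("fit requires at least one sample")
        pre, gen_cfg, disc_cfg, train_cfg = self._configs()
        if len(X) >= 2:
            train, val = split_train_val(list(X), pre)
            if not val:
                train, val = list(X), None
        else:
            train, val = list(X), None
        gen, disc, log = _fit(train, val, gen_cfg, disc_cfg, train_cfg, pre,
                              out_dir=out_dir)
        self.generator_ = gen
        self.discriminator_ = disc
        self.history_ = log
        self.preproc_config_ = pre
        return self

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise AttributeError("this VesselSegmenter is not fitted yet; call fit first")

    def predict_proba(self, X: list[RetinalSample]) -> list[np.ndarray]:
        """Per-sample H×W positive-class (vessel) probability maps."""
        self._check_fitted()
        return [predict_sample(self.generator_, s, self.preproc_config_) for s in X]

    def predict(self, X: list[RetinalSample], threshold: float = 0.5) -> list[np.ndarray]:
        """Binary vessel masks at the given probability threshold."""
        return [(p >= threshold).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X: list[RetinalSample], y=None) -> float:
        """Pooled ROC AUC over the FOV pixels of X."""
        self._check_fitted()
        probs = self.predict_proba(X)
        rep = evaluate_samples(probs, [s.vessel_mask for s in X],
                               [s.fov_mask for s in X])
        return rep.roc_auc

    def evaluate(self, X: list[RetinalSample], threshold: float = 0.5):
        """Full metrics report (ACC/SE/SP/ROC_AUC/PR_AUC) pooled over X."""
        self._check_fitted()
        probs = self.predict_proba(X)
        return evaluate_samples(probs, [s.vessel_mask for s in X],
                                [s.fov_mask for s in X], threshold=threshold)
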