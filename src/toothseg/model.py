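"""Model/Results facade over the network, trainer and evaluator.

Follows the fit-and-results idiom of statistical modelling packages: a
:class:`ToothSegmentation` object owns the data and configuration, its
:meth:`~ToothSegmentation.fit` returns a :class:`ToothSegmentationResults`
carrying the trained network, the loss trace, the split manifest, prediction
and evaluation methods and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np

from .network import (NetworkConfig, SEIBEDNetwork, softmax_to_binary,
                      threshold_predictions)
from .synthetic import sample_dataset
from .training import TrainConfig, fit as _fit, split_dataset
from .evaluation import MetricsReport, per_tooth_report, pixel_confusion_matrix

__all__ = ["ToothSegmentation", "ToothSegmentationResults"]


class ToothSegmentation:
    """A trainable multi-label tooth segmentation model bound to a dataset.

    Parameters
    ----------
    samples
        Sequence of ``(image, masks)`` pairs; images are (H, W) grayscale in
        [0, 1] with H, W divisible by 32, masks are
        :class:`~toothseg.synthetic.ToothMaskStack` or (H, W, 32) arrays.
    network_config, train_config
        Architecture and optimization settings; defaults are the reference
        architecture and a 200-epoch Adam recipe.
    """

    def __init__(self, samples, network_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None) -> None:
        if len(samples) == 0:
            raise ValueError("no samples provided")
        self.samples = list(samples)
        self.network_config = network_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_synthetic(cls, n: int, seed: int = 0,
                       network_config: NetworkConfig | None = None,
                       train_config: TrainConfig | None = None,
                       **scene_kwargs) -> "ToothSegmentation":
        """Build the model on freshly generated synthetic scenes."""
        samples = sample_dataset(n, seed=seed, **scene_kwargs)
        return cls(samples, network_config, train_config)

    def fit(self, holdout: bool = True, callback=None) -> "ToothSegmentationResults":
        """Train the network; with ``holdout`` a split_fraction train/test
        split is made first, otherwise the model trains on every sample."""
        cfg = self.train_config
        ids = list(range(len(self.samples)))
        if holdout and len(ids) >= 2:
            train_ids, test_ids = split_dataset(ids, cfg.split_fraction, cfg.seed)
        else:
            train_ids, test_ids = ids, []
        net = SEIBEDNetwork(self.network_config, seed=cfg.seed)
        result = _fit(net, [self.samples[i] for i in train_ids], cfg,
                      callback=callback)
        result.train_ids, result.test_ids = train_ids, test_ids
        return ToothSegmentationResults(self, result)


class ToothSegmentationResults:
    """Fitted model: trained parameters, loss trace, split, and scoring."""

    def __init__(self, model: ToothSegmentation, fit_result) -> None:
        self.model = model
        self.network = fit_result.model
        self.loss_trace = fit_result.loss_trace
        self.train_ids = fit_result.train_ids
        self.test_ids = fit_result.test_ids

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]

    def predict(self, images) -> np.ndarray:
        """Binary (N, H, W, 32) masks for a batch of grayscale images."""
        stack = self.network.forward(np.asarray(images, dtype=np.float32))
        if stack.activation == "sigmoid":
            return threshold_predictions(stack, self.network.config.threshold)
        return softmax_to_binary(stack)

    def predict_proba(self, images):
        """Raw probability stack (sigmoid planes or softmax classes)."""
        return self.network.forward(np.asarray(images, dtype=np.float32))

    def _subset(self, ids):
        imgs = np.stack([np.asarray(self.model.samples[i][0], dtype=np.float32)
                         for i in ids])
        planes = np.stack([np.asarray(getattr(self.model.samples[i][1], "planes",
                                              self.model.samples[i][1]))
                           for i in ids])
        return imgs, planes

    def evaluate(self, on: str = "test") -> MetricsReport:
        """Per-tooth report on the held-out test split (or ``on='train'``)."""
        ids = self.test_ids if on == "test" else self.train_ids
        if not ids:
            raise ValueError(f"no samples in the {on!r} split")
        imgs, planes = self._subset(ids)
        return per_tooth_report(self.predict(imgs), planes)

    def confusion_matrix(self, on: str = "test", threshold: float | None = None):
        if self.network.config.activation != "sigmoid":
            raise ValueError("confusion matrix is defined for the sigmoid head")
        ids = self.test_ids if on == "test" else self.train_ids
        imgs, planes = self._subset(ids)
        t = self.network.config.threshold if threshold is None else threshold
        return pixel_confusion_matrix(self.predict_proba(imgs).probs, planes, t)

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        cfg = self.network.config
        tcfg = self.model.train_config
        lines = [
            "Tooth Segmentation Results",
            "=" * 56,
            f"backbone:        {cfg.encoder.backbone} "
            f"(taps {', '.join(map(str, cfg.encoder.tap_depths))})",
            f"head:            {cfg.activation} ({cfg.out_channels} channels), "
            f"threshold {cfg.threshold}",
            f"branch width:    {cfg.seib.branch_width} "
            f"(fused depth {4 * 3 * cfg.seib.branch_width})",
            f"optimizer:       {tcfg.optimizer}, lr {tcfg.learning_rate}, "
            f"batch {tcfg.batch_size}, {len(self.loss_trace)} epochs, "
            f"seed {tcfg.seed}",
            f"samples:         {len(self.model.samples)} "
            f"(train {len(self.train_ids)} / test {len(self.test_ids)})",
            f"loss ({tcfg.loss}): first {self.loss_trace[0]:.4f} "
            f"-> final {self.final_loss:.4f}",
        ]
        eval_on = "test" if self.test_ids else "train"
        try:
            avg = self.evaluate(on=eval_on).average
            lines.append("-" * 56)
            lines.append(f"macro metrics on {eval_on} split (%):")
            lines.append("  " + "  ".join(f"{k} {v:.2f}" for k, v in avg.items()))
        except ValueError:
            pass
        return "\n".join(lines)
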