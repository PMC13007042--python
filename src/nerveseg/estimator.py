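"""Scikit-learn style estimator wrapping the training and inference pipeline.

``NerveSegmenter`` is a thin, pipeline-compatible facade over
:func:`nerveseg.unet.train_model` and :func:`nerveseg.inference.predict_volume`:
``fit`` consumes paired lists of intensity and label volumes, ``predict``
returns label volumes, ``score`` reports the mean foreground Dice. All
configuration objects are constructor parameters, so ``get_params`` /
``set_params`` / ``clone`` work as usual.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .inference import BlendConfig, predict_volume
from .io import IntensityVolume, LabelVolume
from .losses import LossConfig
from .metrics.overlap import dice_coefficient
from .unet import ArchitectureConfig, AugmentationConfig, TrainingConfig, train_model

__all__ = ["NerveSegmenter"]


def _as_intensity(x) -> IntensityVolume:
    return x if isinstance(x, IntensityVolume) else IntensityVolume(np.asarray(x))


def _as_labels(y) -> LabelVolume:
    return y if isinstance(y, LabelVolume) else LabelVolume(np.asarray(y))


class NerveSegmenter(BaseEstimator):
    """3-class nerve segmenter (background / fascicle / epineurium).

    Parameters
    ----------
    arch, training, augmentation, loss
        Configuration dataclasses; ``None`` selects the desk-scale defaults
        (:meth:`ArchitectureConfig.scaled`, :meth:`TrainingConfig.scaled`).
    validation_fraction
        Fraction of the fitted corpus held out for in-training validation
        when fewer than two volumes would remain, the last volume is used.
    random_state
        Overrides ``training.seed`` when given.

    Attributes
    ----------
    network_ : UNet3D
        The trained network.
    history_ : pandas.DataFrame
        Per-epoch loss components and validation Dice.

    Examples
    --------
    >>> from nerveseg.phantom import PhantomSpec, generate_phantom
    >>> phantoms = [generate_phantom(PhantomSpec(seed=s)) for s in range(3)]
    >>> seg = NerveSegmenter().fit([p.image for p in phantoms],
    ...                            [p.labels for p in phantoms])
    >>> pred = seg.predict([phantoms[0].image])[0]
    """

    def __init__(
        self,
        arch: ArchitectureConfig | None = None,
        training: TrainingConfig | None = None,
        augmentation: AugmentationConfig | None = None,
        loss: LossConfig | None = None,
        blend: BlendConfig | None = None,
        validation_fraction: float = 0.25,
        random_state: int | None = None,
    ):
        self.arch = arch
        self.training = training
        self.augmentation = augmentation
        self.loss = loss
        self.blend = blend
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _configs(self):
        from dataclasses import replace

        arch = self.arch or ArchitectureConfig.scaled()
        training = self.training or TrainingConfig.scaled()
        if self.random_state is not None:
            training = replace(training, seed=int(self.random_state))
        blend = self.blend or BlendConfig(patch_size=training.patch_size)
        return arch, training, self.augmentation, self.loss, blend

    def fit(self, X: Sequence, y: Sequence) -> "NerveSegmenter":
        """Train on paired intensity (X) and label (y) volumes."""
        if len(X) != len(y):
            raise ValueError(f"got {len(X)} images but {len(y)} label volumes")
        if len(X) < 2:
            raise ValueError("need at least two volumes (train + validation)")
        pairs = [(_as_intensity(xi), _as_labels(yi)) for xi, yi in zip(X, y)]
        for iv, lv in pairs:
            if iv.shape != lv.shape:
                raise ValueError(f"image/label shape mismatch: {iv.shape} vs {lv.shape}")
        arch, training, aug, loss, _ = self._configs()
        n_val = max(1, int(round(len(pairs) * self.validation_fraction)))
        n_val = min(n_val, len(pairs) - 1)
        train_pairs, val_pairs = pairs[:-n_val], pairs[-n_val:]
        self.network_, self.history_ = train_model(
            train_pairs, val_pairs, arch, training, aug, loss
        )
        return self

    def predict(self, X: Sequence) -> list[LabelVolume]:
        """Predict label volumes for a list of intensity volumes."""
        self._check_fitted()
        _, _, _, _, blend = self._configs()
        return [predict_volume(_as_intensity(x), self.network_, blend)[1] for x in X]

    def predict_proba(self, X: Sequence) -> list[np.ndarray]:
        """Per-voxel class probabilities ``(class, z, y, x)`` per volume."""
        self._check_fitted()
        _, _, _, _, blend = self._configs()
        return [predict_volume(_as_intensity(x), self.network_, blend)[0] for x in X]

    def score(self, X: Sequence, y: Sequence) -> float:
        """Mean foreground (fascicle + epineurium) Dice over the volumes."""
        preds = self.predict(X)
        scores = []
        for pred, truth in zip(preds, (_as_labels(t) for t in y)):
            for c in (1, 2):
                scores.append(dice_coefficient(pred.labels == c, truth.labels == c))
        return float(np.mean(scores))

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("this NerveSegmenter instance is not fitted yet")
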