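"""Synthetic score-vector generator.

Emulates the softmax outputs a convolutional feature extractor would emit
for labelled images: for a sample of true class ``c`` the score vector is a
Dirichlet draw with concentration ``concentration_true`` at position ``c``
and ``concentration_other`` elsewhere.  Dirichlet draws live on the
probability simplex by construction, and the ratio of the two
concentrations is a single separability knob: equal concentrations give
chance-level class structure, large ratios give near-one-hot vectors.

Defaults (``concentration_true=50``, ``concentration_other=1``,
``n_per_class=200``) describe a confident but imperfect upstream network
whose argmax Bayes accuracy is above 99%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scores import LabelledDataset

__all__ = ["GeneratorConfig", "generate", "bayes_accuracy"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_class: int = 200
    n_classes: int = 4
    concentration_true: float = 50.0
    concentration_other: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.concentration_true <= 0 or self.concentration_other <= 0:
            raise ValueError("Dirichlet concentrations must be positive")

    def alpha(self, label: int) -> np.ndarray:
        a = np.full(self.n_classes, self.concentration_other)
        a[label] = self.concentration_true
        return a


def generate(config: GeneratorConfig) -> LabelledDataset:
    """Draw a balanced labelled dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    blocks, labels = [], []
    for c in range(config.n_classes):
        blocks.append(rng.dirichlet(config.alpha(c), size=config.n_per_class))
        labels.append(np.full(config.n_per_class, c, dtype=np.int64))
    return LabelledDataset(np.concatenate(blocks), np.concatenate(labels))


def bayes_accuracy(config: GeneratorConfig, n_mc: int = 10_000) -> float:
    """Monte-Carlo accuracy of the argmax rule under the generator.

    This is the ceiling any downstream classifier of the generated scores
    can reach; labels are drawn in balanced blocks like :func:`generate`.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(config.seed)
    per = n_mc // config.n_classes
    hits = 0
    total = 0
    for c in range(config.n_classes):
        draws = rng.dirichlet(config.alpha(c), size=per)
        hits += int(np.sum(np.argmax(draws, axis=1) == c))
        total += per
    return hits / total
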