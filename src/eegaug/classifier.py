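"""Downstream emotion classifier: a small convolutional network whose every
convolution and dense layer is followed by an adaptive-normalization layer
(AdaBN). During training the normalization uses batch statistics; at
prediction time the statistics are recomputed in one pass over the target
domain's data, which aligns the distributions of real, generated, and test
samples without touching the learned affine parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (DTYPE, Adam, BatchNorm, Conv2d, Dense, Flatten, ReLU,
                  Sequential)


@dataclass
class ClassifierConfig:
    """Widths mirror the generative discriminator stack; dense head 128."""

    n_classes: int = 3
    base_channels: int = 64
    dense_width: int = 128
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    pool_domains: bool = False   # treat real+generated as one training domain


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class EmotionClassifier:
    """Conv stack -> dense(128) -> softmax(K), AdaBN after every layer."""

    def __init__(self, in_shape: tuple, config: ClassifierConfig):
        self.config = config
        self.in_shape = tuple(in_shape)
        rng = np.random.default_rng(config.seed)
        c, b = in_shape[0], config.base_channels
        side = in_shape[1] // 8
        self.net = Sequential([
            Conv2d(c, b, rng), BatchNorm(b), ReLU(),
            Conv2d(b, 2 * b, rng), BatchNorm(2 * b), ReLU(),
            Conv2d(2 * b, 4 * b, rng), BatchNorm(4 * b), ReLU(),
            Flatten(),
            Dense(4 * b * side * side, config.dense_width, rng),
            BatchNorm(config.dense_width), ReLU(),
            Dense(config.dense_width, config.n_classes, rng),
        ])
        self._bn_layers = [l for l in self.net.layers if isinstance(l, BatchNorm)]
        self.domain_stats: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self.trained = False
        self._embed_cut = len(self.net.layers) - 1   # penultimate activations

    # ------------------------------------------------------------ training
    def fit(self, maps: np.ndarray, labels: np.ndarray,
            domains: np.ndarray | None = None) -> list[float]:
        """Cross-entropy training with Adam; returns per-epoch mean loss.

        After the optimization pass, normalization statistics are computed
        once per training domain tag and stored under that tag.
        """
        x = np.asarray(maps, dtype=DTYPE)
        y = np.asarray(labels, dtype=np.int64)
        if x.shape[0] < 2 or len(np.unique(y)) < 2:
            raise ValueError("training needs >= 2 samples from >= 2 classes")
        cfg = self.config
        if domains is None:
            domains = np.zeros(len(y), dtype=np.int64)
        domains = np.asarray(domains)
        if cfg.pool_domains:
            domains = np.zeros(len(y), dtype=np.int64)
        rng = np.random.default_rng(cfg.seed)
        opt = Adam([self.net], lr=cfg.learning_rate)
        self.net.set_training(True)
        n, B = len(y), min(cfg.batch_size, len(y))
        losses = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n - B + 1, B):
                idx = order[start:start + B]
                logits = self.net.forward(x[idx])
                probs = _softmax(logits)
                epoch_loss += -float(np.mean(
                    np.log(np.maximum(probs[np.arange(len(idx)), y[idx]], 1e-12))))
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits = (dlogits / len(idx)).astype(DTYPE)
                opt.zero_grad()
                self.net.backward(dlogits)
                opt.step()
            losses.append(epoch_loss / max(n // B, 1))
        # accumulate per-domain running statistics (one pass per domain)
        for tag in np.unique(domains):
            self.domain_stats[str(tag)] = self._collect_stats(x[domains == tag])
        self.trained = True
        return losses

    def _collect_stats(self, x: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        self.net.set_training(True)     # batch-statistics mode
        self.net.forward(np.asarray(x, dtype=DTYPE))
        return [tuple(np.array(s) for s in bn.last_stats) for bn in self._bn_layers]

    # ----------------------------------------------------------- inference
    def _predict_with_stats(self, x: np.ndarray,
                            stats: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        self.net.set_training(False)
        for bn, (mean, var) in zip(self._bn_layers, stats):
            bn.set_stats(mean, var)
        logits = self.net.forward(np.asarray(x, dtype=DTYPE))
        self.net.set_training(True)
        return _softmax(logits)

    def adapt_and_predict(self, maps: np.ndarray,
                          domain: str = "test") -> np.ndarray:
        """Recompute normalization statistics from this domain's maps
        (adaptive batch normalization), store them under ``domain``, and
        return class posteriors computed with those statistics."""
        if not self.trained:
            raise RuntimeError("classifier is not trained")
        x = np.asarray(maps, dtype=DTYPE)
        if x.shape[0] == 0:
            raise ValueError("empty input")
        self.domain_stats[domain] = self._collect_stats(x)
        return self._predict_with_stats(x, self.domain_stats[domain])

    def predict_proba(self, maps: np.ndarray,
                      domain: str | None = None) -> np.ndarray:
        """Posteriors using stored statistics for ``domain`` (default: the
        first training domain)."""
        if not self.trained:
            raise RuntimeError("classifier is not trained")
        key = domain if domain is not None else sorted(self.domain_stats)[0]
        return self._predict_with_stats(maps, self.domain_stats[key])

    def embed(self, maps: np.ndarray, domain: str | None = None) -> np.ndarray:
        """Penultimate-layer activations — the FID feature embedding."""
        if not self.trained:
            raise RuntimeError("classifier is not trained")
        key = domain if domain is not None else sorted(self.domain_stats)[0]
        self.net.set_training(False)
        for bn, (mean, var) in zip(self._bn_layers, self.domain_stats[key]):
            bn.set_stats(mean, var)
        h = np.asarray(maps, dtype=DTYPE)
        for layer in self.net.layers[:self._embed_cut]:
            h = layer.forward(h)
        self.net.set_training(True)
        return h


def train_classifier(maps, labels, config: ClassifierConfig,
                     domains=None) -> EmotionClassifier:
    maps = np.asarray(maps, dtype=DTYPE)
    clf = EmotionClassifier(tuple(maps.shape[1:]), config)
    clf.fit(maps, labels, domains)
    return clf


def accuracy(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Argmax match rate; np.argmax resolves ties toward the lowest index."""
    posteriors = np.asarray(posteriors)
    labels = np.asarray(labels)
    if posteriors.shape[0] != labels.shape[0]:
        raise ValueError("posteriors and labels lengths differ")
    if posteriors.shape[0] == 0:
        raise ValueError("empty input")
    return float(np.mean(np.argmax(posteriors, axis=1) == labels))
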