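"""Generated-sample quality scores: Inception Score, FID, and MMD.

The Inception-v3 backbone of the original scores is replaced by the
package's own EEG map classifier: IS uses its class posteriors, FID the
Gaussian (Wasserstein-2) distance between embeddings from its penultimate
dense layer, and MMD an RBF-kernel two-sample distance on flattened maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KernelSpec:
    """RBF kernel k(x, y) = exp(-||x - y||^2 / (2 h^2)). ``bandwidth=None``
    selects h by the median heuristic over pooled pairwise distances."""

    name: str = "rbf"
    bandwidth: float | None = None


@dataclass
class QualityReport:
    is_value: float
    fid_value: float
    mmd_value: float
    kernel: KernelSpec
    n_real: int
    n_generated: int

    def as_dict(self) -> dict:
        return {"is": self.is_value, "fid": self.fid_value,
                "mmd": self.mmd_value, "kernel": self.kernel.name,
                "bandwidth": self.kernel.bandwidth,
                "n_real": self.n_real, "n_generated": self.n_generated}


def inception_score(pred_probs: np.ndarray, atol: float = 1e-6) -> float:
    """exp of the mean KL between conditional and marginal class posteriors.

    Bounded by 1 <= IS <= K. Posteriors collapsed onto a single class give
    IS = 1 because the marginal collapses with them — with this substituted
    classifier the marginal term does expose total collapse, but a high IS
    alone still does not certify diversity.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("pred_probs must be (n, K)")
    if (p < -atol).any() or not np.allclose(p.sum(axis=1), 1.0, atol=atol):
        raise ValueError("rows must be probability vectors")
    p = np.clip(p, 0.0, None)
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(marginal))
    kl = np.where(p > 0, terms, 0.0).sum(axis=1)
    return float(np.exp(kl.mean()))


def fid(real: np.ndarray, generated: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet (Wasserstein-2) distance between Gaussian moment fits.

    ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}) on sample means
    and covariances; ``eps`` * I regularizes the covariances before the
    matrix square root.
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    generated = np.atleast_2d(np.asarray(generated, dtype=np.float64))
    if real.shape[1] != generated.shape[1]:
        raise ValueError("embedding dimensions differ")
    mu_r, mu_g = real.mean(axis=0), generated.mean(axis=0)
    cov_r = np.atleast_2d(np.cov(real, rowvar=False)) + eps * np.eye(real.shape[1])
    cov_g = np.atleast_2d(np.cov(generated, rowvar=False)) + eps * np.eye(real.shape[1])
    sqrt_prod = np.asarray(linalg.sqrtm(cov_r @ cov_g))
    if not np.isfinite(sqrt_prod).all():
        raise linalg.LinAlgError(
            "matrix square root did not converge; covariance condition "
            f"numbers {np.linalg.cond(cov_r):.2e}, {np.linalg.cond(cov_g):.2e}")
    if np.iscomplexobj(sqrt_prod):
        sqrt_prod = sqrt_prod.real
    value = (np.sum((mu_r - mu_g) ** 2)
             + np.trace(cov_r) + np.trace(cov_g) - 2.0 * np.trace(sqrt_prod))
    return float(max(value, 0.0))


def median_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Median pooled pairwise distance; falls back to 1 when degenerate."""
    pooled = np.concatenate([x, y])
    d = cdist(pooled, pooled)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med if med > 0 else 1.0


def mmd(real: np.ndarray, generated: np.ndarray,
        kernel: KernelSpec = KernelSpec()) -> float:
    """Biased squared-MMD two-sample estimator with an RBF kernel:

    mean k(x, x') + mean k(y, y') - 2 mean k(x, y).
    """
    x = np.atleast_2d(np.asarray(real, dtype=np.float64))
    y = np.atleast_2d(np.asarray(generated, dtype=np.float64))
    if x.shape[1] != y.shape[1]:
        raise ValueError("sample dimensions differ")
    if kernel.name != "rbf":
        raise ValueError(f"unsupported kernel {kernel.name!r}")
    h = kernel.bandwidth if kernel.bandwidth is not None else median_bandwidth(x, y)
    gamma = 1.0 / (2.0 * h * h)
    kxx = np.exp(-gamma * cdist(x, x, "sqeuclidean"))
    kyy = np.exp(-gamma * cdist(y, y, "sqeuclidean"))
    kxy = np.exp(-gamma * cdist(x, y, "sqeuclidean"))
    return float(max(kxx.mean() + kyy.mean() - 2.0 * kxy.mean(), 0.0))


def evaluate_quality(real_maps: np.ndarray, gen_maps: np.ndarray,
                     classifier, kernel: KernelSpec = KernelSpec(),
                     ) -> QualityReport:
    """Bundle the three scores the way the augmentation study uses them:
    IS on the classifier's posteriors for generated maps, FID on its
    penultimate-layer embeddings, MMD on flattened raw maps."""
    real_maps = np.asarray(real_maps, dtype=np.float32)
    gen_maps = np.asarray(gen_maps, dtype=np.float32)
    probs = classifier.predict_proba(gen_maps)
    emb_real = classifier.embed(real_maps)
    emb_gen = classifier.embed(gen_maps)
    spec = kernel
    if spec.bandwidth is None:
        flat_r = real_maps.reshape(len(real_maps), -1)
        flat_g = gen_maps.reshape(len(gen_maps), -1)
        spec = KernelSpec(name=kernel.name,
                          bandwidth=median_bandwidth(flat_r, flat_g))
    else:
        flat_r = real_maps.reshape(len(real_maps), -1)
        flat_g = gen_maps.reshape(len(gen_maps), -1)
    return QualityReport(
        is_value=inception_score(probs),
        fid_value=fid(emb_real, emb_gen),
        mmd_value=mmd(flat_r, flat_g, spec),
        kernel=spec,
        n_real=len(real_maps),
        n_generated=len(gen_maps),
    )
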