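"""Training loop for VAE-D2GAN, the per-emotion model strategy, and
assembly of augmented training sets.

One iteration performs three alternating updates on a real mini-batch x:

  1. ascend  L_D1 = alpha E[log D1(x)] - E[D1(G(z))] - E[D1(G(z_p))]  in D1,
  2. ascend  L_D2 = beta E[log D2(G(z_p))] + beta E[log D2(G(z))] - E[D2(x)]  in D2,
  3. jointly descend  L_KL + L_Rec  in the encoder and  L_Rec + L_G  in the
     generator (VAE and GAN share G, so its gradient has both parts),

with z = mu + gamma ⊙ exp(log_sigma) from the encoder and z_p ~ N(0, I).
Gradients are evaluated analytically through the layer engine; the whole
loop is a pure function of (data, config.seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import generative as gen
from ._nn import DTYPE, Adam
from .generative import SCORE_FLOOR, GenerativeModel, LossReport, NetworkSpec


@dataclass
class TrainConfig:
    """Optimization settings. Defaults follow the published recipe
    (Adam, learning rate 1e-4, batch size 16); iteration count and network
    width are problem-size choices left to the caller."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    iterations: int = 2000
    alpha: float = 0.2
    beta: float = 0.1
    latent_dim: int = 128
    base_channels: int = 64
    seed: int = 0
    updates_per_step: int = 1          # discriminator updates per iteration
    spec: NetworkSpec | None = None    # overrides latent_dim/base_channels

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.updates_per_step < 1:
            raise ValueError("updates_per_step must be >= 1")

    def resolve_spec(self, in_shape: tuple) -> NetworkSpec:
        if self.spec is not None:
            return self.spec
        return NetworkSpec(kind="conv", in_shape=in_shape,
                           latent_dim=self.latent_dim,
                           base_channels=self.base_channels)


def _as_array(maps) -> np.ndarray:
    """Accept (n, ...) arrays or sequences of TopoMap-like objects."""
    if isinstance(maps, np.ndarray):
        return np.ascontiguousarray(maps, dtype=DTYPE)
    first = maps[0]
    if hasattr(first, "image"):
        return np.stack([m.image for m in maps]).astype(DTYPE)
    return np.stack([np.asarray(m) for m in maps]).astype(DTYPE)


def train_vae_d2gan(real_maps, config: TrainConfig,
                    seed: int | None = None) -> tuple[GenerativeModel, list[LossReport]]:
    """Fit one VAE-D2GAN on a single emotion's maps.

    Returns the trained model and the per-iteration loss history. Fully
    reproducible: two calls with the same data and seed produce bitwise
    identical histories and parameters.
    """
    data = _as_array(real_maps)
    n = data.shape[0]
    B = config.batch_size
    if n < B:
        raise ValueError(f"need at least batch_size={B} maps, got {n}")
    seed = config.seed if seed is None else seed
    spec = config.resolve_spec(tuple(data.shape[1:]))
    model = GenerativeModel(spec=spec, alpha=config.alpha, beta=config.beta,
                            seed=seed)
    rng = np.random.default_rng(seed)
    d = spec.latent_dim
    alpha, beta = np.float32(config.alpha), np.float32(config.beta)

    opt_d1 = Adam([model.d1], lr=config.learning_rate)
    opt_d2 = Adam([model.d2], lr=config.learning_rate)
    opt_eg = Adam([model.encoder, model.generator], lr=config.learning_rate)

    history: list[LossReport] = []
    invB = np.float32(1.0 / B)
    for it in range(config.iterations):
        x = data[rng.choice(n, B, replace=False)]

        # ---- encode + generate once; caches reused by every backward below
        mu, ls = model.encoder.forward(x)
        gamma = rng.standard_normal((B, d)).astype(DTYPE)
        z_enc = mu + gamma * np.exp(ls)
        z_p = rng.standard_normal((B, d)).astype(DTYPE)
        xg = model.generator.forward(np.concatenate([z_enc, z_p]))
        x_rec, x_gp = xg[:B], xg[B:]

        l_kl = gen.loss_kl(gen.LatentCode(mu=mu, log_sigma=ls))
        l_rec = gen.loss_rec(x, x_rec)

        xcat = np.concatenate([x, xg])

        for _ in range(config.updates_per_step):
            # ---- D1 step (maximize L_D1 -> minimize its negation)
            s1 = np.maximum(model.d1.forward(xcat)[:, 0], SCORE_FLOOR)
            ds1 = np.empty((3 * B, 1), dtype=DTYPE)
            ds1[:B, 0] = -alpha * invB / s1[:B]
            ds1[B:, 0] = invB
            opt_d1.zero_grad()
            model.d1.backward(ds1)
            opt_d1.step()

            # ---- D2 step
            s2 = np.maximum(model.d2.forward(xcat)[:, 0], SCORE_FLOOR)
            ds2 = np.empty((3 * B, 1), dtype=DTYPE)
            ds2[:B, 0] = invB
            ds2[B:, 0] = -beta * invB / s2[B:]
            opt_d2.zero_grad()
            model.d2.backward(ds2)
            opt_d2.step()

        l_d1 = float(alpha * np.log(s1[:B]).mean() - s1[B:2 * B].mean() - s1[2 * B:].mean())
        l_d2 = float(beta * np.log(s2[2 * B:]).mean() + beta * np.log(s2[B:2 * B]).mean()
                     - s2[:B].mean())

        # ---- joint E+G step against the freshly updated discriminators
        s1g = np.maximum(model.d1.forward(xg)[:, 0], SCORE_FLOOR)
        s2g = np.maximum(model.d2.forward(xg)[:, 0], SCORE_FLOOR)
        l_g = float(-(s1g[:B].mean() + s1g[B:].mean())
                    + beta * (np.log(s2g[:B]).mean() + np.log(s2g[B:]).mean()))

        dxg_adv = model.d1.backward(np.full((2 * B, 1), -invB, dtype=DTYPE))
        dxg_adv = dxg_adv + model.d2.backward((beta * invB / s2g)[:, None].astype(DTYPE))

        opt_eg.zero_grad()
        # pass 1: reconstruction gradient only; its dz flows into the encoder
        d_rec = np.zeros_like(xg)
        d_rec[:B] = (2.0 * invB) * (x_rec - x)
        dz = model.generator.backward(d_rec)[:B]
        # pass 2: adversarial gradient; parameters accumulate, dz discarded
        # (the encoder descends L_KL + L_Rec only)
        model.generator.backward(dxg_adv)

        dmu = (invB * mu + dz).astype(DTYPE)
        dls = (invB * (np.exp(2.0 * ls) - 1.0) + dz * gamma * np.exp(ls)).astype(DTYPE)
        model.encoder.backward(dmu, dls)
        opt_eg.step()

        report = LossReport(l_kl=l_kl, l_rec=l_rec, l_g=l_g, l_d1=l_d1, l_d2=l_d2)
        if not np.isfinite(report.total):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: {report.as_dict()}")
        history.append(report)

    return model, history


# ------------------------------------------------------- per-emotion plan

@dataclass
class AugmentationPlan:
    """One independently trained generative model per emotion class."""

    models: dict[int, GenerativeModel] = field(default_factory=dict)
    samples_per_emotion: int = 8000
    seed: int = 0
    histories: dict[int, list[LossReport]] = field(default_factory=dict, repr=False)

    @property
    def classes(self) -> list[int]:
        return sorted(self.models)


def fit_augmentation_plan(maps, labels, config: TrainConfig,
                          samples_per_emotion: int = 8000) -> AugmentationPlan:
    """Train one VAE-D2GAN per observed emotion class on that class's maps.

    Model seeds are ``config.seed + class_index`` so the models are
    independent yet reproducible.
    """
    data = _as_array(maps)
    labels = np.asarray(labels)
    plan = AugmentationPlan(samples_per_emotion=samples_per_emotion,
                            seed=config.seed)
    for cls in np.unique(labels):
        cls = int(cls)
        subset = data[labels == cls]
        if subset.shape[0] < config.batch_size:
            raise ValueError(
                f"class {cls} has {subset.shape[0]} maps, fewer than "
                f"batch_size={config.batch_size}")
        model, hist = train_vae_d2gan(subset, config, seed=config.seed + cls)
        plan.models[cls] = model
        plan.histories[cls] = hist
    return plan


def generate_augmented_set(plan: AugmentationPlan,
                           n_per_emotion: int | None = None,
                           chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Draw z_p ~ N(0, I) through each class's trained generator.

    Returns (maps, labels) with exactly ``n_per_emotion`` maps per class,
    clipped to the [0, 1] image codomain for image models.
    """
    if not plan.models:
        raise ValueError("augmentation plan has no trained models")
    n_per = plan.samples_per_emotion if n_per_emotion is None else int(n_per_emotion)
    all_maps, all_labels = [], []
    for cls in plan.classes:
        model = plan.models[cls]
        rng = np.random.default_rng([plan.seed, cls])
        out = []
        for start in range(0, n_per, chunk):
            m = min(chunk, n_per - start)
            z = rng.standard_normal((m, model.latent_dim)).astype(DTYPE)
            out.append(gen.generate(model, z))
        if out:
            maps = np.concatenate(out)
            if model.spec.kind == "conv":
                np.clip(maps, 0.0, 1.0, out=maps)
            all_maps.append(maps)
            all_labels.append(np.full(n_per, cls, dtype=np.int64))
    if not all_maps:
        shape = next(iter(plan.models.values())).spec.in_shape
        return np.empty((0,) + shape, dtype=DTYPE), np.empty(0, dtype=np.int64)
    return np.concatenate(all_maps), np.concatenate(all_labels)


def _largest_remainder(n: int, pools: dict[int, int]) -> dict[int, int]:
    """Class-balanced apportionment of n draws, capped by pool sizes."""
    classes = sorted(pools)
    K = len(classes)
    quota = n / K
    alloc = {c: int(np.floor(quota)) for c in classes}
    rem = n - sum(alloc.values())
    frac = quota - np.floor(quota)
    order = sorted(classes, key=lambda c: (-frac, c))
    for c in order[:rem]:
        alloc[c] += 1
    # cap at pool sizes; push the deficit to classes with spare samples
    deficit = 0
    for c in classes:
        if alloc[c] > pools[c]:
            deficit += alloc[c] - pools[c]
            alloc[c] = pools[c]
    if deficit:
        warnings.warn("generated pool is class-imbalanced; using the "
                      "nearest balanced subset", stacklevel=3)
        while deficit:
            spare = [c for c in classes if alloc[c] < pools[c]]
            if not spare:
                raise ValueError("not enough generated samples to draw from")
            take = min(spare, key=lambda c: (alloc[c], c))
            alloc[take] += 1
            deficit -= 1
    return alloc


def assemble_training_set(real_maps, real_labels, gen_maps, gen_labels,
                          n_generated: int, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real set plus a class-balanced random subset of generated maps.

    Returns shuffled (maps, labels, domain) where domain is 0 for real and
    1 for generated samples (used by the classifier's adaptive
    normalization). ``n_generated = 0`` reduces to the real set alone.
    """
    real_maps = _as_array(real_maps) if len(real_maps) else np.asarray(real_maps)
    real_labels = np.asarray(real_labels, dtype=np.int64)
    gen_labels = np.asarray(gen_labels, dtype=np.int64)
    if n_generated > len(gen_labels):
        raise ValueError("n_generated exceeds the generated pool")
    rng = np.random.default_rng(seed)
    if n_generated > 0:
        gen_maps = _as_array(gen_maps)
        pools = {int(c): int((gen_labels == c).sum()) for c in np.unique(gen_labels)}
        alloc = _largest_remainder(int(n_generated), pools)
        pick = []
        for cls in sorted(alloc):
            idx = np.flatnonzero(gen_labels == cls)
            pick.append(rng.choice(idx, alloc[cls], replace=False))
        pick = np.concatenate(pick)
        x = np.concatenate([real_maps, gen_maps[pick]])
        y = np.concatenate([real_labels, gen_labels[pick]])
        dom = np.concatenate([np.zeros(len(real_labels), dtype=np.int64),
                              np.ones(len(pick), dtype=np.int64)])
    else:
        x, y = real_maps.copy(), real_labels.copy()
        dom = np.zeros(len(real_labels), dtype=np.int64)
    order = rng.permutation(len(y))
    return x[order], y[order], dom[order]
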