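"""VAE-D2GAN: four networks and the loss terms of their four-player game.

The model couples a variational auto-encoder (encoder ``E``, generator /
decoder ``G``) with a dual-discriminator GAN. ``D1`` rewards samples that
look like real data; ``D2`` rewards samples that look generated. The
generator has to please both, which penalizes missing modes (through D1's
coverage pressure) and off-distribution output (through D2) at the same
time — the design's answer to mode collapse.

Losses (batch means, discriminator outputs kept strictly positive by a
final softplus so every logarithm is defined):

    L_KL  = E[ KL( N(mu, diag e^{2 log_sigma}) || N(0, I) ) ]
    L_Rec = E[ || x - G(z) ||^2 ],  z = mu + gamma ⊙ exp(log_sigma)
    L_G   = -(E[D1(G(z))] + E[D1(G(z_p))]) + beta (E[log D2(G(z))] + E[log D2(G(z_p))])
    L_D1  = alpha E[log D1(x)] - E[D1(G(z))] - E[D1(G(z_p))]          (maximized)
    L_D2  = beta E[log D2(G(z_p))] + beta E[log D2(G(z))] - E[D2(x)]  (maximized)

with hyperparameters 0 < alpha, beta <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (Conv2d, ConvTranspose2d, Dense, Flatten, ReLU, Reshape,
                  Sequential, Softplus)

DTYPE = _nn.DTYPE


# ------------------------------------------------------------ architecture

@dataclass(frozen=True)
class NetworkSpec:
    """Shared architecture description for E, G, D1 and D2.

    ``kind='conv'`` is the image model: three 5x5 stride-2 convolutions
    (base_channels -> 2x -> 4x) with ReLU, a dense layer, and the mirrored
    transposed-convolution stack in the generator whose final activation is
    ReLU (the sample space is [0,1] images). ``kind='dense'`` is a small
    fully-connected adaptation for low-dimensional diagnostics; its
    generator ends linear because toy samples are signed.
    """

    kind: str = "conv"                      # 'conv' | 'dense'
    in_shape: tuple = (5, 32, 32)
    latent_dim: int = 128
    base_channels: int = 64                 # conv models
    hidden: tuple = (128, 128)              # dense models
    init_std: float | None = None   # None = He-scaled (propagation-preserving)

    def __post_init__(self):
        if self.kind not in ("conv", "dense"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "conv" and (len(self.in_shape) != 3 or self.in_shape[1] % 8):
            raise ValueError("conv models need (C, H, W) input with H, W divisible by 8")

    @property
    def flat_dim(self) -> int:
        return int(np.prod(self.in_shape))


def table1_spec(latent_dim: int = 128, base_channels: int = 64,
                in_shape: tuple = (5, 32, 32)) -> NetworkSpec:
    """The published image architecture (64->128->256 channels, latent 128)."""
    return NetworkSpec(kind="conv", in_shape=in_shape, latent_dim=latent_dim,
                       base_channels=base_channels)


def dense_spec(input_dim: int = 2, latent_dim: int = 8,
               hidden: tuple = (64, 64)) -> NetworkSpec:
    return NetworkSpec(kind="dense", in_shape=(input_dim,),
                       latent_dim=latent_dim, hidden=hidden)


def _conv_trunk(spec: NetworkSpec, rng) -> tuple[Sequential, int]:
    c, b = spec.in_shape[0], spec.base_channels
    side = spec.in_shape[1] // 8
    layers = [Conv2d(c, b, rng, std=spec.init_std), ReLU(),
              Conv2d(b, 2 * b, rng, std=spec.init_std), ReLU(),
              Conv2d(2 * b, 4 * b, rng, std=spec.init_std), ReLU(),
              Flatten()]
    return Sequential(layers), 4 * b * side * side


def _dense_trunk(spec: NetworkSpec, rng) -> tuple[Sequential, int]:
    layers: list = []
    n = spec.in_shape[0]
    for h in spec.hidden:
        layers += [Dense(n, h, rng, std=spec.init_std), ReLU()]
        n = h
    return Sequential(layers), n


class Encoder:
    """Trunk + two parallel dense heads producing mu and log sigma."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        trunk, feat = (_conv_trunk if spec.kind == "conv" else _dense_trunk)(spec, rng)
        self.trunk = trunk
        self.head_mu = Dense(feat, spec.latent_dim, rng, std=spec.init_std)
        self.head_ls = Dense(feat, spec.latent_dim, rng, std=spec.init_std)
        self.spec = spec

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(x)
        return self.head_mu.forward(h), self.head_ls.forward(h)

    def backward(self, dmu: np.ndarray, dls: np.ndarray) -> np.ndarray:
        dh = self.head_mu.backward(dmu) + self.head_ls.backward(dls)
        return self.trunk.backward(dh)

    # Sequential-compatible surface so Adam/checkpoints can treat it uniformly
    def zero_grad(self):
        self.trunk.zero_grad()
        self.head_mu.zero_grad()
        self.head_ls.zero_grad()

    def param_items(self):
        yield from self.trunk.param_items()
        for tag, layer in (("mu", self.head_mu), ("ls", self.head_ls)):
            for name, v in layer.params.items():
                yield (tag, name), v, layer.grads[name]

    def state_dict(self):
        state = {f"trunk.{i}.{n}": v for (i, n), v, _ in self.trunk.param_items()}
        for tag, layer in (("mu", self.head_mu), ("ls", self.head_ls)):
            for n, v in layer.params.items():
                state[f"{tag}.{n}"] = v
        return state

    def load_state_dict(self, state):
        for (i, n), v, _ in self.trunk.param_items():
            v[...] = state[f"trunk.{i}.{n}"]
        for tag, layer in (("mu", self.head_mu), ("ls", self.head_ls)):
            for n, v in layer.params.items():
                v[...] = state[f"{tag}.{n}"]


def build_generator(spec: NetworkSpec, rng) -> Sequential:
    if spec.kind == "conv":
        c, b = spec.in_shape[0], spec.base_channels
        side = spec.in_shape[1] // 8
        return Sequential([
            Dense(spec.latent_dim, 4 * b * side * side, rng, std=spec.init_std), ReLU(),
            Reshape((4 * b, side, side)),
            ConvTranspose2d(4 * b, 2 * b, rng, std=spec.init_std), ReLU(),
            ConvTranspose2d(2 * b, b, rng, std=spec.init_std), ReLU(),
            ConvTranspose2d(b, c, rng, std=spec.init_std), ReLU(),
        ])
    layers: list = []
    n = spec.latent_dim
    for h in spec.hidden:
        layers += [Dense(n, h, rng, std=spec.init_std), ReLU()]
        n = h
    layers.append(Dense(n, spec.in_shape[0], rng, std=spec.init_std))
    return Sequential(layers)


def build_discriminator(spec: NetworkSpec, rng) -> Sequential:
    trunk, feat = (_conv_trunk if spec.kind == "conv" else _dense_trunk)(spec, rng)
    return Sequential(trunk.layers + [Dense(feat, 1, rng, std=spec.init_std), Softplus()])


# ------------------------------------------------------------------ model

@dataclass
class LatentCode:
    """Batched variational posterior parameters; ``z`` once realized."""

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray | None = None


@dataclass
class LossReport:
    l_kl: float
    l_rec: float
    l_g: float
    l_d1: float
    l_d2: float

    @property
    def l_vae(self) -> float:
        return self.l_kl + self.l_rec

    @property
    def total(self) -> float:
        return self.l_vae + self.l_g + self.l_d1 + self.l_d2

    def as_dict(self) -> dict:
        return {"l_kl": self.l_kl, "l_rec": self.l_rec, "l_vae": self.l_vae,
                "l_g": self.l_g, "l_d1": self.l_d1, "l_d2": self.l_d2}


@dataclass
class GenerativeModel:
    """Encoder, generator and the two non-parameter-sharing discriminators."""

    spec: NetworkSpec
    alpha: float = 0.2
    beta: float = 0.1
    seed: int = 0
    encoder: Encoder = field(init=False, repr=False)
    generator: Sequential = field(init=False, repr=False)
    d1: Sequential = field(init=False, repr=False)
    d2: Sequential = field(init=False, repr=False)

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0 and 0.0 < self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in (0, 1]")
        rng = np.random.default_rng(self.seed)
        self.encoder = Encoder(self.spec, rng)
        self.generator = build_generator(self.spec, rng)
        self.d1 = build_discriminator(self.spec, rng)
        self.d2 = build_discriminator(self.spec, rng)

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim

    def _check_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.shape[1:] != self.spec.in_shape:
            raise ValueError(f"expected samples of shape {self.spec.in_shape}, "
                             f"got {x.shape[1:]}")
        return x


def encode(model: GenerativeModel, x: np.ndarray) -> LatentCode:
    """Variational posterior parameters (mu, log sigma) for a batch."""
    mu, ls = model.encoder.forward(model._check_x(x))
    return LatentCode(mu=mu, log_sigma=ls)


def reparameterize(code: LatentCode, gamma: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> LatentCode:
    """z = mu + gamma ⊙ exp(log_sigma), gamma ~ N(0, I) when not supplied."""
    if gamma is None:
        rng = rng if rng is not None else np.random.default_rng()
        gamma = rng.standard_normal(code.mu.shape)
    gamma = np.asarray(gamma, dtype=DTYPE)
    if gamma.shape != code.mu.shape:
        raise ValueError("gamma shape must match mu")
    z = code.mu + gamma * np.exp(code.log_sigma)
    return LatentCode(mu=code.mu, log_sigma=code.log_sigma, z=z.astype(DTYPE))


def generate(model: GenerativeModel, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=DTYPE)
    if z.ndim != 2 or z.shape[1] != model.latent_dim:
        raise ValueError(f"latent batch must be (n, {model.latent_dim})")
    return model.generator.forward(z)


def discriminate(model: GenerativeModel, which: int, x: np.ndarray) -> np.ndarray:
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    net = model.d1 if which == 1 else model.d2
    return net.forward(model._check_x(x))[:, 0]


# ------------------------------------------------------------------ losses

def loss_kl(code: LatentCode) -> float:
    """Closed-form KL(N(mu, diag e^{2 log_sigma}) || N(0, I)), batch mean."""
    mu, ls = code.mu, code.log_sigma
    per = 0.5 * np.sum(mu ** 2 + np.exp(2.0 * ls) - 1.0 - 2.0 * ls, axis=1)
    return float(np.mean(per))


def loss_rec(x: np.ndarray, x_rec: np.ndarray) -> float:
    x, x_rec = np.asarray(x), np.asarray(x_rec)
    if x.shape != x_rec.shape:
        raise ValueError("shape mismatch between x and x_rec")
    diff = (x - x_rec).reshape(x.shape[0], -1).astype(np.float64)
    return float(np.mean(np.sum(diff ** 2, axis=1)))


#: floor applied to discriminator scores inside logs/reciprocals; softplus
#: guarantees positivity mathematically but underflows to 0 in float32
SCORE_FLOOR = 1e-6


def _scores(model, which, x):
    return np.maximum(discriminate(model, which, x).astype(np.float64),
                      SCORE_FLOOR)


def loss_generator(model: GenerativeModel, x_real: np.ndarray,
                   z_enc: np.ndarray, z_p: np.ndarray) -> float:
    """L_G = -L_GD1 + beta * L_GD2 (to be minimized by G)."""
    g_enc = generate(model, z_enc)
    g_p = generate(model, z_p)
    l_gd1 = _scores(model, 1, g_enc).mean() + _scores(model, 1, g_p).mean()
    l_gd2 = (np.log(_scores(model, 2, g_enc)).mean()
             + np.log(_scores(model, 2, g_p)).mean())
    return float(-l_gd1 + model.beta * l_gd2)


def loss_d1(model: GenerativeModel, x_real: np.ndarray,
            x_gen_enc: np.ndarray, x_gen_p: np.ndarray) -> float:
    """alpha E[log D1(x)] - E[D1(gen_enc)] - E[D1(gen_p)] (D1 maximizes this)."""
    return float(model.alpha * np.log(_scores(model, 1, x_real)).mean()
                 - _scores(model, 1, x_gen_enc).mean()
                 - _scores(model, 1, x_gen_p).mean())


def loss_d2(model: GenerativeModel, x_real: np.ndarray,
            x_gen_enc: np.ndarray, x_gen_p: np.ndarray) -> float:
    """beta E[log D2(gen_p)] + beta E[log D2(gen_enc)] - E[D2(x)] (maximized)."""
    return float(model.beta * np.log(_scores(model, 2, x_gen_p)).mean()
                 + model.beta * np.log(_scores(model, 2, x_gen_enc)).mean()
                 - _scores(model, 2, x_real).mean())


def total_objective(model: GenerativeModel, x_real: np.ndarray,
                    rng: np.random.Generator | None = None) -> LossReport:
    """Every component of the four-player objective on one real mini-batch."""
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    x_real = model._check_x(x_real)
    code = reparameterize(encode(model, x_real), rng=rng)
    z_p = rng.standard_normal((x_real.shape[0], model.latent_dim)).astype(DTYPE)
    x_rec = generate(model, code.z)
    x_gp = generate(model, z_p)
    return LossReport(
        l_kl=loss_kl(code),
        l_rec=loss_rec(x_real, x_rec),
        l_g=loss_generator(model, x_real, code.z, z_p),
        l_d1=loss_d1(model, x_real, x_rec, x_gp),
        l_d2=loss_d2(model, x_real, x_rec, x_gp),
    )


# -------------------------------------------------------------- checkpoint

def save_checkpoint(path, model: GenerativeModel) -> None:
    """Single-file checkpoint with an embedded, self-describing config block."""
    import json

    spec = model.spec
    config = {"kind": spec.kind, "in_shape": list(spec.in_shape),
              "latent_dim": spec.latent_dim, "base_channels": spec.base_channels,
              "hidden": list(spec.hidden), "init_std": spec.init_std,
              "alpha": model.alpha, "beta": model.beta, "seed": model.seed}
    arrays = {}
    for tag, net in (("E", model.encoder), ("G", model.generator),
                     ("D1", model.d1), ("D2", model.d2)):
        for key, value in net.state_dict().items():
            arrays[f"{tag}/{key}"] = value
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> GenerativeModel:
    import json

    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    spec = NetworkSpec(kind=config["kind"], in_shape=tuple(config["in_shape"]),
                       latent_dim=config["latent_dim"],
                       base_channels=config["base_channels"],
                       hidden=tuple(config["hidden"]), init_std=config["init_std"])
    model = GenerativeModel(spec=spec, alpha=config["alpha"],
                            beta=config["beta"], seed=config["seed"])
    for tag, net in (("E", model.encoder), ("G", model.generator),
                     ("D1", model.d1), ("D2", model.d2)):
        net.load_state_dict({k.split("/", 1)[1]: v for k, v in arrays.items()
                             if k.startswith(tag + "/")})
    return model
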