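"""Conditional adversarial networks mapping non-EEG features to EEG features.

Three variants share one architecture family:

* **CGAN** — the discriminator ends in a sigmoid and both networks minimise
  the usual cross-entropy objectives.
* **CWGAN** — the critic outputs an unbounded score; losses are the
  Wasserstein surrogate ``mean D(fake) - mean D(real)`` (critic) and
  ``-mean D(fake)`` (generator), with weight clipping enforcing Lipschitz-1.
* **CWGAN-GP** — as CWGAN but Lipschitz-1 is enforced by a gradient penalty
  ``lambda * E[(||grad_xhat D(xhat, y)||_2 - 1)^2]`` on random interpolates
  between real and generated samples.

The generator consumes ``[z, s, one-hot y]`` — noise, the non-EEG feature
row and the emotion label — and grows its representation through residual
blocks whose output is concatenated to their input (linear -> batch norm ->
ReLU). The critic consumes ``[x, one-hot y]`` through
linear -> LeakyReLU(0.2) -> dropout(0.5) layers. All training runs on the
in-repo autodiff engine; everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, grad
from .data import MultimodalDataset, ScalerState
from .fidelity import euclidean_rowwise, empirical_wasserstein

__all__ = [
    "VARIANTS",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "HatlModel",
    "default_specs",
    "generator_forward",
    "discriminator_forward",
    "adversarial_losses",
    "gradient_penalty",
    "train_hatl",
    "synthesize_eeg",
]

VARIANTS = ("cgan", "cwgan", "cwgan-gp")

# Generator / critic widths per dataset family (mini is the test profile).
_GEN_BLOCKS = {"seedv": (64, 128, 256), "deap": (128, 128),
               "graffitivr": (64, 64), "mini": (32, 32)}
_DISC_LAYERS = {"seedv": (128, 64), "deap": (64, 64),
                "graffitivr": (32, 32), "mini": (32, 32)}


@dataclass(frozen=True)
class GeneratorSpec:
    block_units: tuple[int, ...]
    noise_dim: int
    label_dim: int
    cond_dim: int
    out_dim: int

    def __post_init__(self):
        dims = (self.noise_dim, self.label_dim, self.cond_dim, self.out_dim,
                *self.block_units)
        if any(d <= 0 for d in dims):
            raise ValueError("all generator dimensions must be positive")

    @property
    def in_dim(self) -> int:
        return self.noise_dim + self.cond_dim + self.label_dim

    def block_input_width(self, k: int) -> int:
        """Input width of block k under concatenative residual growth."""
        return self.in_dim + sum(self.block_units[:k])

    @property
    def final_in_dim(self) -> int:
        return self.block_input_width(len(self.block_units))


@dataclass(frozen=True)
class DiscriminatorSpec:
    layer_units: tuple[int, ...]
    in_dim: int  # n_eeg + label_dim
    leaky_slope: float = 0.2
    dropout: float = 0.5
    final_sigmoid: bool = False

    def __post_init__(self):
        if any(u <= 0 for u in self.layer_units) or self.in_dim <= 0:
            raise ValueError("discriminator widths must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 1e-6
    betas: tuple[float, float] = (0.5, 0.9)
    epochs: int = 100
    batch_size: int = 64
    n_critic: int | None = None  # default: 5 for Wasserstein variants, 1 for CGAN
    gp_lambda: float = 10.0
    clip_value: float = 0.01
    noise_dim: int = 32
    holdout_rows: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("positive learning rate and batch size required")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")

    def critic_steps(self, variant: str) -> int:
        if self.n_critic is not None:
            return self.n_critic
        return 1 if variant == "cgan" else 5


def default_specs(schema, n_classes: int,
                  config: TrainConfig) -> tuple[GeneratorSpec, DiscriminatorSpec]:
    gen = GeneratorSpec(
        block_units=_GEN_BLOCKS.get(schema.name, (64, 64)),
        noise_dim=config.noise_dim, label_dim=n_classes,
        cond_dim=schema.n_noneeg, out_dim=schema.n_eeg)
    disc = DiscriminatorSpec(
        layer_units=_DISC_LAYERS.get(schema.name, (64, 64)),
        in_dim=schema.n_eeg + n_classes)
    return gen, disc


# ---------------------------------------------------------------------------
# Network modules
# ---------------------------------------------------------------------------

def _he_init(rng, fan_in, fan_out):
    return rng.normal(scale=math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class _Linear:
    def __init__(self, rng, fan_in, fan_out):
        self.W = Tensor(_he_init(rng, fan_in, fan_out))
        self.b = Tensor(np.zeros(fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class _BatchNorm:
    """1-D batch normalisation; batch statistics in training, running in eval."""

    def __init__(self, width, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(width))
        self.beta = Tensor(np.zeros(width))
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class Generator:
    """Residual-growth generator: each block's output is concatenated to its input."""

    def __init__(self, spec: GeneratorSpec, rng):
        self.spec = spec
        self.blocks = []
        for k, units in enumerate(spec.block_units):
            lin = _Linear(rng, spec.block_input_width(k), units)
            self.blocks.append((lin, _BatchNorm(units)))
        self.head = _Linear(rng, spec.final_in_dim, spec.out_dim)

    def forward(self, z: Tensor, s: Tensor, y_onehot: Tensor,
                training: bool) -> Tensor:
        h = concat([z, s, y_onehot], axis=1)
        for lin, bn in self.blocks:
            out = bn(lin(h), training).relu()
            h = concat([h, out], axis=1)
        return self.head(h)

    @property
    def params(self):
        ps = []
        for lin, bn in self.blocks:
            ps += lin.params + bn.params
        return ps + self.head.params

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (lin, bn) in enumerate(self.blocks):
            out[f"g_lin{i}_W"], out[f"g_lin{i}_b"] = lin.W.data, lin.b.data
            out[f"g_bn{i}_gamma"], out[f"g_bn{i}_beta"] = bn.gamma.data, bn.beta.data
            out[f"g_bn{i}_rmean"], out[f"g_bn{i}_rvar"] = bn.running_mean, bn.running_var
        out["g_head_W"], out["g_head_b"] = self.head.W.data, self.head.b.data
        return out

    def load_state_arrays(self, arrays):
        for i, (lin, bn) in enumerate(self.blocks):
            lin.W.data = arrays[f"g_lin{i}_W"]
            lin.b.data = arrays[f"g_lin{i}_b"]
            bn.gamma.data = arrays[f"g_bn{i}_gamma"]
            bn.beta.data = arrays[f"g_bn{i}_beta"]
            bn.running_mean = arrays[f"g_bn{i}_rmean"]
            bn.running_var = arrays[f"g_bn{i}_rvar"]
        self.head.W.data = arrays["g_head_W"]
        self.head.b.data = arrays["g_head_b"]


class Discriminator:
    def __init__(self, spec: DiscriminatorSpec, rng):
        self.spec = spec
        widths = [spec.in_dim, *spec.layer_units]
        self.layers = [_Linear(rng, a, b) for a, b in zip(widths, widths[1:])]
        self.head = _Linear(rng, widths[-1], 1)

    def forward(self, x: Tensor, y_onehot: Tensor, training: bool,
                rng=None) -> Tensor:
        """Returns the pre-sigmoid score (logit), one scalar per row."""
        h = concat([x, y_onehot], axis=1)
        for lin in self.layers:
            h = lin(h).leaky_relu(self.spec.leaky_slope)
            if training and self.spec.dropout > 0:
                keep = 1.0 - self.spec.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * Tensor(mask)
        return self.head(h)

    @property
    def params(self):
        ps = []
        for lin in self.layers:
            ps += lin.params
        return ps + self.head.params

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lin in enumerate(self.layers):
            out[f"d_lin{i}_W"], out[f"d_lin{i}_b"] = lin.W.data, lin.b.data
        out["d_head_W"], out["d_head_b"] = self.head.W.data, self.head.b.data
        return out

    def load_state_arrays(self, arrays):
        for i, lin in enumerate(self.layers):
            lin.W.data = arrays[f"d_lin{i}_W"]
            lin.b.data = arrays[f"d_lin{i}_b"]
        self.head.W.data = arrays["d_head_W"]
        self.head.b.data = arrays["d_head_b"]


class _Adam:
    def __init__(self, params, lr, betas, weight_decay):
        self.params = params
        self.lr, self.b1, self.b2 = lr, betas[0], betas[1]
        self.wd = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data + self.wd * p.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + 1e-8)


@dataclass
class HatlModel:
    """A trained (or initialised) generator/critic pair plus provenance."""

    variant: str
    generator: Generator
    discriminator: Discriminator
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    config: TrainConfig
    schema_hash: str
    n_classes: int
    trained: bool = False
    history: dict[str, list[float]] = field(default_factory=dict)
    eeg_scaler: ScalerState | None = None
    noneeg_scaler: ScalerState | None = None
    # rows of the training dataset reserved for the epoch-wise fidelity
    # history (never used for updates); useful for post-hoc evaluation
    holdout_idx: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.disc_spec.final_sigmoid != (self.variant == "cgan"):
            raise ValueError("final_sigmoid must be set iff variant is cgan")


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    out = np.zeros((y.size, k))
    out[np.arange(y.size), y] = 1.0
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generator_forward(model: HatlModel, z: np.ndarray, s: np.ndarray,
                      y: np.ndarray) -> np.ndarray:
    """Inference-mode generator pass (running batch-norm statistics, no clip)."""
    z, s = np.atleast_2d(z), np.atleast_2d(s)
    if not (z.shape[0] == s.shape[0] == np.asarray(y).size):
        raise ValueError("z, s and y must have the same number of rows")
    if z.shape[1] != model.gen_spec.noise_dim or s.shape[1] != model.gen_spec.cond_dim:
        raise ValueError("z or s width does not match the generator spec")
    yh = _one_hot(y, model.n_classes)
    out = model.generator.forward(Tensor(z), Tensor(s), Tensor(yh), training=False)
    return out.data


def discriminator_forward(model: HatlModel, x: np.ndarray,
                          y: np.ndarray) -> np.ndarray:
    """Inference-mode critic scores; sigmoid applied iff the variant is CGAN."""
    x = np.atleast_2d(x)
    if x.shape[1] + model.n_classes != model.disc_spec.in_dim:
        raise ValueError("x width does not match the discriminator spec")
    yh = _one_hot(y, model.n_classes)
    logit = model.discriminator.forward(Tensor(x), Tensor(yh), training=False)
    score = logit.data.ravel()
    if model.variant == "cgan":
        score = 1.0 / (1.0 + np.exp(-score))
    return score


def adversarial_losses(variant: str, d_real: np.ndarray,
                       d_fake: np.ndarray) -> tuple[float, float]:
    """Scalar (d_loss, g_loss); both are quantities to be minimised.

    CGAN expects probability scores in (0, 1); the Wasserstein variants take
    unbounded critic scores.
    """
    d_real, d_fake = np.asarray(d_real, float), np.asarray(d_fake, float)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("score batches must be non-empty")
    if variant == "cgan":
        if np.any((d_real <= 0) | (d_real >= 1) | (d_fake <= 0) | (d_fake >= 1)):
            raise ValueError("CGAN scores must lie strictly in (0, 1)")
        d_loss = -np.mean(np.log(d_real)) - np.mean(np.log(1.0 - d_fake))
        g_loss = -np.mean(np.log(d_fake))
    elif variant in ("cwgan", "cwgan-gp"):
        d_loss = float(np.mean(d_fake) - np.mean(d_real))
        g_loss = float(-np.mean(d_fake))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(d_loss), float(g_loss)


def _gp_tensor(disc: Discriminator, x_real: np.ndarray, x_fake: np.ndarray,
               yh: np.ndarray, lam: float, rng) -> Tensor:
    eps = rng.random((x_real.shape[0], 1))
    xhat = Tensor(eps * x_real + (1.0 - eps) * x_fake)
    score = disc.forward(xhat, Tensor(yh), training=False).sum()
    g, = grad(score, [xhat])
    norm = ((g * g).sum(axis=1) + 1e-12) ** 0.5
    return ((norm - 1.0) ** 2).mean() * lam


def gradient_penalty(model: HatlModel, x_real: np.ndarray, x_fake: np.ndarray,
                     y: np.ndarray, lam: float, seed: int = 0) -> float:
    """lambda * E[(||grad_xhat D(xhat, y)||_2 - 1)^2] on random interpolates."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x_real, x_fake = np.atleast_2d(x_real), np.atleast_2d(x_fake)
    if x_real.shape != x_fake.shape:
        raise ValueError("real and fake batches must have equal shapes")
    yh = _one_hot(y, model.n_classes)
    rng = np.random.default_rng(seed)
    return float(_gp_tensor(model.discriminator, x_real, x_fake, yh, lam, rng).data)


def train_hatl(dataset: MultimodalDataset, variant: str,
               config: TrainConfig | None = None,
               gen_spec: GeneratorSpec | None = None,
               disc_spec: DiscriminatorSpec | None = None,
               log=None) -> HatlModel:
    """Adversarially train a generator on a scaled multi-subject dataset.

    Alternates ``n_critic`` critic updates per generator update. CWGAN clips
    critic weights to +/- clip_value after every critic step; CWGAN-GP adds
    the gradient penalty to the critic loss. Per-epoch losses plus Euclidean
    and per-feature Wasserstein distances to a fixed held-out real batch are
    recorded in ``model.history``. Fully reproducible from ``config.seed``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if not dataset.scaled:
        raise ValueError("train_hatl expects a min-max scaled dataset")
    classes = np.unique(dataset.y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    config = config or TrainConfig()
    k = dataset.schema.label_scheme.n_classes
    if gen_spec is None or disc_spec is None:
        g_def, d_def = default_specs(dataset.schema, k, config)
        gen_spec = gen_spec or g_def
        disc_spec = disc_spec or d_def
    if variant == "cgan" and not disc_spec.final_sigmoid:
        disc_spec = DiscriminatorSpec(disc_spec.layer_units, disc_spec.in_dim,
                                      disc_spec.leaky_slope, disc_spec.dropout,
                                      final_sigmoid=True)

    rng = np.random.default_rng(config.seed)
    gen = Generator(gen_spec, rng)
    disc = Discriminator(disc_spec, rng)
    model = HatlModel(variant=variant, generator=gen, discriminator=disc,
                      gen_spec=gen_spec, disc_spec=disc_spec, config=config,
                      schema_hash=dataset.schema.hash(), n_classes=k,
                      eeg_scaler=dataset.eeg_scaler,
                      noneeg_scaler=dataset.noneeg_scaler)

    n = dataset.n_rows
    perm = rng.permutation(n)
    n_hold = min(config.holdout_rows, max(2, n // 5))
    hold, train_idx = perm[:n_hold], perm[n_hold:]
    X, S, Y = dataset.X_eeg, dataset.S_noneeg, dataset.y
    x_hold, s_hold, y_hold = X[hold], S[hold], Y[hold]
    yh_hold = _one_hot(y_hold, k)

    opt_g = _Adam(gen.params, config.learning_rate, config.betas, config.weight_decay)
    opt_d = _Adam(disc.params, config.learning_rate, config.betas, config.weight_decay)
    n_critic = config.critic_steps(variant)
    zdim = gen_spec.noise_dim
    history = {"d_loss": [], "g_loss": [], "euclidean": [], "wasserstein": []}

    def critic_loss(x_batch, yh_batch, x_fake):
        d_real = disc.forward(Tensor(x_batch), Tensor(yh_batch), True, rng)
        d_fake = disc.forward(Tensor(x_fake), Tensor(yh_batch), True, rng)
        if variant == "cgan":
            # -log sigmoid(r) - log(1 - sigmoid(f)), in stable softplus form
            loss = ad.softplus(-d_real).mean() + ad.softplus(d_fake).mean()
        else:
            loss = d_fake.mean() - d_real.mean()
            if variant == "cwgan-gp":
                loss = loss + _gp_tensor(disc, x_batch, x_fake, yh_batch,
                                         config.gp_lambda, rng)
        return loss

    bs = min(config.batch_size, train_idx.size)
    iters_per_epoch = max(1, train_idx.size // bs)
    for epoch in range(config.epochs):
        d_losses, g_losses = [], []
        # One generator update per iteration, preceded by n_critic critic
        # updates on freshly sampled batches (the standard Wasserstein-GAN
        # schedule; n_critic = 1 recovers plain alternating CGAN training).
        for _ in range(iters_per_epoch):
            for _ in range(n_critic):
                idx = rng.choice(train_idx, size=bs, replace=False)
                xb, sb, yhb = X[idx], S[idx], _one_hot(Y[idx], k)
                z = rng.normal(size=(bs, zdim))
                x_fake = gen.forward(Tensor(z), Tensor(sb), Tensor(yhb), True).data
                d_loss = critic_loss(xb, yhb, x_fake)
                opt_d.step(grad(d_loss, disc.params))
                d_losses.append(float(d_loss.data))
                if variant == "cwgan":
                    c = config.clip_value
                    for p in disc.params:
                        np.clip(p.data, -c, c, out=p.data)

            idx = rng.choice(train_idx, size=bs, replace=False)
            sb, yhb = S[idx], _one_hot(Y[idx], k)
            z = rng.normal(size=(bs, zdim))
            fake_t = gen.forward(Tensor(z), Tensor(sb), Tensor(yhb), True)
            d_fake = disc.forward(fake_t, Tensor(yhb), True, rng)
            if variant == "cgan":
                g_loss = ad.softplus(-d_fake).mean()
            else:
                g_loss = -(d_fake.mean())
            opt_g.step(grad(g_loss, gen.params))
            g_losses.append(float(g_loss.data))

        z = rng.normal(size=(n_hold, zdim))
        x_gen = gen.forward(Tensor(z), Tensor(s_hold), Tensor(yh_hold), False).data
        x_gen = np.clip(x_gen, 0.0, 1.0)
        eu_mean, _ = euclidean_rowwise(x_hold, x_gen, y_hold)
        ws = np.mean([empirical_wasserstein(x_hold[:, j], x_gen[:, j])
                      for j in range(x_hold.shape[1])])
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)) if g_losses else np.nan)
        history["euclidean"].append(float(eu_mean))
        history["wasserstein"].append(float(ws))
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} "
                f"d_loss={history['d_loss'][-1]:+.4f} "
                f"euclid={eu_mean:.4f} wasserstein={ws:.4f}")

    model.history = history
    model.trained = True
    model.holdout_idx = hold
    return model


def synthesize_eeg(model: HatlModel, s: np.ndarray, y: np.ndarray,
                   seed: int = 0) -> np.ndarray:
    """Sample noise and generate one EEG feature row per input row.

    Outputs are clipped to [0, 1], the range of min-max scaled training
    targets; rows stay aligned with the given labels.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    s = np.atleast_2d(s)
    if s.shape[1] != model.gen_spec.cond_dim:
        raise ValueError("s width does not match the generator spec")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(s.shape[0], model.gen_spec.noise_dim))
    out = generator_forward(model, z, s, y)
    return np.clip(out, 0.0, 1.0)
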