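"""Residual WGAN-GP with a transformer perceptual loss for sinogram patches.

The generator is a fully convolutional encoder/decoder with a skip
concatenation and a global residual connection (output = features + input),
so a zero-initialized network is exactly the identity and whole projections
can be processed at inference without patch stitching.  The critic stacks
four stride-2 residual blocks (widths 64/128/256/512 at full scale) on an
initial 3x3 convolution, then two dense layers to a scalar Wasserstein
score.  Perceptual distance is the mean squared difference between the last
hidden states of a small vision transformer applied to output and target.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    LayerNorm,
    Module,
    Tensor,
    grad,
    no_grad,
    set_training,
)
from .nn import autograd as ag
from .sinogram import SpectralSinogram


# --------------------------------------------------------------- patch pairs

@dataclass
class PatchPairSet:
    """Aligned (distorted, ideal) patches, channel-first (N, N_E, H, W).

    Values are counts divided by `normalization_constant`; `anchors` records
    the (angle, row, column) origin of each pair in the source sinogram.
    """

    distorted: np.ndarray
    ideal: np.ndarray
    anchors: np.ndarray
    normalization_constant: float = 400_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distorted.shape != self.ideal.shape:
            raise ValueError("distorted and ideal patch stacks must be aligned")

    def __len__(self) -> int:
        return self.distorted.shape[0]

    @property
    def patch_size(self) -> int:
        return self.distorted.shape[-1]

    @property
    def n_bins(self) -> int:
        return self.distorted.shape[1] if len(self) else 0


def extract_patch_pairs(
    distorted: SpectralSinogram,
    ideal: SpectralSinogram,
    n_patches: int,
    patch_size: int = 16,
    seed: int = 0,
    normalization_constant: float = 400_000.0,
) -> PatchPairSet:
    """Sample aligned patch pairs at uniform in-bounds anchors over all angles.

    The pair order is shuffled by construction (anchors are drawn i.i.d.);
    each distorted patch stays aligned with its ideal counterpart.
    """
    if distorted.data.shape != ideal.data.shape:
        raise ValueError("sinograms must share a shape")
    if distorted.channel_kind != "counts-in-bins" or ideal.channel_kind != "counts-in-bins":
        raise ValueError("patch extraction expects counts-in-bins sinograms")
    n_angles, n_rows, n_cols, n_bins = distorted.data.shape
    if patch_size > n_rows or patch_size > n_cols:
        raise ValueError("patch size exceeds the sinogram face")
    rng = np.random.default_rng(seed)
    angles = rng.integers(0, n_angles, size=n_patches)
    rows = rng.integers(0, n_rows - patch_size + 1, size=n_patches)
    cols = rng.integers(0, n_cols - patch_size + 1, size=n_patches)
    dist = np.empty((n_patches, n_bins, patch_size, patch_size), np.float32)
    idl = np.empty_like(dist)
    for i, (a, r, c) in enumerate(zip(angles, rows, cols)):
        dist[i] = distorted.data[a, r : r + patch_size, c : c + patch_size].transpose(2, 0, 1)
        idl[i] = ideal.data[a, r : r + patch_size, c : c + patch_size].transpose(2, 0, 1)
    dist /= normalization_constant
    idl /= normalization_constant
    anchors = np.stack([angles, rows, cols], axis=1)
    return PatchPairSet(dist, idl, anchors, normalization_constant, seed)


def split_train_val(pairs: PatchPairSet, train_fraction: float):
    """Disjoint (train, validation) partition with train = round(f * total)."""
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train fraction must be in [0, 1]")
    n_train = int(round(train_fraction * len(pairs)))
    def subset(sl):
        return PatchPairSet(
            pairs.distorted[sl], pairs.ideal[sl], pairs.anchors[sl],
            pairs.normalization_constant, pairs.seed,
        )
    return subset(slice(0, n_train)), subset(slice(n_train, len(pairs)))


# ------------------------------------------------------------- architectures

@dataclass
class NetConfig:
    """Widths and structure for generator, critic and perceptual transformer."""

    n_bins: int = 9
    patch_size: int = 16
    generator_base: int = 64
    disc_initial: int = 64
    disc_widths: tuple[int, ...] = (64, 128, 256, 512)
    disc_dense: int = 1024
    kernel: int = 3
    vit_patch: int = 4
    vit_dim: int = 32
    vit_depth: int = 2
    vit_heads: int = 4
    vit_class_token: bool = False
    adversarial_sign: float = -1.0  # standard Wasserstein generator convention
    seed: int = 0

    @classmethod
    def compact(cls, **overrides) -> "NetConfig":
        """CPU-scale widths for desk experiments and the test suite."""
        cfg = cls(
            generator_base=16, disc_initial=16, disc_widths=(16, 32, 64, 128),
            disc_dense=256,
        )
        return replace(cfg, **overrides)


class Generator(Module):
    """Contract-expand fully convolutional net with a global residual add."""

    def __init__(self, config: NetConfig):
        rng = np.random.default_rng(config.seed)
        w = config.generator_base
        c = config.n_bins
        k = config.kernel
        self.enc1 = Conv2d(c, w, k, rng=rng)
        self.enc2 = Conv2d(w, w, k, rng=rng)
        self.down = Conv2d(w, 2 * w, k, stride=2, rng=rng)
        self.mid1 = Conv2d(2 * w, 2 * w, k, rng=rng)
        self.mid2 = Conv2d(2 * w, 2 * w, k, rng=rng)
        self.up = ConvTranspose2d(2 * w, w, k, rng=rng)
        self.fuse = Conv2d(2 * w, w, k, rng=rng)
        # zero-initialized head: the network starts as the identity map
        self.head = Conv2d(w, c, k, rng=rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("generator input height/width must be even")
        e = ag.leaky_relu(self.enc1(x))
        e = ag.leaky_relu(self.enc2(e))
        d = ag.leaky_relu(self.down(e))
        m = ag.leaky_relu(self.mid1(d))
        m = ag.leaky_relu(self.mid2(m))
        u = ag.relu(self.up(m))
        f = ag.relu(self.fuse(ag.concat([u, e], axis=1)))
        return self.head(f) + x


class _ResBlock(Module):
    """Two 3x3 convolutions with batch norm; skip-add before the last ReLU.

    The first convolution carries the stride; a 1x1 shortcut matches channels
    and stride for the addition."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.conv1 = Conv2d(c_in, c_out, kernel, stride=2, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, kernel, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.shortcut = Conv2d(c_in, c_out, kernel=1, stride=2, pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = ag.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return ag.relu(h + self.shortcut(x))


class Discriminator(Module):
    """Residual Wasserstein critic emitting one unsquashed score per sample."""

    def __init__(self, config: NetConfig):
        if config.patch_size % (2 ** len(config.disc_widths)):
            raise ValueError(
                f"input size {config.patch_size} must be divisible by "
                f"2^{len(config.disc_widths)}"
            )
        rng = np.random.default_rng(config.seed + 1)
        self.initial = Conv2d(config.n_bins, config.disc_initial, config.kernel, rng=rng)
        widths = [config.disc_initial, *config.disc_widths]
        self.blocks = [
            _ResBlock(widths[i], widths[i + 1], config.kernel, rng)
            for i in range(len(config.disc_widths))
        ]
        reduced = config.patch_size // (2 ** len(config.disc_widths))
        self.dense1 = Dense(config.disc_widths[-1] * reduced * reduced, config.disc_dense, rng=rng)
        self.dense2 = Dense(config.disc_dense, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.initial(x))
        for block in self.blocks:
            h = block(h)
        h = ag.reshape(h, (x.shape[0], -1))
        h = ag.leaky_relu(self.dense1(h))
        return self.dense2(h)


class _AttentionBlock(Module):
    def __init__(self, dim, heads, rng):
        self.heads = heads
        self.norm1 = LayerNorm(dim)
        self.qkv = Dense(dim, 3 * dim, rng=rng)
        self.proj = Dense(dim, dim, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.mlp1 = Dense(dim, 2 * dim, rng=rng)
        self.mlp2 = Dense(2 * dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h = self.heads
        dh = d // h
        qkv = self.qkv(self.norm1(x))  # (B, T, 3D)
        qkv = ag.reshape(qkv, (b, t, 3, h, dh))
        qkv = ag.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, H, T, dh)
        q = ag.reshape(ag.slice_(qkv, (0,)), (b * h, t, dh))
        k = ag.reshape(ag.slice_(qkv, (1,)), (b * h, t, dh))
        v = ag.reshape(ag.slice_(qkv, (2,)), (b * h, t, dh))
        scores = ag.matmul(q, ag.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(attn, v)  # (B*H, T, dh)
        ctx = ag.reshape(ctx, (b, h, t, dh))
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (b, t, d))
        x = x + self.proj(ctx)
        m = ag.relu(self.mlp1(self.norm2(x)))
        return x + self.mlp2(m)


class ViT(Module):
    """Small vision transformer; the perceptual feature is the last hidden state."""

    def __init__(self, config: NetConfig):
        rng = np.random.default_rng(config.seed + 2)
        ps = config.vit_patch
        self.patch = ps
        self.dim = config.vit_dim
        self.token_dim = ps * ps * config.n_bins
        self.embed = Dense(self.token_dim, self.dim, rng=rng)
        n_tokens = (config.patch_size // ps) ** 2
        self.use_class_token = config.vit_class_token
        if self.use_class_token:
            self.class_token = Tensor(
                rng.normal(0, 0.02, (1, 1, self.dim)).astype(np.float32), requires_grad=True
            )
            n_tokens += 1
        self.pos = Tensor(
            rng.normal(0, 0.02, (1, n_tokens, self.dim)).astype(np.float32), requires_grad=True
        )
        self.blocks = [
            _AttentionBlock(self.dim, config.vit_heads, rng) for _ in range(config.vit_depth)
        ]
        self.norm = LayerNorm(self.dim)

    def tokenize(self, x: Tensor) -> Tensor:
        b, c, hh, ww = x.shape
        ps = self.patch
        if hh % ps or ww % ps:
            raise ValueError("input size must be divisible by the token patch size")
        gh, gw = hh // ps, ww // ps
        x = ag.reshape(x, (b, c, gh, ps, gw, ps))
        x = ag.transpose(x, (0, 2, 4, 1, 3, 5))  # (B, gh, gw, C, ps, ps)
        return ag.reshape(x, (b, gh * gw, c * ps * ps))

    def forward(self, x: Tensor) -> Tensor:
        tokens = self.embed(self.tokenize(x))
        if self.use_class_token:
            b = x.shape[0]
            cls = ag.broadcast_to(self.class_token, (b, 1, self.dim))
            tokens = ag.concat([cls, tokens], axis=1)
        tokens = tokens + self.pos
        for block in self.blocks:
            tokens = block(tokens)
        return self.norm(tokens)


def build_generator(config: NetConfig) -> Generator:
    gen = Generator(config)
    probe = Tensor(np.zeros((1, config.n_bins, config.patch_size, config.patch_size), np.float32))
    with no_grad():
        out = gen(probe)
    if out.shape != probe.shape:
        raise ValueError("generator output shape does not match its input")
    return gen


def build_discriminator(config: NetConfig) -> Discriminator:
    return Discriminator(config)


def vit_features(batch: Tensor, vit: ViT) -> Tensor:
    """Last-hidden-state token embeddings used as the perceptual feature."""
    return vit(batch)


# -------------------------------------------------------------------- losses

@dataclass
class LossWeights:
    lambda_gp: float = 10.0
    lambda1: float = 1000.0  # MSE
    lambda2: float = 1000.0  # relative MAE
    lambda3: float = 10.0  # perceptual
    eps_rmae: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.lambda_gp, self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be nonnegative")


def gradient_penalty(
    critic: Module, real: Tensor, fake: Tensor, rng: np.random.Generator,
    norm_eps: float = 0.0,
) -> Tensor:
    """E[(||grad_xhat D(xhat)||_2 - 1)^2] on the real/fake segment.

    One uniform interpolation point per pair.  `norm_eps` stabilizes the
    norm's derivative during training; the default 0 keeps the value exact.
    """
    eps = rng.uniform(size=(real.shape[0], 1, 1, 1)).astype(np.float32)
    xhat = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    score = ag.sum_(critic(xhat))
    (gx,) = grad(score, [xhat], create_graph=True)
    sq = ag.sum_(gx * gx, axis=(1, 2, 3))
    norm = ag.sqrt(sq + norm_eps) if norm_eps else ag.sqrt(sq)
    dev = norm - 1.0
    return ag.mean(dev * dev)


def discriminator_loss(
    critic: Module,
    generator: Module | None,
    real: Tensor,
    measured: Tensor,
    lambda_gp: float,
    rng: np.random.Generator | int = 0,
    fake: Tensor | None = None,
    norm_eps: float = 0.0,
) -> Tensor:
    """-E[D(p)] + E[D(G(m))] + lambda * gradient penalty (critic minimizes)."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if fake is None:
        with no_grad():
            fake = generator(measured)
    fake = fake.detach()
    wasserstein = ag.mean(critic(fake)) - ag.mean(critic(real))
    penalty = gradient_penalty(critic, real, fake, rng, norm_eps=norm_eps)
    return wasserstein + lambda_gp * penalty


def generator_loss(
    critic: Module,
    generator: Module,
    real: Tensor,
    measured: Tensor,
    weights: LossWeights,
    vit: ViT | None = None,
    adversarial_sign: float = -1.0,
    fake: Tensor | None = None,
) -> Tensor:
    """Adversarial + lambda1*MSE + lambda2*RMAE + lambda3*perceptual.

    The adversarial term is sign * E[D(G(m))] with the standard Wasserstein
    generator convention sign = -1 (configurable).
    """
    if fake is None:
        fake = generator(measured)
    loss = ag.mean(critic(fake)) * adversarial_sign
    diff = fake - real
    if weights.lambda1:
        loss = loss + weights.lambda1 * ag.mean(diff * diff)
    if weights.lambda2:
        loss = loss + weights.lambda2 * ag.mean(ag.abs_(diff / (real + weights.eps_rmae)))
    if weights.lambda3 and vit is not None:
        fdiff = vit_features(fake, vit) - vit_features(real, vit)
        loss = loss + weights.lambda3 * ag.mean(fdiff * fdiff)
    return loss


# ------------------------------------------------------------------ training

@dataclass
class TrainState:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 5
    batch_size: int = 64
    critic_steps: int = 4
    seed: int = 0
    history: dict = field(default_factory=lambda: {
        "critic_loss": [], "generator_loss": [], "val_rmse": [],
    })


def _batch_tensor(arr: np.ndarray, idx: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(arr[idx]))


def validation_rmse(generator: Module, pairs: PatchPairSet, batch_size: int = 256) -> float:
    """RMSE of G(m) against p over a pair set, in normalized units."""
    if len(pairs) == 0:
        return float("nan")
    set_training(generator, False)
    total, count = 0.0, 0
    with no_grad():
        for lo in range(0, len(pairs), batch_size):
            sl = slice(lo, min(lo + batch_size, len(pairs)))
            out = generator(Tensor(pairs.distorted[sl]))
            total += float(((out.data - pairs.ideal[sl]) ** 2).sum())
            count += pairs.ideal[sl].size
    set_training(generator, True)
    return float(np.sqrt(total / count))


def pretrain_vit(
    vit: ViT, pairs: PatchPairSet, epochs: int = 1, batch_size: int = 64,
    lr: float = 1e-3, seed: int = 0,
) -> ViT:
    """Train the transformer as a distorted-to-ideal patch regressor.

    A linear decoder maps each spatial token back to its pixel patch; the
    decoder is discarded and the encoder frozen for perceptual use.  (A
    random frozen encoder is the fallback when pretraining is skipped.)
    """
    rng = np.random.default_rng(seed)
    decoder = Dense(vit.dim, vit.token_dim, rng=rng)
    params = vit.parameters() + decoder.parameters()
    opt = Adam(params, lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for lo in range(0, len(pairs), batch_size):
            idx = order[lo : lo + batch_size]
            x = _batch_tensor(pairs.distorted, idx)
            target = vit.tokenize(Tensor(pairs.ideal[idx]))
            tokens = vit(x)
            if vit.use_class_token:
                tokens = ag.slice_(tokens, (slice(None), slice(1, None)))
            diff = decoder(tokens) - target
            loss = ag.mean(diff * diff)
            opt.step(grad(loss, params))
    return vit


def train_wgan(
    train: PatchPairSet,
    val: PatchPairSet,
    config: NetConfig,
    weights: LossWeights,
    state: TrainState,
    vit: ViT | None = None,
) -> tuple[Generator, dict]:
    """Alternating critic/generator updates with Adam; fully seeded.

    Aborts with a diagnostic if any loss becomes non-finite.  Returns the
    trained generator and the per-epoch history (critic loss, generator
    loss, validation RMSE).
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(state.seed)
    generator = build_generator(config)
    critic = build_discriminator(config)
    gen_params = generator.parameters()
    critic_params = critic.parameters()
    opt_g = Adam(gen_params, lr=state.lr, beta1=state.beta1, beta2=state.beta2)
    opt_d = Adam(critic_params, lr=state.lr, beta1=state.beta1, beta2=state.beta2)

    n = len(train)
    bs = min(state.batch_size, n)
    for _epoch in range(state.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        pos = 0
        while pos + bs <= n or (pos == 0 and n < bs):
            for _ in range(state.critic_steps):
                idx = rng.choice(n, size=bs, replace=False)
                real = _batch_tensor(train.ideal, idx)
                meas = _batch_tensor(train.distorted, idx)
                d_loss = discriminator_loss(
                    critic, generator, real, meas, weights.lambda_gp, rng, norm_eps=1e-12
                )
                opt_d.step(grad(d_loss, critic_params))
                d_losses.append(d_loss.item())
            idx = order[pos : pos + bs]
            if idx.size < bs:
                idx = order[:bs]
            real = _batch_tensor(train.ideal, idx)
            meas = _batch_tensor(train.distorted, idx)
            g_loss = generator_loss(
                critic, generator, real, meas, weights, vit, config.adversarial_sign
            )
            opt_g.step(grad(g_loss, gen_params))
            g_losses.append(g_loss.item())
            if not (np.isfinite(d_losses[-1]) and np.isfinite(g_losses[-1])):
                raise RuntimeError(
                    f"training diverged: critic={d_losses[-1]}, generator={g_losses[-1]}"
                )
            pos += bs
        state.history["critic_loss"].append(float(np.mean(d_losses)))
        state.history["generator_loss"].append(float(np.mean(g_losses)))
        state.history["val_rmse"].append(validation_rmse(generator, val))
    set_training(generator, False)
    return generator, state.history


# --------------------------------------------------------------- checkpoints

def save_checkpoint(path, generator: Generator, config: NetConfig,
                    normalization_constant: float = 400_000.0) -> None:
    """Single-file archive: weights + architecture + normalization metadata."""
    import yaml

    from dataclasses import asdict

    meta = asdict(config)
    meta["disc_widths"] = list(meta["disc_widths"])
    meta["normalization_constant"] = float(normalization_constant)
    arrays = {f"w{i:03d}": w for i, w in enumerate(generator.state_dict())}
    np.savez(path, meta=np.frombuffer(yaml.safe_dump(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Generator, NetConfig, float]:
    import yaml

    with np.load(path) as archive:
        meta = yaml.safe_load(bytes(archive["meta"]).decode())
        weights = [archive[k] for k in sorted(k for k in archive.files if k != "meta")]
    norm = float(meta.pop("normalization_constant"))
    meta["disc_widths"] = tuple(meta["disc_widths"])
    config = NetConfig(**meta)
    generator = build_generator(config)
    generator.load_state_dict(weights)
    set_training(generator, False)
    return generator, config, norm


# ----------------------------------------------------------------- inference

def correct_projections(generator: Module, distorted: SpectralSinogram,
                        normalization_constant: float = 400_000.0) -> SpectralSinogram:
    """Run each angle's full projection through the generator in one shot.

    The projection is normalized, reflect-padded to even height/width if
    needed, processed whole (no patch stitching), cropped, de-normalized and
    clipped at zero.
    """
    set_training(generator, False)
    data = distorted.data
    out = np.empty_like(data, dtype=np.float32)
    n_angles, h, w, n_bins = data.shape
    pad_h, pad_w = h % 2, w % 2
    with no_grad():
        for a in range(n_angles):
            x = data[a].transpose(2, 0, 1)[None].astype(np.float32) / normalization_constant
            if pad_h or pad_w:
                x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
            y = generator(Tensor(x)).data[0]
            y = y[:, :h, :w]
            out[a] = y.transpose(1, 2, 0) * normalization_constant
    return distorted.with_data(np.clip(out, 0.0, None))
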