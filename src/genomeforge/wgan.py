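"""Convolutional Wasserstein GAN with gradient penalty for haplotype panels.

The critic approximates the earth-mover's distance between real and
generated distributions; training alternates critic maximisation of
E[C(x)] − E[C(G(z))] (with a gradient penalty enforcing the Lipschitz
constraint) against generator minimisation. Architecture features follow
the large-genome design: sequence lengths of the form 2^n − 1 scaled by
stride-2 (transposed) convolutions, a trainable location-specific channel
concatenated at every block (restoring the positional information that
convolutions are invariant to), two fresh noise channels per generator
block, residual blocks between scaling blocks, and "packing" — the critic
scores groups of ``packing`` sequences jointly, so it can punish the low
within-batch diversity of a mode-collapsed generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, grad
from . import nn
from .haplotype_io import HaplotypeMatrix


def _is_pow2m1(n: int) -> bool:
    return n >= 3 and ((n + 1) & n) == 0


@dataclass
class WganArchConfig:
    """Architecture of generator and critic.

    ``target_length`` must be of the form 2^n − 1. Lengths scale through
    the chain 3 → 7 → 15 → … → target_length; channel widths start at
    ``base_channels`` at the coarsest resolution and halve (floor 8) as the
    length doubles. ``packing`` sequences are scored jointly by the critic.
    The generator's latent input has length 4.
    """

    target_length: int = 255
    base_channels: int = 32
    packing: int = 3
    noise_channels_per_block: int = 2
    leaky_slope: float = 0.01
    latent_length: int = 4
    latent_channels: int = 8
    residual_every: int = 2      # residual block after every Nth scaling block
    critic_norm: str = "none"    # "none" or "instance"
    seed: int = 0

    def __post_init__(self) -> None:
        if not _is_pow2m1(self.target_length):
            raise ValueError(f"target_length must be 2^n - 1 >= 3, got {self.target_length}")
        if self.packing < 1:
            raise ValueError("packing must be >= 1")
        if self.critic_norm not in ("none", "instance"):
            raise ValueError("critic_norm must be 'none' or 'instance'")

    @property
    def n_blocks(self) -> int:
        # number of stride-2 scalings between length 3 and target_length
        n = 0
        length = 3
        while length < self.target_length:
            length = 2 * length + 1
            n += 1
        return n

    def channels_at(self, level: int) -> int:
        """Channel width at scaling level (0 = coarsest, length 3)."""
        return max(8, self.base_channels >> level)


@dataclass
class WganTrainConfig:
    lr_generator: float = 5e-4
    lr_critic: float = 5e-4
    adam_betas: tuple[float, float] = (0.5, 0.9)
    critic_steps_per_gen: int = 10
    gp_lambda: float = 10.0
    batch_size: int = 96          # sequences per step; must be divisible by packing
    epochs: int = 50
    phase2_lr_generator: float = 5e-5
    phase2_epochs: int = 0
    pca_stop_threshold: float = 0.15
    eval_every: int = 0           # epochs between PCA-overlap evaluations (0 = off)
    seed: int = 0


class _ResidualBlock(nn.Module):
    """Two same-length convolutions; the input is added to the output."""

    def __init__(self, channels: int, norm: str, slope: float, rng):
        self.conv1 = nn.Conv1d(channels, channels, 3, 1, 1, rng=rng)
        self.conv2 = nn.Conv1d(channels, channels, 3, 1, 1, rng=rng)
        norms = {"batch": nn.BatchNorm1d, "instance": nn.InstanceNorm1d, "none": _Identity}
        self.n1 = norms[norm](channels)
        self.n2 = norms[norm](channels)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.n1(self.conv1(x)), self.slope)
        h = ad.leaky_relu(self.n2(self.conv2(h)), self.slope)
        return x + h


class Generator(nn.Module):
    """Latent (N, latent_channels, 4) -> sigmoid sequences (N, 1, target_length)."""

    def __init__(self, arch: WganArchConfig):
        rng = np.random.default_rng(arch.seed)
        self.arch = arch
        c0 = arch.channels_at(0)
        self.fc = nn.Linear(arch.latent_channels * arch.latent_length, c0 * 3, rng=rng)
        self.blocks: list[nn.Module] = []
        self.locations: list[Tensor] = []
        self.residuals: list[nn.Module | None] = []
        length = 3
        level = 0
        while length < arch.target_length:
            c_in = arch.channels_at(level)
            c_out = arch.channels_at(level + 1)
            self.locations.append(Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True))
            self.blocks.append(nn.ConvTranspose1d(
                c_in + 1 + arch.noise_channels_per_block, c_out, 3, stride=2, pad=0, rng=rng))
            self.blocks.append(nn.BatchNorm1d(c_out))
            length = 2 * length + 1
            level += 1
            if arch.residual_every and level % arch.residual_every == 0 and length < arch.target_length:
                self.residuals.append(_ResidualBlock(c_out, "batch", arch.leaky_slope, rng))
            else:
                self.residuals.append(None)
        c_last = arch.channels_at(level)
        self.out_location = Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True)
        self.out_conv = nn.Conv1d(c_last + 1, 1, 3, 1, 1, rng=rng)

    def __call__(self, z: Tensor, rng: np.random.Generator) -> Tensor:
        a = self.arch
        n = z.shape[0]
        h = self.fc(z.reshape(n, a.latent_channels * a.latent_length))
        h = ad.leaky_relu(h, a.leaky_slope).reshape(n, a.channels_at(0), 3)
        for i in range(0, len(self.blocks), 2):
            loc = ad.broadcast_to(self.locations[i // 2], (n, 1, h.shape[2]))
            noise = Tensor(rng.normal(size=(n, a.noise_channels_per_block, h.shape[2])))
            h = ad.concat([h, loc, noise], axis=1)
            h = self.blocks[i](h)          # transposed conv
            h = ad.leaky_relu(self.blocks[i + 1](h), a.leaky_slope)  # batch norm
            res = self.residuals[i // 2]
            if res is not None:
                h = res(h)
        loc = ad.broadcast_to(self.out_location, (n, 1, h.shape[2]))
        return ad.sigmoid(self.out_conv(ad.concat([h, loc], axis=1)))

    def sample_latent(self, n: int, rng: np.random.Generator) -> Tensor:
        a = self.arch
        return Tensor(rng.normal(size=(n, a.latent_channels, a.latent_length)))


class _Identity(nn.Module):
    def __init__(self, *args):
        pass

    def __call__(self, x: Tensor) -> Tensor:
        return x


class Critic(nn.Module):
    """Packed sequences (N, packing, target_length) -> scalar scores (N,).

    ``arch.critic_norm`` selects per-layer normalisation: instance norm, or
    none (the default). With instance norm, the critic's input-gradient
    norms scale with the inverse per-sample activation spread, which differs
    systematically between binary real data and smooth early-generator
    output; the gradient penalty then cannot be satisfied uniformly and its
    noise drowns the Wasserstein signal. A norm-free critic (common WGAN-GP
    practice) has no such heterogeneity.
    """

    def __init__(self, arch: WganArchConfig):
        rng = np.random.default_rng(arch.seed + 1)
        self.arch = arch
        self.blocks: list[nn.Module] = []
        self.locations: list[Tensor] = []
        self.residuals: list[nn.Module | None] = []
        use_in = arch.critic_norm == "instance"
        length = arch.target_length
        level = arch.n_blocks
        c_in = arch.packing
        while length > 3:
            c_out = arch.channels_at(level - 1)
            self.locations.append(Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True))
            self.blocks.append(nn.Conv1d(c_in + 1, c_out, 3, stride=2, pad=0, rng=rng))
            self.blocks.append(nn.InstanceNorm1d(c_out) if use_in else _Identity())
            length = (length - 1) // 2
            level -= 1
            if arch.residual_every and level % arch.residual_every == 0 and length > 3:
                self.residuals.append(_ResidualBlock(
                    c_out, "instance" if use_in else "none", arch.leaky_slope, rng))
            else:
                self.residuals.append(None)
            c_in = c_out
        self.fc = nn.Linear(c_in * 3, 1, rng=rng)
        self._calibrate_lipschitz(rng)

    def _calibrate_lipschitz(self, rng: np.random.Generator) -> None:
        """Rescale the output layer so initial input-gradient norms are ~1.

        The gradient penalty drives ‖∇_x C‖ toward 1; starting far from 1
        wastes the early critic updates on pure rescaling (the penalty term
        dwarfs the Wasserstein term). The critic is linear in its last
        layer, so scaling it rescales all input gradients uniformly.
        """
        probe = Tensor(rng.random((8, self.arch.packing, self.arch.target_length)),
                       requires_grad=True)
        (g,) = grad(self(probe).sum(), [probe])
        norm = float(np.sqrt((g.data ** 2).sum(axis=(1, 2))).mean())
        if np.isfinite(norm) and norm > 0:
            self.fc.w.data /= norm
            self.fc.b.data /= norm

    def __call__(self, packs: Tensor) -> Tensor:
        a = self.arch
        h = packs
        n = h.shape[0]
        for i in range(0, len(self.blocks), 2):
            loc = ad.broadcast_to(self.locations[i // 2], (n, 1, h.shape[2]))
            h = ad.concat([h, loc], axis=1)
            h = ad.leaky_relu(self.blocks[i + 1](self.blocks[i](h)), a.leaky_slope)
            res = self.residuals[i // 2]
            if res is not None:
                h = res(h)
        return self.fc(h.reshape(n, h.shape[1] * 3)).reshape(n)

    @property
    def packing(self) -> int:
        return self.arch.packing

    def score(self, packs: np.ndarray) -> np.ndarray:
        """Numpy scoring convenience (no graph)."""
        with ad.no_grad():
            return self(Tensor(np.asarray(packs, dtype=np.float64))).data.copy()


def build_generator(arch: WganArchConfig) -> Generator:
    return Generator(arch)


def build_critic(arch: WganArchConfig) -> Critic:
    return Critic(arch)


def gradient_penalty(critic, real_pack, fake_pack, gp_lambda: float,
                     rng: np.random.Generator) -> Tensor:
    """WGAN-GP penalty: gp_lambda · E[(‖∇_x C(x̂)‖ − 1)²] at random interpolates.

    x̂ interpolates uniformly per pack between a real and a fake pack; the
    input-gradient norm is taken over all entries of the pack. The returned
    tensor carries the double-backprop graph so it can join the critic loss.
    """
    real = Tensor(np.asarray(real_pack if not isinstance(real_pack, Tensor) else real_pack.data, dtype=np.float64))
    fake = fake_pack if isinstance(fake_pack, Tensor) else Tensor(np.asarray(fake_pack, dtype=np.float64))
    if real.shape != fake.shape:
        raise ValueError("real and fake packs must have the same shape")
    eps = rng.uniform(size=(real.shape[0], 1, 1))
    interp = Tensor(eps * real.data + (1 - eps) * fake.data, requires_grad=True)
    scores = critic(interp)
    (g,) = grad(scores.sum(), [interp], create_graph=True)
    norms = ad.sqrt(((g ** 2).sum(axis=(1, 2))) + 1e-12)
    return gp_lambda * ((norms - 1.0) ** 2).mean()


def wgan_losses(critic_scores_real, critic_scores_fake, penalty):
    """critic_loss = mean(fake) − mean(real) + penalty; generator_loss = −mean(fake)."""
    real = critic_scores_real if isinstance(critic_scores_real, Tensor) else Tensor(critic_scores_real)
    fake = critic_scores_fake if isinstance(critic_scores_fake, Tensor) else Tensor(critic_scores_fake)
    if real.data.size == 0 or fake.data.size == 0:
        raise ValueError("score vectors must be non-empty")
    pen = penalty if isinstance(penalty, Tensor) else Tensor(penalty)
    critic_loss = fake.mean() + (-1.0) * real.mean() + pen
    generator_loss = (-1.0) * fake.mean()
    return critic_loss, generator_loss


@dataclass
class WganTrainingLog:
    critic_loss: list[float] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    pca_distance: list[tuple[int, np.ndarray]] = field(default_factory=list)
    stopped_early: bool = False


@dataclass
class WganModel:
    generator: Generator
    critic: Critic
    arch: WganArchConfig
    train_cfg: WganTrainConfig
    log: WganTrainingLog


def _make_packs(x: np.ndarray, packing: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of the batch into packs of `packing` sequences."""
    n = (x.shape[0] // packing) * packing
    idx = rng.permutation(x.shape[0])[:n]
    return x[idx].reshape(n // packing, packing, x.shape[1])


def train_wgan(data: HaplotypeMatrix, arch: WganArchConfig, train_cfg: WganTrainConfig) -> WganModel:
    """Two-phase alternating Adam optimization of critic and generator.

    Per generator step the critic takes ``critic_steps_per_gen`` updates.
    When ``eval_every`` is set, PCA-overlap distance between real data and a
    generated panel is logged and training stops early once all monitored
    components fall below ``pca_stop_threshold``. Phase 2 (optional)
    continues with a 10-fold lower generator learning rate.
    """
    x = np.asarray(data.alleles, dtype=np.float64)
    if x.shape[1] != arch.target_length:
        raise ValueError(
            f"data has {x.shape[1]} columns but the architecture expects {arch.target_length}; "
            "pad with pad_to_pow2m1 first")
    rng = np.random.default_rng(train_cfg.seed)
    gen = Generator(arch)
    critic = Critic(arch)
    opt_g = nn.Adam(gen.parameters(), train_cfg.lr_generator, train_cfg.adam_betas)
    opt_c = nn.Adam(critic.parameters(), train_cfg.lr_critic, train_cfg.adam_betas)
    log = WganTrainingLog()
    batch = (train_cfg.batch_size // arch.packing) * arch.packing
    steps_per_epoch = max(1, x.shape[0] // batch)

    def one_phase(n_epochs: int, lr_g: float, epoch_offset: int) -> bool:
        opt_g.lr = lr_g
        for epoch in range(n_epochs):
            for _ in range(steps_per_epoch):
                for _ in range(train_cfg.critic_steps_per_gen):
                    real_pack = _make_packs(x[rng.choice(x.shape[0], batch, replace=False)],
                                            arch.packing, rng)
                    with ad.no_grad():
                        fake = gen(gen.sample_latent(batch, rng), rng)
                    fake_pack = _make_packs(fake.data[:, 0, :], arch.packing, rng)
                    both = critic(Tensor(np.concatenate([real_pack, fake_pack], axis=0)))
                    sc_real = both[: real_pack.shape[0]]
                    sc_fake = both[real_pack.shape[0] :]
                    pen = gradient_penalty(critic, real_pack, fake_pack, train_cfg.gp_lambda, rng)
                    c_loss, _ = wgan_losses(sc_real, sc_fake, pen)
                    opt_c.zero_grad()
                    c_loss.backward()
                    opt_c.step()
                fake = gen(gen.sample_latent(batch, rng), rng)
                fake_pack = _pack_tensor(fake, arch.packing, rng)
                g_loss = (-1.0) * critic(fake_pack).mean()
                opt_g.zero_grad()
                opt_c.zero_grad()
                g_loss.backward()
                opt_g.step()
                if not np.isfinite(c_loss.data) or not np.isfinite(g_loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch_offset + epoch}")
                log.critic_loss.append(float(c_loss.data))
                log.generator_loss.append(float(g_loss.data))
            if train_cfg.eval_every and (epoch + 1) % train_cfg.eval_every == 0:
                model = WganModel(gen, critic, arch, train_cfg, log)
                ags = generate_wgan(model, min(x.shape[0], 200), seed=train_cfg.seed + 99)
                dist, stop = pca_overlap_distance(x, ags.alleles.astype(float),
                                                  threshold=train_cfg.pca_stop_threshold)
                log.pca_distance.append((epoch_offset + epoch, dist))
                if stop:
                    log.stopped_early = True
                    return True
        return False

    stopped = one_phase(train_cfg.epochs, train_cfg.lr_generator, 0)
    if not stopped and train_cfg.phase2_epochs:
        one_phase(train_cfg.phase2_epochs, train_cfg.phase2_lr_generator, train_cfg.epochs)
    return WganModel(gen, critic, arch, train_cfg, log)


def _pack_tensor(fake: Tensor, packing: int, rng: np.random.Generator) -> Tensor:
    n = (fake.shape[0] // packing) * packing
    idx = rng.permutation(fake.shape[0])[:n]
    seq = ad.getitem(fake, (idx, 0, slice(None)))
    return seq.reshape(n // packing, packing, fake.shape[2])


def generate_wgan(model: WganModel, n: int, seed: int = 0, binarize: str = "threshold") -> HaplotypeMatrix:
    """Sample n haplotypes from the generator.

    Sigmoid outputs become alleles by a deterministic 0.5 threshold
    (default) or a Bernoulli draw; batch-norm layers use their running
    statistics, so generation is a pure function of (weights, seed).
    """
    rng = np.random.default_rng(seed)
    nn.set_training(model.generator, False)
    try:
        with ad.no_grad():
            out = model.generator(model.generator.sample_latent(n, rng), rng).data[:, 0, :]
    finally:
        nn.set_training(model.generator, True)
    if binarize == "threshold":
        alleles = (out >= 0.5).astype(np.int8)
    elif binarize == "bernoulli":
        alleles = (rng.random(out.shape) < out).astype(np.int8)
    else:
        raise ValueError("binarize must be 'threshold' or 'bernoulli'")
    return HaplotypeMatrix(alleles)


def pca_overlap_distance(real, generated, n_components: int = 4, threshold: float = 0.15):
    """Normalized per-component 1-D Wasserstein distance in real-fitted PC space.

    PCA is fitted on the real panel; both panels are projected and, per
    component, the Wasserstein distance between the real and generated score
    distributions is divided by the real scores' standard deviation. The
    stopping signal is True when every component's normalized distance is
    below ``threshold`` (an automated stand-in for judging visual overlap of
    the PC clouds).
    """
    from sklearn.decomposition import PCA
    from scipy.stats import wasserstein_distance

    r = np.asarray(real.alleles if isinstance(real, HaplotypeMatrix) else real, dtype=float)
    g = np.asarray(generated.alleles if isinstance(generated, HaplotypeMatrix) else generated, dtype=float)
    if np.allclose(r.var(axis=0), 0) or np.allclose(g.var(axis=0), 0):
        raise ValueError("degenerate (constant) data")
    n_components = min(n_components, min(r.shape) - 1)
    pca = PCA(n_components=n_components)
    rs = pca.fit_transform(r)
    gs = pca.transform(g)
    dist = np.array([
        wasserstein_distance(rs[:, c], gs[:, c]) / max(rs[:, c].std(), 1e-12)
        for c in range(n_components)
    ])
    return dist, bool((dist < threshold).all())


def save_wgan(path, model: WganModel) -> None:
    arrays = {f"g_{k}": v for k, v in model.generator.state_arrays().items()}
    arrays.update({f"c_{k}": v for k, v in model.critic.state_arrays().items()})
    arrays["meta"] = np.array(json.dumps({
        "arch": asdict(model.arch), "train_cfg": asdict(model.train_cfg)}))
    np.savez(path, **arrays)


def load_wgan(path) -> WganModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arch = WganArchConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in meta["arch"].items()})
        cfg = WganTrainConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in meta["train_cfg"].items()})
        gen = Generator(arch)
        critic = Critic(arch)
        gen.load_state_arrays({k[2:]: z[k] for k in z.files if k.startswith("g_")})
        critic.load_state_arrays({k[2:]: z[k] for k in z.files if k.startswith("c_")})
    return WganModel(gen, critic, arch, cfg, WganTrainingLog())
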