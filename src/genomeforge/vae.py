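"""Benchmark variational autoencoder sharing the convolutional block design.

The encoder mirrors the WGAN critic (without packing) and ends in linear
layers producing per-dimension means mu and standard deviations sigma; the
decoder mirrors the generator (without the extra per-block noise channels)
and ends in a sigmoid. The loss is the usual evidence lower bound: binary
log loss of the reconstruction summed over sites, plus the closed-form KL
divergence between the diagonal-Gaussian posterior and the standard normal
prior. Sampling draws standard-normal latents through the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from . import nn
from .haplotype_io import HaplotypeMatrix
from .wgan import WganArchConfig, pca_overlap_distance


@dataclass
class VaeConfig:
    latent_dim: int = 64
    arch: WganArchConfig = field(default_factory=WganArchConfig)
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def kl_standard_normal(mu, sigma):
    """KL( N(mu, diag(sigma²)) || N(0, I) ) = Σ_d ½(mu_d² + sigma_d² − 1 − 2 ln sigma_d).

    Accepts arrays (returns a float) or Tensors (returns a Tensor summed over
    all dimensions; divide by batch size externally for a mean).
    """
    if isinstance(mu, Tensor) or isinstance(sigma, Tensor):
        if (sigma.data <= 0).any():
            raise ValueError("sigma must be positive")
        return 0.5 * ((mu ** 2) + (sigma ** 2) - 1.0 - 2.0 * ad.tlog(sigma)).sum()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValueError("sigma must be positive")
    return float(0.5 * (mu ** 2 + sigma ** 2 - 1 - 2 * np.log(sigma)).sum())


def vae_loss(x, reconstruction_probs, mu, sigma, clip: float = 1e-7):
    """Per-batch ELBO loss: summed binary log loss + KL, as a float or Tensor."""
    if isinstance(reconstruction_probs, Tensor):
        p = reconstruction_probs
        xt = x if isinstance(x, Tensor) else Tensor(x)
        rec = (-1.0) * (xt * ad.tlog(_clip_t(p, clip)) +
                        (1.0 - xt) * ad.tlog(_clip_t(1.0 - p, clip))).sum()
        return rec + kl_standard_normal(mu, sigma)
    p = np.clip(np.asarray(reconstruction_probs, dtype=float), clip, 1 - clip)
    x = np.asarray(x, dtype=float)
    rec = float(-(x * np.log(p) + (1 - x) * np.log(1 - p)).sum())
    return rec + kl_standard_normal(mu, sigma)


def _clip_t(p: Tensor, clip: float) -> Tensor:
    # additive clip keeps log finite while preserving gradients
    return p * (1 - 2 * clip) + clip


class Encoder(nn.Module):
    """Sequences (N, 1, L) -> (mu, sigma), each (N, latent_dim)."""

    def __init__(self, arch: WganArchConfig, latent_dim: int, seed: int):
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.blocks: list[nn.Module] = []
        self.locations: list[Tensor] = []
        length = arch.target_length
        level = arch.n_blocks
        c_in = 1
        while length > 3:
            c_out = arch.channels_at(level - 1)
            self.locations.append(Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True))
            self.blocks.append(nn.Conv1d(c_in + 1, c_out, 3, stride=2, pad=0, rng=rng))
            self.blocks.append(nn.BatchNorm1d(c_out))
            length = (length - 1) // 2
            level -= 1
            c_in = c_out
        self.fc_mu = nn.Linear(c_in * 3, latent_dim, rng=rng)
        self.fc_logsigma = nn.Linear(c_in * 3, latent_dim, rng=rng)

    def __call__(self, x: Tensor):
        h = x
        n = h.shape[0]
        for i in range(0, len(self.blocks), 2):
            loc = ad.broadcast_to(self.locations[i // 2], (n, 1, h.shape[2]))
            h = ad.concat([h, loc], axis=1)
            h = ad.leaky_relu(self.blocks[i + 1](self.blocks[i](h)), self.arch.leaky_slope)
        flat = h.reshape(n, h.shape[1] * 3)
        mu = self.fc_mu(flat)
        sigma = ad.texp(self.fc_logsigma(flat))
        return mu, sigma


class Decoder(nn.Module):
    """Latents (N, latent_dim) -> sigmoid sequences (N, 1, L)."""

    def __init__(self, arch: WganArchConfig, latent_dim: int, seed: int):
        rng = np.random.default_rng(seed)
        self.arch = arch
        c0 = arch.channels_at(0)
        self.fc = nn.Linear(latent_dim, c0 * 3, rng=rng)
        self.blocks: list[nn.Module] = []
        self.locations: list[Tensor] = []
        length = 3
        level = 0
        while length < arch.target_length:
            c_in = arch.channels_at(level)
            c_out = arch.channels_at(level + 1)
            self.locations.append(Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True))
            self.blocks.append(nn.ConvTranspose1d(c_in + 1, c_out, 3, stride=2, pad=0, rng=rng))
            self.blocks.append(nn.BatchNorm1d(c_out))
            length = 2 * length + 1
            level += 1
        c_last = arch.channels_at(level)
        self.out_location = Tensor(rng.normal(0, 0.1, (1, 1, length)), requires_grad=True)
        self.out_conv = nn.Conv1d(c_last + 1, 1, 3, 1, 1, rng=rng)

    def __call__(self, z: Tensor) -> Tensor:
        a = self.arch
        n = z.shape[0]
        h = ad.leaky_relu(self.fc(z), a.leaky_slope).reshape(n, a.channels_at(0), 3)
        for i in range(0, len(self.blocks), 2):
            loc = ad.broadcast_to(self.locations[i // 2], (n, 1, h.shape[2]))
            h = ad.concat([h, loc], axis=1)
            h = ad.leaky_relu(self.blocks[i + 1](self.blocks[i](h)), a.leaky_slope)
        loc = ad.broadcast_to(self.out_location, (n, 1, h.shape[2]))
        return ad.sigmoid(self.out_conv(ad.concat([h, loc], axis=1)))


@dataclass
class VaeModel:
    encoder: Encoder
    decoder: Decoder
    config: VaeConfig
    loss_history: list[float] = field(default_factory=list)


def train_vae(data: HaplotypeMatrix, config: VaeConfig) -> VaeModel:
    """Reparameterized ELBO training with Adam (default settings, lr 1e-3)."""
    x = np.asarray(data.alleles, dtype=np.float64)
    if x.shape[1] != config.arch.target_length:
        raise ValueError("data columns must equal arch.target_length (pad upstream)")
    rng = np.random.default_rng(config.seed)
    enc = Encoder(config.arch, config.latent_dim, config.seed)
    dec = Decoder(config.arch, config.latent_dim, config.seed + 1)
    opt = nn.Adam(enc.parameters() + dec.parameters(), config.lr)
    model = VaeModel(enc, dec, config)
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            xb = x[order[start : start + config.batch_size]]
            xt = Tensor(xb[:, None, :])
            mu, sigma = enc(xt)
            z = mu + sigma * Tensor(rng.normal(size=mu.shape))
            probs = dec(z)
            loss = vae_loss(Tensor(xb), probs.reshape(xb.shape), mu, sigma) * (1.0 / xb.shape[0])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite VAE loss at epoch {epoch}")
            epoch_loss += float(loss.data) * xb.shape[0]
        model.loss_history.append(epoch_loss / n)
    return model


def sample_vae(model: VaeModel, n: int, seed: int = 0, binarize: str = "threshold") -> HaplotypeMatrix:
    """Draw standard-normal latents through the decoder; binarize as in the WGAN."""
    rng = np.random.default_rng(seed)
    nn.set_training(model.decoder, False)
    try:
        with ad.no_grad():
            z = Tensor(rng.normal(size=(n, model.config.latent_dim)))
            out = model.decoder(z).data[:, 0, :]
    finally:
        nn.set_training(model.decoder, True)
    if binarize == "threshold":
        alleles = (out >= 0.5).astype(np.int8)
    elif binarize == "bernoulli":
        alleles = (rng.random(out.shape) < out).astype(np.int8)
    else:
        raise ValueError("binarize must be 'threshold' or 'bernoulli'")
    return HaplotypeMatrix(alleles)
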