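"""Binary restricted Boltzmann machine with out-of-equilibrium (Rdm-k) training.

The model is a joint distribution over binary visible units s (one per SNP)
and binary hidden units tau,

    p(s, tau) = (1/Z) exp( Σ_ia w_ia s_i tau_a + Σ_i theta_i s_i + Σ_a eta_a tau_a ),

trained by likelihood gradient ascent. The out-of-equilibrium (Rdm-k) scheme
departs from conventional persistent/contrastive training in one precise
way: the negative-phase Monte-Carlo chains are always started fresh from a
fixed initial law p0 (uniform Bernoulli 0.5 here) and run exactly k
alternating Gibbs steps — both during every gradient update and later when
generating samples. The model is then used as a sampler matched to that
dynamical process rather than as an equilibrium distribution, so generation
reproduces the training-time dynamics exactly (same p0, same k).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np

from .haplotype_io import HaplotypeMatrix


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class RBMParams:
    """Weights and biases of one machine: w (n_visible, n_hidden), visible
    biases theta, hidden biases eta."""

    w: np.ndarray
    theta: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        nv, nh = self.w.shape
        if self.theta.shape != (nv,) or self.eta.shape != (nh,):
            raise ValueError("inconsistent parameter shapes")
        if not (np.isfinite(self.w).all() and np.isfinite(self.theta).all() and np.isfinite(self.eta).all()):
            raise ValueError("non-finite parameters")

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.w.copy(), self.theta.copy(), self.eta.copy())


@dataclass
class RdmKConfig:
    """Out-of-equilibrium training configuration.

    ``k_steps`` is the fixed Monte-Carlo step count used in every negative
    phase and at generation time (the paper-scale defaults are 100 for long
    panels and 200 at the 10,000-SNP scale). ``learning_rate`` defaults to
    0.005; p0 is uniform Bernoulli(0.5) and is part of the scheme, not a
    knob.
    """

    k_steps: int = 100
    learning_rate: float = 0.005
    n_hidden: int = 64
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_steps < 1:
            raise ValueError("k_steps must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainingLog:
    top_singular_values: list[np.ndarray] = field(default_factory=list)
    exact_log_likelihood: list[float] = field(default_factory=list)
    epochs: int = 0


def hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(tau_a = 1 | v) = logistic(Σ_i w_ia v_i + eta_a); v may be a batch."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != params.n_visible:
        raise ValueError(f"visible width {v.shape[-1]} != {params.n_visible}")
    return _sigmoid(v @ params.w + params.eta)


def visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(s_i = 1 | h) = logistic(Σ_a w_ia h_a + theta_i); h may be a batch."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(f"hidden width {h.shape[-1]} != {params.n_hidden}")
    return _sigmoid(h @ params.w.T + params.theta)


def gibbs_k(params: RBMParams, v0: np.ndarray, k_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Run k full alternating block updates (hidden then visible) from v0."""
    if k_steps < 1:
        raise ValueError("k_steps must be >= 1")
    v = np.atleast_2d(np.asarray(v0, dtype=np.float64))
    for _ in range(k_steps):
        ph = hidden_conditional(params, v)
        h = (rng.random(ph.shape) < ph).astype(np.float64)
        pv = visible_conditional(params, h)
        v = (rng.random(pv.shape) < pv).astype(np.float64)
    return v if np.asarray(v0).ndim == 2 else v[0]


def sample_p0(n: int, n_visible: int, rng: np.random.Generator) -> np.ndarray:
    """The fixed initial law p0: each unit iid Bernoulli(0.5)."""
    return (rng.random((n, n_visible)) < 0.5).astype(np.float64)


def _moments(v: np.ndarray, ph: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = v.shape[0]
    return v.T @ ph / n, v.mean(axis=0), ph.mean(axis=0)


def rdmk_gradient(params: RBMParams, batch: np.ndarray, config: RdmKConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood gradient with the Rdm-k negative phase.

    Positive phase: data moments with hidden means given the batch.
    Negative phase: moments of fresh chains started from p0 and run exactly
    ``config.k_steps``; hidden means (not samples) are used on the final
    visible state. Returns (grad_w, grad_theta, grad_eta).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    pos_w, pos_t, pos_e = _moments(batch, hidden_conditional(params, batch))
    v_neg = gibbs_k(params, sample_p0(batch.shape[0], params.n_visible, rng), config.k_steps, rng)
    neg_w, neg_t, neg_e = _moments(v_neg, hidden_conditional(params, v_neg))
    return pos_w - neg_w, pos_t - neg_t, pos_e - neg_e


def train_rbm(data: HaplotypeMatrix | np.ndarray, config: RdmKConfig,
              track_exact_ll: bool = False,
              checkpoint_every: int | None = None) -> tuple[RBMParams, TrainingLog] | tuple[RBMParams, TrainingLog, list[RBMParams]]:
    """Train an RBM by plain SGD on Rdm-k gradients.

    The log records the top singular values of w per epoch (the learning is
    healthy when they grow smoothly from ~0 to O(1) over the first epochs)
    and, when ``track_exact_ll`` is set and the machine is small enough, the
    exact mean log-likelihood per epoch. With ``checkpoint_every`` set,
    per-epoch parameter snapshots are returned as a third element so that
    model selection (e.g. by AA_TS on generated samples) can pick an epoch a
    posteriori.
    """
    x = data.alleles if isinstance(data, HaplotypeMatrix) else np.asarray(data)
    x = x.astype(np.float64)
    n, nv = x.shape
    rng = np.random.default_rng(config.seed)
    params = RBMParams(
        rng.normal(0, 0.01, (nv, config.n_hidden)), np.zeros(nv), np.zeros(config.n_hidden)
    )
    log = TrainingLog()
    checkpoints: list[RBMParams] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = x[order[start : start + config.batch_size]]
            gw, gt, ge = rdmk_gradient(params, batch, config, rng)
            params.w += config.learning_rate * gw
            params.theta += config.learning_rate * gt
            params.eta += config.learning_rate * ge
        if not (np.isfinite(params.w).all() and np.isfinite(params.theta).all()
                and np.isfinite(params.eta).all()):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        sv = np.linalg.svd(params.w, compute_uv=False)
        log.top_singular_values.append(sv[: min(5, sv.size)])
        if track_exact_ll and min(nv, config.n_hidden) <= 20:
            log.exact_log_likelihood.append(exact_log_likelihood(params, x))
        if checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            checkpoints.append(params.copy())
        log.epochs = epoch + 1
    if checkpoint_every:
        return params, log, checkpoints
    return params, log


def sample_rbm(params: RBMParams, n_samples: int, config: RdmKConfig, seed: int | None = None) -> HaplotypeMatrix:
    """Generate samples with the same dynamical process used in training.

    Each of the ``n_samples`` chains starts fresh from p0 and runs exactly
    ``config.k_steps`` Gibbs steps — the matched out-of-equilibrium sampler.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    v = gibbs_k(params, sample_p0(n_samples, params.n_visible, rng), config.k_steps, rng)
    return HaplotypeMatrix(v.astype(np.int8))


def _free_energy_terms(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """Per-sample unnormalized log-marginal: theta·s + Σ_a softplus(w^T s + eta)."""
    act = v @ params.w + params.eta
    return v @ params.theta + np.logaddexp(0.0, act).sum(axis=-1)


def exact_log_likelihood(params: RBMParams, data: np.ndarray | HaplotypeMatrix) -> float:
    """Mean log-likelihood with Z enumerated over the smaller layer.

    Only feasible for tiny machines (min(n_visible, n_hidden) <= 20); the
    partition function is intractable beyond that and a larger machine is
    refused.
    """
    x = data.alleles if isinstance(data, HaplotypeMatrix) else np.asarray(data)
    x = np.atleast_2d(x).astype(np.float64)
    nv, nh = params.n_visible, params.n_hidden
    if min(nv, nh) > 20:
        raise ValueError("machine too large: partition function is intractable")
    if nh <= nv:
        # enumerate hidden layer: Z = Σ_h exp(eta·h) Π_i (1 + exp(w h + theta)_i)
        states = np.array(list(product((0.0, 1.0), repeat=nh)))
        log_terms = states @ params.eta + np.logaddexp(0.0, states @ params.w.T + params.theta).sum(axis=1)
    else:
        states = np.array(list(product((0.0, 1.0), repeat=nv)))
        log_terms = _free_energy_terms(params, states)
    from scipy.special import logsumexp

    log_z = float(logsumexp(log_terms))
    return float(_free_energy_terms(params, x).mean() - log_z)


def save_rbm(path, params: RBMParams, config: RdmKConfig) -> None:
    """Keyed-array checkpoint (.npz) holding w/theta/eta plus the config."""
    np.savez(path, w=params.w, theta=params.theta, eta=params.eta,
             config=json.dumps(asdict(config)))


def load_rbm(path) -> tuple[RBMParams, RdmKConfig]:
    with np.load(path, allow_pickle=False) as z:
        params = RBMParams(z["w"], z["theta"], z["eta"])
        config = RdmKConfig(**json.loads(str(z["config"])))
    return params, config
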