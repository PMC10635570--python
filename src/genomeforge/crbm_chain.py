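"""Conditional RBMs and windowed chaining for arbitrarily long sequences.

A conditional RBM (CRBM) splits its visible window into pinned variables x
(clamped to given values) and inferred variables s, and models

    p(s | x) ∝ exp( Σ_ia w_ia s_i tau_a + Σ_i theta_i s_i + Σ_a eta_a tau_a
                    + Σ_a tau_a Σ_j wpin_ja x_j ),

i.e. a classical RBM over the inferred block whose hidden biases are shifted
by the pinned variables. Chaining one unconditional RBM (for the first
window) with a sequence of CRBMs whose pinned range overlaps the previously
generated sequence lets the stack generate sequences far longer than any
single machine could handle: generate the first window, then repeatedly pin
the trailing ``overlap`` columns and sample the next inferred block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .haplotype_io import HaplotypeMatrix
from .rbm_core import (
    RBMParams,
    RdmKConfig,
    TrainingLog,
    _sigmoid,
    hidden_conditional,
    visible_conditional,
    sample_p0,
    sample_rbm,
    train_rbm,
    _moments,
)


@dataclass
class CRBMParams:
    """An RBM over the inferred units plus pinned-to-hidden couplings."""

    base: RBMParams
    w_pin: np.ndarray

    def __post_init__(self) -> None:
        self.w_pin = np.asarray(self.w_pin, dtype=np.float64)
        if self.w_pin.ndim != 2 or self.w_pin.shape[1] != self.base.n_hidden:
            raise ValueError("w_pin must be (n_pinned, n_hidden) sharing the hidden dimension")
        if not np.isfinite(self.w_pin).all():
            raise ValueError("non-finite w_pin")

    @property
    def n_pinned(self) -> int:
        return self.w_pin.shape[0]

    @property
    def n_inferred(self) -> int:
        return self.base.n_visible


@dataclass
class WindowPlan:
    """Window coordinates (0-based half-open) tiling [0, n_snps) exactly.

    ``first_window`` is generated by the unconditional RBM;
    ``crbm_windows`` entries are (pinned_start, pinned_end, inferred_start,
    inferred_end), each pinned range lying inside previously generated
    columns.
    """

    first_window: tuple[int, int]
    crbm_windows: list[tuple[int, int, int, int]]
    n_snps: int

    def validate(self) -> None:
        covered_end = self.first_window[1]
        if self.first_window[0] != 0:
            raise ValueError("first window must start at 0")
        for ps, pe, istart, iend in self.crbm_windows:
            if not (ps < pe <= covered_end and istart == covered_end and iend > istart):
                raise ValueError("windows must tile contiguously with pinned range inside covered columns")
            covered_end = iend
        if covered_end != self.n_snps:
            raise ValueError("windows do not tile [0, n_snps)")


def plan_windows(n_snps: int, first_width: int, window_width: int, overlap: int) -> WindowPlan:
    """Tile a sequence into one RBM window plus overlapping CRBM windows.

    The first ``first_width`` columns go to the unconditional RBM. Each CRBM
    window spans ``window_width`` columns of which the leading ``overlap``
    are pinned to already-generated columns, so each machine infers
    ``window_width − overlap`` fresh columns. The last window is end-aligned:
    its inferred block is the (possibly shorter) remainder, keeping the
    tiling exact.
    """
    if not (0 < overlap < window_width <= n_snps):
        raise ValueError("need 0 < overlap < window_width <= n_snps")
    if first_width < overlap or first_width > n_snps:
        raise ValueError("need overlap <= first_width <= n_snps")
    windows = []
    covered = first_width
    step = window_width - overlap
    while covered < n_snps:
        iend = min(covered + step, n_snps)
        windows.append((covered - overlap, covered, covered, iend))
        covered = iend
    plan = WindowPlan((0, first_width), windows, n_snps)
    plan.validate()
    return plan


@dataclass
class CRBMChain:
    first: RBMParams
    rest: list[CRBMParams]
    plan: WindowPlan
    config: RdmKConfig

    def __post_init__(self) -> None:
        if len(self.rest) != len(self.plan.crbm_windows):
            raise ValueError("machine count must equal CRBM window count")


def crbm_hidden_conditional(params: CRBMParams, s_inferred: np.ndarray, x_pinned: np.ndarray) -> np.ndarray:
    """P(tau_a = 1 | s, x) = logistic(Σ_i w_ia s_i + eta_a + Σ_j wpin_ja x_j)."""
    s = np.asarray(s_inferred, dtype=np.float64)
    x = np.asarray(x_pinned, dtype=np.float64)
    if s.shape[-1] != params.n_inferred or x.shape[-1] != params.n_pinned:
        raise ValueError("inferred/pinned width mismatch")
    return _sigmoid(s @ params.base.w + params.base.eta + x @ params.w_pin)


def sample_crbm(params: CRBMParams, x_pinned: np.ndarray, k_steps: int,
                rng: np.random.Generator) -> np.ndarray:
    """Sample the inferred block given pinned values (pinned held fixed).

    Chains start from p0 on the inferred units only and run ``k_steps``
    alternating updates; the pinned variables contribute fixed hidden-bias
    shifts throughout.
    """
    x = np.atleast_2d(np.asarray(x_pinned, dtype=np.float64))
    s = sample_p0(x.shape[0], params.n_inferred, rng)
    bias_shift = x @ params.w_pin  # constant across steps
    for _ in range(k_steps):
        ph = _sigmoid(s @ params.base.w + params.base.eta + bias_shift)
        h = (rng.random(ph.shape) < ph).astype(np.float64)
        ps = visible_conditional(params.base, h)
        s = (rng.random(ps.shape) < ps).astype(np.float64)
    return s if np.asarray(x_pinned).ndim == 2 else s[0]


def crbm_rdmk_gradient(params: CRBMParams, s_batch: np.ndarray, x_batch: np.ndarray,
                       config: RdmKConfig, rng: np.random.Generator):
    """Conditional-likelihood gradient with the Rdm-k negative phase.

    Both phases pin x to the data; the negative phase resamples only the
    inferred units for k steps. Returns (gw, gtheta, geta, gwpin).
    """
    s_batch = np.atleast_2d(np.asarray(s_batch, dtype=np.float64))
    x_batch = np.atleast_2d(np.asarray(x_batch, dtype=np.float64))
    if s_batch.shape[0] == 0:
        raise ValueError("empty batch")
    n = s_batch.shape[0]
    ph_pos = crbm_hidden_conditional(params, s_batch, x_batch)
    pos_w, pos_t, pos_e = _moments(s_batch, ph_pos)
    pos_pin = x_batch.T @ ph_pos / n
    s_neg = sample_crbm(params, x_batch, config.k_steps, rng)
    ph_neg = crbm_hidden_conditional(params, s_neg, x_batch)
    neg_w, neg_t, neg_e = _moments(s_neg, ph_neg)
    neg_pin = x_batch.T @ ph_neg / n
    return pos_w - neg_w, pos_t - neg_t, pos_e - neg_e, pos_pin - neg_pin


def train_crbm(data: HaplotypeMatrix | np.ndarray, window: tuple[tuple[int, int], tuple[int, int]],
               config: RdmKConfig) -> tuple[CRBMParams, TrainingLog]:
    """Train a CRBM on one (pinned_range, inferred_range) window of the data."""
    x_full = data.alleles if isinstance(data, HaplotypeMatrix) else np.asarray(data)
    x_full = x_full.astype(np.float64)
    (ps, pe), (istart, iend) = window
    if not (0 <= ps < pe <= x_full.shape[1] and 0 <= istart < iend <= x_full.shape[1]):
        raise ValueError("window ranges outside data columns")
    pinned = x_full[:, ps:pe]
    inferred = x_full[:, istart:iend]
    n = x_full.shape[0]
    rng = np.random.default_rng(config.seed)
    params = CRBMParams(
        RBMParams(rng.normal(0, 0.01, (iend - istart, config.n_hidden)),
                  np.zeros(iend - istart), np.zeros(config.n_hidden)),
        rng.normal(0, 0.01, (pe - ps, config.n_hidden)),
    )
    log = TrainingLog()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            gw, gt, ge, gp = crbm_rdmk_gradient(params, inferred[sel], pinned[sel], config, rng)
            params.base.w += config.learning_rate * gw
            params.base.theta += config.learning_rate * gt
            params.base.eta += config.learning_rate * ge
            params.w_pin += config.learning_rate * gp
        if not np.isfinite(params.base.w).all() or not np.isfinite(params.w_pin).all():
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        sv = np.linalg.svd(params.base.w, compute_uv=False)
        log.top_singular_values.append(sv[: min(5, sv.size)])
        log.epochs = epoch + 1
    return params, log


def _machine_seed(master_seed: int, window_index: int) -> int:
    """Stable per-machine seed; makes serial and concurrent training identical."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(window_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def train_chain(data: HaplotypeMatrix | np.ndarray, plan: WindowPlan,
                config: RdmKConfig) -> CRBMChain:
    """Train the first RBM and every CRBM of a window plan independently.

    Machines share no mutable state and get per-machine seeds derived from
    the master seed, so they can be trained serially or concurrently with
    identical results.
    """
    plan.validate()
    x = data.alleles if isinstance(data, HaplotypeMatrix) else np.asarray(data)
    if x.shape[1] != plan.n_snps:
        raise ValueError("plan does not match data columns")
    from dataclasses import replace

    f0, f1 = plan.first_window
    first, _ = train_rbm(x[:, f0:f1], replace(config, seed=_machine_seed(config.seed, 0)))
    rest = []
    for i, (ps, pe, istart, iend) in enumerate(plan.crbm_windows):
        cfg_i = replace(config, seed=_machine_seed(config.seed, i + 1))
        try:
            params, _ = train_crbm(x, ((ps, pe), (istart, iend)), cfg_i)
        except Exception as exc:
            raise RuntimeError(f"CRBM window {i} ({ps}:{pe} | {istart}:{iend}) failed") from exc
        rest.append(params)
    return CRBMChain(first, rest, plan, config)


def sample_chain(chain: CRBMChain, n_samples: int, seed: int = 0) -> HaplotypeMatrix:
    """Generate full-length sequences window by window.

    The first window comes from the unconditional RBM; each CRBM then pins
    the trailing overlap of the sequence generated so far and appends its
    inferred block. Every output column is produced by exactly one machine
    and pinned columns are never resampled.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros((n_samples, chain.plan.n_snps), dtype=np.int8)
    f0, f1 = chain.plan.first_window
    first_block = sample_rbm(chain.first, n_samples, chain.config, seed=int(rng.integers(2**31)))
    out[:, f0:f1] = first_block.alleles
    for params, (ps, pe, istart, iend) in zip(chain.rest, chain.plan.crbm_windows):
        pinned = out[:, ps:pe].astype(np.float64)
        block = sample_crbm(params, pinned, chain.config.k_steps,
                            np.random.default_rng(int(rng.integers(2**31))))
        out[:, istart:iend] = block.astype(np.int8)
    return HaplotypeMatrix(out)


def save_chain(path, chain: CRBMChain) -> None:
    """Keyed-array archive of per-machine parameters + plan + config."""
    arrays = {
        "first_w": chain.first.w, "first_theta": chain.first.theta, "first_eta": chain.first.eta,
        "meta": np.array(json.dumps({
            "first_window": list(chain.plan.first_window),
            "crbm_windows": [list(w) for w in chain.plan.crbm_windows],
            "n_snps": chain.plan.n_snps,
            "config": asdict(chain.config),
        })),
    }
    for i, p in enumerate(chain.rest):
        arrays[f"crbm{i}_w"] = p.base.w
        arrays[f"crbm{i}_theta"] = p.base.theta
        arrays[f"crbm{i}_eta"] = p.base.eta
        arrays[f"crbm{i}_wpin"] = p.w_pin
    np.savez(path, **arrays)


def load_chain(path) -> CRBMChain:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        first = RBMParams(z["first_w"], z["first_theta"], z["first_eta"])
        rest = [
            CRBMParams(RBMParams(z[f"crbm{i}_w"], z[f"crbm{i}_theta"], z[f"crbm{i}_eta"]), z[f"crbm{i}_wpin"])
            for i in range(len(meta["crbm_windows"]))
        ]
        plan = WindowPlan(tuple(meta["first_window"]), [tuple(w) for w in meta["crbm_windows"]], meta["n_snps"])
        return CRBMChain(first, rest, plan, RdmKConfig(**meta["config"]))
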