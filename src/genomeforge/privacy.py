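"""Overfitting/underfitting and privacy-leakage metrics for artificial genomes.

The central quantity is the nearest-neighbour adversarial accuracy AA_TS:
with T the real (truth) set and S the generated (synthetic) set, each of n
samples,

    AA_truth = (1/n) Σ_i 1( d_TS(i) > d_TT(i) )
    AA_syn   = (1/n) Σ_i 1( d_ST(i) > d_SS(i) )
    AA_TS    = (AA_truth + AA_syn) / 2

where d_XY(i) is the distance from sample i of set X to its nearest
neighbour in set Y (within-set neighbours exclude the sample itself) and the
indicators use strict inequality. AA_TS = 0.5 is the well-calibrated ideal;
values below 0.5 indicate overfitting (generated points sit too close to
real ones), values above 0.5 indicate underfitting. The privacy score is the
difference Test AA_TS − Train AA_TS; its expectation is 0 when the generator
leaks nothing about its training samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .haplotype_io import HaplotypeMatrix


def _as_array(x) -> np.ndarray:
    if isinstance(x, HaplotypeMatrix):
        return np.asarray(x.alleles, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _distances(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    # hamming counts (number of differing sites) rather than scipy's fraction:
    # monotone-equivalent for nearest neighbours, but more interpretable
    if metric == "hamming":
        return cdist(a, b, metric="hamming") * a.shape[1]
    return cdist(a, b, metric=metric)


@dataclass
class AAtsResult:
    aa_truth: float
    aa_syn: float
    aa_ts: float
    d_tt: np.ndarray
    d_ts: np.ndarray
    d_st: np.ndarray
    d_ss: np.ndarray


def aa_ts(truth, synthetic, metric: str = "hamming") -> AAtsResult:
    """Nearest-neighbour adversarial accuracy between equal-sized sets.

    Within-set nearest neighbours exclude self; indicators use strict
    inequality, so exact duplicates across sets (tied zero distances) count
    toward overfitting.
    """
    t = _as_array(truth)
    s = _as_array(synthetic)
    if t.shape[0] != s.shape[0]:
        raise ValueError(
            f"truth and synthetic must have equal row counts (got {t.shape[0]} vs {s.shape[0]}); "
            "resample upstream"
        )
    if t.shape[1] != s.shape[1]:
        raise ValueError("truth and synthetic must have equal column counts")
    d_cross = _distances(t, s, metric)
    d_tt_m = _distances(t, t, metric)
    np.fill_diagonal(d_tt_m, np.inf)
    d_ss_m = _distances(s, s, metric)
    np.fill_diagonal(d_ss_m, np.inf)
    d_ts = d_cross.min(axis=1)
    d_st = d_cross.min(axis=0)
    d_tt = d_tt_m.min(axis=1)
    d_ss = d_ss_m.min(axis=1)
    aa_truth = float(np.mean(d_ts > d_tt))
    aa_syn = float(np.mean(d_st > d_ss))
    return AAtsResult(aa_truth, aa_syn, (aa_truth + aa_syn) / 2, d_tt, d_ts, d_st, d_ss)


@dataclass
class PrivacyScoreResult:
    score: float
    train_aats: AAtsResult
    test_aats: AAtsResult


def privacy_score(train, test, synthetic, metric: str = "hamming") -> PrivacyScoreResult:
    """Privacy score = Test AA_TS − Train AA_TS.

    Positive values mean generated samples sit closer to the training set
    than to held-out samples from the same distribution, i.e. training data
    leaks into the output.
    """
    train_r = aa_ts(train, synthetic, metric)
    test_r = aa_ts(test, synthetic, metric)
    return PrivacyScoreResult(test_r.aa_ts - train_r.aa_ts, train_r, test_r)


@dataclass
class ChainPatternTable:
    """Frequencies of S/T patterns along nearest-neighbour chains.

    ``frequencies[pattern]`` is the fraction of chain starts (over all
    samples of both sets) whose visited-set-label sequence equals
    ``pattern``. For each length, frequencies over patterns starting with S
    sum to 0.5, likewise for T.
    """

    frequencies: dict[str, float]
    n_starts: int

    def by_length(self, length: int) -> dict[str, float]:
        return {p: f for p, f in self.frequencies.items() if len(p) == length}


def nn_chain_frequencies(truth, synthetic, max_len: int = 5, metric: str = "hamming") -> ChainPatternTable:
    """Nearest-neighbour chain pattern frequencies over the union of both sets.

    A chain starts at every sample of both sets and repeatedly hops to the
    nearest neighbour among all samples not yet visited; the pattern is the
    sequence of set labels (S for synthetic, T for truth) along the chain.
    Frequencies are reported for every pattern of length 2..max_len. Under
    exchangeable sets every pattern of length L has expected frequency
    2^-L (0.25 at length 2, …, 0.03125 at length 5). Ties are broken by
    lowest sample index.
    """
    t = _as_array(truth)
    s = _as_array(synthetic)
    if t.shape[0] != s.shape[0]:
        raise ValueError("truth and synthetic must have equal row counts")
    n_t = t.shape[0]
    union = np.vstack([t, s])
    n_total = union.shape[0]
    if max_len > n_total:
        raise ValueError("chain length exceeds total sample count")
    labels = np.array(["T"] * n_t + ["S"] * s.shape[0])
    d = _distances(union, union, metric)
    np.fill_diagonal(d, np.inf)
    counts: dict[str, int] = {}
    for start in range(n_total):
        visited = [start]
        dist_row = d[start].copy()
        pattern = labels[start]
        for _ in range(max_len - 1):
            nxt = int(np.argmin(dist_row))  # argmin is lowest-index on ties
            pattern += labels[nxt]
            visited.append(nxt)
            if len(pattern) < max_len:
                dist_row = d[nxt].copy()
                dist_row[visited] = np.inf
            if len(pattern) >= 2:
                counts[pattern] = counts.get(pattern, 0) + 1
        # counts above accumulates every prefix length 2..max_len exactly once
    freqs = {p: c / n_total for p, c in counts.items()}
    return ChainPatternTable(freqs, n_total)


def rank_accuracy(scores, true_membership, top_fractions=(0.01, 0.10, 0.25, 0.50)) -> dict[float, float]:
    """Membership-prediction accuracy of a score ranking.

    Candidates are sorted by descending score (stable, so ties at the cut
    are broken by input order); for each fraction the top n = fraction ×
    total are predicted members, and accuracy is the fraction of those
    predictions that are true members.
    """
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(true_membership, dtype=bool)
    if scores.shape != member.shape:
        raise ValueError("scores and membership flags must have equal length")
    order = np.argsort(-scores, kind="stable")
    out = {}
    for frac in top_fractions:
        n = max(1, int(round(frac * len(scores))))
        out[float(frac)] = float(member[order[:n]].mean())
    return out


@dataclass
class MiaResult:
    mode: str
    accuracy: dict[float, float]
    scores_train: np.ndarray
    scores_test: np.ndarray


def score_with_packed_critic(critic, candidates, packing: int, n_packings: int = 16, seed: int = 0) -> np.ndarray:
    """Score single samples through a packing critic.

    The critic consumes `packing` samples at once, so a single candidate has
    no canonical score. Each candidate is scored as the mean critic output
    over ``n_packings`` random packings, the candidate occupying each slot
    position in turn and the remaining slots filled with random candidates.
    """
    x = _as_array(candidates)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for r in range(n_packings):
        slot = r % packing
        packs = np.empty((n, packing, x.shape[1]))
        fill = rng.integers(0, n, size=(n, packing))
        packs[:] = x[fill]
        packs[:, slot, :] = x
        total += critic.score(packs)
    return total / n_packings


def mia_white_box(critic, candidates, membership_flags, top_fractions=(0.01, 0.10, 0.25, 0.50),
                  n_packings: int = 16, seed: int = 0) -> MiaResult:
    """White-box membership inference: score candidates with the trained critic.

    ``critic`` is a trained WGAN critic (exposing ``.score(packs)`` and
    ``.packing``); candidates mix known training and held-out samples, and
    the top-ranked fraction is predicted to be training data.
    """
    member = np.asarray(membership_flags, dtype=bool)
    scores = score_with_packed_critic(critic, candidates, critic.packing, n_packings, seed)
    acc = rank_accuracy(scores, member, top_fractions)
    return MiaResult("white_box", acc, scores[member], scores[~member])


def mia_black_box(ags, arch, train_cfg, candidates, membership_flags,
                  top_fractions=(0.01, 0.10, 0.25, 0.50), n_packings: int = 16) -> MiaResult:
    """Black-box membership inference via a shadow critic.

    A fresh WGAN with the published architecture is trained on the released
    artificial genomes (and deliberately overtrained to induce overfitting);
    its critic then scores the candidates exactly as in the white-box attack.
    Model-agnostic: only the AGs, not the original model, are needed.
    """
    from .wgan import train_wgan

    member = np.asarray(membership_flags, dtype=bool)
    model = train_wgan(ags if isinstance(ags, HaplotypeMatrix) else HaplotypeMatrix(ags), arch, train_cfg)
    scores = score_with_packed_critic(model.critic, candidates, arch.packing, n_packings, train_cfg.seed + 1)
    acc = rank_accuracy(scores, member, top_fractions)
    return MiaResult("black_box", acc, scores[member], scores[~member])
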