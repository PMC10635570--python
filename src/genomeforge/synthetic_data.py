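"""Structured synthetic haplotypes and controlled truth/synthetic scenarios.

Real SNP-array panels show three features that matter for both the generative
models and the evaluation metrics: population structure (a few broad
continental modes), a site-frequency spectrum skewed towards low-frequency
alternative alleles, and linkage disequilibrium that decays with distance.
:func:`simulate_structured_haplotypes` emulates all three with a
Balding-Nichols frequency model plus a first-order haplotype-copying process,
so every model and metric in the package is testable without external data.

:func:`make_scenario_pair` builds truth/synthetic pairs that realise the
canonical pathological outcomes of generative training (exact copying,
disjoint clusters, locally averaged pockets, high-variance scatter around the
real modes) which honest training cannot reliably produce on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_io import HaplotypeMatrix

SCENARIOS = (
    "exchangeable",
    "overfit_copy",
    "underfit_clusters",
    "aberration_syn_pockets",
    "aberration_truth_modes",
)


@dataclass
class PopSimConfig:
    """Configuration of the structured-haplotype simulator.

    Attributes
    ----------
    n_pops
        Number of population modes (default 3, emulating broad continental
        structure).
    n_hap_per_pop
        Haplotypes per population.
    n_snps
        Number of SNP columns.
    fst
        Balding-Nichols divergence between populations, in [0, 1).
    copy_switch_prob
        Per-site probability that the latent copying state is refreshed;
        small values give long-range LD, 1.0 gives independent sites.
    beta_sfs
        (a, b) shape of the Beta distribution of ancestral allele
        frequencies. The default (0.3, 0.9) skews towards low-frequency
        alternative alleles, mimicking a SNP-panel site-frequency spectrum.
    share_prob
        Probability that a haplotype is an imperfect copy (identity by
        descent) of an earlier haplotype of its population rather than a
        fresh draw. Real panels show pervasive haplotype sharing; it also
        spreads the nearest-neighbour Hamming-distance spectrum, which
        otherwise concentrates on a few integer values at small SNP counts.
        Default 0 (off) for the plain simulator.
    share_mut_range
        Per-site mutation-rate range for shared copies (uniform draw).
    seed
        Seed for all randomness.
    """

    n_pops: int = 3
    n_hap_per_pop: int = 100
    n_snps: int = 1000
    fst: float = 0.1
    copy_switch_prob: float = 0.1
    beta_sfs: tuple[float, float] = (0.3, 0.9)
    share_prob: float = 0.0
    share_mut_range: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 < self.copy_switch_prob <= 1):
            raise ValueError("copy_switch_prob must be in (0, 1]")
        for name in ("n_pops", "n_hap_per_pop", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.beta_sfs) <= 0:
            raise ValueError("beta_sfs shapes must be positive")
        if not (0 <= self.share_prob <= 1):
            raise ValueError("share_prob must be in [0, 1]")


def _population_frequencies(cfg: PopSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model."""
    a, b = cfg.beta_sfs
    p = rng.beta(a, b, size=cfg.n_snps)
    p = np.clip(p, 0.01, 0.99)
    if cfg.fst == 0:
        return np.tile(p, (cfg.n_pops, 1))
    c = (1 - cfg.fst) / cfg.fst  # Beta(c*p, c*(1-p)) has mean p, var fst*p*(1-p)
    return rng.beta(c * p, c * (1 - p), size=(cfg.n_pops, cfg.n_snps))


def simulate_structured_haplotypes(config: PopSimConfig) -> HaplotypeMatrix:
    """Simulate a structured haplotype panel with decaying LD.

    Each population draws allele frequencies from a Balding-Nichols
    distribution around shared ancestral frequencies (mean p, variance
    fst·p(1−p)). Within a haplotype, alleles are thresholded latent uniforms
    (site j carries allele 1 iff u_j < f_j); the latent uniform is carried
    along the chromosome and refreshed at each site with probability
    ``copy_switch_prob``. Marginal site frequencies are therefore exactly
    the Balding-Nichols draws, while sites d apart share their latent state
    with probability (1 − copy_switch_prob)^d, producing r² that decays
    geometrically with SNP distance (copy_switch_prob = 1 gives independent
    sites).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = _population_frequencies(config, rng)
    n_total = config.n_pops * config.n_hap_per_pop
    out = np.empty((n_total, config.n_snps), dtype=np.int8)
    labels = []
    row = 0
    n, m = config.n_hap_per_pop, config.n_snps
    for pop in range(config.n_pops):
        f = freqs[pop]
        switch = rng.random((n, m)) < config.copy_switch_prob
        switch[:, 0] = True
        fresh_u = rng.random((n, m))
        # carry the last refreshed uniform forward between switch events
        seg = np.maximum.accumulate(np.where(switch, np.arange(m), -1), axis=1)
        u = np.take_along_axis(fresh_u, seg, axis=1)
        haps = (u < f).astype(np.int8)
        if config.share_prob > 0:
            haps = _apply_sharing(haps, config, rng)
        out[row : row + n] = haps
        labels += [f"pop{pop} h{i}" for i in range(n)]  # two-token hapt label convention
        row += n
    return HaplotypeMatrix(out, labels=labels)


def _apply_sharing(haps: np.ndarray, config: PopSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Replace some haplotypes with imperfect copies of earlier ones (IBD)."""
    lo, hi = config.share_mut_range
    for i in range(1, haps.shape[0]):
        if rng.random() < config.share_prob:
            donor = rng.integers(0, i)
            rate = rng.uniform(lo, hi)
            flips = rng.random(haps.shape[1]) < rate
            haps[i] = np.where(flips, 1 - haps[donor], haps[donor])
    return haps


def binomial_baseline(real: HaplotypeMatrix, n_out: int, seed: int = 0) -> HaplotypeMatrix:
    """Site-independent Bernoulli generator matched to the real frequencies.

    Every output entry is drawn independently at its column's empirical
    alternative-allele frequency. This is the weakest sensible generator: it
    matches the allele-frequency spectrum exactly in expectation but carries
    no LD, and serves as the lower anchor of the pairwise-distance radar
    score.
    """
    rng = np.random.default_rng(seed)
    f = real.frequencies()
    alleles = (rng.random((n_out, real.n_snps)) < f).astype(np.int8)
    return HaplotypeMatrix(alleles, positions=real.positions)


def iid_exchangeable_sets(n_sets: int, n: int, n_snps: int, seed: int) -> list[np.ndarray]:
    """Draw ``n_sets`` exchangeable haplotype sets from one distribution.

    One panel is simulated (shared population frequencies; haplotype sharing
    on, so nearest-neighbour distances are effectively continuous) and each
    population's rows are split at random between the sets, keeping every
    set's composition identical — the sets are then exchangeable by
    construction. This is the null scenario for AA_TS / privacy-score /
    chain-frequency calibration.
    """
    rng = np.random.default_rng(seed)
    n_pops = 3
    m = int(np.ceil(n / n_pops))
    cfg = PopSimConfig(
        n_pops=n_pops,
        n_hap_per_pop=n_sets * m,
        n_snps=n_snps,
        fst=0.15,
        copy_switch_prob=0.1,
        share_prob=0.8,
        share_mut_range=(0.01, 0.10),
        seed=int(rng.integers(2**31)),
    )
    pool = simulate_structured_haplotypes(cfg).alleles.reshape(n_pops, n_sets * m, n_snps)
    parts: list[list[np.ndarray]] = [[] for _ in range(n_sets)]
    for p in range(n_pops):
        perm = rng.permutation(n_sets * m)
        for k in range(n_sets):
            parts[k].append(pool[p, perm[k * m : (k + 1) * m]])
    return [np.concatenate(chunks)[:n] for chunks in parts]


def _two_iid_sets(n: int, n_snps: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    a, b = iid_exchangeable_sets(2, n, n_snps, int(rng.integers(2**31)))
    return a, b


def make_scenario_pair(
    scenario: str, n: int, n_snps: int, seed: int = 0
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Build a (truth, synthetic) pair realising a named training outcome.

    ``exchangeable``
        both sets iid from one structured distribution (the well-calibrated
        null: AA_TS concentrates at 0.5);
    ``overfit_copy``
        synthetic is a row-permuted copy of truth (extreme overfitting,
        AA_TS = 0 when truth rows are distinct);
    ``underfit_clusters``
        the two sets form disjoint, well-separated clusters (extreme
        underfitting, AA_TS = 1);
    ``aberration_syn_pockets``
        synthetic points are duplicated local averages of small truth
        neighbourhoods (nearest neighbours of everything are synthetic:
        AA_syn >> 0.5, AA_truth << 0.5);
    ``aberration_truth_modes``
        synthetic scatters at high variance around the truth modes (nearest
        neighbours of everything are real: AA_truth >> 0.5, AA_syn << 0.5).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)

    if scenario == "exchangeable":
        truth, syn = _two_iid_sets(n, n_snps, rng)
    elif scenario == "overfit_copy":
        truth, _ = _two_iid_sets(n, n_snps, rng)
        syn = truth[rng.permutation(n)].copy()
    elif scenario == "underfit_clusters":
        mode_t = rng.integers(0, 2, n_snps, dtype=np.int8)
        mode_s = 1 - mode_t  # maximally distant cluster centres
        truth = _scatter(mode_t, n, 0.02, rng)
        syn = _scatter(mode_s, n, 0.02, rng)
    elif scenario == "aberration_syn_pockets":
        # sharing off: truth rows must not have near-duplicate relatives,
        # otherwise the pocket average cannot undercut d_TT
        cfg = PopSimConfig(n_pops=3, n_hap_per_pop=int(np.ceil(n / 3)), n_snps=n_snps,
                           fst=0.15, copy_switch_prob=0.1, seed=int(rng.integers(2**31)))
        truth = simulate_structured_haplotypes(cfg).alleles[:n]
        pocket = 4
        # greedy nearest-neighbour pockets: each synthetic point is the
        # majority vote of a small local truth neighbourhood, duplicated
        from scipy.spatial.distance import cdist

        d = cdist(truth, truth, metric="hamming")
        np.fill_diagonal(d, np.inf)
        unused = np.ones(n, dtype=bool)
        centers = []
        while unused.sum() >= pocket:
            seed_row = int(np.flatnonzero(unused)[0])
            dd = d[seed_row].copy()
            dd[~unused] = np.inf
            dd[seed_row] = -1.0  # the seed row belongs to its own pocket
            members = np.argsort(dd)[:pocket]
            unused[members] = False
            group = truth[members]
            centers.append((group.mean(axis=0) >= 0.5).astype(np.int8))
        centers = np.array(centers)
        syn = centers[np.repeat(np.arange(len(centers)), pocket)][:n]
        if syn.shape[0] < n:  # pad with duplicates of the first centre
            syn = np.vstack([syn, np.tile(centers[0], (n - syn.shape[0], 1))])
    else:  # aberration_truth_modes
        n_modes = 3
        modes = rng.integers(0, 2, (n_modes, n_snps), dtype=np.int8)
        assign = rng.integers(0, n_modes, n)
        truth = np.vstack([_scatter(modes[a], 1, 0.03, rng) for a in assign])
        syn = np.vstack([_scatter(modes[a], 1, 0.25, rng) for a in assign])
    return HaplotypeMatrix(truth), HaplotypeMatrix(syn)


def _scatter(mode: np.ndarray, n: int, flip_prob: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random((n, mode.shape[0])) < flip_prob
    return np.where(flips, 1 - mode[None, :], mode[None, :]).astype(np.int8)
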