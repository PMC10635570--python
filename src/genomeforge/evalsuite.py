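"""Population-genetic summary statistics comparing real and generated panels.

Each report takes a real and a generated :class:`HaplotypeMatrix` with the
same column count and measures one facet of generation quality: allele
frequencies (with a zoom on low-frequency alleles), linkage-disequilibrium
decay on a log-distance pair subsample, 3-point correlations, k-mer motif
counts in non-overlapping windows, haplotypic pairwise-distance
distributions, fixed-allele accounting, and PCA projections. The radar
aggregation maps six of these onto [0, 1] scores (1 = perfect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .haplotype_io import HaplotypeMatrix
from .privacy import AAtsResult


def _alleles(x) -> np.ndarray:
    if isinstance(x, HaplotypeMatrix):
        return np.asarray(x.alleles, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _check_same_cols(real, gen) -> tuple[np.ndarray, np.ndarray]:
    r, g = _alleles(real), _alleles(gen)
    if r.shape[1] != g.shape[1]:
        raise ValueError("real and generated matrices must have the same column count")
    return r, g


# ---------------------------------------------------------------- allele freq

@dataclass
class AlleleFreqReport:
    real_freq: np.ndarray
    gen_freq: np.ndarray
    r_all: float | None
    slope_all: float | None
    intercept_all: float | None
    r_low: float | None
    slope_low: float | None
    intercept_low: float | None
    low_freq_cap: float


def _corr_ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None, None, None
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def allele_freq_report(real, generated, low_freq_cap: float = 0.2) -> AlleleFreqReport:
    """Correlate per-site allele frequencies, overall and at low frequency.

    The low-frequency subset (real frequency <= cap, default 0.2) is where
    generative models typically struggle; Pearson r plus OLS slope/intercept
    are reported for both site sets.
    """
    r, g = _check_same_cols(real, generated)
    fr, fg = r.mean(axis=0), g.mean(axis=0)
    r_all, s_all, i_all = _corr_ols(fr, fg)
    low = fr <= low_freq_cap
    r_low, s_low, i_low = _corr_ols(fr[low], fg[low])
    return AlleleFreqReport(fr, fg, r_all, s_all, i_all, r_low, s_low, i_low, low_freq_cap)


# ------------------------------------------------------------------------ LD

@dataclass
class LdDecayTable:
    bin_edges: np.ndarray          # distance bin edges (ascending)
    mean_r2_real: np.ndarray       # per-bin mean r², NaN for empty bins
    mean_r2_generated: np.ndarray
    pair_distances: np.ndarray
    r2_real: np.ndarray            # per sampled pair
    r2_generated: np.ndarray
    distance_unit: str             # "bp" or "index"
    n_pairs: int


def _r2_pairs(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between column pairs (textbook r² = D²/(p1 q1 p2 q2))."""
    a = x[:, i]
    b = x[:, j]
    pa = a.mean(axis=0)
    pb = b.mean(axis=0)
    d = (a * b).mean(axis=0) - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    return d * d / denom


def ld_decay(real, generated, n_pairs: int = 50_000, seed: int = 0,
             positions_mode: str | None = None, n_bins: int = 20) -> LdDecayTable:
    """LD (r²) decay over a log-distance subsample of site pairs.

    Sites fixed in either dataset are removed first. ``n_pairs`` site pairs
    are drawn approximately uniformly along the log of their distance
    (base pairs when positions are available, SNP-index units otherwise),
    avoiding the full quadratic pair matrix; r² is computed per pair in both
    datasets and averaged in log-spaced distance bins.
    """
    r, g = _check_same_cols(real, generated)
    if positions_mode is None:
        positions_mode = "bp" if (isinstance(real, HaplotypeMatrix) and real.positions is not None) else "index"
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    fr, fg = r.mean(axis=0), g.mean(axis=0)
    seg = (fr > 0) & (fr < 1) & (fg > 0) & (fg < 1)
    idx = np.flatnonzero(seg)
    if idx.size < 2:
        raise ValueError("fewer than 2 sites segregating in both datasets")
    if positions_mode == "bp":
        pos = np.asarray(real.positions, dtype=float)[idx]
    else:
        pos = idx.astype(float)
    rng = np.random.default_rng(seed)
    max_d = pos[-1] - pos[0]
    # log-uniform target distances, then snap to the nearest real site
    target_d = np.exp(rng.uniform(0, np.log(max_d), size=n_pairs))
    i_site = rng.integers(0, idx.size, size=n_pairs)
    partner_pos = pos[i_site] + np.where(pos[i_site] + target_d <= pos[-1], target_d, -target_d)
    j_site = np.clip(np.searchsorted(pos, partner_pos), 0, idx.size - 1)
    keep = j_site != i_site
    i_site, j_site = i_site[keep], j_site[keep]
    dist = np.abs(pos[j_site] - pos[i_site])
    r2_r = _r2_pairs(r[:, idx], i_site, j_site)
    r2_g = _r2_pairs(g[:, idx], i_site, j_site)
    edges = np.exp(np.linspace(0, np.log(max_d + 1), n_bins + 1))
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    mean_r, mean_g = np.full(n_bins, np.nan), np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = which == b
        if m.any():
            mean_r[b] = r2_r[m].mean()
            mean_g[b] = r2_g[m].mean()
    return LdDecayTable(edges, mean_r, mean_g, dist, r2_r, r2_g, positions_mode, int(i_site.size))


# ------------------------------------------------------------------- 3-point

@dataclass
class ThreePointReport:
    per_spacing_r: dict[int, float | None]
    random_r: float | None
    skipped_spacings: list[int]


def _triplet_stat(x: np.ndarray, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0, keepdims=True)
    return (c[:, i] * c[:, j] * c[:, k]).mean(axis=0)


def three_point_report(real, generated, spacings=(1, 4, 16, 64, 256, 512, 1024),
                       n_random_triplets: int = 2000, seed: int = 0) -> ThreePointReport:
    """Correlation of 3-point statistics between real and generated panels.

    For each spacing d, triplets (i, i+d, i+2d) are scored by the centred
    third cross-moment mean_h[(s_i − p_i)(s_j − p_j)(s_k − p_k)]; the report
    gives the Pearson correlation of that statistic between datasets across
    triplets, plus the same for randomly drawn (unevenly spaced) triplets.
    Spacings too wide for the matrix are skipped.
    """
    r, g = _check_same_cols(real, generated)
    m = r.shape[1]
    rng = np.random.default_rng(seed)
    per: dict[int, float | None] = {}
    skipped = []
    for d in spacings:
        if 2 * d + 1 > m:
            skipped.append(d)
            continue
        i = np.arange(0, m - 2 * d)
        stat_r = _triplet_stat(r, i, i + d, i + 2 * d)
        stat_g = _triplet_stat(g, i, i + d, i + 2 * d)
        rr, _, _ = _corr_ols(stat_r, stat_g)
        per[int(d)] = rr
    if m >= 3:
        trip = np.sort(np.array([rng.choice(m, size=3, replace=False) for _ in range(n_random_triplets)]), axis=1)
        stat_r = _triplet_stat(r, trip[:, 0], trip[:, 1], trip[:, 2])
        stat_g = _triplet_stat(g, trip[:, 0], trip[:, 1], trip[:, 2])
        random_r, _, _ = _corr_ols(stat_r, stat_g)
    else:
        random_r = None
    return ThreePointReport(per, random_r, skipped)


# --------------------------------------------------------------------- k-mer

@dataclass
class KmerReport:
    k: int
    counts_real: dict[tuple[int, str], int]      # (window index, motif) -> count
    counts_generated: dict[tuple[int, str], int]
    r: float | None
    slope: float | None
    intercept: float | None


def _kmer_counts(x: np.ndarray, k: int) -> dict[tuple[int, str], int]:
    n, m = x.shape
    out: dict[tuple[int, str], int] = {}
    powers = 1 << np.arange(k - 1, -1, -1)
    for w, start in enumerate(range(0, m - k + 1, k)):
        codes = (x[:, start : start + k].astype(np.int64) @ powers).astype(np.int64)
        vals, cnts = np.unique(codes, return_counts=True)
        for v, c in zip(vals, cnts):
            out[(w, format(int(v), f"0{k}b"))] = int(c)
    return out


def kmer_report(real, generated, k: int = 4) -> KmerReport:
    """Count k-SNP motifs in non-overlapping windows and correlate counts.

    The genome is cut into windows of k consecutive SNPs (trailing remainder
    dropped); within each window the occurrences of every observed binary
    motif are counted per dataset, and the Pearson correlation is taken over
    all (window, motif) pairs observed in either dataset.
    """
    r, g = _check_same_cols(real, generated)
    if r.shape[1] < k:
        raise ValueError(f"need at least {k} columns for k={k}")
    cr = _kmer_counts(r.astype(np.int8), k)
    cg = _kmer_counts(g.astype(np.int8), k)
    keys = sorted(set(cr) | set(cg))
    xr = np.array([cr.get(key, 0) for key in keys], dtype=float)
    xg = np.array([cg.get(key, 0) for key in keys], dtype=float)
    rho, slope, intercept = _corr_ols(xr, xg)
    return KmerReport(k, cr, cg, rho, slope, intercept)


# ---------------------------------------------------------- pairwise distance

@dataclass
class PairwiseDistanceReport:
    within_real: np.ndarray
    within_generated: np.ndarray
    between: np.ndarray
    wasserstein: float
    n_duplicate_pairs_generated: int
    n_generated_copied_from_real: int


def pairwise_distance_report(real, generated) -> PairwiseDistanceReport:
    """Haplotypic pairwise Hamming-distance distributions.

    Returns all unordered within-set distances and all cross-set distances
    (in differing-site counts), the 1-D Wasserstein distance between the two
    within-set distributions, and duplicate accounting: identical generated
    pairs and generated rows copied verbatim from the real set.
    """
    from scipy.spatial.distance import pdist, cdist

    r, g = _check_same_cols(real, generated)
    if r.shape[0] < 2 or g.shape[0] < 2:
        raise ValueError("need at least 2 rows per dataset")
    m = r.shape[1]
    wr = pdist(r, metric="hamming") * m
    wg = pdist(g, metric="hamming") * m
    bt = (cdist(r, g, metric="hamming") * m).ravel()
    w = float(stats.wasserstein_distance(wr, wg))
    return PairwiseDistanceReport(
        wr, wg, bt, w,
        n_duplicate_pairs_generated=int((wg == 0).sum()),
        n_generated_copied_from_real=int(((cdist(r, g, metric="hamming") * m).min(axis=0) == 0).sum()),
    )


# ------------------------------------------------------------- fixed alleles

@dataclass
class FixedAlleleReport:
    n_fixed_generated: int
    n_fixed_real: int
    n_generated_fixed_real_polymorphic: int
    real_freq_at_generated_fixed: np.ndarray


def fixed_allele_report(real, generated) -> FixedAlleleReport:
    """Sites fixed (frequency 0 or 1) in the generated panel, vs real frequency."""
    r, g = _check_same_cols(real, generated)
    fr, fg = r.mean(axis=0), g.mean(axis=0)
    fixed_g = (fg == 0) | (fg == 1)
    fixed_r = (fr == 0) | (fr == 1)
    return FixedAlleleReport(
        int(fixed_g.sum()),
        int(fixed_r.sum()),
        int((fixed_g & ~fixed_r).sum()),
        fr[fixed_g & ~fixed_r],
    )


# ----------------------------------------------------------------------- PCA

@dataclass
class PcaScores:
    real_scores: np.ndarray
    generated_scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray


def pca_scores(real, generated, n_components: int = 4) -> PcaScores:
    """Project both panels on PCs fitted to the real panel (real-centred)."""
    from sklearn.decomposition import PCA

    r, g = _check_same_cols(real, generated)
    if np.allclose(r.var(axis=0), 0):
        raise ValueError("degenerate real matrix: all columns constant")
    n_components = min(n_components, min(r.shape) - 1, r.shape[1])
    pca = PCA(n_components=n_components)
    rs = pca.fit_transform(r)
    gs = pca.transform(g)
    return PcaScores(rs, gs, pca.explained_variance_ratio_, pca.components_)


# --------------------------------------------------------------- radar scores

@dataclass
class RadarScores:
    allele_frequency: float | None
    three_point: float | None
    pairwise_distance: float | None
    overfitting: float
    underfitting: float
    ld: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "allele_frequency": self.allele_frequency,
            "three_point": self.three_point,
            "pairwise_distance": self.pairwise_distance,
            "overfitting": self.overfitting,
            "underfitting": self.underfitting,
            "ld": self.ld,
        }


def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def radar_scores(aa: AAtsResult, ld_table: LdDecayTable, af_lowfreq_r: float | None,
                 threepoint_random_r: float | None, wasserstein_pd: float | None = None,
                 wasserstein_pd_binomial_baseline: float | None = None) -> RadarScores:
    """Aggregate the evaluation into six [0, 1] radar scores (1 = perfect).

    Overfitting  = 1 − (0.5 − min(AA_truth, 0.5)) − (0.5 − min(AA_syn, 0.5))
    Underfitting = 1 − (max(AA_truth, 0.5) − 0.5) − (max(AA_syn, 0.5) − 0.5)
    LD           = 1 − Σ(LD_real − LD_gen)² / Σ LD_real²   (over decay-bin means)
    allele_frequency and three_point pass through the low-frequency AF and
    random-triplet correlations; pairwise_distance min-max scales the
    within-distance Wasserstein against the binomial-baseline value (the
    baseline pins score 0, identity pins 1).
    """
    at, asy = aa.aa_truth, aa.aa_syn
    overfit = _clamp01(1 - (0.5 - min(at, 0.5)) - (0.5 - min(asy, 0.5)))
    underfit = _clamp01(1 - (max(at, 0.5) - 0.5) - (max(asy, 0.5) - 0.5))
    ok = ~np.isnan(ld_table.mean_r2_real) & ~np.isnan(ld_table.mean_r2_generated)
    lr = ld_table.mean_r2_real[ok]
    lg = ld_table.mean_r2_generated[ok]
    denom = float((lr ** 2).sum())
    ld = _clamp01(1 - float(((lr - lg) ** 2).sum()) / denom) if denom > 0 else 0.0
    if wasserstein_pd is None or wasserstein_pd_binomial_baseline is None:
        pd_score = None
    elif wasserstein_pd_binomial_baseline == 0:
        pd_score = None  # degenerate baseline: scaling undefined
    else:
        pd_score = _clamp01(1 - min(1.0, wasserstein_pd / wasserstein_pd_binomial_baseline))
    af = None if af_lowfreq_r is None else _clamp01(af_lowfreq_r)
    tp = None if threepoint_random_r is None else _clamp01(threepoint_random_r)
    return RadarScores(af, tp, pd_score, overfit, underfit, ld)
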