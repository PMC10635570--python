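"""Structured evaluation reports: run the full suite on a real/generated pair.

The report is a plain JSON-serialisable dict with a stable key schema;
floats are rounded to 6 digits and the package version is stamped in. The
radar block always contains exactly the six named scores.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .haplotype_io import HaplotypeMatrix
from .synthetic_data import binomial_baseline
from . import evalsuite
from .privacy import aa_ts

RADAR_KEYS = ("allele_frequency", "three_point", "pairwise_distance",
              "overfitting", "underfitting", "ld")


def _round(x):
    if isinstance(x, dict):
        return {k: _round(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), 6)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def evaluate_pair(real: HaplotypeMatrix, generated: HaplotypeMatrix,
                  n_ld_pairs: int = 20_000, n_random_triplets: int = 2000,
                  seed: int = 0) -> dict[str, Any]:
    """Compute every summary statistic and the radar scores for one pair.

    The pairwise-distance radar score is anchored by a binomial-baseline
    panel generated at matched sample count from the real frequencies.
    """
    real = real.drop_padding()
    generated = generated.drop_padding()
    af = evalsuite.allele_freq_report(real, generated)
    ld = evalsuite.ld_decay(real, generated, n_pairs=n_ld_pairs, seed=seed)
    tp = evalsuite.three_point_report(real, generated, n_random_triplets=n_random_triplets, seed=seed)
    kmer = evalsuite.kmer_report(real, generated, k=4)
    pd_rep = evalsuite.pairwise_distance_report(real, generated)
    fixed = evalsuite.fixed_allele_report(real, generated)
    aa = aa_ts(real.alleles[: generated.n_haplotypes], generated.alleles[: real.n_haplotypes]) \
        if real.n_haplotypes == generated.n_haplotypes else \
        _aa_subsampled(real, generated, seed)
    baseline = binomial_baseline(real, generated.n_haplotypes, seed=seed + 1)
    pd_base = evalsuite.pairwise_distance_report(real, baseline)
    radar = evalsuite.radar_scores(aa, ld, af.r_low, tp.random_r,
                                   pd_rep.wasserstein, pd_base.wasserstein)
    from . import __version__

    return _round({
        "version": __version__,
        "n_real": real.n_haplotypes,
        "n_generated": generated.n_haplotypes,
        "n_snps": real.n_snps,
        "allele_frequency": {
            "r_all": af.r_all, "slope_all": af.slope_all, "intercept_all": af.intercept_all,
            "r_low": af.r_low, "slope_low": af.slope_low, "intercept_low": af.intercept_low,
        },
        "ld": {
            "bin_edges": ld.bin_edges.tolist(),
            "mean_r2_real": np.nan_to_num(ld.mean_r2_real, nan=-1.0).tolist(),
            "mean_r2_generated": np.nan_to_num(ld.mean_r2_generated, nan=-1.0).tolist(),
            "n_pairs": ld.n_pairs,
        },
        "three_point": {"per_spacing_r": {str(k): v for k, v in tp.per_spacing_r.items()},
                        "random_r": tp.random_r},
        "kmer": {"k": kmer.k, "r": kmer.r, "slope": kmer.slope},
        "pairwise_distance": {
            "wasserstein": pd_rep.wasserstein,
            "n_duplicate_pairs_generated": pd_rep.n_duplicate_pairs_generated,
            "n_generated_copied_from_real": pd_rep.n_generated_copied_from_real,
        },
        "fixed_alleles": {
            "n_fixed_generated": fixed.n_fixed_generated,
            "n_fixed_real": fixed.n_fixed_real,
            "n_generated_fixed_real_polymorphic": fixed.n_generated_fixed_real_polymorphic,
        },
        "aa_ts": {"aa_truth": aa.aa_truth, "aa_syn": aa.aa_syn, "aa_ts": aa.aa_ts},
        "radar": {k: getattr(radar, k) for k in RADAR_KEYS},
    })


def _aa_subsampled(real: HaplotypeMatrix, generated: HaplotypeMatrix, seed: int):
    n = min(real.n_haplotypes, generated.n_haplotypes)
    rng = np.random.default_rng(seed)
    r = real.alleles[rng.choice(real.n_haplotypes, n, replace=False)]
    g = generated.alleles[rng.choice(generated.n_haplotypes, n, replace=False)]
    return aa_ts(r, g)


def write_report(results: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
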