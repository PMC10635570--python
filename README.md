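# genomeforge

Generative models for phased haplotypes — and the audit suite that tells
you whether their output is any good and whether it leaks its training
data.

Sharing human genetic data is constrained by donor privacy. One proposed
way out is *artificial genomes* (AGs): synthetic haplotype panels that
reproduce the statistical structure of a real panel (allele frequencies,
linkage disequilibrium, population modes, haplotypic motifs) without
corresponding to real donors. This package implements, in pure scientific
Python, the model stack and evaluation battery for that programme:

- **Out-of-equilibrium RBM (Rdm-k).** A binary restricted Boltzmann machine
  p(s, τ) ∝ exp(Σ wᵢₐsᵢτₐ + Σ θᵢsᵢ + Σ ηₐτₐ) whose negative-phase chains
  always start from uniform Bernoulli(0.5) and run exactly k Gibbs steps —
  during training and, identically, at generation.
- **Conditional-RBM chaining.** Windows tile a long sequence; each
  conditional RBM generates its window's new columns given the trailing
  overlap already generated (pinned variables shifting the hidden biases),
  so arbitrarily long haplotypes are sampled block by block.
- **Convolutional WGAN-GP** with packing (the critic scores 3 sequences
  jointly, punishing mode collapse), trainable location channels, per-block
  noise, residual blocks, and two-phase training. Runs on an in-repo numpy
  autodiff engine with double backprop (for the gradient penalty).
- **Benchmark VAE** sharing the convolutional block design.
- **Evaluation suite**: allele-frequency reports (with a low-frequency
  zoom), LD decay on log-distance pair subsamples, 3-point correlations,
  k-mer motif counts, pairwise-distance distributions, fixed-allele
  accounting, PCA projections, and six [0, 1] radar scores.
- **Privacy auditing**: nearest-neighbour adversarial accuracy
  AA_TS = ½(AA_truth + AA_syn) (0.5 ideal, below = overfitting/memorisation,
  above = underfitting), privacy score (Test − Train AA_TS),
  nearest-neighbour chain pattern frequencies, and white-/black-box
  membership-inference attacks.
- **Synthetic data**: a seeded Balding–Nichols + latent-copying simulator
  (population structure, realistic SFS, geometric LD decay, optional
  haplotype sharing) and scenario generators for the canonical pathological
  training outcomes — everything is testable without external data.

## Worked example

```python
from genomeforge.synthetic_data import PopSimConfig, simulate_structured_haplotypes
from genomeforge.rbm_core import RdmKConfig, train_rbm, sample_rbm
from genomeforge.privacy import aa_ts
import numpy as np

data = simulate_structured_haplotypes(
    PopSimConfig(n_pops=2, n_hap_per_pop=150, n_snps=120, fst=0.25, seed=3))
config = RdmKConfig(k_steps=30, learning_rate=0.02, n_hidden=64,
                    epochs=120, batch_size=128, seed=0)
params, log = train_rbm(data, config)
ags = sample_rbm(params, data.n_haplotypes, config, seed=42)

print(np.corrcoef(data.frequencies(), ags.frequencies())[0, 1])
res = aa_ts(data, ags)
print(res.aa_truth, res.aa_syn, res.aa_ts)
```

Running this (`python examples/02_train_rbm.py`) prints

```
allele-frequency correlation real vs generated: 0.998
AA_truth=0.993 AA_syn=0.347 AA_TS=0.670
```

— the sampler reproduces the panel's allele frequencies almost exactly
(r = 0.998), but the two AA components split: AA_truth ≫ 0.5 with
AA_syn ≪ 0.5 means both real and generated samples have *real* nearest
neighbours — the model found the population modes but scatters its samples
around them with too much variance. The aggregate AA_TS (0.67) alone would
hide that; auditing both components exposes it. This is precisely the kind
of generative aberration the privacy/quality suite is built to catch, and
a short desk-scale run reproduces it.

The `examples/` directory has one short script per capability: simulation +
evaluation radar, RBM, CRBM chaining across windows, privacy auditing,
WGAN training, and membership inference. A thin CLI wraps the same library
calls:

```bash
genomeforge simulate --pops 3 --haps 200 --snps 1000 --fst 0.1 --seed 7 --out sim.hapt
genomeforge train-rbm --data sim.hapt --hidden 64 --k 100 --lr 0.005 --epochs 100 --out rbm.npz
genomeforge generate --model rbm.npz --n 500 --seed 1 --out ags.hapt
genomeforge evaluate --real sim.hapt --gen ags.hapt --out report.json
genomeforge privacy-audit --train tr.hapt --test te.hapt --gen ags.hapt --out audit.json
```

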