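"""Train an out-of-equilibrium (Rdm-k) RBM and audit the samples it generates.

The RBM is trained with the matched dynamical process: negative-phase chains
always start from uniform Bernoulli(0.5) and run exactly k Gibbs steps, and
generation repeats that exact process. The audit shows a pattern worth
understanding: allele frequencies are recovered almost perfectly, while the
two components of the nearest-neighbour adversarial accuracy split apart —
a generative aberration that aggregate AA_TS alone would hide.
"""

import numpy as np

from genomeforge.synthetic_data import PopSimConfig, simulate_structured_haplotypes
from genomeforge.rbm_core import RdmKConfig, train_rbm, sample_rbm
from genomeforge.privacy import aa_ts

data = simulate_structured_haplotypes(
    PopSimConfig(n_pops=2, n_hap_per_pop=150, n_snps=120, fst=0.25, seed=3))

config = RdmKConfig(k_steps=30, learning_rate=0.02, n_hidden=64,
                    epochs=120, batch_size=128, seed=0)
params, log = train_rbm(data, config)
print(f"trained {config.epochs} epochs; top singular value of w grew "
      f"{log.top_singular_values[0][0]:.2f} -> {log.top_singular_values[-1][0]:.2f}")

ags = sample_rbm(params, data.n_haplotypes, config, seed=42)
r = np.corrcoef(data.frequencies(), ags.frequencies())[0, 1]
res = aa_ts(data, ags)
print(f"allele-frequency correlation real vs generated: {r:.3f}")
print(f"AA_truth={res.aa_truth:.3f} AA_syn={res.aa_syn:.3f} AA_TS={res.aa_ts:.3f}")
print("AA_truth >> 0.5 with AA_syn << 0.5 means both real and generated")
print("samples have REAL nearest neighbours: the model found the population")
print("modes but scatters its samples around them with too much variance.")
print("A short desk-scale run reproduces exactly the AA-component contrast")
print("that makes auditing both components (not just their mean) essential.")
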