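# Methods

`genomeforge` generates artificial genomes (AGs) — synthetic phased
haplotypes intended to mimic a real panel's statistics without exposing its
donors — and audits them for quality and privacy. This note records the
models, the synthetic study conditions, the numerical choices, and what the
test suite does and does not establish.

## Data model

All components operate on a binary matrix of phased haplotypes: rows are
chromosome copies, columns are biallelic SNPs, entries 0 (reference) / 1
(alternative). Files travel as whitespace 0/1 text ("hapt", with optional
two leading label columns) or phased VCF (each diploid sample contributes
two rows; multiallelic or missing-genotype records are skipped, never
imputed). Convolutional models require sequence lengths of the form
2^n − 1; shorter panels are right-padded with a constant allele, the padded
columns recorded in a mask. Evaluation statistics exclude padded columns via
that mask — how (or whether) padding was excluded from published statistics
is not documented anywhere we know of, so exclusion is this package's
choice.

## Synthetic study conditions

No external data ships with the package; every experiment runs on the
simulator in `genomeforge.synthetic_data`, which emulates the three features
of real SNP panels that the models and metrics are sensitive to:

- **Population structure.** Per-site ancestral frequencies p ~
  Beta(0.3, 0.9) (skewed to low-frequency alternative alleles, like a SNP
  array's site-frequency spectrum); per-population frequencies follow the
  Balding–Nichols law Beta with mean p and variance Fst·p(1−p). Defaults:
  3 populations, Fst 0.1–0.15.
- **LD decay.** Within a haplotype, site j carries allele 1 iff u_j < f_j,
  where the latent uniform u is carried along the chromosome and refreshed
  with probability `copy_switch_prob` per site (default 0.1). Marginal
  frequencies are exactly the Balding–Nichols draws; sites d apart share
  their latent with probability (1−s)^d, so r² decays geometrically and
  s = 1 reproduces the independent-site null (mean adjacent r² ≈ 1/n from
  finite-sample bias).
- **Haplotype sharing.** Optionally (`share_prob`), a haplotype is an
  imperfect copy of an earlier haplotype of its population (per-site
  mutation rate drawn from `share_mut_range`), emulating the pervasive
  identity-by-descent of real panels.

The sharing stage matters for metric calibration. Hamming nearest-neighbour
distances between a few hundred binary haplotypes of a few hundred SNPs
concentrate on a narrow band of integers and tie between candidate
neighbours 5–11% of the time; the strict-inequality AA indicators (below)
then sit visibly below their continuous-case null. With sharing on
(share_prob 0.8, mutation 1–10%), nearest-neighbour distances spread over a
wide range, ties drop to ~1%, and the exchangeable null lands at
AA_TS = 0.499 ± 0.004 (30-seed calibration). The null-scenario helper
`iid_exchangeable_sets` therefore simulates one panel with sharing on and
splits each population's rows at random between the sets, so all sets have
identical composition and are exchangeable by construction. These
parameters were fixed once, from that calibration, before the acceptance
tests were frozen.

Controlled truth/synthetic pairs for metric tests come from
`make_scenario_pair`: `exchangeable` (the well-calibrated null),
`overfit_copy` (synthetic = row-permuted truth), `underfit_clusters`
(disjoint clusters), `aberration_syn_pockets` (duplicated majority votes of
small truth neighbourhoods — everything's nearest neighbour is synthetic),
and `aberration_truth_modes` (high-variance scatter around truth modes —
everything's nearest neighbour is real). Honest training cannot produce
these outcomes on demand, which is why they are constructed.

## Out-of-equilibrium RBM (Rdm-k)

The RBM is the standard binary-unit energy model
p(s, τ) ∝ exp(Σ w_ia s_i τ_a + Σ θ_i s_i + Σ η_a τ_a), trained by
likelihood gradient ascent. The out-of-equilibrium scheme fixes the
negative phase precisely: chains start fresh from p0 = uniform
Bernoulli(0.5) and run exactly k alternating Gibbs sweeps — at every
gradient update and, identically, at generation time. The model is used as
a sampler matched to that dynamics, not as an equilibrium distribution.
Defaults follow the large-scale settings where stated (learning rate 0.005;
k = 100/200 at full scale, smaller in tests; hidden-unit count of the order
of the visible units); batch size (256) and epoch counts are unstated
upstream and are this package's defaults. Training is plain SGD with a
constant rate; the per-epoch top singular values of w are logged so users
can verify the healthy regime (smooth growth from ~0 to O(1)) rather than
the trainer auto-tuning. For machines with min(n_visible, n_hidden) ≤ 20
the exact log-likelihood is available by enumerating the smaller layer;
larger machines refuse (the partition function is intractable) — model
selection at scale goes through per-epoch checkpoints scored by AA_TS.

The conditional RBM (CRBM) adds pinned visible variables x that shift the
hidden biases by Σ_j wpin_ja x_j; training pins x to data in both phases
and resamples only the inferred block. A long sequence is tiled by
`plan_windows`: one unconditional RBM for the first window, then CRBM
windows each pinning the trailing `overlap` columns of the already-covered
range. The last window is end-aligned with a possibly shorter inferred
block, keeping the tiling exact: every output column is produced by exactly
one machine and no column is resampled after being pinned downstream
(non-divisible lengths are not addressed upstream; this rule is ours).
Per-machine seeds derive from the master seed and the window index, so
serial and concurrent training give identical results.

## WGAN-GP

The critic approximates the Wasserstein distance; training alternates 10
critic steps (Adam, lr 5e-4, betas (0.5, 0.9)) per generator step, with
gradient penalty λ·E[(‖∇C(x̂)‖−1)²] at per-pack uniform interpolates
(λ = 10, the canonical choice; the upstream coefficient is unstated). The
generator maps a length-4 Gaussian latent through stride-2 transposed
convolutions 3 → 7 → … → 2^n − 1, each block concatenating one trainable
location channel (restoring position information that convolutions erase)
and two fresh noise channels; batch norm + leaky ReLU (0.01) per block,
residual blocks (two convolutions, input added to output) interleaved,
sigmoid output. The critic mirrors this downward and consumes packs of 3
sequences as channels, so a mode-collapsed generator's low within-pack
diversity is penalised; packs are drawn by random partition of each batch,
re-drawn every step. Channel widths start at `base_channels` at the
coarsest resolution and halve (floor 8) per doubling of length.

Two deliberate departures from the published description, both load-bearing
at desk scale:

- **Critic normalisation defaults to none.** With instance norm (the
  published choice, still available via `critic_norm="instance"`), the
  critic's input-gradient norm scales inversely with the per-sample
  activation spread, which differs systematically (~6×) between binary real
  data and the smooth output of an early generator. The two-sided penalty
  then has no uniform solution: it stalls at a floor with parameter
  gradients orders of magnitude above the Wasserstein term, and the critic
  never learns to separate trivially separable inputs (we measured a score
  gap pinned at ~0 over 2500 steps that reaches −11 within 200 steps with
  the penalty removed). A norm-free critic — standard WGAN-GP practice —
  trains immediately.
- **Lipschitz-calibrated critic init.** The critic's output layer is
  rescaled once at construction so the initial input-gradient norm is ~1
  (the critic is linear in its last layer). Otherwise the initial penalty
  is ~10³–10⁴ and the first epochs are spent purely rescaling weights.

Sigmoid outputs become alleles by a deterministic 0.5 threshold (default)
or a Bernoulli draw — unstated upstream, declared here. Stopping is
automated: PCA is fitted on the real panel, both panels projected, and
per-component (1–4) one-dimensional Wasserstein distances normalized by the
real component spread; training may stop when all components fall below a
threshold (default 0.15). This replaces visual inspection of PC overlap
with a measurable criterion. A second training phase with 10× lower
generator learning rate is available (`phase2_epochs`).

## VAE

The benchmark VAE reuses the convolutional block design: encoder ≅ critic
without packing (batch norm; final linear μ and σ heads, σ through an
exponential), decoder ≅ generator without the per-block noise channels.
Loss = summed binary log loss (probabilities clipped at 1e-7 by an affine
squeeze that preserves gradients) + closed-form KL to the standard normal,
Σ_d ½(μ² + σ² − 1 − 2 ln σ). Adam at lr 1e-3. Latent dimensionality is
unstated upstream; default 64 (16 in the scaled-down tests). The upstream
study could not train a VAE at the 65,535-SNP scale; we likewise scope the
VAE to ≤ 16,383 targets and document rather than fix that limitation.

## Evaluation suite

All statistics exclude padding and, where both matrices are required, check
matching column counts. Fixed sites (frequency 0 or 1 in either panel) are
removed before LD computation. LD uses the textbook r² = D²/(p₁q₁p₂q₂) on
site pairs subsampled approximately uniformly in log distance (base pairs
when positions exist, SNP-index units otherwise; n_pairs default 50,000 in
the library, less in tests), averaged in 20 log-spaced bins — the full pair
matrix is never built. The 3-point statistic for a triplet (i, j, k) is the
centred third cross-moment mean over haplotypes of
(s_i−p_i)(s_j−p_j)(s_k−p_k); the published analyses name the statistic but
not its formula, so this stand-in is declared openly and any monotone
variant can be swapped behind the same interface. k-mer reports count every
observed binary motif in non-overlapping k-SNP windows (k = 4 or 8,
trailing remainder dropped). Pairwise-distance reports use Hamming counts
over all unordered within-set and cross-set pairs, the 1-D Wasserstein
distance between the two within-set distributions, and duplicate
accounting.

Radar scores map everything to [0, 1] (1 = perfect):
Overfitting = 1 − (0.5 − min(AA_truth, 0.5)) − (0.5 − min(AA_syn, 0.5));
Underfitting = 1 − (max(AA_truth, 0.5) − 0.5) − (max(AA_syn, 0.5) − 0.5);
LD = 1 − Σ(LD_real − LD_gen)²/Σ LD_real² over decay-bin means; allele
frequency and 3-point pass through the low-frequency (≤ 0.2) AF correlation
and the random-triplet correlation; the pairwise score min-max scales the
Wasserstein distance with the site-independent binomial generator
(matched sample count) pinning 0. All scores clamp to [0, 1]; degenerate
denominators are reported as undefined rather than guessed.

## Privacy metrics

AA_truth = mean over truth samples of 1(d_TS > d_TT), AA_syn symmetrically,
AA_TS their average; within-set nearest neighbours exclude self, and the
indicators use strict inequality, so exact duplicates across sets push
toward overfitting — the correct semantics for a memorising generator.
Hamming distance is used throughout (the published chain analysis states
Hamming; the AA metric's distance is unstated upstream — one metric is used
here for consistency on binary data). Privacy score = Test AA_TS − Train
AA_TS, expectation 0 without leakage. Nearest-neighbour chains start at
every sample of both sets, hop to the nearest not-yet-visited sample in the
union, and record the set-label pattern; per length L the pattern
frequencies over each start letter sum to 0.5, and under exchangeability
every pattern has expectation ~2^−L. Ties break deterministically to the
lowest sample index; tie influence is negligible under the calibrated
null (above).

Membership inference ranks candidates by a critic score and predicts the
top fraction (1/10/25/50%) as training members; accuracy is the member
fraction among predictions, ties broken by stable input order. White-box
uses the trained critic; since a packed critic has no single-sample score,
a candidate is scored as its mean critic output over 16 random packings,
occupying each slot position in turn (protocol unstated upstream; declared
here). Black-box trains a fresh WGAN on the released AGs with the published
architecture, deliberately overtrains it, and uses its critic the same way.

## Problem sizes and what the tests show

The published headline numbers (AA_TS 0.82/0.47 on 1000 Genomes panels,
chain tables from trained CRBMs, MIA accuracies ~0.82) require the
1000 Genomes data and GPU-scale training, out of scope here. The test suite
instead anchors on analytic expectations and oracle equivalences, with
scaled-down generative recovery as the integration check: 2 populations ×
200 haplotypes × 255 SNPs, WGAN/VAE/RBM each trained minutes on one CPU,
judged on generated-vs-real allele-frequency correlation (> 0.8) and PCA
mode coverage. Null calibrations use 200–500 haplotypes × 300–500 SNPs over
20 seeds. Passing these shows the machinery is correct and calibrated at
desk scale; it does not show that desk-scale models reach publication
quality on real genomes, nor that the privacy conclusions transfer to
panels with different relatedness structure.

Known limitations: the numpy autodiff engine is single-threaded and
CPU-bound, so full-scale (65,535-SNP) training is out of reach in this
implementation; the CRBM conditions only through hidden-bias shifts (the
printed law), with no direct pinned→inferred couplings; the chain
tie-break is deterministic, which under heavy-tie regimes (very short
panels) deflates same-set patterns slightly; WGAN mode coverage at desk
scale requires the longer of the tested training budgets.
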