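# Methods

## Model and objective

`snpflow` implements a sequential neural process whose latent path is
enriched by planar normalizing flows, for predicting the next-visit
diagnosis (CN / MCI / AD) from a sliding window of k consecutive patient
visits.

**Windowing.** A patient's date-sorted visits yield stride-1 windows of k
(feature, label) context pairs; the target is the immediately following
visit's label. A patient with V visits emits max(0, V − k) windows, so
patients with fewer than k + 1 visits contribute none. With the default
k = 4 this reproduces the usual exclusion of participants with fewer than
four visits while keeping the window length equal to four observed visits.
Splitting is at the patient level, stratified by each patient's last
observed label, because stride-1 windows of one patient overlap — a
window-level split would leak visits across the train/test boundary.
Feature standardization and missing-value medians are fitted on training
patients only.

**Architecture.** Two encoder paths condition the decoder:

- *Deterministic*: affine embedding of the concatenated standardized
  features and one-hot label per visit, plus sinusoidal positional
  encoding over the visit slots; a post-norm transformer encoder
  (multi-head self-attention + 2×-width ReLU feed-forward, residuals,
  layer norm); mean pooling over slots gives r_d.
- *Latent*: an unshared transformer of the same shape pools to s; two
  affine heads give μ and log σ, with σ clamped to [10⁻⁴, 10]; a
  reparameterized sample z₀ = μ + σ⊙ε is pushed through K planar flow
  steps to z_K with accumulated log-det Jacobian.

The decoder concatenates [r_d, z_K] and applies a two-layer ReLU head to
produce 3-class logits.

**Loss.** Cross-entropy of the predicted next-visit label plus β·KL between
the posterior conditioned on context + target pair (q_full) and the
context-only posterior (q_context), β = 1, one latent sample per window.
Training-mode decoding uses z_K from q_full; evaluation never reads the
target pair. Predictive probabilities at evaluation average the decoder
softmax over 8 flowed latent draws (a Monte-Carlo approximation of
∫ p(y|z) q(z) dz); purely deterministic variants use a single pass.

**KL under a shared flow.** Both posteriors ride the same global flow
chain, and KL is invariant under a shared invertible map: the log-det
corrections of the change-of-variables formula cancel pointwise at the
shared base sample, so KL(flow(q_full) ‖ flow(q_context)) equals the
diagonal-Gaussian KL of the bases. The model therefore computes that KL in
closed form — the exact, zero-variance value of the quantity a shared-base
Monte-Carlo estimator targets. The flows shape what the decoder sees, not
the divergence. The general estimator for *different* chains (sample z₀
from the first base; base log-ratio plus the difference of both chains'
log-dets at that z₀) is `snpflow.flows.kl_between_flowed`; it reduces to
closed form when both chains are empty, which also makes a depth-0 SNP-NF
bitwise identical to the flow-free SNP under shared seeds.

**Invertibility.** Planar steps are reparameterized with
û = u + (m(wᵀu) − wᵀu)·w/‖w‖², m(a) = −1 + softplus(a), so wᵀû ≥ −1 and the
scalar map a ↦ a + (wᵀû)·tanh(a + b) is strictly monotone. All flow
primitives (`planar_forward`, `chain_forward`, `planar_inverse`) take steps
whose `u` *is* the constrained direction; `constrain_step` produces them and
the model applies the reparameterization to its raw learned directions at
every forward pass. Inversion reduces to a bracketed 1-D Brent root-find in
a = wᵀz (bracket t ± (|wᵀû| + 1)), then z = z′ − û·tanh(a + b).

## Ablation variants

`build_variant` constructs: `np_plain` (feed-forward per-point encoders, no
flows), `tnp_latent_only` / `tnp_deterministic_only` (one path removed),
`snp` (both paths, no flows), `nf_only` (mean-pooled raw pairs → affine →
flow chain → classifier head; cross-entropy only), `np_nf_no_transformer`
(feed-forward encoders + flows), and the full `snp_nf`. Parameters are
drawn in a fixed order with flow parameters last, so `snp` and
`snp_nf`-at-depth-0 initialize identically under one seed.

## Parameters

| parameter | default | notes |
|---|---|---|
| window k | 4 | context visits; target = next visit |
| embedding dim | 128 | reference configuration |
| encoder layers | 2 | per path, unshared |
| attention heads | 4 | must divide the embedding dim |
| latent dim | = embedding dim | |
| flow depth K | 5 | reference; 4 is the cost/accuracy trade-off point, 0 disables flows |
| learning rate | 10⁻⁵ | Adam; reference configuration |
| epochs | 10 | |
| batch size | 16 | |
| β (KL weight) | 1 | no annealing |
| test fraction | 0.2 | patient-level, stratified |

The **scaled-down preset** (`ModelConfig.scaled_down()`, CLI `--scaled`)
uses embedding 32, 1 encoder layer, 2 flow steps, batch 16, 10 epochs and
Adam lr 10⁻³. The reference learning rate of 10⁻⁵ is calibrated to
full-scale training on the real cohort; at a few hundred windows for 10
epochs it barely moves a freshly initialized model, so the small preset
raises it to 10⁻³. All tests and the acceptance script use the scaled
preset; nothing in the package depends on GPU hardware.

## Synthetic cohorts

The generator emulates the *structure* of TADPOLE-style data, not its
marginals: per patient, a latent severity starts at a uniform baseline and
grows monotonically with AR(1)-correlated positive increments at a
patient-specific rate (truncated-normal, mean 0.45/visit); two fixed
thresholds (1.2, 2.6) define the ordinal CN→MCI→AD stages, so labels never
regress. Features are affine in severity with instrument-like intercepts
and slopes (burden scores and ventricular volume rise; MMSE, RAVLT and the
other volumes fall), plus Gaussian noise scaled per feature to
noise_sd × |slope| so one knob spans the very different native units.
`multimodal_mix` assigns each patient a sign-flipped loading mode with the
given probability, making the feature distribution at fixed severity
bimodal — the one-to-many structure the flowed latent is meant to capture.
Missingness is completely at random.

What it does **not** emulate: informative missingness and dropout,
measurement floors/ceilings, reversion of clinical diagnoses, covariate
effects (age, APOE), or realistic correlations between instruments. Tests
passing on these cohorts show the machinery learns ordinal-progression
structure with heterogeneity and multimodality; they say nothing about
performance on real ADNI-derived data, which is access-restricted and out
of scope.

Study conditions used by the test suite and acceptance script (chosen once
as the package's own desk-scale defaults):

- *Learning check*: the default cohort (200 patients, 5–8 visits,
  noise_sd 0.35, single mode), scaled-down model, held-out mAUC ≥ 0.85
  expected (≈ 0.98 in practice).
- *Ablation direction checks*: 200 patients, multimodal_mix 0.5,
  noise_sd 1.2 — the noise level is raised until the task is clearly
  non-trivial (mAUC well below 1), since at the default noise every
  variant saturates and orderings are undefined; medians over 5 seeds.

## Numerical choices

- σ head clamps log σ to [log 10⁻⁴, log 10]; gradients vanish outside.
- log-det is log of |1 + tanh′·(wᵀû)| floored at 10⁻¹² before the log;
  with constrained steps the argument is positive anyway (tanh′ < 1).
- Planar inversion: Brent with xtol 10⁻¹²; the bracket is exact by the
  monotonicity bound, so convergence failures cannot occur for
  constrained steps.
- Hand–Till AUC uses midranks, so constant scores give 0.5; argmax
  prediction breaks ties toward the lowest class index; macro averages run
  over classes present in the labels, with never-predicted classes scored
  precision 0 under a warning.
- Determinism: every stochastic step (cohort draw, split, init, batch
  order, latent samples) derives from explicit seeds; repeated runs are
  bitwise identical.
- Training runs on the package's own vectorized reverse-mode autodiff
  engine (`snpflow.autodiff`): a tape of numpy ops with broadcasting-aware
  gradients, batched matmul, and an Adam implementation. Gradients are
  verified against central finite differences in the test suite.

## Known limitations

- The transformer is small and windows are short (k = 4); no attempt is
  made at long-sequence efficiency.
- Flow parameters are global (one chain shared across windows); amortized
  per-context flows are out of scope.
- The flow family is planar only; the interface admits other step types
  but none are provided.
- Missing-data handling is limited to row-dropping or forward-fill +
  training-median imputation; informative missingness is future work.
- Real-data preprocessing beyond the single-CSV visit-table dialect
  (e.g. the original multi-spreadsheet distribution of TADPOLE) is not
  implemented.
- At desk scale the flow benefit is small: on the multimodal condition the
  median mAUC gain of the flowed model over the flow-free SNP is a few
  thousandths, grows with flow depth, and is not uniform across cohort
  draws — shallow (2-step) flows can tie or trail SNP on some cohorts
  while 4-step flows consistently help. Conclusions about the size of the
  flow effect on real data cannot be drawn from these cohorts.
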