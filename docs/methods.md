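# Methods

## Problem setting

N medical institutions (sites) each hold a longitudinal EHR dataset
D_n = {(r_i, y_i)}: per patient a matrix of dynamic numeric features over
T record indices, two demographics (age, gender), and a task label —
mortality at the end of the stay (binary) and/or the remaining days to
outcome at every record (regression). Sites record *different but
overlapping* feature sets and may pursue different tasks. Raw records
never leave a site; the only cross-site traffic is (a) per-feature moment
triples for standardization and (b) model parameters or gradients for the
shared channels.

## Model

**Per-feature recurrent channels.** Each dynamic feature x has its own
single-layer unidirectional GRU with scalar input and hidden width h
(default 32). The channel summary f_x is the final hidden state over the
patient's standardized, imputed value sequence; hidden state starts at
zero. The GRU convention is

    z_t = σ(x_t W_z + h_{t-1} U_z + b_z)
    r_t = σ(x_t W_r + h_{t-1} U_r + b_r)
    n_t = tanh(x_t W_n + (r_t ⊙ h_{t-1}) U_n + b_n)
    h_t = (1 − z_t) ⊙ h_{t-1} + z_t ⊙ n_t

so the all-zero parameter point fixes h ≡ 0. Demographics are embedded by
a matrix W_base ∈ R^{h×m}, f_{x+1} = W_base·base (the literature's shape
convention for this map is ambiguous; we fix W_base as h×m so the output
lives in the channel space). In the training path a GELU follows the
demographic projection and dropout (0.1) is applied to the patient
representation, both standard regularization choices; the exported
`embed_demographics` operation itself stays linear.

**Feature matrix and recalibration.** Rows f_1..f_{x+1} are stacked in a
canonical global feature order; features a site does not record become
zero rows with a recorded-row mask, so every site indexes rows
identically. Attention recalibration computes a context f̄ = mean of the
*recorded* rows (the demographic row, always recorded, is included), then
per-row queries/keys/values with independent h×h projections per
canonical row: q_i = W_i^q f̄, k_i = W_i^k f_i, v_i = W_i^v f_i. Scores
ζ_i = q_i·k_i are replaced by −10⁹ at unrecorded rows; the softmax then
underflows those weights to exactly zero (and the implementation routes
exactly-zero gradients to masked rows — the freeze-and-mask contract).
The health-status representation is s = Σ α_i v_i. Recalibration
parameters are always private: they encode each site's task- and
case-mix-specific feature importances.

**Heads and losses.** Private per site: mortality probability
σ(W_cla·s + b_cla) (clamped to [1e−7, 1−1e−7]) with mean binary
cross-entropy over patients; remaining-days prediction W_reg·s + b_reg
with mean squared error over all valid (patient, record) pairs. The LOS
head consumes the representation built from the sequence prefix up to
each record (the GRU hidden state at step t), so predictions are causal.
A site with both tasks minimizes the unweighted sum of the two losses.

## Federation

Channels for features recorded by ≥2 sites are shared; a feature shared
by a strict subset of sites is averaged over the contributing sites only.
The demographic embedding is shared when all sites record the same
demographic schema. Two protocols:

* **fedavg** (default): each round every active site runs one local epoch
  of AdamW (lr 1e−3, weight decay 0.01, batch 1024) and uploads its
  parameters and training-set size M_n; the server replaces each shared
  key by Σ (M_n/M) w_n and broadcasts.
* **accum**: each site uploads the gradient of its loss on one batch with
  unused-parameter keys absent; the server sums gradients and applies one
  optimizer step to the shared keys while sites step their private keys
  with the same rule.

Both appear in the source literature of this design (weight averaging and
gradient accumulation are genuinely different protocols); both are kept
behind a flag. In fedavg mode a client clears its Adam moments whenever
the incoming aggregated snapshot differs from the parameters it uploaded:
momentum accumulated on the pre-average trajectory is misdirected at the
averaged point and, left in place, produces client drift (we observed
occasional catastrophic federated runs without the reset). Because the
reset triggers only on an actual parameter jump, a single-site federation
— where averaging is the identity — remains bit-identical to isolated
training. Early stopping is per site on validation AUPRC
(classification sites) or MSE (regression-only), patience 10 within a
50-epoch default budget; each site's best-validation snapshot is the
returned model. Splits are 70/10/20 train/val/test, seeded.

Comparison regimes: **isolated** runs the identical loop with aggregation
skipped (one site in federated mode is bit-identical to isolated, a
property the tests assert); **centralized** is the pooled-data oracle —
every site's patients are projected onto the shared feature set (private
features dropped) and train one parameter set with a single global
recalibration/head namespace under one optimizer, minibatches interleaved
across sites. An earlier draft emulated centralized training by sharing
every key under FedAvg; that under-performs true pooling because
parameter averaging across task-heterogeneous sites is not data pooling,
and it was replaced. Note that pooling is not guaranteed to dominate the
federated regime here: the federated models keep *private* recalibration
and heads specialized to each site's recorded-feature mask and case mix,
while the pooled model must serve every mask pattern with one attention
parameterization — personalization can genuinely win, especially for
small evaluation cohorts.

**Privacy surface.** A client message contains parameter or gradient
tensors (keyed by namespace) and one integer count; a schema test asserts
nothing patient-shaped can travel. Transport encryption and formal
guarantees (secure aggregation, differential privacy) are out of scope.

## Standardization by moment sharing

Sites exchange per-feature (count, sum, sum-of-squares) over *observed*
cells only. Pooled mean/std follow from the count-weighted identity;
population (divide-by-N) variance makes the merge exact and
order-independent. Features with pooled std < 1e−8 or zero count pass
through unstandardized. After standardization, missing cells are
mean-imputed (zero in standardized space) while the observation mask is
preserved for the recalibration stage. Moments are computed on the full
local datasets before splitting in the shipped pipeline; computing them
on train splits only would be the stricter choice and is noted as a
limitation.

## Synthetic cohorts

The generator emulates a three-hospital collaboration: per patient a
latent risk trajectory z_t ∈ R³ follows a Gaussian random walk
(z_0 ~ N(0, I), increments N(0, 0.25·I)); every dynamic feature is a fixed
random linear readout a_f·z_t + ε, ε ~ N(0, 0.5²), with the readout shared
across sites (a lab test is the same quantity everywhere — this is what
makes cross-site channel sharing informative). Mortality is
Bernoulli(σ(b + w·z_T + weak age/gender effects)) with w = (1.2, −0.8,
0.5); the intercept b is calibrated to the target prevalence (default
0.15) by bisection on a fixed-seed Monte Carlo sample (n = 10 000) of the
logit distribution. Sequence length T ∈ [4, 10] decreases monotonically
with early latent risk, and the remaining-days label is exactly
T − 1 − t, so it is non-negative, decrements by the unit record gap, and
is predictable from the features through T's dependence on risk. (A
per-record noisy map from risk to remaining days cannot satisfy the exact
decrement invariant; tying the label to a risk-dependent length is the
resolution adopted here.) Observations are dropped i.i.d. at rate 0.2.

The default collaboration has feature Venn structure 8 globally shared +
4 per pairwise intersection + 4 private per site (union 32), cohort sizes
400/1500/600 echoing real small/large/medium asymmetry at desk scale,
sites 1–2 with both tasks and site 3 mortality-only.

What the generator does *not* emulate: realistic clinical marginals,
informative missingness, treatment feedback, inter-site distribution
shift beyond feature-set differences. Passing tests therefore demonstrate
mechanism correctness and the existence of federation benefit under a
shared latent signal — not clinical performance.

## Numerical engine

The models are differentiated by a small tape-based reverse-mode
autodiff over float64 numpy arrays written for this package (Tensor with
broadcasting-aware elementwise ops, batched matmul, masked softmax,
per-row projection primitives, and a fused GRU-sequence primitive with a
hand-derived backward pass). Every primitive and the fused recurrence are
verified against central finite differences in the test suite, and the
whole channel stack against an independent scalar recurrence oracle. The
mask value −10⁹ makes masked softmax entries underflow to exact zeros;
probability clamping at 1e−7 bounds the BCE; Adam/AdamW use β =
(0.9, 0.999), ε = 1e−8.

## Desk-scale experiment sizes

The collaboration-benefit study (the package's central empirical claim)
runs the default three-site cohort for 10 training epochs with batch 32
in each regime, 10 independently seeded collaborations in the test suite
and 3 in the acceptance script; the isolated regime trains only the
smallest site, whose test AUPRC is the comparison quantity. These sizes
were chosen so the full study runs on one CPU core in minutes while each
model still takes enough optimizer steps to learn the latent signal.

## Known limitations

* Eq.-level fidelity choices where the source design is ambiguous (f̄
  definition, demographic row in f̄, Adam vs AdamW in the accumulation
  protocol, split ratios) are single documented decisions, not switches.
* Standardization moments use the full local dataset (see above).
* No client sampling, stragglers, or transport layer; all clients
  participate every round.
* The regression and classification losses are summed unweighted at
  dual-task sites; loss balancing is left to future work.
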