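# Methods

`fedbids` is a desk-scale re-implementation of a server/client federated
learning workflow for regression on BIDS-organised T1-weighted brain MRI:
brain-age prediction on healthy-control cohorts, and transfer learning of
such a model to a clinical cognitive score (the Symbol Digit Modalities
Test, SDMT, in multiple sclerosis). This note documents the model, the
procedures, the synthetic data used to exercise them, and the design
decisions taken where the problem was genuinely open.

## The federation procedure

One server coordinates a fixed set of clients, each holding a BIDS dataset
(`participants.tsv` + `sub-*/anat/*_T1w.nii.gz`). All communication is a
two-file protocol: a payload file followed by a zero-byte `.done` completion
marker. A receiver only ever reads a payload whose marker exists, so slow or
interrupted transfers cannot be consumed half-written. Message names are
deterministic (`<kind>_round<r>_<sender>.<ext>`), making re-sends idempotent.
Two transports implement the copy step: a shared-filesystem transport (used
by the single-process simulation) and a configurable copy-command transport
for genuinely remote clients (an `scp`-style command template; the test
suite exercises it with a loopback `cp`).

Per federation round:

1. the server broadcasts the current global weight set to every client;
2. each client re-partitions its fixed training pool into five random
   75/25 train/validation splits ("bootstraps"), trains one model copy per
   bootstrap from the incoming global weights (L1 objective, Adam), and
   returns the weights of the bootstrap with the lowest validation MAE,
   together with its training-pool image count `n_i` and the five
   validation MAEs (a plan switch selects averaging the five weight sets
   instead of taking the best; `best` is the default);
3. the server draws a uniform random sample of `clients_per_round` clients
   and aggregates their weight sets by federated averaging with weights
   `n_i / Σ_j n_j` (FedAvg). Aggregation runs in double precision as an
   anchored sum `w_0 + Σ λ_i (w_i − w_0)`, so identical updates aggregate
   to themselves bit-exactly;
4. the server records the mean validation MAE across the *sampled* clients.
   Training stops early after `patience` consecutive rounds without a new
   minimum of that quantity, and the final model is the aggregate of the
   round with the minimum — not the last round run.

Data splitting is always at the subject level: a participant's images all
fall on one side of every split, so no image of a training subject can leak
into validation or test. The 80/20 train/test split is drawn once per client
and reused every round; with five 75/25 bootstraps of the 80% pool this
yields the familiar 60/20/20 accounting (exact when n is divisible by 20).
"Bootstrapping" is implemented as repeated random partitions *without*
replacement: disjoint train/validation subsets are the only reading under
which 60/20/20 adds up. Split sizes use round-half-to-even with a floor of
one subject per side. The split is not stratified by the target.

A hyperparameter-synced centralised benchmark trains a single model on the
union of the client training pools, reusing each client's per-round
bootstrap splits (identical derived seeds) merged by bootstrap index, with
the same early stopping and best-round selection. Test evaluation in the
centralised regime pools all test subjects.

Client failure policy is abort-and-report: a silent client would otherwise
corrupt the sample-size weighting unnoticed. Client sampling is uniform
random under a seed derived from (plan seed, round index).

## The network

The regressor is the densely connected convolutional network (DenseNet-121
topology) in 3D, single input channel, scalar output: 7³ stride-2 initial
convolution (64 features), 3³ stride-2 max-pool, four dense blocks of
6/12/24/16 layers (growth rate 32; each layer is norm → ReLU → 1³
bottleneck to 128 → norm → ReLU → 3³ convolution to 32, concatenated onto
the block's feature stack), compression-0.5 transitions (1³ convolution +
2³ average-pool), a final norm + adaptive average-pool, and a fully
connected 1,024 → 1 head. Convolutions carry no bias. This configuration
has exactly **11,243,649** trainable parameters, of which **1,025** (1,024
weights + 1 bias) are the head — both counts are checked against an
analytic per-segment ledger, layer group by layer group. Adaptive pooling
makes the parameter count independent of the input volume size.

Transfer learning: *shallow* mode trains only the head (1,025 parameters);
*deep* mode trains everything. In shallow mode the frozen feature
extractor — including normalisation statistics — passes through training
bit-identically.

The network, backpropagation and the Adam optimiser are implemented
directly on NumPy arrays (convolutions lowered to BLAS matrix products via
sliding windows); every layer's backward pass is verified against central
finite differences in the test suite.

**Normalisation statistics.** Batch-normalisation layers use their stored
statistics at all times and never update them during local training
(frozen-statistics semantics; the affine scale and shift remain
learnable). This makes a local round a pure function of the exchanged
parameters — a zero-learning-rate round returns the incoming weights
bit-exactly — and spares federated averaging from naively mixing batch
statistics that diverge across non-IID clients. At desk scale a pilot
showed live batch statistics learn no faster (their running averages lag
over the few dozen optimisation steps a round contains).

## Preprocessing

The implementable tail of the standard brain-age preparation chain runs
deterministically in-process: reorientation to RAS (pure axis
permutation/flip, world coordinates preserved), isotropic resampling to
1.4 mm (output shape per axis = round(extent/spacing); linear
interpolation), centre crop / symmetric zero-pad to a 130³ window (the odd
voxel of an odd difference goes to the trailing side — fixed so outputs
are bit-reproducible), and per-volume intensity normalisation. Skull
stripping, N4 bias-field correction and affine MNI registration are
external third-party tools in that chain, so they are exposed only as
optional command hooks (`{in}`/`{out}` templates) run on temporary NIfTI
files, in that order, between the two RAS passes. Results are cached keyed
by input bytes and configuration.

Intensity normalisation defaults to per-volume min-max to [0, 1]; whether
(and how) the original chain normalises intensities is not specified
anywhere we could rely on, so the choice is surfaced in configuration
rather than hidden. The phantom study below uses per-volume z-scoring,
which conditioned optimisation noticeably better in pilots.

## Synthetic phantoms

Each phantom "brain" is a unit-intensity sphere containing a darker
(intensity 0.2) inner "ventricle" sphere whose radius grows linearly with
the regression target — a cartoon of ventricular enlargement with brain
ageing. Defaults: 32³ voxels at 1.0 mm, target drawn uniformly from
[20, 80] "years", slope 0.1 voxels per year around the mid-range radius,
Gaussian intensity noise (sd 0.1) inside the brain sphere. Thresholded
ventricle voxel counts recover the target with R² > 0.9 by ordinary least
squares at n ≥ 60, so a competent model can learn the mapping.

A per-client `target_shift` adds a constant to the *tabulated* target
while the geometry keeps encoding the unshifted draw — a label shift
mimicking between-centre differences in test administration, the cleanest
dial for fabricating non-IID clients. A shifted client carries an
irreducible bias, so its validation MAE stays elevated and the server's
round-to-round validation curve zigzags with the sampling, lower whenever
the sample excludes the shifted client.

What the phantoms do **not** model: anatomy, scanner/contrast variation,
registration errors, lesions, or any image-level site effect. Passing
tests therefore demonstrate that the federation machinery, splitting,
aggregation and optimisation behave correctly — not that the network
reaches any particular accuracy on real MRI.

## Desk-scale study conditions

The end-to-end check federates three phantom clients of 40/60/80 subjects
(32³ volumes), with client 1's targets shifted by +15 (≈0.9 SD of the
target distribution), for 10 rounds sampling 2 of 3 clients per round,
batch size 10, five bootstraps, one epoch per round, Adam at learning rate
3e-3, L1 loss, on a scaled-down network preset (blocks 2/2/2/2, growth 8,
16 initial features). The optimiser settings come from a pilot of raw
training dynamics: with sign-like Adam steps the 1,024-weight head moves
predictions by roughly (head width × lr) per step, so rates near 1e-1
overshoot violently while 3e-3 descends stably; one epoch per round keeps
a three-seed federation within a few minutes on one CPU. The run is
repeated for three seeds; the median final server validation MAE must fall
below the round-1 value, and rounds excluding the shifted client must show
lower server validation MAE on average.

## Numerical and degenerate-input choices

- Seeds for every stochastic step (splits, bootstraps, batch order,
  client sampling, weight initialisation) derive from the plan seed plus
  stable string/int tuples via SHA-256, so runs are reproducible across
  platforms and the single-client federation is bit-identical to a
  standalone training loop.
- Checkpoints are a deterministic container (JSON manifest + raw
  little-endian arrays); save → load → save is byte-identical.
- Pearson p-values use the exact t-transform (n − 2 df). Correlations with
  a constant margin (e.g. the brain-age difference of a uniformly offset
  predictor) are reported as flagged nulls, never as 0 or silent NaN.
- The 95% confidence interval across bootstraps is t-based (4 df at the
  default five bootstraps).
- Constant volumes are rejected by min-max/z-score normalisation; empty
  pools, single-subject bootstraps and out-of-range phantom targets raise
  input errors rather than degrade silently.
- No brain-age bias correction is applied; the BAD–age correlation is a
  reported diagnostic only.

## Known limitations

- The NumPy network trains on one CPU at toy scale only; the full-size
  architecture is built and audited (parameter ledger, freeze policies,
  forward pass) but not trained here.
- The remote-copy transport is a command contract tested against a local
  loopback; real SSH/VPN deployment, key management and host provisioning
  are out of scope.
- Skull stripping, bias correction and registration are not
  re-implemented; without configured hooks the pipeline assumes approximate
  spatial comparability of inputs.
- Early-stopping patience has no authoritative default (it ships as 20);
  the published stop/minimum round pairs for the two real experiments
  ("minimum after 48 rounds, stopped early after 27"; "minimum after 18,
  stopped after 38") are mutually inconsistent under any single patience
  value and are recorded here verbatim rather than resolved.
- Whether the real toolbox transmits the best bootstrap model or an
  average of the five is unstated; both are implemented (`best` default).
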