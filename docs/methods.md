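# Methods

## Model

`latentnets` turns a univariate series into a weighted graph in two stages: a
recurrent VAE maps the series to M univariate latent Gaussians, and
information geometry turns those Gaussians into network nodes with geodesic
edge weights. A second stage compares whole networks by lifting them to SPD
matrices and working in a common tangent space.

### Recurrent VAE

The encoder is a single-layer LSTM (96 hidden units by default, configurable)
reading one value per step; series of different lengths are zero-padded and
masked, and the hidden state at each series' true last step feeds two linear
heads producing Zμ and the log-variance vector (so Zσ = exp(logvar/2) is
strictly positive by construction). A reparameterized draw Z = Zμ + Zσ⊙ε,
ε ~ N(0, I), passes through a linear layer to the decoder LSTM's full initial
state — hidden *and* cell. (Initializing only the hidden state leaves the
latent code with almost no influence on a long zero-input decoder, and the KL
term then squeezes it out entirely; the cell pathway is what carries
information across many steps.) The decoder input at every step is a *learnable token
initialized at zero and trained by backprop* (our reading of the "initialized
to zero and updated by backpropagation" design; no teacher forcing), and a
linear output layer emits the reconstruction.

Loss per series: the sum of squared reconstruction errors over unmasked steps
(the Gaussian-decoder log-likelihood with unit variance, averaged over L
Monte-Carlo samples of Z; L = 1 by default) plus
`kl_scale`·Σ_m(μ_m² + σ_m² − 1 − log σ_m²). `kl_scale = 0.5` (default) gives
the exact KL divergence against the standard-normal prior; 1.0 reproduces a
common unscaled convention. Masked (padded) steps contribute nothing to either
the loss or the gradients.

Training uses Adam (lr 5e-4 default), global-norm gradient clipping at 5, and
early stopping on a training-loss plateau (patience 20 epochs, min delta
1e-6). The KL weight is annealed linearly from 0 over the first
`kl_warmup_epochs` (30 by default) — KL warm-up, the standard guard against
posterior collapse in recurrent VAEs; early stopping is disabled until warm-up
ends because the objective is still changing. One integer seed drives
parameter initialization (uniform ±1/√H), batch shuffling, and all ε draws;
with single-threaded numpy this makes loss histories bit-reproducible.

Everything (forward pass, backpropagation through time, Adam) is implemented
directly on numpy arrays; the analytic gradients are validated against central
finite differences in the test suite.

Class labels are never read during training — the representation is fully
unsupervised, which the suite checks by permuting labels and asserting an
identical loss history.

### Gaussian embedding and the latent network

N(μ, σ²) embeds as P = v⁻¹·[[v + μ², μ], [μ, 1]] with v = σ² — the univariate
case of the (det Σ)^(−2/(D+1))-normalized block embedding of a D-dimensional
Gaussian into (D+1)×(D+1) SPD matrices. (The embedding formula is sometimes
printed with σ in the variance slot; the two agree only when σ denotes the
variance, so we square the encoder's standard deviation. A
`sigma_as_variance` flag exposes the literal reading for sensitivity checks.)

Edge weights are affine-invariant (AIRM) geodesic distances
d(P_i, P_j) = ‖log(P_i^{-1/2} P_j P_i^{-1/2})‖_F, computed from the
generalized eigenvalues of (P_j, P_i). The *squared* distance (the same
quantity without the square root) is available via `squared=True`; since the
square root is monotone, quantile-based edge thresholding is identical under
either convention, but only the rooted version is a metric (triangle
inequality), so it is the default.

Thresholding: `apply_threshold(net, tau)` keeps weights strictly greater than
τ. `threshold_by_fraction(net, q)` picks τ as the (1−q) linear-interpolation
quantile of the M(M−1)/2 upper-triangle weights and keeps weights ≥ τ, so
edges tied exactly at the threshold all survive; with distinct weights the
retained count is round(q·M(M−1)/2). Keeping the *largest* distances follows
the printed rule; `mode="similarity"` keeps the smallest instead, and a
Gaussian-kernel transform w → exp(−w²/2s²) is provided, because "strong edge"
is ambiguous when weights are distances. The default network-of-networks path
uses the dense adjacency (thresholding is for visualization and topology
highlighting, not required by the Laplacian lift).

### Network of networks

Each adjacency A_k lifts to L_k = (D_k − A_k) + λI, which is SPD for any λ>0
because the Laplacian of a nonnegative graph is positive semidefinite. The
default λ is 1e-3 times the mean node degree across networks (floored at
1e-6), scaling the ridge to the data; λ only needs to bound eigenvalues away
from zero, and the tests confirm the identical-networks fixture yields B = 0
across orders of magnitude of λ.

The default comparison strategy log-maps every L_k to the tangent space at the
Karcher mean M of {L_k} (fixed-point iteration initialized at the
log-Euclidean mean; stops when the tangent-mean norm drops below 1e-8, max 100
iterations) and takes distances there. The tangent inner product is the
affine-invariant one at M — distances are Frobenius norms of whitened
differences M^{-1/2}(y_i − y_j)M^{-1/2} — so the norm of a single log-mapped
point equals its geodesic distance from the reference, tying the two stages
together exactly. A `strategy="manifold"` option computes pairwise geodesic
distances between the L_k directly instead.

Class separation in B is quantified by the mean within-class and between-class
distances and the silhouette score computed on B as a precomputed distance
matrix (singleton classes contribute only to between-class terms; scikit-learn
assigns silhouette 0 to singleton clusters).

## Synthetic data

The generator emulates heartbeat-archive data: each class is a fixed sum of
Gaussian bumps a·exp(−(t−c)²/2w²) on the fractional grid t = i/N (centers c
and amplitudes a per class, width w = 0.04 of the series length by default)
plus i.i.d. Gaussian noise, with imbalanced class counts (default 60/30/10,
length 140). It reproduces what matters for exercising the pipeline —
class-dependent morphology, noise, imbalance, optional unequal lengths — and
deliberately omits what real ECGs have: beat-to-beat warping, baseline wander,
correlated noise, amplitude drift, and within-class morphology variants.
Passing tests therefore show the pipeline recovers class structure from
cleanly separated pulse shapes, not that it does so on real recordings.
Records are generated from independently spawned child seeds, so a dataset is
byte-identical across runs and independent of generation order.

## The synthetic replication study

The end-to-end validation uses a scaled-down two-class study: 100 series
(60/40), length 140, noise sd 0.05, trained with M = 8 latent dimensions and
32 hidden units (learning rate 3e-3, batch 16, KL warm-up 50 epochs, max 300
epochs, patience 60). Sizes were chosen so a full train-encode-compare run
completes in about two minutes on one CPU core while leaving the qualitative
target — same-class series cluster in B (positive silhouette, within <
between) — reproducible across seeds. The corresponding check runs three
seeds and requires a majority to pass, since a single stochastic training run
of a small VAE can land in a poor optimum.

Two structural caveats discovered while building the study are worth stating.
First, the latent network is blind to a *global* sign flip of all latent
means (the embedding satisfies P(−μ) = E P(μ) E with E = diag(1, −1), a
congruence that preserves all pairwise distances) — so a class code carried
purely in the sign of one mean, with all other means at zero, is invisible in
A_k. Second, if the KL term fully collapses the posterior (all nodes at
N(0,1)), every latent network is identical. Both failure modes are mitigated,
not eliminated, by KL warm-up and the moderate KL weight.

## Numerical choices

- Matrix functions of symmetric matrices go through `eigh`; inputs are
  symmetrized ((P+Pᵀ)/2) first, and eigenvalues below 1e-12 raise rather than
  being silently floored.
- Symmetry tolerance for SPD validation: 1e-10 relative to the largest entry.
- Geodesic distances use `scipy.linalg.eigvalsh(Pj, Pi)` (generalized
  symmetric eigenproblem) rather than forming P_i^{-1/2} explicitly; the
  literal sqrt/log/trace pipeline is kept as a test oracle at 1e-8 agreement.
- The encoder's log-variance is clipped to ±15 before exponentiation.
- Quantiles use numpy's linear interpolation definition.
- Checkpoints are `.npz` archives holding the weight arrays plus a JSON
  header (config, loss history, format tag); reloading restores `encode`
  bit-exactly.

## Limitations

- The decoder reconstructs from the initial hidden state alone (zero-input
  LSTM); over long horizons this limits reconstruction sharpness and is one
  reason the small study needs a few hundred epochs.
- Separation of classes in B is a property of the *trained* model; a seed
  that lands in a collapsed or sign-symmetric optimum can fail it, which is
  why the study reports a majority over seeds rather than a single run.
- GRU/plain-RNN cells, β-VAE-style loss variants, and KL/Bhattacharyya node
  distances are out of scope; the log-Euclidean mean appears only as the
  Karcher-mean initializer.
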