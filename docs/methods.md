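# Methods

## Model

`pfcg` treats coarse-grained (CG) dynamics as probabilistic one-step
forecasting. Let `R_t` be the vector of 3N scaled, rigid-motion-invariant CG
features at time index t. The transition density is modeled as a diagonal
Gaussian,

    R_{t+1} ~ N(mu_{t+1}, diag(sigma_{t+1}^2)),

with additive Markovian and non-Markovian contributions:

    mu_{t+1}    = bound( R_t + mu_m(R_t) + mu_nm(R_t ... R_{t-l+1}) )
    sigma_{t+1} = softplus( s_m(R_t) + s_nm(R_t ... R_{t-l+1}) )

`bound(x) = 0.75 tanh(x / 0.75)` keeps the mean inside the scaled feature
range while acting as the identity near zero (a flag switches to plain
`0.75 tanh(x)`.) The Markovian block is the analogue of the effective force
in a Langevin equation; the non-Markovian block is the analogue of the
memory integral in a generalized Langevin equation (GLE), justified by the
standard argument that a non-Markovian process becomes Markovian in an
extended state space, and that hidden state can be reconstructed from a
delay history of the observables.

Both blocks share a transformer-style trunk. Each scalar feature is
embedded as a token (width 8), multi-head self-attention (4 heads) mixes
tokens so the block sees many-body correlations, and residual MLP stacks
with layer normalization follow; the final MLP applies dropout (0.1) and a
linear head emits `2 * 3N` outputs, split into the mean shift and the raw
sigma contribution. The non-Markovian block first time-differences its
history window (a velocity proxy), integrates it with a 2-layer GRU of
hidden size `h_dim` (default 2x the feature count), and feeds the final
hidden state to the same trunk.

Summing the *raw* sigma heads and applying one softplus (rather than
softplus per block) keeps sigma strictly positive while making a
zero-initialized non-Markovian head an exact no-op: stage-2 training starts
at exactly the stage-1 loss, with no spurious jump in predicted noise.

The six features pinned to zero by the local frame transformation are
carried through the network and overwritten at the output (`mu = 0`,
`sigma = 1e-12`), and every sampled configuration re-zeroes them.

Ablation modes mirror the architecture study: `nonprobabilistic` (mu-only
head, MSE loss, deterministic inference), `nm_only` (no Markovian block),
and `sigma_g = 0` (no input-noise regularization).

## Featurization

CG sites are mass-weighted centers of their particle groups (for proteins,
one site per residue; an optional PDB reader derives the grouping). The
local frame transformation translates reference site j to the origin and
rotates with the orthonormal right-handed basis (e1 along r_jk, e3 along
r_jk x r_ji, e2 = e3 x e1), so k lies on +x and i in the xy plane with
positive y. The printed unnormalized frame vectors would not form a
rotation, so rows are normalized — only then is the transform a rigid
motion with a well-defined canonical pose and exactly six zero features
(verified to 1e-8 under random rigid motions). Features are min-max scaled
onto [-0.75, 0.75] with the scaler fitted once on the reference data;
constant columns receive the identity map and are re-zeroed by the mask.
The scaled map is applied in the `(x - min)/span` form so the fitted
extremes hit +/-0.75 exactly in floating point; no clipping is applied to
out-of-range values.

## Training

Windows of l history frames plus n_future target frames are cut at a
configurable frame stride Delta t; windows never cross trajectory
boundaries, a sample cap subsamples at uniform stride, and the pool is
shuffled and split 70/15/15 (train/validation/test) with a fixed seed.
The loss is the Gaussian negative log likelihood averaged over the batch
and the unmasked features; minimizing it minimizes the cross-entropy to the
true conditional path distribution, whose floor is the path entropy. On a
synthetic AR(1) process with known conditional entropy the trained
validation NLL sits within ~1% of that floor (the acceptance suite checks
5%).

Stage 1 trains the Markovian block on one-step windows. Stage 2 freezes
theta_m bit-exactly (the block is detached from the graph, so its gradients
are identically zero) and trains the non-Markovian block on five-step
windows, scored as five parallel teacher-forced one-step predictions: the
prediction at offset s conditions on the *true* window ending at t+s-1 —
no autoregressive rollout during training. Gaussian input noise of width
sigma_g = 0.01 (scaled-feature units) is added to every unmasked input
entry, resampled at each batch draw and disabled at evaluation/inference.

Defaults follow the reference protocol: batch 256, Lion optimizer with
learning rate 5e-5 and weight decay 0.1, early stopping after 7 epochs
without validation improvement, best-validation weights restored. An AdamW
fallback is provided; the desk-scale studies in the tests and the
acceptance script use AdamW at 1e-3 because the small models converge in
minutes there, versus hours at the reference Lion setting.

## Autoregressive CG simulation

Replicas start from randomly chosen test-split windows and advance by
sample-append-drop, batched over replicas. Each replica owns a spawned RNG
substream, so its trajectory is independent of how many replicas run
besides it (verified by 1-vs-8 replica equality). Samples are clamped to
the open interval (-0.75, 0.75): the Gaussian tail beyond the tanh bound
would otherwise push the rollout into feature regions the model never saw.
Non-finite samples abort with the step index. Desk-scale defaults are 8
replicas x 2e4 steps (the reference protocol used 128 replicas).

## Reference simulators and oracles

The fine-grained stand-in is a 4-bead chain with harmonic bonds
(k = 100 energy/length^2, r0 = 1), harmonic angles (k = 20 energy/rad^2,
theta0 = 1.9 rad), and a dihedral term `U = eps (1 - cos 2 phi)` with
eps = 3 kT, giving a symmetric double well with a 6 kT barrier — the
slowest coordinate, crossing every ~2.5e4 steps at gamma = 1. Masses and kT
are 1; dt = 0.005 keeps the stiffest bond mode at omega dt = 0.05.

* Langevin dynamics uses the BAOAB splitting (velocity Verlet with an exact
  Ornstein-Uhlenbeck midpoint substep), chosen for its small configurational
  bias at finite dt. Noise magnitude follows the fluctuation-dissipation
  theorem.
* GLE dynamics realizes the kernel `K(t) = (c2/tau_m) exp(-t/tau_m)`
  exactly through one auxiliary OU force variable per degree of freedom,
  with colored noise matched by the second fluctuation-dissipation theorem;
  an optional residual white-noise friction remains. Only coordinates are
  saved, so the saved process is genuinely non-Markovian while sharing the
  Boltzmann configurational ensemble of the Langevin chain (verified:
  dihedral-histogram JSD < 0.01 in the Markovian limit, equipartition
  within 5%).
* Oracles: the dihedral free-energy profile from quadrature of the
  Boltzmann weight (barrier exactly 2 eps, wells 50/50), harmonic variance
  kT/k, and the OU autocorrelation exp(-gamma t). Integrator noise is
  pre-generated in chunks from a seeded PCG64 stream, so fixed-seed runs
  are bit-identical.

The memory-dominated study condition uses gamma = 0.1, c2 = 8, tau_m = 2
(kernel friction 80x the white friction, memory spanning 20 saved frames at
save stride 20). There the TIC2 autocorrelation oscillates — a signature a
position-Markovian model cannot reproduce (its rollout ACF is flat), while
the non-Markovian model recovers both the oscillation and the slow hopping,
roughly quartering epsilon_ACF.

## Fidelity analysis

TICA is estimated from mean-free reference features with symmetrized lagged
covariance and a 1e-6 ridge on the instantaneous covariance (this gives
constant/masked columns zero loading); eigenvalues are sorted descending
and stay <= 1 after symmetrization. All definitions — TICA projection,
histogram ranges (union of both sample sets, 72^2 bins), k-means
microstates (k-means++; 250 default, fewer at desk scale), and the
2-macrostate split from the sign structure of the second right eigenvector
— are fitted on the reference data only and applied unchanged to generated
data. D_JS uses natural logs with 0 ln 0 = 0; PMFs are -kT ln P shifted to
zero minimum. ACFs average over time origins and replicas, normalized at
lag 0; the pooled mean is subtracted by default (TICs are near mean-free; a
flag disables it). epsilon_ACF is the mean squared ACF difference on the
common lag grid, summed over the configured components. MFPTs solve the
microstate linear system `m = lag + T m` with the target macrostate
absorbing, averaged over the source macrostate under the restricted
stationary distribution; the linear solve matches a 1e5-realization
Monte-Carlo first-passage simulation within 2%. Disconnected transition
graphs fall back to the largest strongly connected set with a warning.

## Numerical and engineering choices

The forecaster, its attention/GRU layers, and both optimizers run on a
compact reverse-mode autodiff core (`pfcg.nn`) written for this package;
every layer's analytic gradient is checked against finite differences in
the test suite. Checkpoints are a single `.npz` with the weight arrays plus
JSON metadata (architecture, scaler, mask) and round-trip bit-exactly.
Integrator hot loops are numba kernels.

## Problem sizes

The shipped studies are deliberately desk-scale: reference runs of 2-4e6
integrator steps (1e5 saved frames), 1.5-5e4 training windows, models with
~6e4 parameters, and 8 x 2e4-step rollouts. The full suite runs in about
ten minutes on one CPU.

## What the synthetic data does and does not show

The bead chains reproduce the structural features that matter for the
method — multi-well free-energy surfaces, a separation between fast
vibrations and slow barrier crossings, and tunable memory — with exact
reference statistics. They do not contain mapping degeneracy (every CG
configuration corresponds to exactly one fine-grained configuration up to
the integrated-out momenta), solvent anisotropy, or measurement noise, so
the input-noise regularizer has less to do here than on real mapped
atomistic data: its benefit shows at fine integration steps, where
transitions are nearly deterministic and rollout errors accumulate, and is
neutral at coarse steps. Passing tests demonstrate the pipeline's
correctness and the qualitative claims (memory helps dynamics; the
probabilistic output prevents pinning), not quantitative transfer to
proteins.

## Known limitations

* Markovian models at coarse time steps can recover the free-energy
  surface while getting barrier-crossing kinetics wrong by an order of
  magnitude (visible as large MARE_MFPT in the acceptance output); this is
  a property of the modeling regime, not an implementation defect.
* Short stage-2 training can underfit the rare hopping channel; the
  stage-2 budget in the shipped studies (20 epochs) was set so the
  non-Markovian rollout reproduces both fast and slow ACF components.
* The diagonal covariance ignores cross-feature noise correlations.
* No backmapping to fine-grained coordinates and no periodic-boundary
  handling (non-periodic solutes only).
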