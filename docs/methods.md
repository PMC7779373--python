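# Methods

`pfmlab` infers probabilistic functional modes (PFMs) from multi-subject,
multi-run fMRI by hierarchical Bayesian matrix factorisation. This note
describes the model, the inference scheme, the synthetic-data generator, the
numerical choices, and the limitations we have characterised empirically.

## The model

Each run's data matrix (voxels × time) decomposes as

    D^(sr) = P^(s) H^(sr) A^(sr) + ε^(sr)

with subject-specific spatial maps `P^(s)` (V × M), run-specific time courses
`A^(sr)` (M × T), per-run mode amplitudes `h^(sr)` (`H = diag(h)`), and white
Gaussian residuals with one precision `ψ^(sr)` per run.

**Spatial sub-model.** Each weight `P_vm^(s)` comes from a two-branch
mixture: a *signal* branch `N(μ_vm, σ_vm²)` shared across subjects, or a
*noise* branch `N(0, (η_m^(s) ζ_v)²)` that absorbs small spurious weights. A
binary membership with group probability `π_vm` selects the branch. The
group means `μ_vm` carry a spike-and-double-slab prior (point mass at zero
plus two Gaussian slabs with different spreads, giving sparse group maps
with heavy-tailed non-zero weights); `σ`, `ζ` take inverse-gamma priors,
`π` a beta prior, and `η` a zero-mean Gaussian prior on the standard
deviation. Group maps are summarised as `E[π_vm μ_vm]`, which folds
membership uncertainty into the map.

**Temporal sub-model.** Time courses split as `A = B + ξ`. `B` is the
haemodynamically plausible part: a white "neuronal" process convolved with
the canonical double-gamma HRF acquires the temporal autocorrelation encoded
by a T × T Toeplitz kernel `K_B` (unit diagonal), and `B` follows a
matrix-normal prior `MN(0, α⁻¹, K_B)`. The row precision `α^(sr)` is the
run-level functional-coupling netmat; a group-level Wishart hyperprior `β`
ties the run netmats together (optionally one `β` per experimental
condition, or one `α` per subject when runs are pooled). `ξ` is unstructured
Gaussian noise with per-mode precision `ω_m`; it is included when projecting
data onto maps but excluded from the netmat sufficient statistics, so
temporally specific noise stabilises map estimation without contaminating
the coupling estimates. The fraction `fABT = power(B) / (power(B) +
power(ξ))` is the model-based analogue of fALFF.

**Amplitudes.** `h^(sr)` has a joint Gaussian prior `N(μ_h, Σ_h)` with
conjugate hyperpriors, so consistent cross-subject amplitude structure
(e.g. correlated sensorimotor amplitudes) is represented explicitly. Sign
indeterminacy is resolved post hoc: a negative posterior amplitude mean is
negated together with the corresponding time-course row, leaving `P H A`
unchanged.

## Inference

All posteriors are factorised (mean-field) and updated by coordinate ascent;
every update is the exact conditional maximiser of the evidence lower bound
in its conjugate-exponential family, so the bound is non-decreasing across
sweeps (asserted in the tests with 1e-8 relative tolerance). The only
non-conjugate parameter, the subject noise scale `η`, is updated by 1-D MAP;
its stationary condition is a quadratic in `η²` with a single positive root,
so the maximiser is closed-form, and the point estimate contributes a
penalised-likelihood term to the bound (updating it also ascends the bound).

The matrix-normal `B` update diagonalises `K_B` once per run length: in the
kernel eigenbasis the posterior separates into T independent M × M
Gaussians, each requiring one small solve. Wisharts use the *rate*
parameterisation throughout, which makes the `α → β` hierarchy exactly
conjugate.

Sweep order: subject maps → group spatial hyperparameters → amplitudes
(then the positivity convention) → time courses → netmats → temporal noise
→ global noise → amplitude hyperparameters. Initialisation is deterministic
given the seed: per-subject randomized SVD, group-level SVD of the reduced
blocks, varimax rotation with a positive-skew sign convention, ridge
regression for subject maps and time courses. Convergence is declared after
three consecutive sweeps with relative bound change below 1e-6, capped at
200 sweeps. Modes whose group map or mean amplitude collapse below 1e-3 are
flagged as eliminated by the complexity penalties (evaluated after
sweep 20); they stay in the containers but are dropped from exports.

**Preprocessing.** The homoscedastic white-noise likelihood is justified by
the internal normalisation: every voxel is demeaned and the run is scaled so
the mean temporal variance is one (relative voxel variances are kept;
full per-voxel variance normalisation is optional). The spatial
degrees-of-freedom weight `c ∈ (0, 1]` tempers every data-derived term in
the updates to compensate for spatially smoothed noise; the default is 1
(no correction). The normalisation convention is recorded in output
metadata, so results are comparable only within one convention.

## Hyperprior defaults

| Parameter | Default | Meaning |
|---|---|---|
| λ_μ | (0.95, 0.04, 0.01) | spike / main slab / heavy slab weights |
| τ_μ1, τ_μ2; γ_μ1, γ_μ2 | 1, 3; 0.5, 0.5 | slab locations and spreads (ordered to break slab label degeneracy) |
| a_σ, b_σ; a_ζ, b_ζ | 1, 1 | signal / noise spread priors |
| a_π, b_π | 1, 4 | prior membership ≈ 20% (see below) |
| γ_η | 0.1 | subject noise-scale prior sd |
| a_α, a_β, B_β | M+1, M+1, (M+1)·I | weak netmat hierarchy |
| a_ω, b_ω | 1, 1 | temporal noise |
| τ_μh, γ_μh; a_h, B_h | 1, 1; M+1, (M+1)·I | amplitude hierarchy |
| a_ψ, b_ψ | 1e-3 | broad global noise prior |

The membership prior deserves a note. A very sparse prior (≈5% membership)
looks natural, but in small cohorts it contributes more pseudo-counts than
the subjects do, and when modes genuinely cover 10–25% of the analysed
voxels it slowly starves true memberships: we observed fits that started
from a good initialisation and progressively merged two identifiable modes
while a third shrank to elimination. Beta(1, 4) (≈20% prior membership,
five pseudo-counts) matches the coverage regime of the lattice-scale
analyses here and removes that failure mode. For high-resolution data where
modes occupy a much smaller fraction of grayordinates, raise `b_pi`.

## The synthetic-data generator

The generator reproduces the structure that makes multi-subject mode
estimation hard. Modes live on a 1-D voxel lattice: the model is voxelwise
exchangeable, so geometry matters only through smoothness and misalignment,
and the lattice keeps desk-scale cost low (a wrapper embeds lattices into
NIfTI volumes for I/O).

* **Group maps** are Gaussian blobs whose support covers 10–25% of the
  lattice (rising with the overlap setting), plus a secondary blob placed
  inside *another* mode's territory, so modes genuinely share voxels and the
  maps are spatially correlated — the regime in which group-seeded
  regression is known to struggle.
* **Subject maps** displace the group maps with a smooth random field
  (default magnitude: half the blob width — residual misalignment comparable
  to the size of functional regions), mix a second displaced copy
  (approximating non-homotopic splits), and jitter the weights. The
  model-matched preset instead uses voxelwise-independent additive
  deviations (the model's own form of subject variability), because smooth
  multiplicative jitter changes map norms coherently and is then
  fundamentally confounded with amplitudes — no method could separate them.
* **Time courses** are white neuronal processes with a run-specific
  correlation matrix sampled around a group netmat, convolved with a
  double-gamma HRF whose delay varies by subject, mixed across space between
  an early and a late variant (space-varying HRF), and passed through a weak
  `x + κ(tanh x − x)` saturation (κ = 0.1). Convolution is applied to a
  padded process and only the steady-state segment is kept; the start-up
  transient otherwise distorts the temporal autocorrelation enough to bias
  netmat estimates even under ideal conditions.
* **Amplitudes** are lognormal with a categorical correlation structure: two
  mode blocks correlate positively within and negatively across. (A global
  common amplitude factor is removed exactly by any per-run normalisation,
  so it is unrecoverable by construction and is not simulated as the
  structure of interest.)
* **Residuals** are Gaussian, smoothed in space and time, scaled to the
  target SNR (default 1). Optional structured artefacts add a rank-1
  subject-specific component with a localised or global spatial profile.

Defaults follow the reference study conditions: 15 modes, 40 subjects, two
runs, 10,000 voxels, 500 time points at TR 2 s; replication pools 10
datasets. The desk preset (10 modes, 12 subjects × 2 runs, 2,000 voxels,
300 time points, 3 datasets) keeps the full comparison suite under a few
minutes on one CPU; the model-matched preset (5 modes, 6 subjects, 500
voxels, 200 time points, SNR 1) is used for parameter-recovery checks.

What passing tests on these data do *not* show: the generator has no
physiological noise waveforms, no real registration errors, and its 1-D
geometry cannot produce the 2-D/3-D rearrangements of real cortex, so
recovery numbers here bound what the same pipeline would do on real data
from above.

## Evaluation metrics

Modes are matched once between estimated and true *group* maps (Hungarian
assignment on absolute spatial correlation, signs aligned) and the matching
is applied to all subject-level quantities. Four metrics, all invariant to
mode permutation and sign flips:

* **Spatial accuracy** — mean Pearson correlation between estimated and true
  subject maps.
* **Netmat accuracy** — correlation between vectorised off-diagonal partial
  correlations of estimated and true run netmats, averaged over runs.
* **Amplitude accuracy** — per-mode cross-subject correlation of *relative*
  amplitudes: every run's amplitude vector is divided by its mean over modes
  on both sides (each method, and the internal normalisation, fixes per-run
  scale by its own convention), then each mode by its cross-subject mean.
* **Spatial→temporal bias** — Pearson correlation, across mode pairs and
  runs, between the netmat error (estimated − true partial correlation) and
  the subject's true spatial map correlations; zero means the temporal
  estimates are uncontaminated by spatial overlap. A regression-slope
  variant is exposed as an option.

## Numerical choices

* `K_B` gets 1e-8 diagonal jitter and is re-normalised to an exact unit
  diagonal; its eigendecomposition is cached per run length.
* Responsibilities use log-odds clipped at ±700 before the logistic;
  mixture component weights are normalised via a max-shifted softmax.
* `η` is floored at 1e-6; with zero pooled noise mass the MAP is the prior
  mode (zero, reported at the floor).
* Degenerate inputs raise typed errors (`DegenerateDataError` for
  all-constant runs, `ConfigurationError` for infeasible shapes,
  `NumericalError` for non-finite or non-PSD intermediates, with the
  offending update named).
* HDF5 output is written with `track_times=False`, so identical content
  produces identical bytes; everything downstream of a seed is reproducible
  at bit level.

## Known limitations

* **Residual cross-mode map mixing.** The subject-map posterior is fully
  factorised over (voxel, mode) — five scalars per triple. The factorisation
  discards the cross-mode covariance of map errors, and at desk scale the
  fitted subject maps retain ≈2% of the *other* modes' true maps. This tiny
  mixing propagates into the netmats: the implied deterministic error
  correlates ≈0.9 with the true spatial correlations. Consequences,
  established by experiment: the run-netmat machinery is exactly unbiased
  when given the true maps (and matches a dense joint-Gaussian solve to
  1e-15), but full fits show a positive spatial→temporal bias correlation of
  ≈0.4–0.6 whose *magnitude* is small (mean absolute partial-correlation
  error ≈0.06, below the T=200 sampling floor) yet whose correlation with
  spatial structure is persistent — it does not vanish with more subjects or
  time points, because those shrink the random error faster than the
  systematic one. The same behaviour appears on data generated exactly from
  the model's own equations, so it is a property of the variational family
  at these problem sizes, not of the simulator or the implementation.
* Related: late in a fit the bound keeps creeping upward (≈5e-6 relative per
  sweep) along this mixing direction, so desk-scale fits typically end at
  the sweep cap rather than the tolerance.
* Dual regression seeded with the true group maps shows netmat errors that
  align strongly (+0.4) with the subject-specific *deviation* of spatial
  correlations from the group pattern, but a static-overlap component of the
  opposite sign largely cancels it in the bias metric against the total
  spatial correlation. Comparisons of bias *between* methods at desk scale
  are therefore delicate, and the method ordering on the bias metric is the
  least stable result in the comparison suite; map recovery orderings are
  robust.
* No MRF/spatial smoothness prior across voxels; no subject-specific HRF
  estimation (deliberate: one canonical kernel); no streaming/batched
  inference — full-batch desk scale only.
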