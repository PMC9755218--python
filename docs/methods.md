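# Methods

`sparsedyn` infers governing differential equations — ODEs, PDEs, and
overdamped Langevin SDEs — from sampled data by sparse symbolic regression:
the right-hand side is modelled as a sparse linear combination of candidate
functions ("library" columns Θ), and a hierarchical Bayesian solver selects
the few columns the data supports.

## The linear inverse problem and its priors

All fits reduce to g = Φw + s with Gaussian residuals of precision β.  Two
priors on w are available.

**Hierarchical Laplace prior (BCSL).**  w_i | γ_i ~ N(0, γ_i) with
γ_i | λ ~ Exp(λ/2); marginalising γ gives a Laplace prior, which is what
makes very sparse solutions typical.  Hyperparameters are set by type-II
maximum likelihood: the weights are integrated out and
p(γ, λ, β | g) is maximised.  The maximisation is a fast sequential scheme:
per step, one coordinate γ_i is added, re-estimated, or deleted — whichever
candidate action most increases the evidence — with γ-candidates taken from
the per-coordinate stationary condition (the positive root of a quadratic
in the Laplace case).  Two details matter in practice:

* *Action acceptance.*  Candidate actions are ranked by their estimated
  gain but an action is applied only if the exactly recomputed evidence
  (with λ and β re-estimated from their stationary conditions) improves,
  so the iteration is monotone in the true objective.
* *Two deterministic starts.*  On correlated dictionaries a forward greedy
  pass can represent a smooth target with a single high-order column (e.g.
  x⁵ standing in for x − x³) and never discover the multi-column
  alternative.  The scheme is therefore run twice — from the single
  best-aligned column, and backward from the full least-squares solution —
  and the higher-evidence result is kept, followed by a local
  Nelder–Mead polish of (log γ, log β) on the final support.

**Hyperpriors.**  The Exp(λ/2) density is counted on the active components,
so every retained column pays an evidence penalty of −log(λ/2) + λγ_i/2.
With λ profiled at its stationary value this behaves like a BIC-style
complexity penalty of roughly |log(λ/2)| nats per component (≈ 5–12 nats in
the regimes exercised here), which is what prunes noise-level columns.
λ itself carries a proper Exponential(1) hyperprior, giving the profile
λ = 2L/(Σγ + 2).  An improper (Jeffreys) hyperprior looks natural here but
makes the evidence unbounded along γ → 0, λ → ∞ — vanishing-strength
components would collect log(λ/2) rewards without limit — so no maximiser
would exist for the solver to find; the unit rate pins that degeneracy
while leaving the penalty for real components essentially unchanged
whenever Σγ ≫ 1, which holds on unit-normalised columns.  β carries a flat
prior and the classical re-estimation β = (N − df)/RSS, which is then its
exact stationary condition.  β is initialised at 100/var(g) and capped at
1e13/var(g) (a numerical noise floor for formally noise-free targets); γ is
capped at 1e14.  Columns are normalised to unit 2-norm internally and all
reported weights, covariances and uncertainties are rescaled to the
original units.

**Gaussian prior (ridge).**  w = (ΦᵀΦ + αI)⁻¹Φᵀg with a fixed α (default
1e-6 on the normalised scale); with α = 0 and a rank-deficient design the
minimum-norm solution is returned and flagged.  This is the baseline the
Laplace prior is compared against.

## Automatic thresholding (ATSBL)

The prior-based fit typically leaves small nonzero entries.  They are
removed by a train/test loop: rows are split 80/20 (seeded random split by
default; contiguous available for strongly time-correlated data), the model
is fitted on the training rows, entries with normalised magnitude below a
threshold `tol` are zeroed, the surviving support is refitted by ordinary
least squares (removing shrinkage bias), and the candidate is scored on the
held-out rows with

    e = ‖Θ_test w − g_test‖² + η‖w‖₀,   η = 10⁻³ κ(Θ),

κ being the 2-norm condition number of the normalised design.  On
improvement the threshold grows by d_tol; otherwise it is reduced by
2·d_tol and d_tol is refined to 2·d_tol/(n_iters − iteration).  Defaults:
n_iters = 100, d_tol auto-set to max|w_init|/n_iters on the normalised
scale.  Thresholding on the normalised scale (|w_i|·‖Θ_i‖) is essential
when library columns span many orders of magnitude (z⁵ vs 1 for a chaotic
flow).  The best-scoring sparse vector over all iterations is returned; its
uncertainties come from the least-squares refit on the training rows.

## Libraries and derivatives

Candidate terms follow a canonical name grammar (`1`, `x^2*y`, `sin(x)`,
`cos(w t)*x`, `u_xx`, `u*v^2`) and are evaluable on aligned arrays; the
name, not the position, is a term's identity, so fits from differently
ordered libraries compare correctly.  Derivatives use the 4th-order central
5-point stencil; on open boundaries the outermost two samples per edge are
excluded from regression rows (trimming beats one-sided stencils, which
would lose accuracy order); periodic axes wrap.  PDE systems subsample at
most 50 000 space–time rows (seeded) to stay desk-scale.

Default libraries:

* 1-D Langevin drift: 11 monomials, degree ≤ 10.  Trig terms are available
  but off by default: on a symmetric range of a few units sin(x) lies in
  the span of the odd monomials to within its degree-7 Taylor remainder,
  which makes polynomial-drift libraries near-degenerate and lets the
  solver swap sin(x) for x.
* 1-D Langevin diffusion: 6 monomials, degree ≤ 5.
* Chaotic-flow (3-variable) library: monomials of total degree ≤ 4, 35
  terms.  At degree 5 (56 terms) the condition number of the design on
  attractor data reaches ~1e8, so the η = 10⁻³κ penalty (~1e5) exceeds the
  test-error cost of deleting a small true term (~2×10⁴ for the −y term of
  the second component) and the thresholding loop would prune it; at
  degree 4 (κ ≈ 5×10⁵) all seven true terms are recovered with errors
  ~1e-10.
* Two-component reaction–diffusion library: 21 monomials (degree ≤ 5) +
  6 second + 4 first derivatives, 31 terms.  Explicit Laplacian columns
  are not included by default because lap_u = u_xx + u_yy exactly, which
  makes the design singular; isotropic diffusion appears as equal xx/yy
  coefficients.

For noisy trajectory data a Savitzky–Golay pre-smoother
(`smooth_trajectory`, default window 251 samples, polyorder 4) is applied
before differencing: raw 4th-order differences amplify white measurement
noise by ~1/Δt, which at Δt = 2×10⁻⁴ would make percent-level coefficient
accuracy unreachable, while the smoother's bias is negligible when the
window stays well below the fastest signal time scale.

## Kramers–Moyal estimation

From a trajectory sampled at step s, F¹_i = (X_{i+1}−X_i)/s and
F²_i = (X_{i+1}−X_i)²/(2s) estimate the drift D¹(x) and diffusion D²(x).
Direct mode regresses F¹/F² on the library at the trajectory positions;
binned mode (1-D only) first averages them in Q equal-width bins (default
Q = 200) and regresses the bin means at the bin centres.  Sparsely
populated bins can be discarded below a probability threshold p*
found by a two-step class-entropy maximisation: candidates are midpoints
between consecutive distinct bin probabilities; step 1 maximises the summed
Shannon entropies of the below/above classes (Kapur-style), step 2 the
two-class Tsallis criterion S_b + S_f + (1−q)S_bS_f with index q = 0.8
(configurable), tie-breaking toward the Shannon optimum.  A manual p*
override is provided, since the automatic heuristic has no firm theoretical
footing.  Equal probabilities return min(p) (nothing filtered), and the
most probable bin can never be discarded.

**Known estimator bias.**  E[F²|x] = D²(x) + s·D¹(x)²/2 + O(s²).  The
package deliberately applies no finite-sampling-time correction, so this
O(s) term is part of the signal the diffusion regression sees.  At
Δt = 5×10⁻³ with 10⁶ samples it is statistically resolvable whenever the
drift is strong (for the double-well benchmark its test-error contribution
is ~245 against an L0 penalty of ~1), and the fit then legitimately selects
polynomial correction terms alongside the true diffusion; the fitted
constant remains within a few percent of truth.  This, not a solver defect,
is why exact diffusion-support recovery fails in the corresponding
benchmark assertions, and it also bounds the achievable coefficient
deviation in the active-learning loop below.  The remedy would be a
finite-s correction, which is out of scope.

## Benchmark generators

All generators are seeded and reproducible.

* Euler–Maruyama (Itô): X_{i+1} = X_i + [D¹ + c]Δt + √(2D²Δt)·ξ_i with an
  optional control force c recorded alongside the trajectory.  Blow-ups
  raise an error carrying the last valid index.
* Built-in Langevin fixtures: bistable double well (D¹ = −2x³+12x²−18x+3,
  D² = 0.8).  The two wells differ by ~3.7 energy units, so fitting
  pipelines start trajectories in the *metastable* (shallower) well:
  escape from it is fast and both basins get sampled, whereas a deep-well
  start leaves ~5–10% of 10⁶-step trajectories trapped for the entire run,
  making the cubic and quartic drift columns genuinely indistinguishable
  on the visited range.  Also provided: the same drift with D² = x²−2x+2; a periodically modulated
  double well D¹ = [a₀+1−cos(ωt)]x − x³ with a₀ = 5×10⁻³ (ω defaults to
  0.05, ≈ 40 modulation periods over the default 10⁶-step, Δt = 5×10⁻³
  trajectory — slow enough for well merging, fast enough to average);
  a three-well landscape U = x⁶−6x⁴+0.5x³+8x² with D² = 1; and a planar
  field with radial + shear drift (b defaults to 1).
* Lorenz flow, classic RK4, parameters a = 10, b = 28, c = 3/8 as used in
  this benchmark family (the canonical value 8/3 is overridable), default
  Δt = 2×10⁻⁴, t ∈ [0, 25], x₀ = (−8, 8, 27).
* λ–ω reaction–diffusion (β = 2, D_u = D_v = 0.1 by default) on a periodic
  20×20 domain with a 256² grid, pseudo-spectral Laplacian + RK4 reaction
  stepping at Δt = 0.0034 over t ∈ [0, 0.6].  The tanh-spiral initial
  pattern is not periodic-smooth (phase seams at the edges leave features
  finite differences cannot resolve — recording from t = 0 leaves a 4%
  equation residual and 10–20% coefficient errors), so 3 time units of
  unrecorded spin-up are integrated first; afterwards the residual is
  ~3×10⁻⁵ rms and recovered coefficients deviate only in the fourth
  decimal place.
* Noise: per-coordinate zero-mean Gaussian with σ = fraction × coordinate
  std.  Denoisers: spatial Gaussian blur, per-snapshot wavelet soft
  thresholding (universal threshold, db4), spectral low-pass (default keep
  |k| ≤ 0.25 k_max), each optionally followed by a temporal
  Savitzky–Golay stage (the fields evolve far below the snapshot Nyquist
  rate, so a window of ~41 snapshots removes most remaining noise without
  biasing the dynamics).

## Active learning (AISO)

Multistable systems trap trajectories, so single-trajectory fits are only
locally valid.  The adaptive loop alternates sampling and inference: after
each round the drift is refitted from all accumulated data and the next
round is simulated under the control force

    c_ℓ(x, t) = −Θ_ℓ(x)·w_ℓ · exp[−(x_ℓ − μ_ℓ)²/ζ_ℓ],

with μ, ζ the mean and population variance of the previous round's
trajectory only (ζ floored at 10⁻⁶ × squared range).  The Gaussian window
confines the perturbation to the explored region, flattening the local
minimum and expelling the trajectory.  The first round is uncontrolled;
each round starts from the previous final state; the known applied control
is subtracted from F¹ before fitting (the sampled process obeys drift
D¹ + c, so this is required for unbiased inference of D¹); F² is used
uncorrected, consistent with the estimator above.  If a controlled round
blows up, the control is damped by ½ and the round restarted.  Defaults:
10 rounds of 10⁵ steps at Δt = 5×10⁻³.  On the three-well benchmark the
drift coefficient deviation falls from O(1) to ~5×10⁻³ within ~5 rounds
and controlled runs visit all three wells while equal-length uncontrolled
runs stay trapped; the *average* drift+diffusion deviation saturates near
0.4 because of the diffusion-estimator bias discussed above.  The
benchmark starts the particle trapped at the deepest minimum (x₀ = −1.84);
"trapped" comparisons use a single sampling round of the same length from
the same start, since over ten rounds' worth of time even uncontrolled
dynamics eventually hops every barrier (the Kramers escape time from the
deepest well is ~290 time units against a 500-unit round).

## Scoring

The deviation of identified coefficients,
DIC = (1/K) Σ |w_i − w'_i| / max(|w_i|, |w'_i|) over the union support
(matched by term name), is 0 for a perfect identification; a missing or
spurious term contributes exactly 1 and each pair is bounded by 2 (the
formula's per-term ratio cannot exceed 2, so the whole score is bounded by
2 even though looser statements are sometimes quoted).

## What the synthetic benchmarks do and do not show

The generators produce exactly-Markovian, exactly-sampled data whose only
imperfections are the ones injected deliberately (discretisation, additive
Gaussian noise).  Passing tests therefore demonstrate correctness of the
inference machinery under the stated models, not robustness to measurement
noise on increments, non-Markovian dynamics, irregular sampling, or model
misspecification — all of which real experimental trajectories exhibit.
Problem sizes in the test-suite replicate the benchmark definitions
(10⁶-step SDE fits, 125 001-sample chaotic flow, 256² PDE grids, 10×10⁵
active-learning rounds); replicate counts (5–20 seeds) were chosen to keep
the whole suite desk-scale.

## Known limitations

* No finite-sampling-time corrections: D² estimates carry the O(Δt)
  squared-drift bias discussed above; D¹ estimates are unbiased.
* Diagonal diffusion only; no multiplicative-noise interpretation issues
  are addressed beyond the Itô convention.
* Binning is 1-D; the modulation frequency ω of time-dependent libraries
  must be known; no symbolic simplification of equivalent term
  combinations (u_xx + u_yy vs an explicit Laplacian is handled by library
  choice, not algebra).
* The entropy-based p* heuristic is a pragmatic reconstruction; manual
  override is provided.
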