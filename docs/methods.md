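# Methods

## Model

A composition is a nonnegative vector `s` with `Σ s_i = 1`. The
compositional maximum-entropy (CME) model is the distribution on the
simplex with maximal Shannon entropy subject to the observed first and
second moments. By Lagrange duality it is the exponential family

    P(s) ∝ exp[ Σ_i ( h_i + ½ Σ_{j≠i} K_ij s_j ) s_i ],

supported on the **closed** simplex — exact zeros are valid data and
need no pseudocounts, in contrast to log-ratio approaches. Because the
constraint makes one component redundant (`M_N`, `chi_iN` follow from
the others), the natural parameters are defined only up to a gauge; we
adopt `h_N = 0` and `K_ii = 0`, with component N taken as the last
column of the input table (selectable via `reference=`). Softmax
influence weights `Q_i = e^{h_i}/Σ e^{h_j}` are invariant under the
residual shift freedom of `h`.

## Pseudolikelihood fitting

The normalizer `Z` is an (N-1)-dimensional simplex integral with no
closed form, so exact maximum likelihood is out of scope. Instead each
free component i = 1..N-1 contributes a conditional density on
`[0, upper]`, `upper = 1 - Σ_{j≠i, j<N} s_j`:

    P(s_i | s_~i) ∝ exp[(h̃_i + ½ K̃_ii s_i + Σ_{j≠i} K̃_ij s_j) s_i],

with reduced ("tilde") parameters `h̃_i = h_i + ½(K_iN + K_Ni)`,
`K̃_ij = K_ij − K_iN − K_Nj`. The per-node objective is the average
conditional log-density over samples; in moment form

    ℓ_i = h̃_i M_i + ½ K̃_ii chi_ii + Σ_{j≠i} K̃_ij chi_ij − mean_d log Z̃_i(s^d).

The equality of the moment form and the average-log-density form is an
algebraic identity and serves as the primary correctness oracle in the
test suite. `log Z̃_i` is the log-partition of a one-dimensional
exponential family with sufficient statistics `(s, s²/2)`, hence convex
in `(a, b) = (linear coefficient, K̃_ii)`; since `a` is affine in the
parameters, each ℓ_i is concave and L-BFGS-B from the all-zero (flat
model) start converges to the global optimum. Gradients are analytic:
`∂ log Z̃ / ∂a = E[s]`, `∂ log Z̃ / ∂b = ½ E[s²]`, with the conditional
moments computed from the same stable closed forms as the integral.

The N-1 node problems are solved independently (they share no
parameters) and the generally asymmetric K̃ is reconciled by the
refinement

    K_ij = ½(K̃_ij + K̃_ji − K̃_ii − K̃_jj),  K_iN = −½ K̃_ii,  h_i = h̃_i − K_iN,

which always yields a symmetric, zero-diagonal K. On gauge-fixed
parameters refinement exactly inverts the tilde map.

Practical points:

- **Reference dependence.** Each conditional's optimum is
  parameterization-free, but the symmetrization reconciles per-node
  asymmetries in a way that depends on which component was eliminated.
  The refined `K` and `Q` therefore agree across reference choices
  only up to finite-sample error, O(1/√D); at D = 1500 the residual is
  a few percent of the interaction scale.
- **Weak identification of h on concentrated data.** When the data
  cluster tightly (covariances of order 1e-3 or smaller), the fitted
  `K` is large (of order the inverse covariance) and the objective is
  nearly flat along directions that trade `h` against `K`. Means and
  covariances of the fitted model are reproduced accurately, but `h` —
  and hence `Q` — carries wide uncertainty. Interpret `Q` on such fits
  with care.
- **Degenerate inputs.** Samples whose integration range vanishes
  (`s_i + s_N ≈ 0`) carry no information about node i and are dropped
  from that node's averages. A component constant across samples makes
  its parameters unidentifiable; the fit then requires an explicit L2
  ridge (`ridge > 0`, applied to the tilde parameters; default 0).

## The partition integral

Everything rests on `Z̃(a, b, u) = ∫_0^u exp(a s + ½ b s²) ds` and its
first two moments, evaluated stably for any finite `(a, b)`. After
rescaling to the unit interval (`A = a·u`, `B = b·u²`) three branches
cover the plane:

- `|B| ≤ 0.25`: a 13-term series in `B` whose coefficients are moment
  integrals `∫ t^j e^{At} dt`, evaluated by a fixed 64-point
  Gauss-Legendre rule (spectrally exact for this integrand). The
  scale-invariant switch on `B = b·u²` (rather than on `b` alone)
  matters: the closed forms below lose precision exactly when the
  quadratic variation across the interval is small, whatever the
  magnitude of `b`.
- `B < −0.25`: truncated-Gaussian form via differences of `erf`,
  computed in the log domain with `erfcx` so that far-tail truncation
  (peak far outside `[0, u]`) neither underflows nor cancels.
- `B > 0.25`: the convex analogue via `∫_0^z e^{t²} dt = e^{z²} D(z)`
  (Dawson function), again combined in the log domain.

Conditional moments in the closed-form branches come from the endpoint
identities `w(u) − w(0) = a Z̃ + b Z̃₁` and `u·w(u) = Z̃ + a Z̃₁ + b Z̃₂`
(with `w` the unnormalized density), evaluated as ratios of
exponentials of log quantities. The implementation agrees with
adaptive quadrature to better than 1e-10 relative error over
`a ∈ [−20, 20] × b ∈ [−50, 50] × u ∈ (0, 1]` and remains finite far
outside that range (fits of tightly concentrated data routinely reach
`|b| ~ 10³`).

## Monte-Carlo simulation

Sampling from a fitted model uses pairwise-exchange Metropolis: pick
two components, transfer an amount drawn uniformly from a symmetric
window, reject if either coordinate would go negative. The proposal
conserves the sum exactly, so every draw is on the simplex by
construction, and acceptance uses only log-density differences (no
`Z`). The window width adapts toward 30-50% acceptance during burn-in
and is frozen afterwards, preserving detailed balance. A fraction
(default 10%) of proposals use the full window `U(−1, 1)` regardless
of adaptation: strongly competitive models concentrate mass at the
simplex vertices, and without occasional long jumps the chain cannot
hop between modes within any practical run length. Defaults: burn-in
`10^4·N` steps, thinning `N`, initial width 0.1.

`estimate_moments` attaches batch-means standard errors (20 batches)
to every mean and covariance entry so that agreement checks can be
expressed in sampling-error units. For N ≤ 4, `brute_force_moments`
computes the exact moments by nested Gauss-Legendre quadrature over
the simplex with order doubling until entries change by < 1e-9; it is
the ground truth for sampler validation. As the warning emitted for
N > 20 or `max|K| > 50` indicates, simulation cost grows quickly with
size and interaction strength; the fitting path never needs it.

## Synthetic data: competitive Lotka-Volterra

The benchmark generator integrates

    ds̃_i/dt = r_i s̃_i (1 − Σ_j α_ij s̃_j / κ_i)

with fixed-step RK4 (dt = 0.01, negative excursions clamped at 0, an
instability guard at 10× max κ). Defaults mirror the symmetric
three-species benchmark: `r = κ = α_ii = 1`, off-diagonal α equal,
with presets `mutualism` (α = 0.6), `neutralism` (α = 1.2),
`competition` (α = 4.0). For α < 1 the coexistence fixed point
`s̃ = κ/(1 + (N−1)α)` is stable (unimodal compositions around equal
shares); for α > 1 the dynamics are winner-take-all (compositions
concentrate at the simplex vertices).

A dataset is built from 100 trajectories started at i.i.d.
Uniform(0, 1) abundances, integrated to t = 100; the first half of
each trajectory is discarded as transient, 2000 (trajectory, time)
pairs are drawn uniformly, Gaussian noise (sd 0.05, in raw abundance
units) is added, negatives are clamped, all-zero rows re-noised, and
rows are closed to the simplex. The noise sd, trajectory count,
transient fraction and sampling scheme are generator choices, not
dictated by the dynamics; 0.05 visibly perturbs the distributions
without destroying the regimes.

What the generator does *not* emulate: sequencing-style count noise
(multinomial resampling), compositional measurement bias, temporal
autocorrelation between retained samples, or non-stationary
environments. Passing the benchmark therefore demonstrates that the
estimator recovers interaction structure from idealized stationary
relative-abundance snapshots, not that it is robust to the full error
structure of real surveys.

### Modality classification

The unimodal/multimodal label is computed from the histogram of one
species' marginal (25 bins on [0, 1], 5-bin boxcar smoothing,
zero-padded ends so boundary peaks count, peaks required to have
prominence ≥ 20% of the maximum). The smoothing window is deliberately
wider than one bin: clamping observation noise at zero creates a
single-bin atom at exactly 0 which is an artifact of the noise model,
not a mode of the stationary distribution; five-bin smoothing erases
it while the broad vertex peaks of genuinely multimodal regimes
survive. With these settings the classification is stable across
independent seeds, flipping between α = 1.0 and α = 1.2 (the sweep
grid brackets the critical value near 1.1-1.2).

## Logit-normal baseline

The comparison model places a Gaussian on additive log-ratios
`y_j = log(s_j/s_N)`; its interaction summary is the negated precision
matrix `K* = −Σ_LN⁻¹`, symmetrized into a full N×N zero-diagonal
matrix by the same refinement transformation CME uses. Zeros require a
pseudocount (default: half the smallest positive value, applied only
when zeros are present); a diagonal ridge is added only if the
covariance is numerically singular.

Two caveats found while validating, both inherent to the baseline:
the symmetrized matrix is **not** invariant to the log-ratio reference
(the ALR precision does not transform as a CME tilde matrix under
reference change, so the refinement cannot undo the change of basis —
verified with exact population covariances), and on boundary-heavy
competitive data the pseudocounted log-ratios inflate `Σ_LN` so the
interaction estimates collapse toward zero rather than turning
negative. CME, fitted to identical data, flips sign cleanly — the
head-to-head test in the suite records exactly this contrast.

## Problem sizes and tolerances in the test suite

Unit tests run at small D (tens to thousands) chosen so the whole
suite completes in well under a minute of CPU except for the
end-to-end checks, which use the generator defaults (2000 samples) and
chains of 5·10^4-2.5·10^5 draws; multimodal fitted models get the
longer chains because the mode-occupancy fractions, not the
within-mode moments, dominate the Monte-Carlo error. Stochastic
assertions are phrased in standard-error units where a standard error
is estimable (3 SE), and in absolute tolerances matched to the
sampling distribution of the quantity otherwise (e.g. species-mean
symmetry under competition is checked at the trajectory-count scale,
since every trajectory collapses to one vertex). Deterministic
numerical claims (partition integrals, refinement round trips, closure
identities) are asserted at 1e-10 or tighter.
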