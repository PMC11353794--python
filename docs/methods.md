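# Methods

## The measure

Contrast information is specific information written as a relative
entropy: for target `A`, source outcome `b` and context outcome `c`,

    I(A; b | c) = D( p(A|b,c) : p(A|c) ),

a sum over a discrete target or an integral over a continuous one. Of
the two standard definitions of specific information (relative entropy
vs. entropy difference), only the relative-entropy form is invariant
under invertible differentiable re-descriptions of a continuous state
space; the price is additivity, which the entropy-difference form keeps
instead. Because the goal here is a single dynamic measure usable across
discrete and continuous processes, the relative-entropy form is the one
implemented, and the package asserts non-additivity rather than assuming
a chain rule.

Values are reported in bits by default. The discrete worked example
(stay-probability .95 two-state chain giving ≈2.95 for the switch) pins
the base to 2; the Gaussian KL formula is naturally in nats and is
converted at the boundary. Every public function takes `base="bits"`
or `"nats"`.

Discrete conventions: `0·log 0 = 0`; joints are accepted when their
total mass is within 1e-9 of 1 and silently renormalised (larger
deviations raise — that is the caller's bug). Inside one consistent
joint the marginal `p(a|c)` dominates every conditional `p(a|b,c)`, so
the +infinity branch (absolute-continuity violation) can only be reached
through the generic KL kernel with mismatched distributions; it returns
`inf` with a structured warning instead of raising.

## Temporal variants

A window around the present moment assigns the past X, present Y and
future Z to the three roles. Six permutations are meaningful:

| variant       | target | source | context |
|---------------|--------|--------|---------|
| predictive    | Z      | y      | x       |
| connective    | Z      | x      | y       |
| reflective    | Y      | z      | x       |
| b-predictive  | X      | y      | z       |
| b-connective  | X      | z      | y       |
| b-reflective  | Y      | x      | z       |

Past/future regimes may be points at offsets (j, k) or (u, v), or
extended intervals (used by the Gaussian profiles).

## Markov chains

Transition matrices are column-stochastic: `P[j,k] = p(next=j |
current=k)` (columns sum to 1; one-hot states are column vectors, so
`⟨z|P^k|y⟩` is entry [z, y] of `P^k`). The stationary vector comes from
the leading eigenvector with a residual check (`‖Pπ−π‖∞ ≤ 1e-10`) and a
power-iteration fallback; irreducibility is checked by strong
connectivity of the positive-support graph and periodicity by counting
unit-modulus eigenvalues. `pi` is computed lazily so that estimated,
possibly non-ergodic chains can still be stored and inspected. Time
reversal is `R = D_π P^T D_π^{-1}` (same formula for rate matrices).

The six closed forms are sums over entries of `P^j, P^k, P^{j+k}`
(forward variants) or the corresponding powers of `R` (backward),
with matrix exponentials `e^{uQ}` replacing powers in continuous time
(scipy's scaling-and-squaring `expm`). Both connective variants are
identically zero for any Markov model — the code returns exact 0.0 and
the tests verify the definitional sum agrees to 1e-12. Every closed form
is validated against brute-force contrast on the exactly assembled
three-point joint `p(x,y,z) = π_x ⟨y|P^j|x⟩ ⟨z|P^k|y⟩`.

Estimation: DTMC transition counts are pooled across all corpus
sequences (never across sequence boundaries), with optional additive
pseudocounts; a state never departed from (pseudocount 0) is an error
naming the state. The CTMC maximum-likelihood estimator is jumps over
dwell time, `q̂[j,k] = N(k→j) / T(k)`, with consecutive repeats of a
symbol merged into one dwell; this standard MLE is the package's choice
since only the estimate's existence, not its form, was prescribed.
Degenerate conditioning paths (zero probability) raise rather than
returning NaN.

Profiles: a DTMC profile has one row per event whose j-past and k-future
neighbours exist (N−2 rows at j=k=1). A CTMC profile is a curve sampled
every `grid_step` between consecutive onsets: the predictive family pins
X and Y at the two most recent onsets and sweeps Z across the dwell
(whose realised symbol is still the current one); the reflective family
pins X and Z at the flanking onsets and sweeps Y between them. The grid
resolution is a free parameter with no canonical value; it only controls
plotting density, not the measure.

## Gaussian processes

For jointly Gaussian regimes both conditionals are Gaussian and the
contrast is the closed-form KL divergence

    D(N(m1,S1):N(m2,S2)) = ½[(m2−m1)ᵀS2⁻¹(m2−m1) + tr(S2⁻¹S1)
                             − ln(|S1|/|S2|) − n]   (nats),

with `n` the target length recorded by the regime partition (this
matters when the future regime is extended). Conditioning uses the block
formulas with Cholesky solves. For scalar regimes the general path
reduces exactly to the one-dimensional formula
`½[(m_bc−m_c)²/s_c² + s_bc²/s_c² − ln(s_bc²/s_c²) − 1]`, and the tests
hold the two routes to 1e-12 of each other.

A stationary model is a mean plus autocovariance γ at integer lags
(discrete) or a polynomial in |t| fitted to those lags (continuous;
default degree 10 — "high-degree" is the only guidance the setting
offers, so the degree is a parameter). Any window of time tags induces a
Toeplitz covariance. Fitted autocovariances need not induce positive
definite windows; windows are repaired by symmetrising, adding diagonal
jitter starting at `1e-10·γ(0)` and doubling at most 20 times, then
eigenvalue-clipping at `1e-12·γ(0)` with a warning. The autocovariance
estimator is the biased (1/N) pooled form by default because it favours
PSD Toeplitz matrices; the unbiased divisor is available by flag.

Unlike the Markov case, connective contrast does **not** vanish for
general GPs; it is only near zero when γ is of AR(1) (exactly Markov)
type, which the tests check as an inequality, not an identity.

Long GP simulations (> 512 points) use circulant embedding: the real
part of an FFT of complex normals scaled by the embedding eigenvalues,
times √2, has exactly the target Toeplitz covariance where the
embedding is non-negative; tiny negative eigenvalues are clipped.

## PPM

Escape method C with backoff (not interpolation) and no update
exclusion; the order −1 base case is uniform over the training alphabet,
so no prediction is ever zero and information content is always finite.
Training is static: counts are accumulated once over the corpus and
never updated while profiling.

PPM predicts one step ahead only, so the joint over (present, next
event) needed by forward predictive contrast is constructed by
marginalising over a hypothetical present:
`p(z|x) = Σ_y' p(y'|x) · p(z|x,y')`, contexts truncated to the order
bound. This construction makes the discrete upper bound
(per-event contrast ≤ information content) hold exactly, and the tests
assert it on random corpora. It is a documented modelling choice — a
one-step-ahead count model has no canonical joint over longer futures —
so correlations computed here are not expected to replicate any
particular external implementation number-for-number, and corpus-scale
correlation tables are out of scope for the test suite. Correlations
pool events across the corpus by default (`--per-sequence` averages
per-sequence coefficients instead).

The convergence check ties the modules together: on corpora simulated
from a known first-order chain, the order-1 PPM predictive-contrast
profile approaches the chain's exact closed-form profile, with the mean
absolute gap shrinking monotonically across training sizes 10³, 10⁴ and
10⁵ symbols (sizes chosen to make the trend unambiguous at desk scale).

## Synthetic data

All fixtures are generated by the seeded simulators: DTMC paths sampled
from π then P by inverse-CDF lookup, CTMC jump chains with exponential
dwells, GP draws from the induced Toeplitz covariance. These emulate the
stationarity assumptions of the models exactly — which is the point of
the oracle tests — and therefore say nothing about non-stationary
structure, tempo drift, or the heavy-tailed pitch distributions of real
melodies. Recovery tolerances (L∞ ≤ .01 on P̂ at 10⁵ steps, ≤5% per rate
at ~10⁴ jumps, γ̂ within .08 at 10⁴ points) are the usual Monte-Carlo
rates at those sample sizes. MIDI input is read by a minimal built-in
monophonic SMF parser (note on/off only, polyphony rejected); note
number m maps to `440·2^((m−69)/12)` Hz in real-valued mode.

## Known limitations

- Higher-order Markov closed forms are not provided; use the PPM module
  or augment the alphabet.
- No density estimation or quadrature for the continuous definition
  beyond the seeded Monte-Carlo estimator.
- The continuous autocovariance is a global polynomial, fine at melody
  scale but a poor extrapolant; evaluation outside the fitted lag domain
  is an error by design.
- Multiple-viewpoint combination (entropy-weighted mixing of feature
  models) and derived viewpoints are out of scope; `link_viewpoints`
  covers the Cartesian-product case only.
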