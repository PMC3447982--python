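# Methods

## Model overview and assumptions

`spinedyn` models the set of synaptic contacts between one pre- and one
postsynaptic neuron.  The M close appositions of the pair are treated as
independent sites, each in one of three coarse-grained states: unrealized
(no contact), inactive (thin spine, contributes no EPSP) or active (large
spine, unitary EPSP u).  Contacts of *different* neuron pairs do not
interact; competition across pairs and axonal remodelling are out of scope.

The coupling between the contacts of one pair is purely indirect.  Each
active contact raises the probability p that a postsynaptic spike is
causally paired (presynaptic spike just before it):

    p(N_a) = clip(p0 + N_a * lambda_resp * u_epsp, 0, 1).

The linearization can leave [0, 1] for extreme parameters; it is clipped
with a logged warning rather than rejected, because the biological quantity
saturates and the fitted models never place mass at such active counts.

Each spine's correlation trace is an exponential-kernel shot noise (jumps
+-c at Poisson pairing events, leak tau) plus white noise sigma.  The
adiabatic assumption — structural plasticity is slow compared with spiking —
lets us use only the trace's stationary law, which by Campbell's theorem is
normal with mean tau*nu*c*(2p-1) and variance (tau/2)(nu*c^2 + sigma^2).
The variance is independent of p; only the mean carries the activity signal.
These closed forms are validated in the test suite against a direct
Euler-Maruyama simulation of the jump diffusion (`simulate_trace`), which
exists for exactly that purpose.

## The saturating escape-rate law

A structural transition triggers when the trace crosses a threshold theta.
Far from threshold, the escape rate of a Brownian approximation of the trace
is the Arrhenius factor exp(-(theta-mu)^2 / (2 Var)).  Near and beyond
threshold the cellular machinery limits the rate, so the law plateaus at
|A|.  The implementation stitches the Gaussian flank to the plateau at
mu = theta:

    r(mu) = |A|                                 on the side sign(A)*(mu-theta) >= 0
    r(mu) = |A| exp(-(theta-mu)^2 / (2 sd^2))   otherwise.

This is the minimal function that (i) reduces to the Arrhenius rate far from
threshold, (ii) saturates at a plateau, and (iii) flips between right- and
left-saturating with the sign of A.  It is continuous and once
differentiable at the junction.  A logistic-flank variant would satisfy the
same constraints; the rate law is deliberately confined to
`plateau_arrhenius_rate` so it can be swapped in one place.  The sd in the
exponent is the full equilibrium sd of the trace (shot noise plus the
class-specific white noise), since the escape argument applies to the whole
process.

Maturation uses thin-spine noise; shrinkage uses large-spine noise; pruning
shares the shrinkage amplitude and threshold but thin-spine noise (pruning
happens to thin spines).  The sharing is enforced by construction: the
pruning law is a derived property, not a stored field.  All three rates are
evaluated at the *pre-transition* active count, and inactive contacts
contribute nothing to p.  An amplitude of exactly 0 denotes an inactive law
(intrinsic-only models).  The intrinsic rate delta adds to all three
transitions; creation occurs at gamma per unrealized site with gamma = 1
fixing the time unit.

## Master equation and steady state

States (N_a, N_i) with N_a + N_i <= M are enumerated lexicographically;
the generator assigns, from state (a, i) with u = M - a - i:

    creation   (a,i) -> (a,i+1)   gamma * u
    maturation (a,i) -> (a+1,i-1) i * r_mat(a)
    shrinkage  (a,i) -> (a-1,i+1) a * r_shr(a)
    pruning    (a,i) -> (a,i-1)   i * r_prn(a)

Per-contact rates are multiplied by the number of eligible contacts — the
combinatorial convention consistent with M independent sites, confirmed by
the closed-form oracle below.  Columns sum to zero by construction.

The stationary law solves Q P = 0 with sum(P) = 1, via a dense linear solve
with the normalization replacing one row, falling back to an SVD null space;
residual tolerance 1e-10, with tiny negative entries (roundoff) clipped and
renormalized.  Dense solves are used throughout: the default cap M <= 25
gives at most 351 states, far below where sparsity pays.  For gamma = 0 the
chain is reducible and the empty synapse absorbing; the point-mass solution
is returned with a warning.  Ill-conditioning warnings from extreme rate
ratios during optimization are suppressed inside the solver — the residual
check is the arbiter of solution quality.

Two independent oracles guard the solver: (1) with lambda_resp*u = 0 the
contacts decouple and the joint is the multinomial over the per-contact
three-state stationary probabilities, matched to 1e-10; (2) long Gillespie
runs must reproduce the stationary occupancy within sampling error.

Per-M solutions are averaged over the close-apposition pmf a(M); marginals
of total, active and inactive counts, first moments and the Na-Ni Pearson
correlation are computed from the averaged joint.

## Lifetimes, turnover, timescale

Contact lifetime is the expected time until pruning.  In a mean-field
freezing of the other contacts (the focal contact's own transitions move n
by one), summing the geometric number of inactive-active excursions gives

    L_inactive(n) = (1 + m(n)/s(n+1)) / q(n)
    L_active(n)   = 1/s(n) + L_inactive(n-1)

with m, s, q the maturation/shrinkage/pruning rates.  A zero pruning rate is
reported as +inf rather than an exception.  Equilibrium averages weight the
per-n lifetimes by the expected number of eligible contacts, i*P(a,i) for
inactive and a*P(a,i) for active ("occupancy" weighting — the lifetime of a
randomly chosen contact); state-probability weighting is available behind a
flag.  The closed form is validated against Monte-Carlo first-passage
sampling.

The spine turnover ratio over an observation window T is
(gained + lost) / (2 * observed), with expected gains = creation flux,
losses = pruning flux (equal at stationarity) and observed = <N_a + N_i>.
Turnover bookkeeping uses expected event rates, not spine-identity tracking;
the Gillespie cross-check counts creation and pruning events.  Matching a
measured turnover target over a real window of D days fixes the timescale
omega (days per model time unit) = (model turnover per unit time) * D /
target.

## Fitting

The observable fitted by default is the total contact number (active +
inactive), since light-microscopy counts cannot separate the two; fitting
the active marginal instead is a switch.  The reference pmf combines a
histogram over connected pairs with the connection probability:
P(0) = 1 - P_conn, P(k>=1) = P_conn * f_k / sum(f) — the only normalization
consistent with both inputs.  Residuals are scaled by the maximum of the
reference pmf (comparability across datasets) and include k = 0; E is their
sum of squares.

Eight parameters are fitted: tau, sigma_thin, sigma_large, A_mat, theta_mat,
A_shr, theta_shr, delta.  Positive parameters are log-transformed (clamped
at exp(+-30) so the unconstrained optimizer cannot overflow); amplitudes and
thresholds are fitted signed.  nu, c, lambda_resp, p0 and gamma = 1 are
fixed configuration constants — p0 is not identifiable anyway (see the
threshold-shift identity), and the remaining constants set units.  The
optimizer is Levenberg-Marquardt (`scipy.optimize.least_squares`,
method="lm") from multiple starts drawn deterministically (given a seed)
from a factorial design of four candidate values per dimension; threshold
candidates scale with the trace-mean shift per active contact at the start's
tau, so starts stay commensurate across the tau decades.  Failures of
individual starts are recorded, not fatal.  The error landscape has many
near-equivalent local minima, so recovery is asserted on the fitted
*distribution* (error and total variation), not on parameter identity.

## Diagnostics

- Hebbian index: central finite difference of <N_a> in p0 (step 1e-3,
  shrunk at the [0,1] boundary).  Positive = Hebbian, negative =
  anti-Hebbian, zero (intrinsic-only models) = neutral.
- Threshold shift: replacing p0 by p0' while translating every threshold by
  2*tau*nu*c*(p0' - p0) preserves all distances to threshold, hence every
  rate and the stationary law exactly.  This makes the baseline correlation
  a free parameter.
- Homeostasis derivative: d<N_a>/dnu (relative step 1e-3) after
  re-expressing the model at an effective baseline via the threshold shift;
  nu enters both the trace mean and variance.  Negative values mean a firing
  rate increase prunes synapses — firing-rate homeostasis.
- Two-state infeasibility: for a model without the inactive state, detailed
  balance forces ratio(n) = P(n+1)(n+1) / (P(n)(M-n)) = g(n)/q(n+1).
  Inverting an observed pmf with suppressed P(1) and a secondary peak yields
  a ratio sequence that plunges and rises again — only highly non-monotone
  rate functions could produce it, which motivates the three-state model.

## Synthetic data

The generators supply every input the pipeline needs.  The close-apposition
pmf is a discretized gamma truncated to 0..m_max; because truncation biases
both moments, the scale is root-solved for the mean and an outer
one-parameter search widens the parent until the realized sd matches
(tolerance 5% on both).  Only mean and sd of real apposition counts are
published, so any smooth unimodal discrete family with matched moments is an
adequate stand-in; gamma discretization was chosen for its smooth tails.

Datasets are forward-sampled: per pair, M ~ a(M), then (N_a, N_i) from the
stationary joint at M; connected pairs (k >= 1) form the histogram and their
fraction the connection probability.  The default study conditions are
mean 5, sd 2, m_max 10 appositions and 10,000 pairs — the scale of the
anatomical reconstructions and an optimistic but attainable paired-recording
sample.

The reference fixture model (`default_fixture_params`: tau = 1000, sigma = 1,
A_mat = -5, theta_mat = 150, A_shr = -50, theta_shr = -30, delta = 0.05,
gamma = 1, with nu = 5, c = 1, lambda_resp = 0.01, u = 1 mV) was chosen once
so that all three activity-dependent rates decrease with the active count —
the regime the fitted models occupy — and the stationary total-contact pmf
is bimodal with P(1) roughly thirty-fold below the secondary peak, the
qualitative shape of the experimental histograms.  `make_bimodal_target`
provides the same shape as a pure template for the infeasibility analysis.

What the synthetic data do *not* emulate: optical detection limits on thin
spines, EPSP amplitude dispersion across contacts, non-Poisson postsynaptic
spiking, and the true shapes of reconstructed apposition distributions.
Passing the recovery tests therefore shows the estimation machinery is
correct and well-conditioned at realistic sample sizes, not that the model
is identified on any particular experimental dataset.

## Numerical choices and problem sizes

- Stationary residual tolerance 1e-10; generator column sums < 1e-12;
  distribution normalization 1e-10.
- Trace simulations use exact per-step decay exp(-dt/tau) with Poisson event
  counts and binomial causal labels per step; batch-means (30 batches) give
  autocorrelation-aware standard errors, and simulation-vs-closed-form
  comparisons use 3 SE bands.
- Gillespie cross-checks run 1e5 time units on synapses with M <= 3;
  recovery experiments use 10,000 pairs and 24 generic starts (the full 4^8
  factorial is subsampled).  These sizes keep every stochastic check's
  sampling error well inside its tolerance while the whole suite runs in
  about a minute.
- Tie-breaks and degenerate inputs: gamma = 0 returns the absorbing point
  mass with a warning; zero pruning yields infinite lifetimes; zero interior
  bins in the two-state inversion yield inf/0 ratios rather than errors;
  degenerate all-unconnected synthetic samples raise a descriptive error.

## Known limitations

- The plateau-Arrhenius law is one member of a family of saturating flanks;
  conclusions that depend on the exact flank shape (not just monotonicity
  and plateau) should be re-checked against a variant law.
- The lifetime recursion freezes the background contact configuration
  (mean-field); it is exact for activity-independent rates and an
  approximation otherwise, accurate when rates vary slowly over one
  excursion.
- The generator's creation term scales with the number of unrealized sites;
  a constant-per-synapse alternative would change the saturation behaviour
  near full occupancy and lives entirely inside `build_generator`.
- Multi-start local least squares finds good minima reliably at the fixture
  scale but is not a global optimizer; parameter values at near-equal error
  can differ wildly (only the distribution is identified).
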