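# Methods

## The model

`mhnet` implements Mutual Hazard Networks (MHNs): continuous-time Markov
chains on the Boolean lattice {0,1}^n that describe how a tumor accumulates
n binary, irreversible progression events (e.g. driver-gene SNVs) before it
is detected. The process starts in the healthy state 0, and from state x two
kinds of transitions compete:

* event i (with x_i = 0) fires at rate
  `lambda_i(x) = exp(theta_ii + sum_{j != i, x_j = 1} theta_ij)`;
* the tumor is observed (absorbing) at rate
  `omega(x) = exp(sum_{j: x_j = 1} theta_obs_j)`.

All parameters live in one (n+1) x n matrix on natural-log scale: diagonal
entries are log base rates, off-diagonal entries log multiplicative effects
of one event on another's rate ("mutual hazards"), and the last row the log
effects of each event on the observation rate. Genotype-dependent
observation matters because cross-sectional cohorts are conditioned on
diagnosis: events that accelerate detection are over-represented, and
ignoring that induces spurious (collider) associations among them.

The observation event's own base rate is fixed to 1 (log 0) rather than
fitted: the process is identified only up to a global rescaling of time, so
the observation base rate defines the time unit. The `classic` kind keeps
the observation rate constant at 1 and ignores the last row; it reproduces
the earlier MHN variant without an explicit observation event and is exactly
the observation-aware model with the last row frozen at zero (an equality
the test suite asserts bit-for-bit).

## Exact likelihood by state space restriction

The probability of observing genotype x is the probability that the chain is
absorbed while in state x:

    p(x) = omega(x) * q(x),
    q(0) = 1 / R(0),
    q(y) = [ sum_{i: y_i = 1} lambda_i(y - e_i) q(y - e_i) ] / R(y),

where R(y) = omega(y) + sum over inactive i of lambda_i(y) is the total exit
rate. Because events are irreversible, ordering states by their integer
encoding makes the system matrix triangular, so q is obtained by a single
forward substitution — exact, O(k 2^k), no iterative solver or convergence
tolerance.

Crucially, q(y) for y below x depends only on states below y, so the
recurrence can be run on the 2^k sub-lattice of states contained in x
(k = number of active events) and still produce the *exact* p(x), provided
R(y) keeps counting the rates of all n events. Dropping the out-of-lattice
event rates from R is the characteristic implementation bug of restricted
solvers; it is caught here by testing every genotype against a dense linear
solve of the full 2^n system. The hard limit is k <= 32 active events per
sample (states are machine integers); a warning is emitted above 25, where
the 2^k cost dominates. The number of events n is limited only by memory for
the (2^k x n) rate tables — cohorts with many events are cheap as long as
individual samples are not extremely mutated.

The gradient of log p(x) is computed per sample from the same lattice with
one extra adjoint (transposed, back-substitution) solve, accumulating three
contribution groups: within-lattice transition rates, the exit rates on the
diagonal (including rates of events outside the active set, which depend on
the theta rows of inactive events), and the absorption factor omega(x).
Identical genotypes are aggregated by count before likelihood and gradient
evaluation; this changes nothing numerically (summation order is fixed by
genotype code) and reduces the number of solves to the number of distinct
genotypes.

Probabilities are kept in linear space; a value below 1e-300 raises rather
than silently underflowing. This is a documented limitation: with k <= 32
and moderate parameter magnitudes, linear space does not underflow in
practice.

## Training

The fitted objective is the per-sample mean log-likelihood minus a scaled
penalty, `J = (1/N) log L - strength * penalty`, maximized by L-BFGS-B with
analytic gradients from the independence-logit start
(`theta_ii = logit(f_i)`, clipped to [1/(2N), 1 - 1/(2N)]; all other entries
zero). The 1/N scaling makes penalty strengths comparable across cohort
sizes. Defaults: 500 iterations maximum, projected-gradient tolerance 1e-6.
Fitting is deterministic given data and options.

Penalties apply to all off-diagonal entries and, by default, to the
observation row (`penalize_observation=False` disables the latter);
diagonals are never penalized because base rates set the time scale of the
dynamics. Available penalties: l1 (sparsity), l2 (ridge), symmetric — a
pairwise group penalty `sqrt(theta_ij^2 + theta_ji^2 + eps^2) - eps` that
makes the two directions of an interaction vanish or survive together, plus
smoothed l1 on the observation row — and arbitrary user callables. The l1
and symmetric absolute values are smoothed with eps = 1e-4 so a smooth
quasi-Newton method applies; the exact functional form of the symmetric
penalty is this package's choice.

Cross-validation selects the penalty strength from a grid (default: nine
log-spaced values in [1e-4, 1]) by seeded shuffling into `folds` contiguous
blocks (default 5), scoring each strength by held-out mean per-sample
log-likelihood, breaking ties toward the smaller strength, and refitting on
the full cohort.

## Simulation

`sample_history` runs the standard competing-exponentials (Gillespie) walk:
wait Exp(R(x)), pick observation with probability omega(x)/R(x) or an
inactive event with probability lambda_i(x)/R(x), stop at observation. The
categorical choice uses a single uniform against cumulative rate fractions
in fixed event order (observation last) so draws are bit-reproducible.
`sample_dataset` derives each history's generator from (seed, draw index),
so any prefix of a cohort is reproducible independently of N.

The simulator and the likelihood engine are independent derivations of the
same law — the Gillespie walk never touches the triangular solver — so their
agreement on empirical genotype frequencies (4-sigma per-genotype bands and
a chi-square goodness-of-fit test at n=4, N=100 000) is the strongest
internal cross-check in the package.

## Most likely histories and trajectory trees

The probability that the chain takes one exact accumulation order
sigma_1..sigma_m and is then observed is the product of per-step competing
risks, `prod_s lambda_{sigma_s}(x_{s-1}) / R(x_{s-1}) * omega(x_m) / R(x_m)`;
summed over all m! orders it reproduces p(x) exactly (asserted to 1e-10).
The most likely order maximizes this by dynamic programming over the 2^k
subsets; conditioning on the observed genotype divides all paths by the same
p(x) and leaves the maximizer unchanged. Exact float ties break toward the
smallest event index at the earliest differing step, so results are
reproducible; each subset stores its best path, which makes memory (not
time) the binding constraint and motivates the k <= 25 limit.

At cohort level, genotypes shared by at least `min_count` patients (default
3, applied to genotype groups, not tree nodes) contribute their most likely
order as a root-to-node path weighted by the group count; shared prefixes
merge into a rooted trajectory tree whose terminal flags mark where observed
genotypes end. DOT export scales node size and edge width linearly with
patient counts — a display choice, as no canonical scaling exists.

## Synthetic data and what the tests show

All fixtures are generated by the package's own simulator. The planted
recovery study uses a sparse 5-event truth — base rates e^-1 (about 1.3
events per tumor, event frequencies near 25%, in the range typical of driver
events in targeted sequencing panels), three pairwise effects of magnitude
|log-effect| = 1 (one suppressive), and one observation effect — with
N = 20 000 tumors and l1 strength 1e-3, small enough to leave effects of
magnitude 1 essentially unbiased while taming rare-genotype overfitting.
Passing shows the estimator recovers the generative law (total variation
< 0.02) and the planted signs under a correctly specified model; it does not
show robustness to model misspecification, unobserved events, sequencing
error, or intra-tumor heterogeneity, none of which the generator emulates.

Problem sizes throughout (n <= 10 for enumeration oracles, k <= 6 for
factorial brute force, N <= 100 000 draws) were chosen so every check runs
on a single CPU in minutes while the statistical tests retain power.

## Numerical choices and limitations

* Triangular substitutions, not generic solvers: exact and tolerance-free.
* Gradient checks: central differences at step 1e-5 agree to ~1e-7 relative.
* The optimizer trace is monotone up to line-search tolerance 1e-10.
* Objective failure (non-finite likelihood) raises with iterate diagnostics
  instead of returning garbage.
* No GPU kernels; pure NumPy. Per-sample cost 2^k keeps cohorts with heavily
  mutated samples (k near the 32 limit) out of practical reach on CPU.
* Identifiability: the genotype distribution has 2^n - 1 degrees of freedom
  against n(n+1) parameters, so for n <= 3 the parameter matrix is not
  identifiable from cross-sectional data at all, and in general the
  *direction* of a pairwise effect is weakly identified even when its
  presence is clear (regularization then decides the orientation; the
  symmetric penalty is the principled default when effects are expected to
  be reciprocal).
* No conditional sampling given a final genotype, no posterior distributions
  over orderings, no longitudinal (time-stamped) input.
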