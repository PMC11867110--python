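# Methods

## The editing model

A barcode design is a DNA sequence with M ordered target intervals
`[s_k, e_k)` and cut bonds `s_k <= c(k) < e_k` (all 0-based; cut bonds may
also be given as offsets from each target's 3' end, the usual GESTALT
metadata convention). The editing process is a continuous-time Markov
chain over alleles. Events are lumped into **target tracts**
`(j0, j, j', j1)`:

* a single cut at target `j` (`j = j'`) or a double cut at `j < j'`;
* a left trim that is *short* (`j0 = j`) or *long* (`j0 = j - 1`,
  deactivating the left neighbour), and symmetrically on the right.

Hazards: `lambda_j` for a single cut, `omega (lambda_j + lambda_j')` for
a double cut, each multiplied by the trim-class odds `gamma0/(1+gamma0)`
or `1/(1+gamma0)` on the left (gamma1 on the right). The class factors
are intrinsic to the tract; whether a tract is *available* in a given
target status is a separate question: its cut targets, and for long
trims the adjacent trim target, must be active and the trim window
non-empty. Inner targets of a double cut need **not** be active — cutting
across an already-edited inner target is exactly how masking arises.
A consequence worth noting: next to an edited neighbour the long-trim
variants disappear and the total hazard at that target drops below
`lambda_j`; the model treats a disrupted neighbourhood as reducing the
repair outcomes available, not as renormalizing onto the remaining ones.

**Trim windows.** Short trims stay inside the cut target
(`0 .. c(j)-s_j` on the left). Long trims must reach into the adjacent
target's interval and stop at least one bond short of its cut site
(`c(j)-e_{j-1}+1 .. c(j)-c(j-1)-1`). For designs with inter-target
spacers, trim lengths that would terminate inside a spacer have
probability zero; real GESTALT arrays (e.g. V7: ten contiguous 23-bp
units) have no spacers, so nothing is lost. This convention makes the
trim class, the tract implied by an indel, and the target status all
mutually consistent, and it guarantees that a new deletion either
strictly contains or is disjoint from every earlier indel's footprint —
the geometric fact that makes the lumped likelihood exact.

**Details.** Given a tract, the left trim, right trim and insert length
are independent: truncated Poisson on the short window (absolute
length), window-minimum plus truncated-Poisson offset on the long window
(so the long-trim mean is "extra bases beyond the minimum"), and
truncated Poisson on `0..max_insert_len` for the insert, with uniform
nucleotide content contributing `(1/4)^len`. For a plain single cut
(short/short) the all-zero detail would be an unobservable
self-transition; it is excluded and the law renormalized. Detail laws
sum to one per tract (tested at 1e-9).

Defaults: clock 0.02 indels/site/time-unit, cut rates 1 (mean-1
constrained during inference so the clock carries the time scale),
omega 0.3, gamma 0.1, trim means 3 bp, insert mean 1 bp, insert cap
10 bp. The calibration regime centres omega and gamma at 0.05,
consistent with the magnitudes previously estimated for the V7 barcode.

## Likelihood

Branch transition probabilities are entries of `expm(G r t)` where `G`
is the sub-stochastic generator of a per-branch state space `(A, H)`:
`A` the set of the child's new indels already introduced, `H` the
pending *hidden* spans — target spans deactivated by events that are
never observed because a later deletion masks them. Hidden events are
admitted only if their span fits strictly inside a pending observed
deletion's inner targets (rate thinned by the detail-fit probability
`p_fit`, which is identically 1 under the trim windows above) or if the
span survives to the child as part of its node state. All other events
leak to an absorbing sink. The branch probability is multiplied by the
detail probabilities of the introduced indels; details factor out of the
chain because future dynamics depend on events only through their
deactivated spans.

Node states extend the parsimony-guided candidate alleles (indels
observed in some leaf below and compatible with every leaf below —
present identically, or strictly inside one of that leaf's deletions)
with **hidden span sets**: disjoint target spans that every leaf below
can mask. Without these, histories in which an unobserved indel crosses
an internal node before being masked in both child subtrees would be
dropped; with them, pruning agrees with brute-force enumeration to
machine precision. The root state is the unedited barcode; an origin
(stem) branch above the root is optional and contributes its survival
factor.

Candidate enumeration is capped (`max_states`, default 256 per node)
with an explicit error instructing to raise the cap — never silent
truncation. Partial likelihoods are cached per node under a structural
signature (child signatures, branch rate-lengths, parameter version), so
local tree moves only recompute the changed path to the root.

**Oracle.** `gestaltree.oracle` enumerates the complete allele space of
a tiny design (every tract x admissible detail x insert sequence),
builds the exact allele-level generator with masking applied by removing
strictly-contained indels, and evaluates the alignment likelihood by
matrix-exponential action on full-space partial vectors. It shares the
model definition but none of the pruning machinery, and anchors the
test suite at 1e-6 (observed agreement ~1e-14).

**Fast path.** `FixedTreeLikelihood` compiles the pruning structure of a
fixed tree+alignment into flat arrays and evaluates the likelihood in a
numba kernel (uniformization of each branch chain, log-sum-exp pruning),
~20 microseconds per evaluation for a 10-tip, 4-target dataset. It is
bit-checked against the pure-Python reference in the tests. Detail-law
parameters are frozen at construction; rates (clock, cut rates, omega,
gammas) and node times may vary per evaluation.

## Simulation

Trees: forward Gillespie birth-death from one founder over a fixed
duration, rho-sampling of survivors, pruning to sampled tips, rejection
until the tip count lands in the configured range (error with
diagnostics after 1000 rejections). A stop-at-n pure-birth variant
provides exactly-n-tip trees directly; all constant-rate birth-death
processes share the same conditioned topology law, which is what the
tree-shape checks use. Alignments: competing-exponential simulation of
tract events along each branch, details drawn from the configured laws,
masked indels physically removed. Simulator and likelihood are two views
of one process; their agreement is tested via single-branch total
variation distance (< 0.03 at 10,000 replicates) and first-event class
frequencies.

The generator's default validation regime — 4-target V7-style design,
~10-tip trees rescaled to a 25-unit experiment, clock centred at 0.02
indels/site/unit — yields roughly half of the target sites edited:
deliberately information-poor, so calibration results are a lower bound
on inferential performance. What the simulator does *not* emulate:
sequencing or consensus errors, allele dropout, rate tapering over
developmental time, or cell-type-dependent editing; passing tests say
nothing about robustness to those.

## Tree priors

Birth-death-sampling with present-day rho-sampling uses the standard
constant-rate `p0/p1` functions; conditioning is on the origin age and
survival by default, on the root (both sides surviving) as an option,
and on origin plus tip count for normalization checks, where the n-1
node ages are i.i.d. with density `b p1(x) / int b p1` (closed-form
normalizer, quadrature-checked). The critical case beta = delta uses its
own closed forms. The exponential-growth coalescent uses the
deterministic trajectory `N(s) = N_sampling e^{-g s}` backward in time
and reduces exactly to Kingman at g = 0; densities are for the labeled
tree (rate 1/N per eligible pair). Derived quantities:
`E[N(t)] = e^{(beta-delta) t}` and the reported sampling proportion
`s / e^{g t}` with N = 1 at the founder.

## MCMC

Metropolis-Hastings with: multiplicative scale moves on positive scalars
(Hastings ratio e^u), a mass-transfer move on the cut-rate simplex
(lambda = M w keeps the mean-1 constraint), uniform node-time slides, a
whole-tree age scaler (Jacobian s^{#internal}), narrow exchange
(symmetric by construction: fixed-size selection sets, rejection for
time-infeasible swaps) and Wilson-Balding (Hastings ratio
window_new/window_reverse with uniform destination choice over a set
whose size is topology-independent given the pruned node). Pooled
inference shares editing and growth parameters across replicates, each
with its own tree, multiplying the replicate likelihoods. A deliberate
mis-specification hook (`likelihood_rate_factor`) scales the inference
model's editing rates for negative-control studies.

Move correctness is tested empirically: scale-move stationarity on a
known 1-d target, prior-recovery (KS) for scalar and simplex parameters,
and 4-taxon topology frequencies against the exact Yule law
(chi-square). ESS uses `n / (1 + 2 sum rho_k)` truncated at the first
non-positive autocorrelation (constant series: ESS = n). HPD intervals
are the narrowest contiguous window containing `ceil(level * n)` sorted
samples. MCC summaries pick the sampled tree maximizing the product of
clade frequencies, with per-clade median heights (clamped to respect
parent-child order) or the tree's own heights.

## Calibration study

Per replicate: draw editing parameters from their priors (clock
LogNormal(log 0.02, 0.4); omega, gamma0, gamma1 LogNormal(log 0.05,
0.4); cut rates M x Dirichlet(10)), simulate a 10-tip tree and
alignment, infer with matched priors and the tree fixed to truth, and
record whether each alpha-level HPD contains the truth, for alpha =
0.05..0.95 in steps of 0.1. Coverage is compared with the central 95%
band of Binomial(n, alpha). The default scale is 30 replicates x 2e5
iterations (thinning 20, 30% burn-in) so the study runs in minutes on
one CPU; replicates with any ESS <= 200 are flagged, never dropped.
Note the multiplicity inherent in the check: 8 parameters x 10 levels =
80 correlated band tests, so an occasional point at a band edge is
expected even under perfect calibration, and the finite posterior sample
makes the min-width HPD estimator slightly narrow at mid levels. The
negative control re-runs the study with the inference model's rates
doubled; coverage then collapses far outside the bands.

## Numerical choices and limitations

* Matrix exponentials: dense scaling-and-squaring (scipy) in the
  reference path; uniformization with Poisson-tail truncation at 1e-14
  in the compiled path. Branch generators are upper triangular
  (irreversibility), so all eigenvalues are the non-positive diagonal.
* Impossible transitions return -inf rather than raising, so MCMC
  rejects gracefully; a non-finite *initial* posterior names the
  offending component.
* Likelihood values depend on branches only through r * t (tested to
  relative 1e-12); per-branch rate multipliers are accepted as fixed
  inputs (relaxed clocks are not estimated).
* Only bifurcating trees are supported; multifurcation resolution and
  parsimony-restricted tree search are out of scope.
* The likelihood cost grows quickly with per-branch indel counts and
  with deep inter-target deletions (hidden-state spaces); datasets with
  thousands of cells are outside the intended scale.
* The exact trim/insert length laws of the original editing model are
  not published in full; the truncated-Poisson family here is a
  documented stand-in, and oracle, simulator and likelihood all consume
  the same configured laws, so correctness statements are law-independent.
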