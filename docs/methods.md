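# Methods

## Model

`gtrlink` implements maximum-likelihood estimation of a single ("linked")
amino-acid exchangeability matrix shared across all classes of a profile
mixture model, together with the likelihood machinery, a simulator, and
model-comparison utilities.

For a profile `pi = (pi_1, ..., pi_20)` the time-reversible rate matrix is

    q_ij = s_ij * pi_j  (i != j),   q_ii = -sum_{j != i} q_ij,

rescaled so the mean rate `-sum_i pi_i q_ii` is 1, making branch lengths
expected substitutions per site.  `S = {s_ij}` is symmetric and
non-negative; since `S` and `cS` give the same normalized `Q`, the
tyrosine/valine entry (position (19, 20) in the standard PAML residue order
A R N D C Q E G H I L K M F P S T W Y V) is pinned at 1 during estimation,
leaving 189 free exchangeabilities.

A site pattern `x_p` on a fixed tree `T` has mixture likelihood

    L(x_p) = sum_{c=1..C} w_c sum_{k=1..K} d_k P(x_p | T, S, pi_c, r_k),

with fixed class profiles `pi_c`, weights `w_c` on the simplex, and
discretized-gamma rates: `K` equal-probability categories whose rates are
the conditional means of the mean-1 gamma with shape `alpha` between
consecutive `1/K` quantiles, renormalized to discrete mean exactly 1
(within-category medians are available as an option).  The alignment
log-likelihood is the sum over sites; identical columns are collapsed into
patterns with multiplicities, which leaves the likelihood unchanged.

Each class rate matrix is normalized to unit mean rate independently, so
"one unit of branch length" means one expected substitution within every
class.

## Likelihood engine

Pruning runs on a postorder array representation of the tree.  Per class,
the symmetrized matrix `diag(sqrt pi) Q diag(1/sqrt pi)` is
eigendecomposed once; transition matrices for all branches and rate
categories are formed from the eigensystem in one batched operation.
Conditional-likelihood arrays are scaled per node and per pattern, with
log-scalers accumulated, so underflow cannot occur on deep trees.  Gaps
and all ambiguity codes are treated as fully missing data (conditional
vector of ones).  Trees are effectively unrooted under reversibility; the
stored root is used for simulation and display only.

Gradients of the log-likelihood with respect to branch lengths and all 190
exchangeabilities are analytic.  A root-to-tip pass produces, for every
branch, the sensitivity of the log-likelihood to that branch's transition
matrix; the divided-difference (Daleckii–Krein) form of the matrix-
exponential derivative in the eigenbasis converts these into a gradient
with respect to each class's rate matrix, and the chain rule through
`q_ij = s_ij pi_j / z(S, pi)` (where `z` is the normalizer) yields the
exchangeability gradient.  The implementation is validated against central
finite differences in the test suite.

## Estimation

Parameters are split into four blocks, cycled in the order branch lengths
→ gamma shape → mixture weights → exchangeabilities until the outer
improvement falls below `outer_tol` (default 0.01 log-units, at most
`max_outer_rounds` cycles):

* **Branch lengths** — L-BFGS-B on log-lengths with analytic gradients,
  clamped to `1e-8` or more.  Joint quasi-Newton optimization replaced a
  per-branch line-search design because the gradient pass prices all
  branches at once, making the joint update strictly cheaper with the same
  monotonicity contract.
* **Gamma shape** — bounded scalar search on `alpha in [0.02, 100]`;
  boundary solutions are flagged.  `alpha` is not identifiable at `K = 1`
  and requesting it raises an error.
* **Weights** — EM responsibility updates, monotone by construction; the
  per-class site likelihoods do not depend on the weights, so the EM loop
  costs a single likelihood evaluation.  Weights collapsing below `1e-8`
  are floored and flagged; duplicate profiles are flagged as
  non-identifiable.
* **Exchangeabilities** — L-BFGS-B on `log s_ij` (positivity by
  parameterization) with the Y/V entry fixed at 1, initialized at the
  all-ones (POISSON) matrix by default.  The default projected-gradient
  tolerance is 1e-2 with L-BFGS memory 40; pilot runs showed this matches
  tighter settings to within 0.05 log-likelihood units and 2e-4 SAD at
  roughly half the cost.

Every accepted block update is monotone in the log-likelihood (the
recorded trace is asserted non-decreasing in the tests).  Fixed-block
protocols — e.g. freezing branch lengths and `alpha` while estimating
exchangeabilities and weights — use the same scheduler with blocks
disabled.

## Comparing exchangeability matrices (SAD)

Two matrices are compared through their rate matrices under the uniform
profile (`pi_i = 1/20`), which removes the arbitrary scale used during
optimization.  The comparison form normalizes the 380 off-diagonal entries
of the uniform-profile rate matrix to total mass one and keeps the 190
distinct pairs; SAD is the sum of absolute differences of these vectors.
Under this convention the distance between the published LG matrix and the
all-ones matrix is 0.506.  The alternative convention (normalizing the 190
distinct entries to sum one) doubles every value and was rejected because
it places LG and the uniform matrix about one full unit apart, which is
inconsistent with how this separation is usually quoted.  SAD is a
pseudometric: zero between a matrix and any positive rescaling of itself,
symmetric, and triangle-inequality consistent.

## Simulator

Alignments are simulated column-wise: each site independently draws a
class from `{w_c}` and a rate category from `{d_k}`, the root residue from
`pi_c`, and child states through `exp(Q_c r_k t_b)` along each branch.
Latent class and rate assignments are recorded and exportable.  A single
seeded Philox stream with a fixed draw order makes runs bit-reproducible;
replicates use deterministic seed offsets.  Sites are independent — no
indels, no autocorrelated rates, no compositional drift over the tree —
so passing recovery tests demonstrates correctness of the estimator under
the model, not robustness to model violation in real data.

## Study designs

The simulation studies need a tree and a profile set; both are bundled and
fixed so that experiments are reproducible.

* **Recovery study** — a fixed 10-taxon tree with total length 3.22,
  reflecting the divergence of the deep phylogenomic alignments for which
  linked-exchangeability estimation is intended; shallow trees carry too
  little substitution signal to pin down 189 parameters at moderate
  alignment lengths.  Four synthetic site-class profiles concentrate 70%
  of their mass on one biochemical category (hydrophobic AVLIMFWC, charged
  DEKRH, polar STNQYC, small AGSTPC) with the remainder spread uniformly:
  distinct, like empirically derived profile classes, but with full
  support so every exchangeability stays identifiable.  Class weights
  0.35/0.15/0.25/0.25, gamma shape 0.67 with four categories, 2,000 sites
  per replicate, truth = LG, starting point = all-ones.  Pilot runs give a
  median SAD to the truth of ~0.13, versus 0.506 for the starting matrix.
* **Long-branch study** — a 4-taxon Felsenstein quartet (two non-sister
  terminal branches of 1.5, all other branches 0.02) versus the
  artifactual topology that joins the long branches.  Data are generated
  under uniform exchangeabilities with the four profiles above (gamma
  shape fixed at 0.5); fits add an empirical-frequency class and estimate
  weights and branch lengths, with exchangeabilities either fixed
  (uniform, LG) or estimated.  The reported comparison is the proportion
  of replicates in which the true topology attains the higher maximized
  log-likelihood, with McNemar tests (exact binomial below 25 discordant
  pairs, continuity-corrected chi-square otherwise) between fitting
  models.  Preference ties below 1e-6 log-units count half for each
  topology.

Problem sizes in the shipped experiments (replicate counts, 2,000-site
alignments, iteration caps) are desk-scale choices: large enough for the
qualitative conclusions, small enough to run on a laptop core in minutes.

## Numerical choices and degenerate inputs

* Validation tolerances on model objects are 1e-10 relative (symmetry,
  stochasticity, stationarity, detailed balance, unit mean rate).
* Transition probabilities clamp tiny negative eigen-round-off to zero and
  renormalize rows; an exactly zero branch yields the exact identity.
* A profile concentrated on states with no exchange routes produces a
  zero mean rate and raises a "degenerate rate matrix" error; sites
  impossible under every class raise an error listing the offending
  sites.
* The empirical ("+F") profile adds a pseudocount of 0.5 per residue
  before normalizing (switchable), so unobserved residues keep a small
  positive frequency and the rate matrix stays irreducible.
* BIC uses the number of alignment sites as the sample size (not pattern
  counts, not sites x taxa).
* Nearly equal eigenvalues in the matrix-exponential derivative use the
  midpoint limit `tau * exp(lambda tau)` to avoid cancellation.

## Known limitations

* Tree topology search is out of scope; all estimation is on a fixed
  topology.
* Profile vectors themselves are never estimated — profile sets are
  user-supplied or bundled fixtures, as in standard C-series usage.
* The optimizer offers no Hessian-based standard errors.
* Likelihood cost grows linearly in `C x K`; very large profile sets
  (hundreds of classes) are usable but slow on a single core.
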