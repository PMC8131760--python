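# Methods

## The model

A binary phenotype (state 1 = trait present, 0 = absent) evolves along a
rooted phylogeny with branch lengths as a two-state continuous-time Markov
chain with generator Q = [[-q01, q01], [q10, -q10]], rates in transitions
per unit branch length. Two parameterizations are fitted: ER (q01 = q10 = q,
one free parameter) and ARD (both free). The transition probabilities have
the closed form P(t) = Π + e^{-(q01+q10)t}(I - Π), where Π stacks the
stationary row π = (q10, q01)/(q01 + q10); for q01 = q10 = 0 the chain is
frozen and P(t) = I. The closed form is used everywhere (likelihood,
simulation, per-pair probabilities); the matrix exponential appears only as
an independent oracle in the tests.

## Likelihood and root conventions

Tip likelihoods are computed with Felsenstein's pruning algorithm over the
post-order node array: leaf partials are state indicators (or (1, 1) for a
marginalized unknown tip), internal partials are products over children of
P(t_child)·L_child, and every internal node is renormalized with the log
scale factor accumulated, so deep trees cannot underflow. Polytomies are
handled natively — the child product simply has more factors — and a root
edge, when present in the input file, is carried through serialization but
never enters the likelihood.

The root is handled by summation against a weight vector:

- `flat` (default for the library functions): weights (1/2, 1/2);
- `unweighted`: weights (1, 1), the convention used by `ape::ace`, which
  shifts lnL by exactly +ln 2 relative to `flat` (verified against ace on a
  fixture to ~1e-11);
- `stationary`: π of the model (default for *simulation*, where it is a
  genuine sampling distribution; under ER it coincides with flat);
- any user-supplied probability 2-vector.

The full pipeline reports lnL under `unweighted` so its numbers are directly
comparable to analyses done with the reference R tooling. Rate estimates,
the LRT statistic and ancestral marginals are invariant to the choice.

## Fitting

Rates are optimized on the natural-log scale (positivity for free) with
L-BFGS-B inside [1e-8, 1e3] per rate, from three starts: 0.1/height,
1.0/height, and the best point of a coarse log-grid spanning 0.01/height to
100/height. The grid pre-scan exists because the profile likelihood can
carry a saturation ridge at large q on which local search otherwise strands
(observed roughly once per several hundred fits before the guard; the
affected fit then sat ~11 log units below the interior optimum found by the
reference implementation). Convergence tolerance is 1e-12 on the objective;
fits within 1e-6 (log scale) of a bound are flagged `at_boundary`.

Standard errors are Wald: square roots of the diagonal of the inverse
observed information, with the Hessian of -lnL taken by central differences
on the natural rate scale with step max(1e-4, 1e-4·|θ̂|). They are reported
as unavailable at boundary optima or when the Hessian is not positive
definite. Note that `ape::ace` reports SEs computed from the Hessian of the
*deviance* (-2 lnL) without the factor-two correction, so its SEs are
smaller than these by √2; comparisons with ace-derived SEs must account for
that.

The "total garbage" baseline ignores the tree entirely: p̂ = n1/(n0+n1),
lnL = n1·ln p̂ + n0·ln(1-p̂) (0·ln 0 ≡ 0). It is compared to the Mk fits
informally, by magnitude, not by a nested LRT — the models are not nested.

ER vs ARD uses the standard likelihood-ratio test: 2(lnL_ARD − lnL_ER)
against chi-square with 1 df. Statistics within −1e-6 of zero are clamped
(optimizer noise); anything more negative raises, because it means the full
model was under-optimized. The pipeline keeps ER unless the LRT rejects at
0.05, mirroring the usual parsimony-first selection rule.

## Ancestral states

Marginal (not joint) reconstruction via the up-down algorithm: the inside
pass reuses the pruning partials; the outside pass propagates, per node, the
root weights times the sibling messages through the connecting branch; the
per-node marginal is the normalized product of inside and outside terms.
Node identifiers are the stable post-order indices assigned at parse time,
reported together with the first/last leaf of the clade for human
cross-reference. Correctness is pinned to an exhaustive-enumeration oracle
on small random trees (agreement to 1e-10).

## Simulation

Tip states are simulated by exact endpoint sampling: draw the root from the
chosen prior (stationary by default), then sweep pre-order drawing each
child from P(branch length) given the parent. For tip-state functionals this
is equivalent in law to simulating the full jump history; an optional
full-history mode additionally samples endpoint-conditioned change counts
per branch by uniformization with rejection. Replicate i of a batch uses the
RNG stream spawned from (seed, i), so batches are bitwise reproducible and a
longer batch extends, rather than reshuffles, a shorter one at the same
seed.

## The displacement test

The statistic D counts sympatric pairs whose members have determined,
unequal states. Pairs with an unknown-state member are reported separately
and make the empirical count a range [d_min, d_max]; tail probabilities are
emitted for every value in the range, none privileged. The null is the
Monte Carlo distribution of D over n_sims simulated tip-state datasets on
the *full* tree (unknown-state taxa still evolve and can sit in pairs);
tails are plain Monte Carlo proportions Σ_{k≥d} count[k]/n_sims without the
(r+1)/(n+1) correction, matching how such simulated nulls are conventionally
reported. The test is one-sided upper-tail (excess divergence =
displacement signal); a lower-tail variant covers the convergence direction.
Parameter uncertainty in the fitted rate is deliberately not propagated —
the null is conditional on the point estimate, as in the analysis this
package reproduces.

Under ER the per-pair divergence probability has the closed form
(1 − e^{−2qT})/2 with T the tip-to-tip path length, because the difference
process along the path joining two tips is itself a two-state symmetric
chain and the root's position on that path is irrelevant by reversibility.
This is the module's oracle: simulated per-pair frequencies must match it
within binomial error, and by linearity the null's mean must match the sum
of per-pair probabilities even though pairs sharing tree paths are
correlated.

## Synthetic data

`yule_tree` draws pure-birth trees by the exponential waiting-time
construction (per-lineage rate λ, default 1.0), with one extra Exp(nλ)
stretch after the last split so terminal sisters have positive length;
trees are ultrametric, labels t1..tn. Tree height is then distributed as
Σ_{k=2}^{n} Exp(kλ), which the tests verify in expectation. Pure birth was
chosen over birth-death as the simplest model with species-tree-like shape;
extinction would add a parameter the downstream analyses never see.

`generate_dataset` assembles the full study-shaped input: Yule tree, one
simulated trait replicate as ground truth, n disjoint sympatric pairs, and
an unknown-state mask. Defaults mirror the study conditions this package
was built around: 80 tips, ER q = 0.26, 9 pairs, 15% of tips masked
(= 12 of 80). Pair mode `distant` samples each pair from the top quintile
of path lengths among still-unused tips — sympatric pairs in the motivating
system are between different species or species complexes, i.e. deep,
non-sister pairs whose divergence probability under the fitted rate is
close to the 1/2 stationary ceiling. Masking picks exactly
round(fraction·n) tips uniformly without replacement; missingness is not
phylogenetically clumped (no mechanism was specified for the real data, so
uniform is the neutral, recorded default). Every generation parameter is
stored in the dataset for exact replay.

What the generator does **not** emulate: the real population tree's
topology and height, geographic structure in sympatry or missingness, and
any dependence of the trait on body size or island area. Tests passing on
synthetic data therefore validate the machinery and the statistical
calibration of the method, not claims about the real system.

## Numerical and statistical behaviour worth knowing

- **LRT finite-sample size.** Under ER truth (q = 0.26) on 100-tip Yule
  trees the ER-vs-ARD LRT at α = 0.05 rejects ~8–10% of the time, not 5%:
  with a single binary character the ARD direction can chase sampling noise
  (e.g. datasets with almost no transitions in one direction push one rate
  toward zero for a real likelihood gain). The statistics are not an
  optimization artifact — the reference ML implementation reproduces them to
  ~1e-10 on the same datasets. The suite asserts the verified behaviour
  (nesting inequality, mean statistic near 1, size within [2%, 13%]) and
  keeps a separate strict nominal-size check that documents the inflation.
- **Discreteness of the displacement p-value.** D takes few values, so
  P(p ≤ α) sits below α rather than at it; the null-sizing tests are
  one-sided (no anti-conservatism) for this reason.
- **Rate information.** At 200 tips the ER MLE's median relative error is
  ≈15% with 95% Wald coverage ≈0.94; single binary characters simply carry
  limited information, and Monte Carlo checks of such sampling-distribution
  claims use explicit 3-SE slack.
- **Degenerate inputs.** One-state datasets fit at the rate floor with the
  boundary flagged and SEs withheld; q = 0 trees are handled exactly
  (identity transition matrix); zero-length branches are legal; the
  stationary distribution is undefined at q01 = q10 = 0 and raises.

## Problem sizes

The test suite simulates at the scales stated in each test (up to 1,000
LRT replicates on 100-tip trees, 150 recovery replicates at 200 tips,
50,000 single-branch endpoint draws) and completes in a few minutes on one
CPU; the acceptance script's full pipeline run (80 tips, 1,000 null
simulations) takes seconds.
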