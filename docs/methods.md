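# Methods

This note records the model as implemented, the defaults and why they are
what they are, the numerical conventions, and what the synthetic designs do
and do not establish.

## Model and priors

For a continuous response the likelihood is
`y_i ~ N(f(x_i), sigma^2)` with `f(x) = mu0 + sum_t g(x; T_t, M_t)` over
`K` trees. The priors factor over trees:

- **Tree structure.** A node at depth `d` (root `d = 0`) is internal with
  probability `alpha (1+d)^-beta`, `alpha in (0,1)`, `beta > 0`. Internal
  nodes carry a rule `x_j <= a` (ties route left); `j` is drawn from the
  categorical prior `S` on the p-simplex; the cut `a` is uniform over the
  candidate cuts that split the node's observations non-trivially (below).
- **Terminal values.** i.i.d. `N(0, sigma_mu^2)` with
  `sigma_mu = 0.5/(k sqrt(K))` (continuous) or `3/(k sqrt(K))` (binary).
  The continuous form presumes the response mapped to `[-0.5, 0.5]`;
  `run_chains` performs that affine standardization internally and
  transforms every exposed quantity (fits, sigma^2 draws, leaf values)
  back to the original scale.
- **Error variance.** `sigma^2 ~ InvGamma(nu/2, nu*lambda/2)`. `lambda` is
  calibrated so that the prior's 0.75 quantile equals `(2/3) Var(y)`;
  because the inverse-gamma quantile is linear in its scale this is solved
  exactly by rescaling the unit-scale quantile, and the realized quantile
  is verified to 1e-6. Both the quantile level and the multiplier are
  arguments of `calibrate_lambda`.
- **Binary responses** use the Albert–Chib probit augmentation with
  `sigma^2 = 1` fixed (no `(nu, lambda)`), latents redrawn every sweep from
  one-sided truncated normals, and `mu0 = probit(mean(y))`.

Presets: *rigid* `(alpha, beta, k) = (0.1, 4, 1)` favors stumps and
interpretability; *flexible* `(0.95, 2, 2)` is the common default.
`K = 50`, `nu = 10`, uniform `S`, `mu0 = mean(y)`.

## Sampler

One MH structure move per tree per sweep (GROW 0.25, PRUNE 0.25, CHANGE
0.40, SWAP 0.10), with the terminal values integrated out of the
acceptance ratio, followed by conjugate leaf redraws, and per sweep a
conjugate `sigma^2` draw (or latent refresh). Trees live in flat heap
arrays inside a numba kernel; per-tree observation routing is cached and
updated incrementally.

Conventions that matter for correctness:

- **Candidate cuts.** The global candidate set per covariate is the
  midpoints of consecutive distinct observed values (frozen at fit start).
  Proposals and the cut prior are uniform on the subset of cuts strictly
  between the node's member minimum and maximum of the chosen covariate —
  the data-driven cut convention of the classic samplers. GROW/PRUNE cut
  factors cancel between prior and proposal; CHANGE and SWAP change the
  member sets below the modified node, so the subtree product of
  `1/n_valid` factors enters their ratios, and a rule that loses its
  support vetoes the move.
- **CHANGE** redraws the rule of a uniformly chosen internal node (any, not
  only bottom nodes), keeping the subtree and rerouting its members; a move
  that empties a leaf is rejected.
- **SWAP** exchanges the rules of a uniformly chosen parent–child internal
  pair (every non-root internal node identifies one pair).
- **Illegal move types** (e.g. PRUNE on a root-only tree) are resampled up
  to 10 times, then counted as a no-op. The MH asymmetry term uses the
  effective selection probability `p_m (1 - F^10)/(1 - F)` (`F` the illegal
  mass in the current state), so resampling does not bias the chain: with
  the likelihood switched off the chain reproduces the generative
  tree-structure prior (chi-squared check in the test suite).
- **Depth cap 12** (GROW beyond it auto-rejected): the prior probability of
  deeper nodes is negligible at both presets; the cap bounds the heap.
- **Minimum node size 1** (config-exposed): proposals creating an empty
  leaf are rejected outright.
- **Seeding.** All randomness descends from one integer through
  numpy `SeedSequence` spawning per (seed, EB iteration, chain); equal seed
  and configuration give bit-identical runs at any chain count.

Convergence reporting uses rank-normalized split R-hat (max of bulk and
folded variants) on `sigma^2` (continuous) or per-observation fits
(binary); values are reported, never enforced.

## Empirical-Bayes updates and the co-data model

Each EB iteration maximizes the Monte-Carlo expected log prior of the kept
draws with respect to the parameter being updated:

- `S`: split-rule relative frequencies `b_j / B` — smoothed through the
  co-data model rather than used raw.
- `k`: `sigma_mu_hat^2` = plain second moment of all sampled terminal
  values (the exact maximizer; no degrees-of-freedom correction), inverted
  through the `sigma_mu(k)` formula and clipped to `[0.1, 10]`.
- `alpha`: bounded 1-D maximization of the depth terms over `[0.01, 0.99]`
  (`beta` fixed; joint `(alpha, beta)` estimation is deliberately not
  offered — two correlated shape parameters are weakly identified).
- `(nu, lambda)`: inverse-gamma ML on the `sigma^2` draws; at fixed `nu`
  the stationary `lambda` is the harmonic mean of the draws, `nu` is then
  profiled on `[2.1, 200]`.

The co-data model treats the `B` splitting rules as Bernoulli trials for
each covariate: `b_j ~ Bin(w_j, B)`, `w_j = expit(c_j' eta)`, fit by
grouped-binomial Newton–Raphson with step-halving (gradient tolerance
1e-8, max 100 iterations; dependencies between covariates are knowingly
ignored). Groupings are reference-coded against the intercept (first
sorted level dropped) — level-weight reconstruction is invariant to the
coding, and reference coding keeps the matrix full rank; missing group
labels become their own level. Continuous co-data enters as supplied
(callers pre-transform, e.g. `-logit` of BH-adjusted p-values).
Separation triggers a ridge refit with penalty 1e-6 — small enough not to
move well-posed estimates beyond ~1e-4 — with a warning. The intercept
calibrates the fit, so the weights sum to one; the identity is asserted at
1e-6 and only repaired (with a warning) if violated.

Counts pool all chains and all kept (post-burn-in) draws of the current
iteration.

## Stopping rule

In-sample WAIC per iteration, computed from that iteration's own draws
pooled across chains: `WAIC = -2 lppd + 2 p_waic` with the variance-form
penalty (sample variance over draws, divisor `n_mc - 1`). The loop runs to
`max_eb_iter = 20` with an early stop after 5 consecutive non-improving
iterations; the global minimum is selected (ties toward the smaller
iteration, i.e. less prior adaptation), and the returned model *reuses the
stored draws* of that iteration rather than refitting — the reported WAIC
therefore always describes the returned model.

A caveat of minimum-WAIC selection worth knowing: the rule selects among
refits, so when individual fits carry non-trivial Monte-Carlo error the
selected iteration is favorably sampled on average and looks slightly
better than a single reference fit even when the prior updates carry no
information at all. On an intercept-only co-data control (where the
weights provably stay uniform and all iterations are exchangeable) the
apparent PMSE "gain" of this artifact is about 7% with one 2000-sweep
chain per fit and below 2% with six chains and a five-iteration cap.
Experiments that read small ratio effects (the uninformative-co-data
check) therefore use the multi-chain configuration; at the
application-scale preset the artifact is negligible.

Relatedly, a *permuted* grouping is only an uninformative control when the
groups are large: a permuted 25-covariate group that happens to contain a
predictive covariate still carries genuine membership information, which
the co-data model legitimately exploits. The uninformative experiments use
permuted groups of 100 (G=5 at p=500).

## Chain-length presets

The application-scale preset is 10 chains of 24 000 sweeps with half
burn-in. The replicated simulation experiments in the test suite and the
acceptance script keep the 10-chain structure at a tenth of the length
(2400 sweeps, 1200 burn-in): at p = 500 a single short chain visits too few
covariate subsets and its posterior-mean prediction is noticeably worse,
while averaging ten modest chains is close to converged (lengthening to
6000 sweeps moves the replicated mean PMSE by less than its Monte-Carlo
error). The within-replicate ratio experiments (EB-coBART versus BART on
identical data) use a single 2000-sweep chain for both arms: the
comparison is paired, so the lighter preset affects both arms alike.
Replicate counts are 20 (50 for the tail-fraction experiment); the
published experiments used 500.

## Synthetic designs

- **Sparse non-linear.** `p = 500` i.i.d. Unif(0,1) covariates; response
  `f0(x) = 10 sin(pi x1 x2) + 10 x3 + 20 (x101 - 0.5)^2 + 10 x102` plus
  N(0,1) noise; `Ntest = 500`. Grouping co-data: `G` equal blocks of
  consecutive covariates, so {1,2,3} share group 1 and {101,102} share
  group 2 (G=5) or 5 (G=20). Informative co-data here means "two of G
  groups carry all the signal".
- **Uninformative co-data**: the same design with group membership randomly
  permuted.
- **Dense linear.** `y = X beta + eps` with `beta_j ~ N(0, 0.25)`,
  standard-normal covariates, co-data = `beta` + N(0, 0.01) noise. These
  defaults are this package's choice of a realistic dense regime (signal
  R^2 around `p * 0.25 / (p * 0.25 + 1)`); every knob is exposed and the
  design is exercised property-wise, not against published numbers.
- **Binary fixture.** A synthetic stand-in for a lymphoma prognosis cohort:
  N = 101, p = 140 in blocks of 67 continuous copy-number-like scores, 69
  binary mutations, 3 rare translocations and 1 ordinal clinical index that
  dominates the probit response; ~82% positive rate; grouping co-data =
  block type; continuous co-data = `-logit` BH-adjusted p-values from an
  auxiliary simulated cohort of 430. It exercises the binary code paths and
  the multi-source co-data machinery; it does not reproduce any published
  cohort.

What passing tests show: the sampler targets its stated posterior, the EB
and co-data estimators maximize their stated objectives, and under the
simulated conditions co-data guidance improves prediction while
uninformative co-data is harmless. What they do not show: behavior under
correlated covariates, covariate-dependent noise, or misspecified co-data
beyond random permutation — real omics panels have all three.

## Known limitations

- BART's backfitting does not scale comfortably beyond `p ~ 10^4`.
- The co-data model is linear with no interactions; multi-source co-data
  enters additively.
- WAIC is computed in-sample; cross-validated stopping is not implemented.
- Split rules are univariate; categorical covariates must be pre-encoded.
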