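# ebcobart

Bayesian additive regression trees (BART) with **co-data guided
empirical-Bayes covariate weights** — a prediction method for
high-dimensional, small-sample settings (clinical omics prognosis being the
motivating case) where external information about the *covariates* is
available: a grouping by covariate type, or association scores such as
p-values from a related study.

## The model

BART writes the regression function as a sum of `K` trees,

    f(x) = mu0 + sum_{t=1..K} g(x; T_t, M_t),       y = f(x) + eps,

with regularization priors that keep each tree weak: a node at depth `d` is
internal with probability `alpha (1+d)^-beta`; splitting variables are drawn
from a categorical prior `S = (s_1, ..., s_p)`; terminal values are
`N(0, sigma_mu^2)` with `sigma_mu = 0.5/(k sqrt(K))`; and
`sigma^2 ~ InvGamma(nu/2, nu*lambda/2)`. Binary responses use a probit link
with Albert–Chib latent-variable augmentation (`sigma^2 = 1`,
`sigma_mu = 3/(k sqrt(K))`). Posterior sampling is Bayesian backfitting with
Metropolis–Hastings tree moves (grow / prune / change / swap) and the
terminal values integrated out of the acceptance ratio.

Default BART sets `s_j = 1/p`. This package learns `S` by Monte-Carlo-EM
empirical Bayes: at each iteration the split-rule counts `b_j` from the
posterior draws are the raw EB estimate `S_hat_1 = (b_1/B, ..., b_p/B)`,
which is smoothed through a parsimonious **binomial-logistic co-data model**

    b_j ~ Bin(w_j, B),   w_j = expit(c_j' eta),

whose design matrix `C` (one row `c_j` per covariate) encodes the co-data.
The fitted weights `S_hat_2 = (w_1, ..., w_p)` — which sum to one by the
calibration of the intercept — become the splitting-variable prior of the
next BART fit. Iterations stop at the minimum of the in-sample WAIC, and
the fit at that iteration is the returned model. The same EM framework
optionally re-estimates `alpha` and `k` (`ebco2` mode). Because the weight
update must pass through both the primary data (the counts) and the co-data
(the model matrix), uninformative co-data leaves the weights near-uniform
and the method close to plain BART.

## Worked example

```python
import numpy as np
import ebcobart as eb

# sparse non-linear benchmark: p=500 uniform covariates, 5 predictive,
# grouping co-data with G=20 blocks (predictive covariates sit in groups 1, 5)
sim = eb.simulate_friedman(eb.SimScenario(N=100, p=500, G=20, Ntest=500, seed=11))
groups = eb.make_group_codata(500, 20)
cmat = eb.build_codata_matrix({"group": ("grouping", groups)}, p=500)

run = eb.RunConfig(n_chains=1, n_iter=2000, burn_in=1000,
                   max_eb_iter=10, patience=5, preset="flexible", seed=11)
res = eb.run_ebcobart(sim.train, cmat, run)

bart = eb.fit_bart(sim.train, eb.preset_prior("flexible", "continuous",
                                              sim.train.y, 500), run)
print("q* =", res.q_star)
print("PMSE BART      %.2f" % eb.pmse(sim.test.y, bart.predict_mean(sim.test.X)))
print("PMSE EB-coBART %.2f" % eb.pmse(sim.test.y, eb.predict(res, sim.test.X)))
gw = eb.group_weight_summary(res, groups)
print("weight on predictive groups 1+5: %.2f" % (gw[1] + gw[5]))
```

prints

```
q* = 10
PMSE BART      10.03
PMSE EB-coBART 7.52
weight on predictive groups 1+5: 0.78
```

The co-data-guided prior concentrates most of the total splitting weight on
the two groups (uniform share: 0.10) that contain the five predictive
covariates, and the test-set prediction mean squared error drops by about a
quarter relative to default BART on the same data.

A command-line interface mirrors the library:

```sh
ebcobart simulate --design friedman --n 100 -G 20 --out data/
ebcobart fit --data data/train.csv --response y --codata data/codata.csv \
             --grouping group --out model/
ebcobart predict --model model/ --data data/test.csv --out pred.csv
ebcobart benchmark --reps 20 -G 20 --preset flexible
```

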