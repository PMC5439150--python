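# Methods

This document describes the statistical model implemented by `sadmix`, the
parameterisation, the numerical strategy, the data generator, and the
package's limitations.

## 1. The model

`sadmix` fits multiple-trait longitudinal animal models to records taken on a
shared discrete time grid (e.g. litter size LS and average birth weight ABW
over parities 1–5). For animal $i$, trait $k$ and time $t_j$ the observation
model is

$$
y_{ikj} = x_{ikj}'\beta + u_{ik}(t_j) + p_{ik}(t_j) + [w_{g(i),k}],
$$

with fixed effects $\beta$ (always including a per-trait intercept, plus
declared per-trait factors and covariates), an additive-genetic effect $u$, a
**pseudo-permanent environmental** effect $p$, and optionally an extra random
intercept $w$ (e.g. contemporary group) with one independent variance per
trait. There is **no separate residual**: because every animal has at most
one record per trait-time cell, a residual is not separable from the
permanent effect, which therefore absorbs residual variation. Heritability at
time $t$ is $h^2 = U_{tt}/(U_{tt}+P_{tt}[+\sigma^2_w])$.

Stacking the $d = (\text{traits}) \times (\text{times})$ cells, the random
effects have

$$
\mathrm{Var}(u) = A \otimes U, \qquad \mathrm{Var}(p) = I \otimes P,
$$

where $A$ is the pedigree-derived numerator relationship matrix and $U$, $P$
are $d \times d$ covariance matrices, each structured by a **structured
antedependence (SAD)** specification.

## 2. The SAD covariance family

Within trait $k$, the effect follows an antedependence recursion of order
$\alpha$:

$$
p(t_j) = \sum_{s=1}^{\alpha} \theta_s(t_j)\, p(t_{j-s}) + e(t_j),
$$

where each coefficient $\theta_s(t)$ is a polynomial of degree $\beta_s$ in
the raw time value and the innovation variance is
$\sigma^2(t) = \exp(\text{polynomial of degree } \gamma)$. The structure is
labelled `SAD αβ₁…β_αγ`; e.g. `SAD 111` is order 1 with a linear coefficient
and a log-linear innovation variance. Sums truncate at the start of the grid
(for $j \le \alpha$ only the available lags enter), which keeps the
factorisation triangular.

**Cross-antedependence** links traits: a recursive dependence of trait 2 on
trait 1 contributes $\sum_{s=c}^{\eta} \delta_s(t_j)\, p_1(t_{j-s})$ with
polynomial coefficients $\delta_s$. Lag-0 crosses are directional
(recursive, as in structural equation models); the lag-0 dependence graph
must be acyclic. When both directions start at lag $\ge 1$ an **initial
innovation correlation** $\rho$ may be added: $\rho$ is the correlation of
the two traits' innovations at $t_1$, giving
$\mathrm{Cov} = \rho\,\sigma_1(t_1)\sigma_2(t_1)$ while leaving both
variances unchanged. $\rho$ is estimated on the unconstrained
$\tanh^{-1}$ scale.

### Construction by triangular factorisation

Collect the recursion into a unit lower-triangular matrix $L$ (rows ordered
time-major, traits ordered so that lag-0 regressors precede their targets)
and the innovation variances into a diagonal $D$. Then

$$
\Sigma^{-1} = L' D^{-1} L, \qquad \Sigma = L^{-1} D L^{-\top},
$$

and $\log|\Sigma| = \sum_j \log D_{jj}$. Both $\Sigma$ and the *exact*
precision/log-determinant are exposed; the likelihood never inverts $\Sigma$
numerically, which matters because strong antedependence can drive fitted
innovation variances towards zero, making $\Sigma$ numerically singular while
$L$ and $D$ remain perfectly well defined. The result is permuted back to the
declared trait order. Because innovation variances are exponentials and $L$
is unit-triangular, $\Sigma$ is positive definite for every finite parameter
vector — the optimiser runs unconstrained.

Parameter counts: a `SAD αβ₁…β_αγ` trait costs
$\sum_s (\beta_s + 1) + (\gamma + 1)$; a cross with lags $c..\eta$ costs
$\sum_s (\text{degree}_s + 1)$; $\rho$ costs 1. The unstructured alternative
for $n$ traits and $T$ times costs $d(d+1)$ with $d = nT$ (two symmetric
matrices), e.g. 110 for 2 traits × 5 parities — versus 20 (rabbit) or 16
(pig) for the selected SAD structures.

## 3. REML estimation

The restricted log-likelihood uses the basis-invariant convention

$$
\ell_R = -\tfrac12\left[\log|V| + \log|X'V^{-1}X| - \log|X'X|
 + y'Qy + (n-p)\log 2\pi\right],
$$

which is invariant to reparameterisations $X \mapsto XT$.

Two evaluation paths agree to numerical precision (and with a brute-force
dense implementation, which is part of the test suite):

* **Balanced path** — when every phenotyped animal has a complete record set
  and no extra intercepts are present. With $A_{obs} = Q\Lambda Q'$ the
  rotated records decouple into per-animal blocks $V_i = \lambda_i U + P$,
  evaluated by batched Cholesky factorisations. An **analytic gradient** is
  available here: $\partial \ell / \partial V_i$ has a closed form in the
  per-block solves, summed into gradients w.r.t. $U$ and $P$ and chained
  through the analytic Jacobian of the SAD construction (finite differences
  are used for the rare $\rho$-coupled case). This makes L-BFGS-B fits of a
  ~10k-record two-trait problem take seconds.
* **General path** — arbitrary missingness, attrition and extra random
  intercepts. The mixed-model equations are assembled sparsely with
  Henderson's $A^{-1}$ (Quaas rules with inbreeding, no dense inversion) and
  $\log|V|$ comes from the standard determinant identity through a sparse LU
  factorisation of the MME coefficient matrix. The genetic block uses the
  exact $U^{-1} = L'D^{-1}L$ from the factorisation.

Optimisation: multi-start (jittered) L-BFGS-B on the unconstrained
parameters, with a Nelder–Mead polish if the quasi-Newton run reports
non-convergence. Starting values put all regression coefficients at zero and
split each trait's sample variance evenly between $U$ and $P$.
Non-convergence is reported in the results object, never hidden.

BLUP solutions (fixed effects, breeding values for all pedigree animals,
group effects) come from the sparse mixed-model equations at the REML
estimate.

## 4. Model selection

A two-step stepwise procedure is automated:

1. **Within-trait ladders** (per trait, on that trait's records): starting
   from `SAD 100` for both effects, candidates are tested in the order
   gamma-upgrade (`SAD 101`), beta-upgrade (`SAD 111`), then an order
   increase (`SAD 2..`), each accepted only if the REML likelihood-ratio
   test is significant at $\alpha = 0.05$ (configurable). The LRT guards
   against misuse: both fits must be on identical data (checked by a
   fingerprint) and the specs must be structurally nested.
2. **Cross-dependence selection** with the within-trait structures fixed:
   add the recursive lag-0 degree-0 cross (direction chosen by the user, a
   biological rather than statistical choice), raise its polynomial degree
   while significant, optionally test the initial correlation where
   identifiable.

AIC ($-2\ell_R + 2k$, $k$ = covariance parameters) compares non-nested
families, in particular SAD versus the **random-regression (RR) baseline**:
correlated random coefficients on an orthonormal Legendre basis per trait
(full coefficient covariances parameterised by log-diagonal Cholesky
factors) plus a free within-time residual covariance across traits.

## 5. Data generator

`simulate()` draws a multi-generation random-mating pedigree, then genetic
effects with covariance $A_{obs} \otimes U$ (via the Cholesky factor of
$A_{obs}$) and permanent effects with $I \otimes P$, adds per-trait parity
means and optional contemporary-group effects, and applies **monotone
attrition** (an animal lost at parity $j$ has no later records) and
per-trait, per-parity missingness.

Two presets emulate the record structure and published summaries of the two
motivating datasets:

* `rabbit_like` — ~2300 does over 5 kindlings; LS always recorded, ABW
  recorded for few animals at parity 1 and about half later; mild attrition;
  true parameters calibrated so that $h^2_{LS} \approx 0.14$–0.25,
  $h^2_{ABW}$ rises ≈ 0.22 → 0.39, same-parity genetic correlations between
  the traits are negative, and phenotypic variances are on the data scale.
* `pig_like` — ~1800 sows, strong attrition (record counts decline ~4.5×
  from parity 1 to parity 5), a contemporary-group intercept per trait, flat
  heritability trajectories ($h^2_{LS}\approx 0.18$–0.25,
  $h^2_{ABW} \approx 0.28$–0.34).

Calibration targeted these published-summary ranges only — never the
package's own test statistics. `balanced_recovery_design(n_dams, seed)`
strips attrition/missingness from the rabbit preset for clean recovery
studies.

## 6. Problem sizes and performance

Chosen as the package's own design targets (1 CPU):

* balanced two-trait fits with ~1000 phenotyped animals (10k records):
  seconds per fit via the analytic-gradient balanced path;
* unbalanced/grouped fits at the preset scale (~2000 animals): minutes —
  each general-path evaluation factorises a sparse MME of order roughly
  the number of fixed-effect columns plus 10 × pedigree size;
* pedigrees to a few tens of thousands of animals ($A$ is dense tabular,
  $A^{-1}$ sparse; memory for dense $A$ is the binding constraint beyond
  ~20k animals).

## 7. Limitations

* The time grid is shared by all animals (parity-type data); continuous,
  per-animal time points are out of scope.
* Standard errors of the covariance parameters are not reported (no
  information-matrix inversion); model comparison relies on LRT/AIC.
* The no-residual convention means $P$ is a *pseudo*-permanent covariance;
  it cannot be split into permanent environment and measurement error.
* Selection is stepwise, not exhaustive, and inherits the usual caveats of
  sequential testing.
* Dominance, maternal effects and genotype data are not modelled.
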