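# Methods

This document records the statistical model, the estimators, and the
numerical design decisions behind `branchcov`. Notation: sequences have
`n` aligned sites; `d` is an evolutionary distance in expected
substitutions per site; `r` is the alphabet size; `δ_m` is the length of
the path shared by two leaf-to-leaf paths on a tree.

## 1. Substitution model

Sites evolve independently under a stationary, time-reversible Markov
process with rate matrix `Q` and equilibrium distribution `π`, calibrated
to one expected substitution per site (`-Σ_u π_u Q_uu = 1`). The joint
probability of observing states `(u, v)` in two sequences separated by
distance `d` is

    P_uv(d) = π_u [e^{Qd}]_uv ,

and by reversibility `P(d)` is symmetric. `transition_probability(model,
d, k)` returns the k-th derivative `π_u [Q^k e^{Qd}]_uv` for k ∈ {0, 1, 2};
all likelihood, information and score quantities below are built from it.

The matrix exponential uses the spectral decomposition of the
π-symmetrized rate matrix (`diag(π)^{1/2} Q diag(π)^{-1/2}` is symmetric
for reversible `Q`, so `numpy.linalg.eigh` applies); if symmetrization
fails numerically the code falls back to `scipy.linalg.expm`.

### The r-state symmetric family (N_r)

`make_nr_model(r)` builds the fully symmetric model (uniform `π`, equal
exchange rates; r = 4 is Jukes–Cantor). With `β = (r−1)/r`:

    p_m(d) = β (1 − e^{−d/β})          # mismatch probability at distance d

`β` is the saturation mismatch probability: `p_m(4, 0.1) = 0.09362`,
`p_m → 3/4` for DNA. Empirical amino-acid models are read from
PAML-format rate files (lower-triangular exchangeabilities plus
frequencies) and recalibrated to one substitution per site.

## 2. ML distances and variances

For a pair of aligned sequences the log-likelihood is
`ℓ(d) = Σ_uv F_uv log P_uv(d)` with `F` the site-pair count matrix
(columns containing gaps or out-of-alphabet symbols are dropped first).

* **Symmetric models.** The mismatch count `I` is sufficient, and the MLE
  has the closed form `d̂ = −β log(1 − I/(nβ))`. Example: 30 mismatches
  in 100 sites gives `d̂ = 0.3831`.
* **General models.** A safeguarded Newton iteration on `ℓ'(d)` (bisection
  bracket `[1e−9, ceiling]`, initialized from the symmetric-model map of
  the mismatch fraction) maximizes the likelihood; the test suite checks
  it against the closed form to 1e−8 on symmetric data and against grid
  maximization on general data.
* **Saturation.** If `I/n ≥ β` (or Newton runs into the ceiling) the
  distance is undefined/unbounded; estimates are pinned to a ceiling
  (default 10.0 substitutions per site) and flagged `saturated`. The
  ceiling is a reporting device, not a statistical estimate.

Variance estimators, all per-pair:

* **Expected (Fisher) information**: `V(d̂) = 1 / I_n(d̂)` with
  `I_n(d) = n Σ_uv P'_uv(d)² / P_uv(d)` (the `P''` term vanishes because
  `Σ_uv P''_uv = 0`). For N_r this reduces to the delta-method closed form

      V(d̂) = β [(1−β) e^{2d/β} + (2β−1) e^{d/β} − β] / n ,

  e.g. `V = 5.833e−3` at `d̂ = 0.3831`, `n = 100` (information 171.4).
* **Observed information** (`sample_average_variance`): inverse of
  `−ℓ''(d̂)` evaluated on the actual counts. For symmetric-model data the
  two coincide exactly at the MLE; in general they agree as counts
  approach their expectation.

Both are *plug-in* estimators: `V(d)` is convex and increasing in `d`, so
averaged over replicates `V(d̂)` under-estimates the true sampling
variance at moderate distances (the classical negative bias) but can
over-shoot badly near saturation, where the replicate distribution of
`d̂` is truncated by the ceiling while `V(d̂)` grows like `e^{2d̂/β}`.
The Monte-Carlo harness reports both quantities side by side.

## 3. The branch-covariance identity

Consider two pairs of taxa whose paths share a sub-path of length `δ_m`.
Writing each estimate as a first-order expansion around the truth, the
covariance of the two ML distance estimates reduces to the covariance of
the two score functions, which is carried entirely by the sites' shared
mutation history on the common sub-path. Working this out for the
symmetric family gives

    cov(d̂_ij, d̂_kl) = β [(1−β) e^{2δ_m/β} + (2β−1) e^{δ_m/β} − β] / n ,

which is exactly `V(d̂)` evaluated at `d = δ_m`: **the covariance of two
distance estimates equals the variance of a distance estimate whose true
distance is the shared path length.** Example: `δ_m = 0.2`, `n = 500`
gives `4.934e−4`.

The identity is what makes the estimator cheap: covariance estimation
needs no joint pass over the alignment, only `δ_m` and a variance
evaluation. `general_covariance(model, δ_m, n)` implements it for any
reversible model as `1 / I_n(δ_m)`; the package validates it against the
closed form to 1e−8 relative and against Monte-Carlo replicate
covariances to within 3 standard errors (see §7).

Supporting derivation used as an internal oracle: under the symmetric
model the per-site mismatch indicators `S_ij, S_kl` of a dependent quartet
satisfy

    E[S_ij S_kl] = β (β − β e^{−d_ij/β} − β e^{−d_kl/β}
                      + (1−β) e^{−(d_ij+d_kl−2δ_m)/β}
                      + (2β−1) e^{−(d_ij+d_kl−δ_m)/β}
                      − (1−β) e^{−(d_ij+d_kl)/β})

    cov(S_ij, S_kl) = β [(1−β) e^{−(d_ij+d_kl−2δ_m)/β}
                         + (2β−1) e^{−(d_ij+d_kl−δ_m)/β}
                         − β e^{−(d_ij+d_kl)/β}]

The leading coefficient of the product expectation must be `β` (not 1):
at `δ_m = 0` the expression must factor into `p_m(d_ij) p_m(d_kl)`, which
pins the coefficient. Both formulas are verified against exhaustive
enumeration of all `r⁴` leaf patterns (`joint_pattern_probability`) to
~1e−15 for r ∈ {2, 3, 4}.

## 4. Estimating the shared path: WLS on quartets

Given the six estimated distances among four taxa `(i, j, k, l)` the three
unrooted topologies are scored by

    S(T1) = (d_ij + d_kl − d_il − d_jk)² / (v_ij + v_kl + v_il + v_jk)
    S(T2) = (d_ij + d_kl − d_ik − d_jl)² / (v_ij + v_kl + v_ik + v_jl)
    S(T3) = (d_ik + d_jl − d_il − d_jk)² / (v_ik + v_jl + v_il + v_jk)

i.e. the squared violation of the four-point condition that holds exactly
under each topology, weighted by the variance of the violated sum. Each
`S(T)` equals the minimized weighted sum of squares of the full
five-branch WLS fit under that topology (verified against an independent
least-squares oracle to 1e−14), so the smallest score names the WLS-best
topology. Ties involving T3 resolve to T3 — when the data cannot
distinguish dependence from independence the conservative choice is a
zero covariance.

* If the selected topology separates the two target pairs onto opposite
  sides (T3 for the pair `(d_ij, d_kl)`): the paths share nothing and the
  covariance is **exactly 0.0** (`zero_reason = "independent-topology"`).
* Otherwise the middle branch is estimated by the closed-form WLS blend
  of the two crossing-sum contrasts (equal to the fitted middle branch of
  the five-parameter WLS, verified to 1e−15):

      δ̂_m = [w₁ (d_il + d_jk − d_ik − d_jl) + w₂ (d_ij + d_kl − d_ik − d_jl)] / 2,
      w₁ ∝ 1/(v_il + v_jk),  w₂ ∝ 1/(v_ij + v_kl),  w₁ + w₂ = 1   (topology T1)

  A negative fitted value is clamped to zero and reported as
  `zero_reason = "negative-delta"`.
* Pairs sharing one taxon use the three-point formula
  `δ̂_m = max((d_ij + d_jk − d_ik) / 2, 0)` for the shared sub-path at the
  common taxon `j`.

On 1,000 noiseless additive quartets this recovers the topology 100% of
the time and `δ_m` to 1e−10 (floating-point identity, not a statistical
statement).

## 5. Numerical design decisions

* **Information lookup table.** For expensive models (20-state empirical
  matrices) `build_info_table` precomputes the per-site expected
  information on a grid (default 0.001–5.0, step 0.001).
  Interpolation is linear in the *reciprocal* (per-site variance): the
  information diverges like `1/δ` near zero, where linear interpolation
  of the information itself has ~10% midpoint error at the grid edge,
  while the variance is nearly linear in `δ` and interpolates to better
  than 1e−5 relative over [0.05, 2] at the default step. No
  extrapolation: out-of-range queries raise.
* **Effective length for unequal pairs.** When the two distance estimates
  rest on different numbers of sites the covariance uses an effective `n`
  — geometric mean, rounded (default) or the conservative minimum
  (`n_effective="min"`). The geometric mean is exact for the variance
  scale factors entering the score-product expectation when the two pair
  lengths differ only through independent column drops.
* **Degenerate shared path.** `δ_m < 1e−8` returns exactly 0.0; the
  information diverges there and the covariance limit is zero.
* **Output hygiene.** `covariance_matrix` emits one record per ordered
  pair-of-pairs with the topology, `δ̂_m`, the covariance, and a
  `zero_reason` tag (`none`, `independent-topology`, `negative-delta`),
  so exact zeros are auditable. The column is named `covariance` (not
  `cov`) to avoid shadowing the pandas `DataFrame.cov` method attribute.

## 6. Sample-average (Susko) baseline

The baseline estimator uses the per-column score products over a true
multiple-sequence alignment:

    score s_d(u, v) = [Q e^{Qd}]_uv / [e^{Qd}]_uv = ∂/∂d log P_uv(d)

    cov(d̂_ij, d̂_kl) ≈ n · V_ij · V_kl · mean_c [ s_{d̂_ij}(x_ic, x_jc) · s_{d̂_kl}(x_kc, x_lc) ]

with `V` the per-pair variance estimates and the mean over alignment
columns `c` complete in all four sequences. It is linear in the alignment
length but requires the shared columns — it is not applicable when the
two distances come from independently aligned pairs, which is precisely
the regime the branch-covariance estimator targets.

## 7. Simulator and Monte-Carlo validation

* **Quartets.** `sample_quartet` draws terminal branches uniform in
  [0.02, 0.8] and the middle branch uniform in [0.01, 0.5], then dilates
  all five by a common U(0.5, 2) factor, covering near-star to
  deep-divergence shapes (path lengths up to ~3.7, so some sampled
  settings deliberately probe the saturation regime).
* **Sequences.** The root state is drawn from `π` per site and propagated
  along each branch with `e^{Q δ}`. An exhaustive `r⁴` pattern
  enumeration (`joint_pattern_probability`) provides exact pattern
  probabilities for oracle checks of the evolver.
* **Indels.** Optional corruption deletes segments starting at each site
  with probability 0.01; lengths follow a Zipf law with exponent 1.821
  truncated at 50 (a standard empirical indel-length regime). Corrupted
  pairs are re-aligned globally (affine gaps, open −10 / extend −1, log-odds
  substitution scores at a reference distance of 1.0) so the harness can
  measure the estimators on optimal pairwise alignments rather than the
  true alignment. This emulates alignment-induced noise only; it does not
  model insertion/deletion heterogeneity along the tree.
* **Harness.** `monte_carlo_experiment` evolves `reps` independent
  replicates, estimates the six distances per replicate, evaluates the
  requested covariance estimators, and compares their replicate means and
  MSEs against the replicate sample covariance (an unbiased reference).
  Replicates with a saturated target distance are excluded (warned above
  5%). Every run is a pure function of its integer seed.
  `mse_comparison` wraps this over quartet collections and the three
  topological relations (dependence / triplet / independence), optionally
  adding a through-the-origin regression of Monte-Carlo covariances on
  the variance-at-`δ_m` prediction ("conjecture slope", ≈ 1 when the
  identity holds).
* **Problem sizes.** The shipped validation uses sizes chosen to give
  stable references on one CPU in minutes: 10 quartets × 10,000 reps at
  n = 1000 for the covariance identity (3-SE criterion), 20 quartets ×
  2,000 reps at n = 500 for the MSE head-to-head. Observed outcome: the
  branch-covariance estimator's average MSE is below the baseline's in
  all three relations (ratios ≈ 0.15–0.9 depending on case and seed).

## 8. Known limitations

* The identity is asymptotic (first-order delta method); at small `n` or
  near saturation both it and the baseline inherit the plug-in bias of
  `V(d̂)` described in §2.
* Topology/`δ_m` estimation error propagates into the covariance; the WLS
  step is exact only on additive inputs.
* The indel pipeline models deletions with a fixed length law and scores;
  it is a stress test for alignment noise, not a biological indel model.
* `Quartet.from_newick` accepts only four-leaf, single-internal-edge
  trees; larger trees should be reduced to quartets/triplets by the
  caller (as `covariance_matrix` does for distance tables).
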