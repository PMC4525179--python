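# Methods

This note records the models implemented by `webstab`, the assumptions
behind them, the defaults and why they were chosen, and the numerical
decisions that a user extending or auditing the package should know.

## Community-matrix model

A food web on S species is a binary adjacency matrix K with
K<sub>ij</sub> = 1 when species i (resource) is consumed by species j
(consumer); the diagonal is zero (no cannibalism links are generated).
Each link contributes a pair of community-matrix coefficients drawn from
a bivariate distribution Z = (X, Y): M<sub>ij</sub> = X < 0 (the
consumer's effect on the resource) and M<sub>ji</sub> = Y > 0 (the
resource's effect on the consumer).  Non-links are exactly zero and the
diagonal is −d (default d = 0; a uniform diagonal only shifts every
eigenvalue by −d, and the package reproduces that identity exactly).

Mutual predation — K<sub>ij</sub> = K<sub>ji</sub> = 1, which cyclic
webs produce — is handled by superposition: each of the two links
contributes its own (X, Y) pair and opposing entries are summed,
M<sub>ij</sub> = X₁ + Y₂, M<sub>ji</sub> = Y₁ + X₂.  This is the natural
Lotka–Volterra composition of two opposite predation events; the
alternative (letting one link overwrite the other) silently converts
mutual predation into mutualism and measurably destabilizes niche-model
webs.

## Web generators

* **cascade** — each pair i < j is a link independently with probability
  C; acyclic and strictly upper-triangular by construction.  C is
  defined against the S(S−1)/2 potential pairs.
* **niche** — niche values n ~ U(0,1) (species returned sorted by n),
  diet range r = n·x with x ~ Beta(1, (1−2C)/(2C)) so E[x] = 2C, diet
  centre c ~ U(r/2, n); a consumer eats every species whose niche value
  falls in its diet interval.  This calibrates the *directed*
  connectance L/S² to C (the convention of the model's authors), i.e.
  roughly twice the pairwise connectance of a cascade web at the same C.
  Webs with isolated species, duplicate diets or disconnected components
  are *not* rejected or regenerated; the package measures what the raw
  model produces.  Self-capturing diet intervals do not create
  self-links.  Intervality is checked allowing the consumer's own
  position as a gap in its prey block, since a diet interval may
  straddle the consumer's own niche value.
* **cascade_degree_matched** — consumer diet sizes follow the niche
  generality law k<sub>j</sub> = round(r<sub>j</sub>·S) truncated to the
  number of predecessors, prey chosen uniformly among predecessors.
  The matching mechanism is the simplest one consistent with "same
  consumer degree distribution as the niche model"; it reproduces the
  niche generality law asymptotically (verified by a two-sample test
  against direct sampling of r·S).
* **cascade_interval** — cascade diet sizes (Binomial over predecessors),
  prey placed as one contiguous block of predecessors, position uniform.
* **niche_cycleless** — niche generality law + contiguous placement:
  interval, acyclic, niche-like degrees.

All generators take a single seeded generator per call and are exactly
reproducible from (S, C, seed).

## Interaction-strength distributions

Z is specified by five moments (μ<sub>x</sub> < 0, μ<sub>y</sub> > 0,
σ<sub>x</sub>, σ<sub>y</sub>, ρ<sub>xy</sub>) plus a family tag that
fixes the sampling recipe; all families hit the five moments exactly and
guarantee the sign structure draw by draw:

* `gaussian_copula_lognormal` (default) — |X| and Y lognormal, coupled by
  a Gaussian copula whose parameter is solved in closed form from the
  target Pearson correlation; an explicit error names the constraint if
  the requested correlation is outside the attainable range of the
  lognormal pair.
* `truncated_gaussian` — marginals are normals truncated to the correct
  half-line whose pre-truncation location/scale are solved numerically to
  hit the post-truncation mean and sd; the copula parameter is calibrated
  by Gauss–Legendre quadrature and root-finding.
* `point_mass` — degenerate pairs, useful for exact tests.

Two distinct families with identical moments produce statistically
indistinguishable leading-eigenvalue distributions at S = 500 (a
universality property the test suite checks with a Kolmogorov–Smirnov
test at α = 0.01).

### The body-size stand-in

The empirical pair distribution used in the original study (built from a
consumer/resource body-size database) is not available; `bodysize_standin`
provides documented synthetic scenarios in its place.  The `default`
scenario is

    mu_x = -1.0, mu_y = 0.2, sigma_x = 0.5, sigma_y = 0.1, rho_xy = -0.7

— unit scale for the negative effects, conversion efficiency around 20%,
strong negative pair correlation as found in body-size
parameterizations, and coefficient of variation 0.5.  The CV matters: at
desk scale (S ≤ 1000) the leading eigenvalue of the residual matrix only
reaches its asymptotic elliptic boundary when the matrix entries have
modest kurtosis.  Heavy-tailed marginals (lognormal with CV ≥ 1) are
still covered by the theory asymptotically, but at these sizes the
observed boundary falls visibly short of the formula (a ~10–30% gap in
controlled experiments, against ~2% for light-tailed entries with the
identical second-order structure).  The `weak_positive` and
`strong_positive` scenarios move the dominance between negative and
positive mean effects; `strong_positive` reverses it, which flips the
spectrum of A around the imaginary axis and moves the system into the
regime where stability is lost through a complex pair (flagged in every
prediction; no bifurcation analysis is attempted).  These moments are
configuration, not science: every report echoes them and labels them as
stand-ins.

## Triangular moments and the prediction

For a cascade-parameterized matrix the full-triangle moments are the
Bernoulli-mixture expressions

    mu_U      = C mu_x
    sigma_U^2 = C sigma_x^2 + C(1-C) mu_x^2
    cov_UL    = C rho_xy sigma_x sigma_y + C(1-C) mu_x mu_y

(and symmetrically for the lower triangle), with opposing entries sharing
one Bernoulli indicator.  For an arbitrary matrix the same five moments
are measured directly over all S(S−1)/2 triangle positions, zeros
included, diagonal excluded, in a caller-specified species ordering.

The prediction is Re(λ<sub>A,1</sub>) + r<sub>h,B</sub> − d with the
closed-form circle spectrum for A and the generalized ellipse for B (see
README for the formulas).  Numerical decisions:

* The closed form for A is used in both regimes (it is exact; the dense
  eigendecomposition oracle confirms it to 1e-8 in the tests); the dense
  fallback is used only for the genuinely degenerate ratio
  μ<sub>L</sub>/μ<sub>U</sub> = 1.  When |μ<sub>L</sub>| = |μ<sub>U</sub>|
  with opposite signs the circle degenerates to a vertical line; the
  eigenvalues remain exact and the circle parameters are flagged.
* α has a removable singularity at σ<sub>U</sub> = σ<sub>L</sub>,
  evaluated by its continuous limit Sσ² (this also pins down the
  dimensionally consistent reading of the equal-variance limit "α ≈ S",
  which corresponds to σ = 1).  If exactly one triangle variance is
  zero the α limit is 0 and the ellipse is reported as (0, 0) with a
  low-confidence flag.
* Cyclic webs are reordered before the moments are measured: exact
  subset-DP minimization of the lower-triangle link count for S ≤ 9,
  otherwise a deterministic Eades–Lin–Smyth greedy sequence polished by
  single-insertion (and, for S ≤ 40, pairwise-swap) hill climbing with a
  pass budget.  On niche webs the heuristic lands within ~0.5% of the
  mutual-pair lower bound, i.e. it is effectively optimal there; ties
  are broken by species index and the result is never worse than the
  identity or the greedy start.  Eigenvalues are permutation-invariant
  (checked to 1e-10), so the ordering affects only the measured moments,
  not the ground truth.
* The validation workflow parameterizes the prediction from the
  *measured* moments of the sorted matrix for every model — that is the
  published protocol for cyclic webs, and for cascade webs it removes
  realized-connectance fluctuation from the comparison.
* Dense eigendecomposition (numpy, full spectrum) is the oracle up to a
  configured limit (default S = 2000): exactness over speed at desk
  scale.  Protocol-scale suites use S ∈ {500, 750, 1000} with 30–50
  replicates per condition, the package's chosen desk-scale replication
  of the published 150-replicate protocol.

## Comparison baselines

The May and elliptic-law (Tang et al.) baselines treat all off-diagonal
entries as exchangeable.  The exact moment mapping used (documented here
and in every report): E = (μ<sub>U</sub> + μ<sub>L</sub>)/2,
V = (σ<sub>U</sub>² + σ<sub>L</sub>²)/2 + (μ<sub>U</sub> − μ<sub>L</sub>)²/4,
pairwise correlation ρ̃ = (cov<sub>UL</sub> − (μ<sub>U</sub> −
μ<sub>L</sub>)²/4)/V; then may = √(SV) − d (ignores E and ρ̃) and
tang = √(SV)(1 + ρ̃) − E − d.  On genuinely unstructured webs (randomly
oriented pairs) tang is accurate to a few percent — the baselines fail on
cascade webs not because they are wrong but because they assume away the
structure.

## Sensitivity scan

`theta_scan` re-evaluates the analytic prediction with one parameter
group (S; C; means μ<sub>x</sub>, μ<sub>y</sub> jointly; sds σ<sub>x</sub>,
σ<sub>y</sub> jointly; ρ<sub>xy</sub>) multiplied by θ over a grid
(default 0.5, 0.75, 1, 1.5, 2 — the published grid is not stated).  The
scan is formula-only, hence deterministic; out-of-range rows (C·θ > 1,
|ρ·θ| > 1, S·θ < 2) are flagged, never dropped.

The default scan baseline is S = 500, C = 0.2 with moments
(−1.0, 0.2, **2.0**, **0.4**, −0.7) — the *variance-dominated* regime
σ<sub>x</sub> = 2|μ<sub>x</sub>|, a deliberately different stand-in from
the simulation default.  The reason is structural: mean scaling acts on
the prediction both through A (where it is very constrained) and through
the mixture terms C(1−C)μ² in the triangle variances.  The claim that
mean interaction strengths barely matter is a statement about webs whose
strengths vary much more than their means, where those mixture terms are
negligible; at CV = 0.5 they dominate and mean scaling is *not* minor.
The simulation stand-in keeps CV = 0.5 because the finite-size spectra
have converged there (above); the scan baseline keeps CV = 2 because the
sensitivity statements live there and a formula-only scan has no
finite-size concern.  Users studying their own Z should simply pass it:
both defaults are labeled stand-ins.

## What the synthetic data does and does not show

The generators and the stand-in Z emulate the *structure* the theory
addresses — hierarchy, connectance, diet intervals, degree broadness,
trophic cycles, sign-correlated pairs.  They do not emulate: empirical
degree distributions beyond the niche family, modularity or trophic
groups, body-size-correlated interaction strengths (strengths are
i.i.d. across links given Z), non-equilibrium dynamics, or diagonal
heterogeneity.  Passing tests therefore demonstrate that the
approximation is internally correct and accurate for the stated network
models at desk scale — not that any particular empirical web is stable.

## Known limitations

* The generalized ellipse for B is a conjecture (as in the source
  theory); its finite-size accuracy degrades with entry kurtosis, so
  heavy-tailed Z at S ≲ 1000 will show a systematic positive bias in the
  prediction.
* For positive-dominant systems (μ<sub>L</sub> > −μ<sub>U</sub>) the
  prediction is flagged: the leading eigenvalues there are a complex
  pair, the r<sub>h,B</sub>-based estimate is not designed for that
  regime, and no Hopf/limit-cycle analysis is provided.
* The ordering heuristic is a heuristic; minimum feedback arc set is
  NP-hard, and for adversarial dense digraphs the returned fill can
  exceed the optimum (on S = 8 benchmarks it is optimal in ≥ 18/20 cases
  and within 1 link otherwise).
* Niche-model webs under this package's stand-in Z sit well below the
  cascade prediction (the stabilizing structural effect is large, not
  "slight"); the magnitude of that gap is Z-dependent and only its sign
  is asserted.
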