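# webstab

Analytic stability prediction for large, structured food webs.

## The problem

Local stability of an ecological community hinges on the leading
eigenvalue of its community matrix **M** (the Jacobian at equilibrium):
the equilibrium is stable iff every eigenvalue has negative real part, and
Re(λ<sub>M,1</sub>) at zero self-regulation equals the minimum amount of
self-regulation −d that would stabilize the system.  Classic random-matrix
criteria (May; the elliptic law of Tang et al.) assume the interaction
network is *unstructured* — any two species equally likely to interact.
Real food webs are nothing like that: they are hierarchically ordered
(big fish eat little fish), nearly acyclic and nearly interval.

`webstab` implements an analytic approximation for
Re(λ<sub>M,1</sub>) of food webs built on the **cascade model** — species
ordered 1…S, each consumer feeding on any predecessor independently with
probability C, each trophic link contributing a pair of coefficients
(M<sub>ij</sub>, M<sub>ji</sub>) = (X, Y) drawn from a bivariate
distribution Z with X < 0 < Y — together with everything needed to
validate it end to end: cascade/niche web generators and three structural
cascade variants, sign-safe samplers for Z, a feedback-arc ordering
heuristic for cyclic webs, comparison baselines, a numeric
eigendecomposition oracle and a θ-scaling sensitivity scan.

## The approximation

Write the community matrix (in the hierarchy ordering, diagonal −d) as
**M** = **A** + **B**, where **A** holds the triangular means — every
upper entry μ<sub>U</sub>, every lower entry μ<sub>L</sub> — and
**B** = **M** − **A** is the zero-mean residual.

* **Signal.** The spectrum of **A** has a closed form: the eigenvalues
  are λ<sub>k</sub> = (μ<sub>U</sub>q<sub>k</sub> − μ<sub>L</sub>)/(1 −
  q<sub>k</sub>) with q<sub>k</sub> the S-th complex roots of
  μ<sub>L</sub>/μ<sub>U</sub>; they lie on a circle with centre
  c<sub>A</sub> = (μ<sub>U</sub>r² − μ<sub>L</sub>)/(1 − r²) and radius
  r<sub>A</sub> = |μ<sub>U</sub> − μ<sub>L</sub>| r/|1 − r²|, where
  r = |μ<sub>L</sub>/μ<sub>U</sub>|<sup>1/S</sup>.  In the food-web
  (negative-dominant) regime −μ<sub>U</sub> > μ<sub>L</sub> > 0 one has
  0 ≤ Re(λ<sub>A,1</sub>) ≤ −μ<sub>U</sub> and Re(λ<sub>A,1</sub>) ≈
  c<sub>A</sub> + r<sub>A</sub>.
* **Noise.** The spectrum of **B** approximately fills an ellipse centred
  at the origin with semi-axes
  r<sub>h,B</sub> = (α + ρ<sub>UL</sub>σ<sub>U</sub>σ<sub>L</sub>(S−1))/√α,
  r<sub>v,B</sub> = (α − ρ<sub>UL</sub>σ<sub>U</sub>σ<sub>L</sub>(S−1))/√α,
  with α = S(σ<sub>U</sub>² − σ<sub>L</sub>²)/log(σ<sub>U</sub>²/σ<sub>L</sub>²)
  (continuously σ<sub>U</sub> = σ<sub>L</sub> = σ gives α = Sσ², the
  elliptic law).
* **Prediction.**
  Re(λ<sub>M,1</sub>) ≈ Re(λ<sub>A,1</sub>) + r<sub>h,B</sub> − d.

Here (μ<sub>U</sub>, μ<sub>L</sub>, σ<sub>U</sub>, σ<sub>L</sub>,
ρ<sub>UL</sub>) are the moments of the *full* triangles of **M**, zeros
included — computable either analytically from (Z, C) or by measuring a
given matrix.  Cyclic webs (niche model, user data) are first reordered to
minimize the number of links below the diagonal (a minimum-feedback-arc
heuristic; exact for S ≤ 9) and the moments measured in that order.

## Worked example

```bash
webstab generate --model cascade --S 500 --C 0.2 --seed 42 --out web.tsv
webstab build    --web web.tsv --seed 42 --out mat.csv
webstab predict  --matrix mat.csv --numeric --out report.json
```

prints

```
cascade web S=500 C=0.2 links=24848 -> web.tsv
community matrix S=500 d=0.0 -> mat.csv
predicted Re(lambda_M,1) = 2.202 -> report.json
```

and `report.json` contains (abridged)

```
predicted 2.202 | re_lambda_A 0.0799 | r_h_B 2.1221
numeric   2.2347
may 7.8845   tang 4.5552
```

Read: the hierarchical signal contributes Re(λ<sub>A,1</sub>) ≈ 0.08 and
the noise ellipse r<sub>h,B</sub> ≈ 2.12; their sum 2.202 is within 1.5%
of the numerically computed leading eigenvalue 2.2347, i.e. each species
would need self-regulation of about −2.2 for this web to be stable.  The
structure-blind baselines overshoot badly (May 7.88, Tang 4.56), because
they ignore the cascade sign structure and the strong negative pair
correlation.  A five-replicate validation run
(`webstab validate --model cascade --replicates 5 --S-choices 500 --seed 7
--out val.csv`) summarizes:

```
  model  replicates  mae_predicted  mae_may  mae_tang  bias_predicted  median_rel_error
cascade           5         0.0596 6.307365   2.46363        0.008192          0.025538
```

The same machinery runs for the niche model and the structural cascade
variants (`--model niche|cascade_degree_matched|cascade_interval|niche_cycleless`),
whose observed leading eigenvalues fall *below* the cascade-theory
prediction — trophic cycles, broad consumer degree distributions and
intervality are stabilizing.  `webstab scan` tabulates the θ-scaling
sensitivity of the prediction: variances and pair correlation dominate,
size and connectance act nearly interchangeably, mean interaction
strengths barely matter.

The interaction-strength distribution defaults to a documented synthetic
stand-in (`bodysize_standin`); pass your own moments (`--mu-x`,
`--sigma-x`, …) or matrices to use measured strengths.  See
`docs/methods.md` for model details, parameter meanings and limitations.

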