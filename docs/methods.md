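# Methods

## The regulatory core

Every regulatory connection is a homotypic array of `N` equal binding
sites with binding constant `K` (per nM) and cooperativity fold `C >= 1`.
The statistical weight of a configuration with `i` bound molecules is
`binom(N, i) * C**max(i-1, 0) * (K*A)**i` — each molecule beyond the first
contributes one factor of `C` ("chain" cooperativity). The occupancy used
as a transcriptional response is the probability that at least one site is
bound, `p = 1 - 1/Z` with `Z` the sum of the weights. How the
cooperativity bonus should scale with the number of bound molecules is not
uniquely determined by a macroscopic fold parameter; the chain form is the
package default because it reduces to the familiar single-site hyperbola
and keeps `C` interpretable as a per-contact bonus, and a pairwise
alternative (`C**binom(i,2)`, one factor per bound pair) is available via
`SiteArray(coop="pairwise")`. Both are validated against brute-force
enumeration of all `2**N` configurations.

Activator occupancies and repressor complements multiply (AND); multiple
independent activators combine as `1 - prod(1 - p_i)` (OR). Occupancies
are mathematically below 1 but may round to exactly 1.0 at saturating
concentrations, so the integration helpers accept the closed interval.

## Network wiring

Fourteen connections, twelve sharing the global affinity `K`:

| edge | array |
|---|---|
| Bcd -> Hb, Bcd -> Kni, Bcd -> Gt, Bcd -| Cad | shared Bcd array, global `K` |
| Hb -> Hb, Hb -> Kr, Hb -| Kr (dual) | Hb array, global `K` |
| Hb -| Kni | repressor-specific array, `K1` |
| Kr -| Gt | `K2` |
| Kni -| Hb, Gt -| Kr, Cad -> Gt, Tll -| Kni, Tll -| Gt | global `K` |

Hunchback acting as activator or dual regulator uses one set of constants;
acting as a dedicated repressor on *kni* it may use another (`K1`). The
asymmetric affinities `K1`/`K2` on one side of each mutual-repression pair
are what lets the toggle switches sit in the single-attractor regime where
needed. An optional separate affinity for the repressive arm of the Kr
dual regulation exists behind `ModelParams(kr_rep_K=...)` but is off by
default (the dual regulator shares one array).

Caudal is evaluated once from Bcd as `C_max * (1 - p_Bcd)` and then held
fixed, i.e. it behaves as one more maternal input on the common 0–50 nM
concentration scale. Tailless is a fixed input profile; the terminal
system enters the model only through it, so a *torso* null is modeled as
Tll = 0. Posterior zygotic *hb* (terminal-system controlled) is outside
the network; the Hb fitting range (30–70 % e.l.) avoids the posterior
domain accordingly.

## Dynamics and normalization

The state is integrated by explicit Euler with `dt = 2.2` min on a
100-point axis (`dx = 5` um), with a stability guard `dt * beta < 1`.
Diffusion is applied between Euler steps as a Gaussian filter of standard
deviation `sqrt(2 D dt)` (the 1-D heat kernel), implemented with
reflecting boundaries — the method-of-images solution for a no-flux
domain, which conserves mass exactly. Repression terms are evaluated at
the same time step as the synthesis they modulate.

Synthesis potentials are normalized per gene at `t = 0` (maternal Hb as
the Hb initial condition, the other gap genes at zero):
`omega_A = 1 / max_x P_A(x, 0)`, so every gene starts with the same
maximal synthesis rate `alpha`. Because the normalizer is fixed at `t = 0`
while repressors later release territory, `alpha * omega * P` can
transiently exceed the steady-state ceiling; concentrations are therefore
clipped at `C_max = 50` nM (with a logged warning). The normalizers are
part of a fitted solution: mutant re-simulations keep the wild-type
`omega` (recomputing it on, say, a Bcd-null input would be degenerate).

Synthesis and decay constants are "numerically equal" in units relative
to `C_max`: the single fitted rate parameter `rho` yields
`alpha = rho * C_max` (nM/min) and `beta = rho` (1/min). A literal
equality in mixed units would cap every profile near 1 nM and make the
25 nM amplitude filter unsatisfiable. The default integration spans 40
steps (88 min), long enough for the patterns to reach quasi-steady shape
while preserving the documented transient behaviours (anterior Kni
drift); it is configurable everywhere.

## Fitting

Open parameters live on discrete grids: affinities log-uniform over
1e-3–1e2 nM⁻¹ (100 values), `C` in 1–20 (100 values), `N` on the integers
1–20, `D` in 0–30 um²/min, and `rho` in 0.02–0.45 /min (the upper bound
keeps Euler stable at `dt = 2.2`). A proposal moves one uniformly chosen
parameter by one grid index, reflecting inward at the bounds; acceptance
follows `exp((r_new - r_old)/T) > U` with `T = 0.05` on the correlation
scale, so improvements are always taken and a 0.05 loss in `r` is accepted
with probability ~1/e. The objective is the minimum over the four genes of
the Pearson correlation between simulated and target final profiles inside
the per-gene fitting ranges; a zero-variance model profile scores −1. Each
chain records the best state it visits; a fit returns one solution per
seed point. The production-scale protocol of this design used 1000 seed
points; the package defaults to the scaled-down 50 seeds x 500 steps,
which completes in ~2 minutes per variant on one CPU and is what the
benchmarks report.

Two variants are packaged: **B-7** opens `{K, K1, K2, C, N, D, rho}`;
**B-4** opens `{K, K1, C, rho}` with `D = 0` and `N` fixed (5 by
default), and its single node-specific affinity `K1` serves both toggle
repressor edges (Hb -| Kni and Kr -| Gt).

## Synthetic data

The generator emulates cycle-14 embryo profiles on the model grid:
an exponential anterior Bicoid gradient (amplitude 50 nM, length scale
20 % e.l.), a sigmoidal anterior maternal Hunchback profile (midpoint
47 % e.l., width 3), and a posterior Tailless sigmoid (half-max 80 %
e.l., width 3). Gap-gene targets come in two modes: *model-forward*
(the final state of the dynamic model at given parameters — the
assumption-free ground truth used by all recovery benchmarks) and
*stylized* (Gaussian/sigmoid mixtures placing the anterior Hb plateau,
central Kr domain, abdominal Kni stripe near 65 % e.l. and the two Gt
stripes). Noise, when requested, is multiplicative lognormal (expression
intensities are non-negative with roughly intensity-proportional error;
default sigma 0.1), applied after pattern construction and clipped to the
concentration scale; everything is deterministic given the seed.

What the generator does **not** emulate: nuclear-level scatter,
embryo-to-embryo registration error, 2-D geometry, or the temporal
refinement of the input gradients. Passing the recovery benchmarks
therefore demonstrates that the fitting machinery can identify the model
on data with exactly the model's structure — not that the model fits real
embryo data.

## Packaged reference solution

`gapswitch.reference` ships one grid-point parameter set of the B-7
design (`K = 0.015`, `K1 = 0.34`, `K2 = 0.67` nM⁻¹, `C = 2.5`, `N = 6`,
`D = 4.8` um²/min, `rho = 0.059` /min). It was selected by screening the
fitting grids for wild-type geography on the default synthetic inputs
(anterior Hb to ~47 % e.l., central Kr peaking near 54, Kni stripe near
65, anterior plus posterior Gt) together with the qualitative mutant
panel; the node-specific affinities fall in the realistic
transcription-factor range while the global `K` is weak, and the site
count sits in the 3–7 band typical of quality solutions of this design.
It doubles as the ground-truth generator for model-forward targets.

## Mutant conventions

A mutant spec lists nulled gap genes (synthesis forced to zero and all
outgoing links removed), removed regulatory links (activator occupancy set
to zero; repression factor set to one), input replacements (e.g. uniform
maternal Hb at the anterior amplitude for a *nanos* background, zeroed
profiles for nulls) and dosage multipliers (4 copies of *bcd* = 2x the
wild-type gradient, uniform in x — dosage proportionality preserves the
gradient shape; inputs are allowed to exceed 50 nM in this case). Pattern
calls use a presence threshold of 10 nM (20 % of `C_max`) and a shift
threshold of one grid point (1 % e.l.); multimodal profiles are split into
domains at interior minima below half of the global maximum. Mutant
agreement is qualitative (directions of shifts, presences, amplitude
ratios), not quantitative.

## Numerical notes and limitations

* Attractor search integrates a lattice of initial conditions
  (`[0, alpha_max/beta]^2`, Euler `dt = 0.1/beta`, up to 1e4 steps, early
  exit below 1e-9), clusters endpoints within `1e-3 * alpha_max/beta` and
  verifies candidates by the residual norm **and** linear stability of the
  finite-difference Jacobian — symmetric lattices otherwise land exactly
  on the saddle of a bistable switch along its stable manifold.
* Pearson objectives are clipped to [−1, 1] against floating-point
  overshoot; simulation failures during fitting score −1 and the chain
  continues.
* The model has no posterior zygotic Hb, no pair-rule layer, no nuclear
  divisions and no stochasticity; mutant phenotypes involving residual
  terminal inputs (terminal Gt stripe dynamics) are out of reach.
* The scaled-down chain budget makes the best-of-run objective noticeably
  seed-dependent (best `r` for the 7-parameter self-fit typically falls
  between ~0.80 and ~0.98 across master seeds); the packaged benchmarks
  report whatever the seeded run produces.
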