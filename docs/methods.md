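# Methods

`isoweb` implements the quantitative workflow of a two-lake stable-isotope
food-web analysis: empirical trophic discrimination factors (TDFs), Bayesian
diet mixing models under uniform and biomass-informed Dirichlet priors with
MCMC diagnostics and LOO/WAIC comparison, Monte-Carlo mixing-polygon
validation, two-baseline trophic positions and food-chain length, and binary
food-web topology metrics. This note records the models, the defaults and
why, and what the synthetic data do and do not establish.

## Trophic discrimination factors

A calculated TDF is the mean ± sample SD (n−1 denominator) of the per-source
differences (consumer mean − source mean), one difference per source per
tracer, equally weighted regardless of each source's sample size. Pairing at
the individual level is impossible with summary data, and equal weighting is
the transparent default. The candidate source set is always an explicit
argument: which organisms count as "potential sources" is an ecological
judgement, and silently inferring it from a table invites irreproducible
numbers. Negative carbon TDFs are allowed — littoral grazers can carry
heavier carbon than a fish that eats them. Five rainbow-trout presets
(TDF1–TDF5, `data/tdf_presets.yaml`) cover the published range; TDF1
(Δδ¹³C 0.49 ± 4.7 ‰, Δδ¹⁵N 4.43 ± 1.32 ‰) is the empirically calculated
white-muscle value. TDF4 is published without uncertainties, so its SDs are
stored as 0.

## Dirichlet priors

Both prior kinds keep the total concentration Σα equal to the number of
sources n. The uniform ("generalist") prior sets αᵢ = 1, the conventional
uninformative mixing-model prior (the weaker αᵢ = 1/n reading is selectable
via `alpha_each` but not the default). The biomass prior sets
αᵢ = bᵢ·n/Σb from standing biomass bᵢ (mg C m⁻²); keeping Σα fixed means
biomass moves only the prior means E[pᵢ] = αᵢ/Σα, not the prior's overall
strength — a deliberately gentle ("less aggressive") standardization. A
source with unknown biomass can receive a neutral fill equal to the
arithmetic mean of the known biomasses, giving it an average prior mean
rather than biasing its contribution either way.

## The mixing model

For consumer j and tracer k (δ¹³C, δ¹⁵N):

    x_jk ~ Normal(μ_jk, s_jk)
    μ_jk  = Σᵢ p_jᵢ (μ_S,ik + μ_TDF,k)
    s_jk² = ξ_k · Σᵢ p_jᵢ² (σ_S,ik² + σ_TDF,k²)

with a global diet p ~ Dirichlet(α). A consumer random effect perturbs the
isometric log-ratio (ILR) transform of p with Normal(0, σ_re) deviations per
consumer, back-transformed to per-consumer diets p_j; a multiplicative error
scale ξ_k per tracer inflates (or deflates) the propagated source + TDF
variance to absorb sampling bias. No covariates enter the model — the
population is treated as unstructured apart from the consumer random effect.
Priors: ξ_k ~ Uniform(0, 20) and σ_re ~ Half-Normal(1); the error structure
is standard but no prior widths accompany it in the literature this follows,
so these are wide and explicit. With a single source the simplex forces
p = 1 and the fit returns the degenerate posterior without sampling.

The ILR transform uses the orthonormal Helmert basis: ilr(p) = H·clr(p) with
H the (n−1)×n Helmert submatrix. Any orthonormal basis gives the same
geometry (the test suite cross-checks the norm against scikit-bio's ILR);
back-transform is a softmax, exact to machine precision.

### Sampler

Blocked adaptive random-walk Metropolis on unconstrained coordinates
(ILR of p; the J×(n−1) consumer deviations, updated as J independent
per-consumer blocks in one vectorized step; log ξ_k; log σ_re). The Dirichlet
prior on ILR coordinates includes the log-Jacobian Σ log pᵢ; log-scale
updates of ξ and σ_re include their Jacobians. Proposal scales adapt by
Robbins–Monro (step t^−0.6) toward acceptance 0.28 for vector blocks and
0.44 for scalars — inside the 0.23–0.44 band that is optimal between the
multivariate and scalar limits — and are frozen after burn-in so the
retained chain is a valid Markov chain. Defaults: 3 chains from distinct
child seeds of a mandatory user seed (no silent default seed), 30,000
iterations, 15,000 burn-in, thinning 10. The tests and worked examples use
2–3 chains of 2,500–8,000 iterations, which the recovery experiments below
show is sufficient for the diet parameters at these data sizes; the
random-effect scale σ_re mixes slowest and is the parameter to watch in the
R-hat column.

### Diagnostics

* Split-chain Gelman–Rubin R̂ per scalar parameter; convergence is declared
  when all R̂ < 1.1. Identical chains give R̂ ≤ 1; chains centered far apart
  give R̂ ≫ 1.1.
* Geweke z compares the first 10% of a chain against the last 50%; window
  variances come from the spectral density at frequency zero estimated by an
  AIC-selected autoregressive fit (the classical `spectrum0.ar` estimator —
  Welch-type periodograms are biased low at f = 0 by per-segment mean
  removal). |z| < 1.96 on an iid chain in ≈95% of calibration simulations.

### Model comparison

Pointwise log-likelihoods (per consumer, summed over tracers) are stored for
every retained draw. PSIS-LOO and WAIC are computed through arviz on the
deviance scale; the comparison table mirrors the conventional layout
(LOOic, se_LOOic, dLOOic, se_dLOOic, weight), with the SE of each difference
from the pointwise criterion differences and an Akaike-type pseudo-weight
∝ exp(−dLOOic/2), normalized to sum to 1.

## Mixing-polygon validation

Each of the default 1,500 iterates draws every source vertex from
Normal(μ_S + μ_TDF, √(σ_S² + σ_TDF²)) per tracer (TDF uncertainty in
quadrature; a zone→TDF mapping is honored per source), forms the convex
hull, and tests each consumer for membership (boundary counts as inside;
collinear draws degrade to a segment test). A consumer passes when its
inclusion probability ≥ 0.05 — the published "inside the 95% mixing region"
convention, which the source literature applies but never states as a
number. With all SDs zero the test reduces to a deterministic
point-in-polygon decision.

## Trophic position

Two-baseline form: the littoral reliance α is taken from δ¹³C alone,
α = (δ¹³C_c − δ¹³C_b2)/(δ¹³C_b1 − δ¹³C_b2) clipped to [0, 1], and
TP = λ + (δ¹⁵N_c − [α δ¹⁵N_b1 + (1−α) δ¹⁵N_b2])/Δn. This is the canonical
two-source formulation; no δ¹⁵N correction is applied to the baselines
before mixing. Δn is a required parameter with presets 3.4 ‰ (literature
consensus) and 4.43 ‰ (the calculated trout value): published food-chain
lengths are acutely sensitive to this choice, so it must be explicit.
Food-chain length is the maximum TP over the supplied top consumers.

## Topology

Links are binary, predators in columns, prey in rows; self-links count
toward L and make a node non-basal. Directed connectance is C = L/N²
(consistent with the printed whole-lake values), not L/(N(N−1)). Species
richness S is node metadata summed over nodes, since many species aggregate
into one trophic node. Integer levels: basal = 1, consumer = 1 + max prey
level, self-loops ignored in the recursion; genuine consumer cycles fall
back to shortest-path-to-basal + 1 with a warning. Categories: basal (no
prey), herbivore (only basal prey), omnivore (prey on ≥ 2 distinct integer
levels — the standard rule, chosen because no formal definition accompanies
the printed fractions), predator (animal prey only). Sub-network link
counts bucket profundal with littoral as the benthic compartment, so
littoral + pelagic + coupling = L whenever every node has a zone.

## Synthetic data and the packaged fixture

`gen_mixing_dataset` simulates consumers from exactly the generative process
the sampler inverts, so recovery tests probe the inference, not model
mismatch. Defaults used in the recovery experiments: 3 well-separated
sources (SD 0.5 ‰), diet p* = (0.7, 0.2, 0.1), ξ = 1, σ_re = 0.05, 30
consumers — a deliberately favorable but realistic configuration (sources a
few ‰ apart, per-consumer noise under 1 ‰). Passing recovery shows the
sampler and model are correct under their own assumptions; it does not show
that real consumers satisfy them (isotopic routing, concentration
dependence and temporal baseline drift are all outside the model).
`gen_foodweb` draws webs whose generating categories are recoverable by
construction and hits a target connectance within ±20% when feasible.
Synthetic biomasses are log-uniform over two orders of magnitude, mimicking
the skew of real standing-stock tables without claiming any unpublished
values.

The packaged table (`data/table1_isotopes.csv`) carries the two lakes' group
means ± SD (14 groups in the stocked lake, 6 in the fishless one). Habitat
zones are not printed in the original summary table and were assigned from
the accompanying text (zooplankton, phytoplankton and trout pelagic;
*Tubifex*, *L. hoffmeisteri* and profundal sediment profundal; *L.
variegatus*, *Physa*, macroalgae, macrophytes and littoral sediment
littoral). Per-group sample sizes are not public, so fixture rows carry
n = 1 and individual consumers are, where needed, simulated around the
printed mean ± SD and labelled synthetic.

## Known limitations

* Two tracers only; the polygon test has no >2-tracer (simplex-volume)
  generalization here.
* No concentration weighting and no covariate effects in the mixing model.
* The random-walk sampler is simple and robust but not fast; hierarchical
  scale parameters (σ_re) mix slowly and dominate the R̂ budget.
* Published whole-lake food-chain lengths depend on unstated Δn choices and
  are not reproduced numerically; the module computes the canonical
  formulas with an explicit Δn instead.
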