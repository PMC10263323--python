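# isoweb

Stable-isotope food-web analysis for lake ecologists: who eats whom, in what
proportions, and what the resulting web looks like.

Two tracers carry most of the information in freshwater food-web studies:
δ¹³C (‰ vs VPDB) separates carbon sources — littoral/benthic production is
typically ¹³C-enriched relative to pelagic production — while δ¹⁵N (‰ vs
AIR) increases by a roughly constant discrimination Δ per trophic step.
`isoweb` turns per-sample measurements of consumers and per-source summary
tables into:

* **Trophic discrimination factors (TDFs)** — empirical Δδ¹³C/Δδ¹⁵N as the
  mean ± SD of consumer-minus-source differences, overall and by habitat
  zone, plus five published rainbow-trout presets (TDF1–TDF5).
* **Bayesian diet mixing models** — for consumer j and tracer k,
  x_jk ~ Normal(Σᵢ p_jᵢ(μ_S,ik + μ_TDF,k), s_jk) with
  s_jk² = ξ_k·Σᵢ p_jᵢ²(σ_S,ik² + σ_TDF,k²), a Dirichlet(α) prior on the diet
  p (uniform αᵢ = 1, or biomass-informed αᵢ = bᵢ·n/Σb), a per-consumer
  random effect on the isometric log-ratio scale, and a multiplicative
  error ξ_k per tracer. Sampling is by blocked adaptive random-walk
  Metropolis; diagnostics are split-chain Gelman–Rubin R̂ and Geweke z;
  model grids are ranked by PSIS-LOO or WAIC with Akaike-type weights.
* **Mixing-polygon validation** — the Monte-Carlo in-polygon test: consumers
  must fall inside the convex hull of TDF-corrected sources with
  probability ≥ 0.05 for the mixing model to be feasible at all.
* **Trophic position and food-chain length** — the two-baseline equation
  α = (δ¹³C_c − δ¹³C_b2)/(δ¹³C_b1 − δ¹³C_b2),
  TP = λ + (δ¹⁵N_c − [α δ¹⁵N_b1 + (1−α) δ¹⁵N_b2])/Δn.
* **Food-web topology** — from a 0/1 link matrix (predators as columns):
  links L, linkage densities L/S and L/N, directed connectance C = L/N²,
  basal/herbivore/omnivore/predator fractions, integer trophic levels and
  littoral/pelagic/coupling sub-network links.

A packaged two-lake isotope table (a fish-stocked and a fishless tropical
high-mountain lake) plus seeded synthetic-data generators make every stage
runnable and testable without any external data.

## Worked example

Recover a known diet from simulated consumers
(`examples/03_fit_mixing_model.py`):

```text
true diet: [0.7, 0.2, 0.1]
  p[A] = 0.711  95% CI [0.697, 0.726]
  p[B] = 0.189  95% CI [0.169, 0.208]
  p[C] = 0.100  95% CI [0.085, 0.115]
```

Thirty consumers were drawn from the model's own generative process at
p\* = (0.7, 0.2, 0.1); the posterior means land within ~0.01 of the truth
and every 95% credible interval covers it. Placing the stocked lake's top
predator between its littoral (gastropod) and pelagic (copepod) baselines
(`examples/05_trophic_position.py`):

```text
trout: alpha_littoral = 0.721, TP = 2.97 (delta_n = 3.4)
```

i.e. the trout draws ~72% of its carbon from the littoral pathway and sits
just below trophic level 3. Validating a TDF choice before trusting a
mixing model (`examples/04_polygon_validation.py`):

```text
TDF1: inclusion probabilities [0.926, 0.651, 0.965, ...] -> pass
TDF4: inclusion probabilities [0.247, 0.005, 0.444, ...] -> FAIL
```

TDF4 shifts the source polygon so far that several consumers fall outside
the 95% mixing region — diet proportions fitted under it would be
meaningless. The other examples cover priors, topology metrics and the full
5 × 2 TDF-by-prior model grid with its LOO comparison table.

There is also a thin CLI (`isoweb run-all --seed 42 --out results/`,
plus `simulate`, `tdf`, `prior`, `polygon`, `trophic`, `topology`
subcommands) over the same library calls.

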