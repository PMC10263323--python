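"""Fit the Bayesian mixing model to simulated consumers with a known diet.

Generates 30 consumers from a known diet p* = (0.7, 0.2, 0.1), fits the
model, and prints posterior means with 95% credible intervals — the means
should sit within a few hundredths of p*.
"""

from isoweb import (
    MixingModelSpec, SimulationTruth, SourceSummary, TDFSpec,
    fit, gen_mixing_dataset, uniform_prior,
)

sources = [
    SourceSummary("A", "pelagic", -10.0, 0.5, 0.0, 0.5, 5),
    SourceSummary("B", "pelagic", -20.0, 0.5, 5.0, 0.5, 5),
    SourceSummary("C", "littoral", -15.0, 0.5, 12.0, 0.5, 5),
]
tdf = TDFSpec("zero", 0.0, 0.0, 0.0, 0.0)

truth = SimulationTruth(true_p=[0.7, 0.2, 0.1], tdf=tdf, xi=(1.0, 1.0),
                        sigma_re=0.05, n_consumers=30, seed=11)
consumers, provenance = gen_mixing_dataset(truth, sources)

spec = MixingModelSpec(sources, tdf, uniform_prior([s.name for s in sources]))
post = fit(spec, consumers, chains=3, iterations=8000, burn=4000, thin=4, seed=1)

print("true diet:", truth.true_p.tolist())
ci = post.p_interval(0.95)
for i, s in enumerate(sources):
    print(f"  p[{s.name}] = {post.p_mean[i]:.3f}  95% CI [{ci[i,0]:.3f}, {ci[i,1]:.3f}]")
print(post.diagnostics.to_string(index=False))
# The credible intervals should cover the generating proportions, with
# R-hat near 1 on the diet parameters. The random-effect scale sigma_re is
# the slowest-mixing parameter; if its R-hat exceeds 1.1, lengthen the
# chains before trusting its summary.
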