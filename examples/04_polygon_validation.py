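"""Mixing-polygon validation of a proposed source + TDF configuration.

Simulates trout individuals around the fixture's population summary and
checks each against the Monte-Carlo mixing polygon of the six TDF-corrected
sources. A consumer passes when its inclusion probability is >= 0.05 (it
lies inside the 95% mixing region); a failing TDF choice means the mixing
model cannot explain those consumers at all.
"""

from isoweb import (
    load_tdf_presets, polygon_test, simulated_trout_consumers, trout_diet_sources,
)

sources = trout_diet_sources()
consumers = simulated_trout_consumers(n=9, seed=4)

for name in ("TDF1", "TDF4"):
    tdf = load_tdf_presets()[name]
    res = polygon_test(sources, tdf, consumers, iterates=1500, seed=7)
    status = "pass" if res.all_pass else "FAIL"
    print(f"{name}: inclusion probabilities "
          f"{[round(p, 3) for p in res.consumer_probs.tolist()]} -> {status}")
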