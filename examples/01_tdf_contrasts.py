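"""Zone-wise trophic discrimination factors for an introduced top predator.

Computes the mean difference between the rainbow trout's tissue values and
its candidate food sources, overall and split by habitat zone, from the
packaged two-lake isotope table.
"""

from isoweb import calc_tdf, calc_tdf_by_zone, trout_diet_sources, trout_summary

trout = trout_summary()
consumer = {"d13C": trout.mean_d13C, "d15N": trout.mean_d15N}
sources = trout_diet_sources()

overall = calc_tdf(consumer, sources)
print(f"overall TDF over the six candidate sources: "
      f"d13C {overall.mean_dC:+.2f} ± {overall.sd_dC:.2f} permil, "
      f"d15N {overall.mean_dN:+.2f} ± {overall.sd_dN:.2f} permil")

for zone, t in calc_tdf_by_zone(consumer, sources).items():
    print(f"  {zone:10s} d13C {t.mean_dC:+.2f} permil, d15N {t.mean_dN:+.2f} permil")

# A positive d13C contrast means the trout carries heavier carbon than the
# zone's sources (typical for pelagic prey); a negative one means littoral
# grazers are heavier than the trout itself, hence their negative carbon TDF.
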