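"""Two-baseline trophic position and food-chain length.

Places the top predator between a littoral (gastropod) and a pelagic
(copepod) primary-consumer baseline: delta13C sets the littoral reliance
alpha, delta15N then sets the continuous trophic position.
"""

from isoweb import (
    Baseline, DELTA_N_LITERATURE, food_chain_length, primary_consumer_baseline,
    table1_fixture, trophic_position_single, trophic_position_two_source,
)

table = {s.name: s for s in table1_fixture("El Sol")}
trout = table["Oncorhynchus mykiss"]
physa = table["Physa sp."]
lep = table["Leptodiaptomus cuauhtemoci"]

b_litt = Baseline(physa.name, physa.mean_d13C, physa.mean_d15N, lam=2)
b_pel = Baseline(lep.name, lep.mean_d13C, lep.mean_d15N, lam=2)
res = trophic_position_two_source(
    ("rainbow trout", trout.mean_d13C, trout.mean_d15N),
    b_litt, b_pel, delta_n=DELTA_N_LITERATURE,
)
print(f"trout: alpha_littoral = {res.alpha_littoral:.3f}, "
      f"TP = {res.trophic_position:.2f} (delta_n = {res.delta_n})")
print(f"stocked-lake food-chain length = {food_chain_length([res]):.2f}")

# the fishless lake: its cladoceran is the top consumer over phytoplankton
luna = {s.name: s for s in table1_fixture("La Luna")}
dap, phyto = luna["Daphnia ambigua"], luna["Bulk phytoplankton"]
res2 = trophic_position_single(
    ("Daphnia", dap.mean_d13C, dap.mean_d15N),
    Baseline("phytoplankton", phyto.mean_d13C, phyto.mean_d15N, lam=1),
    delta_n=DELTA_N_LITERATURE,
)
print(f"fishless-lake food-chain length = {res2.trophic_position:.2f}")

# gastropod baseline check: a grazer one step above its littoral producers
tl = primary_consumer_baseline(physa.mean_d15N, [-1.55, -1.2], DELTA_N_LITERATURE)
print(f"gastropod trophic level over littoral producers = {tl:.2f}")
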