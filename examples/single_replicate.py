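"""One full replicate at a 20% unreduced-gamete rate, narrated.

Thirty diploid founders grow to quasi-equilibrium for 199 generations; from
generation 200 diploids produce 20% unreduced gametes, triploids and
tetraploids begin to form, and the run stops at tetraploid fixation or after
1000 more generations.
"""

from polyestab import SimulationConfig, Simulation
from polyestab.experiments import config_for_level

cfg = config_for_level("unreduced", 0.20, SimulationConfig())
sim = Simulation(cfg, seed=1, record_census=True)
summary = sim.run()

print(f"stopped: {summary.stop_reason} at generation {summary.n_generations}")
print(f"final census (2x, 3x, 4x): {summary.final_census}")
print(f"final tetraploid proportion: {summary.final_4x_proportion:.2f}")
print(f"polyploidization events: {summary.bilateral_count} bilateral (2n+2n) + "
      f"{summary.unilateral_count} unilateral (2n+n)")
print(f"successful (SPE, lineage reached 50 tetraploids): {summary.spe_count}; "
      f"unsuccessful (UPE): {summary.upe_count}")
print(f"generations from onset to tetraploid fixation (GuF): {summary.guf}")
print(f"first polyploid to first 50-strong lineage (GPIP): {summary.gpip}")

print("\ncensus trajectory around the onset (generation: 2x/3x/4x):")
for g, n2, n3, n4 in sim.census_log[195:][::20]:
    print(f"  {g:4d}: {n2:5d} / {n3:4d} / {n4:5d}")
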