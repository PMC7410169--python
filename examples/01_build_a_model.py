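"""Build and inspect a demographic model with migration bands.

Constructs the default hominin model (two Africans, two Neanderthals, a
Denisovan, a chimpanzee outgroup and an unsampled super-archaic population)
and prints its discrete time grid, the snapped event times, and the
population paths available to each sampled lineage.
"""

from demarg import enumerate_paths, snap_to_half_time
from demarg.presets import deep_introgression_model

model = deep_introgression_model(t_mig=250e3, t_div=1.0e6)

print("time grid (kya):", [t / 1e3 for t in model.grid.coal_times])
print("half time-points near the leaves (kya):",
      [t / 1e3 for t in model.grid.half_times[:4]])
# user times snap onto half time-points; 1 Mya lands on 1075 kya
print("super-archaic divergence snapped to (kya):",
      snap_to_half_time(model, 1.0e6) / 1e3)

for band in model.bands:
    print(f"band {band.name}: t = {band.time / 1e3:g} kya, "
          f"prior p_M = {band.prior_rate}")

# Each lineage's population paths: resident, plus one per band it can take.
# A Neanderthal lineage has 3 (resident, via Hum->Nea, via Sup->Nea); the
# path count P drives the threading state space, O(L n k^2 P^2).
for pop in ("Afr", "Nea", "Den"):
    paths = enumerate_paths(model, pop)
    tags = ["resident" if p.band is None else model.bands[p.band].name
            for p in paths]
    print(f"{pop}: {len(paths)} paths ({', '.join(tags)})")
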