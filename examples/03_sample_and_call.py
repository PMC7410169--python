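"""Sample ARGs for a simulated window and call introgressed regions.

Runs a short MCMC on one 100 kb window with the three deep pulses, then
prints the region calls for each band and recipient individual next to the
simulator's truth tracts.  Chain settings here are demonstration-scale; a
production run uses 2000 iterations with 500 burn-in and every-20 sampling.
"""

import numpy as np

from demarg.calling import call_regions, posterior_tracks
from demarg.evaluate import basewise_rates, merge_intervals
from demarg.presets import deep_introgression_model
from demarg.sampler import ChainConfig, run_chain
from demarg.simulate import dataset_to_alignment, degrade, simulate_dataset

model = deep_introgression_model(t_mig=250e3, t_div=1.0e6)
ds = simulate_dataset(
    model, 100_000,
    admixture={"Afr->Nea": 0.08, "Sup->Den": 0.04, "Sup->Afr": 0.005},
    seed=37,
)
ds = degrade(ds, phase_randomize=True, seed=38)
aln = dataset_to_alignment(ds, compress=10)

cfg = ChainConfig(n_iter=100, burnin=40, thin=5, start_mig=15, seed=3)
samples = []
for r in run_chain(aln.ctx, model, cfg):
    if r.iteration % 20 == 0:
        print(f"iteration {r.iteration}: log-lik {r.loglik:.0f}, "
              f"migrant columns {r.migrant_columns}")
    if r.sample is not None:
        samples.append(r.sample)
print(f"{len(samples)} retained ARG samples\n")

ends = np.append(aln.starts[1:], aln.window_bp)
lin = {n: i for i, n in enumerate(model.lineage_names)}
for band, ind in [("Afr->Nea", "Altai"), ("Afr->Nea", "Vindija"),
                  ("Sup->Den", "Denisova")]:
    track = posterior_tracks(samples, model, band, ind, aln.starts, ends)
    calls = call_regions(track, threshold=0.5)
    pair = [lin[x] for x in dict(
        (s.sample_id, s) for s in model.samples)[ind].lineages]
    truth = merge_intervals(ds.truth[band][pair[0]] + ds.truth[band][pair[1]])
    r = basewise_rates([(c.start, c.end) for c in calls], truth, ds.window_bp)
    print(f"{band} in {ind}: {len(calls)} calls "
          f"({sum(c.length for c in calls)} bp), truth {r.truth_bp} bp, "
          f"basewise TP {r.tp_rate:.2f}, FP {r.fp_rate:.4f}")
    for c in calls:
        print(f"  [{c.start}, {c.end}) {c.zygosity} "
              f"mean posterior {c.mean_posterior:.2f}")
# TP is the fraction of truly introgressed bases recovered at p >= 0.5;
# FP the fraction of non-introgressed bases wrongly called for this band.
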