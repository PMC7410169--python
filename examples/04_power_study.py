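"""A miniature power / false-positive study.

Replicates the simulation-study design at desk scale: a couple of windows
with the standard pulses analysed end to end, plus no-migration control
windows for false positives.  Full-scale studies use a hundred 2 Mb windows
and 2000-iteration chains; expect desk-scale numbers to be noisy.
"""

from demarg.study import StudyConfig, deep_study

cfg = StudyConfig(n_windows=2, window_bp=60_000, compress=20,
                  n_iter=50, burnin=20, thin=3, start_mig=8)

power = deep_study(cfg, seed=101, t_mig=250e3, t_div=1.0e6,
                   require_truth_band="Afr->Nea")
controls = deep_study(cfg, seed=102, t_mig=250e3, t_div=1.0e6, admixture={})

r = power.band_rates("Afr->Nea")
print(f"Hum->Nea power (t_mig = 250 ky): basewise TP {r['tp_rate']:.2f} "
      f"over {r['truth_bp']} truth bp")
for band in ("Afr->Nea", "Sup->Den", "Sup->Nea", "Afr->Den"):
    rc = controls.band_rates(band)
    print(f"false positives, {band}: {rc['fp_rate']:.4f} "
          f"over {rc['neg_bp']} bp")
# TP is measured only on truly introgressed bases of the right band in the
# right individual; FP comes exclusively from the no-migration controls.
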