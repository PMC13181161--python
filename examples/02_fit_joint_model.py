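"""Fit the location-scale joint model to simulated data.

Samples the joint posterior with the built-in NUTS sampler and prints the
posterior summary for the parameters practitioners read first: the event
covariate effects and the four association coefficients (mean and WIV of
each biomarker), including hazard ratios.  Problem size is kept small so
the example runs in about a minute.
"""

from jointwiv import SimulationConfig, fit, simulate_dataset, summarise_fit

config = SimulationConfig(n_subjects=150, seed=2)
long_data, surv_data, truth = simulate_dataset(config)

result = fit(long_data, surv_data, chains=2, warmup=250, draws=250, seed=7, max_depth=6)
print(f"divergences: {result.divergences}, max R-hat: {result.max_rhat():.3f}")

table = summarise_fit(result)
rows = ["gamma_w1", "gamma_w2", "alpha_mu1", "alpha_sigma1", "alpha_mu2", "alpha_sigma2"]
print(f"{'parameter':14s} {'truth':>7s} {'mean':>7s} {'2.5%':>7s} {'97.5%':>7s} {'HR':>6s}")
for name in rows:
    r = table.loc[name]
    print(
        f"{name:14s} {truth[name]:+7.3f} {r['mean']:+7.3f} "
        f"{r['q2_5']:+7.3f} {r['q97_5']:+7.3f} {r['hr']:6.2f}"
    )
# A positive alpha_sigma means higher within-individual variability of that
# biomarker raises the hazard; at N=150 the intervals are wide but should
# bracket the generating values.
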