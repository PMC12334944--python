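"""Why a 3-result history routes to the population formula: a Monte-Carlo study.

With n = 3 steady-state results the individual route multiplies the
(noisily estimated) CV_T by t(0.95, 2 df) = 4.30 and sqrt(1 + 1/3), so its
interval is typically twice as wide as at n = 10 — often wider than the
population reference interval, which defeats the purpose. The experiment
quantifies that, and checks the population route's coverage stays near the
nominal 95%.
"""

from persoref import MeasurandSim, SimulationConfig, recovery_experiment

cfg = SimulationConfig({"analyte": MeasurandSim(5.0, 8.0, 2.0)}, seed=11)
out = recovery_experiment(cfg, replicates=500)

w3 = out["width_ind_small"]
w10 = out["width_ind_large"]
cov = out["coverage_pop_small"]
print(f"mean prRI_ind width, n=3 history : {w3['mean']:.3f}  (MC SE {w3['mc_se']:.3f})")
print(f"mean prRI_ind width, n=10 history: {w10['mean']:.3f}  (MC SE {w10['mc_se']:.3f})")
print(f"width ratio n=3 / n=10           : {w3['mean'] / w10['mean']:.2f}")
print(f"prRI_pop coverage with n=3       : {cov['mean']:.3f}  (nominal 0.95)")
print(
    "\nAt a true CV_T of ~8.2% the n=3 individual-route interval is about"
    "\ntwice the n=10 one, while the population route keeps ~95% coverage"
    "\neven with the short history — the quantitative basis for recommending"
    "\nthe population route when fewer than 5 steady-state results exist."
)
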