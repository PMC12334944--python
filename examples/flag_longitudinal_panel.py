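"""Flag a simulated infection episode under five criteria and compare counts.

Simulates the default case-like panel (10 measurands, 11 time points from
day -10 to day 115, acute-phase fold-changes on the leukocyte lineages over
days 0-14), estimates each set point from the simulated 3-result history,
and pools flagged-to-total ratios per criterion.
"""

from persoref import RunConfig, case_config, estimate_hsp, flag_panel, simulate_panel
from persoref.case_table import load_case

panel = simulate_panel(case_config(seed=7))
hsps = {name: estimate_hsp(hist) for name, hist in panel.hsp_history.items()}
profiles = [r.profile for r in load_case()]

reports, summary = flag_panel(panel.series, profiles, hsps, RunConfig())

print(f"{panel.n_results} simulated results "
      f"({len(panel.series)} measurands x {len(panel.config.days)} days)\n")
for criterion, s in summary.items():
    print(f"  {criterion:9s} {s['ratio']:>7s} flagged")
print(
    "\nThe personalized criteria (prRI_pop, RCV_pop) flag far more of the"
    "\nepisode than the population interval (popRI): an individual whose set"
    "\npoint sits mid-range can deviate pathologically while staying inside"
    "\nthe population limits. This is the sensitivity ordering the method is"
    "\ndesigned to exploit for longitudinal monitoring."
)
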