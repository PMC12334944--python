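"""Generate a synthetic longitudinal panel and write the CSV interfaces.

Shows the generator contract: seeded determinism, multiplicative
within-person plus analytical noise around each true set point, excursion
windows with known fold-changes, and the long-format files the compute/flag
pipeline consumes (results, steady-state history, truth labels).
"""

import tempfile
from pathlib import Path

from persoref import case_config, simulate_panel
from persoref.io import write_panel

cfg = case_config(seed=42)
panel = simulate_panel(cfg)
again = simulate_panel(case_config(seed=42))
assert panel.series == again.series, "same seed, same panel"

outdir = Path(tempfile.mkdtemp()) / "panel"
paths = write_panel(panel, outdir)
for kind, path in paths.items():
    print(f"{kind:12s} -> {path}  ({len(path.read_text().splitlines()) - 1} rows)")

leuk = panel.series["leukocytes"]
print("\nleukocytes (x10^9/L):")
for (day, value), exc in zip(leuk.points, panel.in_excursion["leukocytes"]):
    marker = "  <- excursion window (fold 1.35)" if exc else ""
    print(f"  day {day:4d}: {value:5.2f}{marker}")
print(
    "\nValues fluctuate around the true set point (4.8) with ~9.4% biological"
    "\nand 1.26% analytical noise; days 0-14 are scaled by the configured"
    "\nacute-phase fold-change. Truth labels record exactly which points were"
    "\nperturbed, so detection methods can be scored against ground truth."
)
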