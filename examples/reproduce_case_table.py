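"""Recompute every derived cell of the packaged case table and check agreement.

Each published cell (intervals, RCVs, CV_T, II) is recomputed from the
printed input columns and compared at the printed precision.
"""

from persoref import reproduce_case_table

report = reproduce_case_table()
print(report.to_string(index=False))

agree = int(report["agrees"].sum())
known = report[~report["agrees"]]
print(f"\n{agree}/{len(report)} cells agree within one unit of the last printed digit.")
print("Cells that cannot be recovered from the printed inputs (the source")
print("computed them from unrounded patient data):")
print(known[["measurand", "cell", "recomputed", "published"]].to_string(index=False))
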