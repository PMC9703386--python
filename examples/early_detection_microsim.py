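"""Microsimulation: what would earlier detection buy, after lead-time correction?

Simulates 200,000 tumours detected at 15 mm from the joint model, removes
the metastases that would never have been seeded had each tumour been
removed 1-3 years earlier, and prints 5-year distant-metastasis risks by
growth-rate tertile — both naively (clock at the earlier diagnosis) and
corrected for lead time (clock fixed at the 15 mm date).
"""

from natmet import reference_params
from natmet.simulate import MicrosimScenario, microsim_early_detection

params = reference_params("frank")
scenario = MicrosimScenario(n_tumours=200_000, seed=7)
table = microsim_early_detection(scenario, params)

rows = table[(table.node_group == 0) & (table.scenario.isin(["baseline", "time"]))]
print("node-negative tumours, 5-year risk of distant metastasis (%)")
print(f"{'earlier by':>11} | {'fast':>12} | {'medium':>12} | {'slow':>12}   (naive / corrected)")
for val, sub in rows.groupby("value"):
    cells = []
    for tert in ("fast", "medium", "slow"):
        row = sub[sub.tertile == tert].iloc[0]
        cells.append(f"{100*row.naive_risk:5.2f}/{100*row.corrected_risk:5.2f}")
    print(f"{val:>9.0f} y | {cells[0]:>12} | {cells[1]:>12} | {cells[2]:>12}")

print()
print("Corrected risks fall with earlier detection only where seeding was")
print("still to come: fast-growing tumours (small inverse growth rate) gain")
print("the most, slow tumours almost nothing. Naive risks mix in lead time")
print("and cannot be compared across detection dates.")
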