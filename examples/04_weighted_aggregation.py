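"""Aggregate per-conflict MASE scores into a single weighted figure.

Given one MASE score per conflict and a weight per conflict (the
maximum refugee count each conflict reached), the weighted average
sum(w*m)/sum(w) summarises forecast skill across conflicts — the
aggregation used for multi-conflict comparison tables.
"""

from campflow import weighted_mase

weights = {"Burundi": 205_445, "CAR": 424_496, "Mali": 89_991}
per_conflict = {
    "flat_w7": {"Burundi": 0.279, "CAR": 0.585, "Mali": 0.23},
    "slope_w30": {"Burundi": 0.0639, "CAR": 0.0367, "Mali": 0.116},
}

for column, cells in per_conflict.items():
    avg = weighted_mase(cells, weights)
    print(f"{column}: per-conflict {cells} -> weighted average {avg:.3g}")
print("Each conflict contributes in proportion to how many people it")
print("displaced, so the biggest crisis dominates the headline score.")
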