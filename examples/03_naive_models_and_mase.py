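"""Score the simulation against naive extrapolators with MASE.

Three baselines consume a warmup of observed data (7 or 30 days): flat
holds the day-w camp count, slope extrapolates the day-0 to day-w trend,
fraction keeps the day-w camp shares of the (known) total. MASE divides
the simulation's averaged error over the whole run by the baseline's
averaged error after its warmup; below 1 means the simulation wins.
"""

from campflow import (ScenarioSpec, Simulation, frame_from_run,
                      generate_scenario, generate_twin_data, mase_table)

scenario = generate_scenario(ScenarioSpec(seed=0))
registrations, _ = generate_twin_data(scenario, seed=10)

run = Simulation.from_scenario(scenario, seed=11).run(100)
frame = frame_from_run(run, registrations)
table = mase_table(frame, warmups=(7, 30), scaled=True)
print(table.round(4).to_string(index=False))
print("Columns are {model}_w{warmup}. Values below 1 mean the simulation's")
print("error is smaller than that baseline's over its prediction window.")
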