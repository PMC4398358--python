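"""Monte-Carlo convergence of the step-settings sweep.

For a moving-machine scenario, repeat-to-repeat scatter of the predicted
LAeq at fixed receivers shrinks as the number of simulation steps grows:
more steps let the walker cover its subarea, so the time-average
stabilises.  The printed column is the between-repeat standard deviation
of LAeq (dB), averaged over the receivers.
"""

from noisewalk import MappingArea, RectRegion, Scenario, experiment_grid
from noisewalk.machinery import DutyCycleProbs, Machine, WalkParams

scenario = Scenario(
    area=MappingArea(40, 24, background_level=48.4),
    moving=[Machine(label="D", kind="moving", lwa_full=108.0,
                    duty=DutyCycleProbs(0.7, 0.0, 0.3),
                    subarea=RectRegion(4, 4, 16, 16),
                    walk=WalkParams(max_step=5.0))],
)
receivers = [(2.0, 2.0), (38.0, 12.0), (20.0, 22.0)]

table = experiment_grid(scenario, [100, 250, 500, 1000, 1500], repeats=5,
                        receiver_points=receivers, base_seed=0)
scatter = table.groupby(["n_steps", "receiver"])["laeq"].std().groupby("n_steps").mean()
print("steps  between-repeat std of LAeq, dB")
for n_steps, sd in scatter.items():
    print(f"{n_steps:>5d}  {sd:.3f}")
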