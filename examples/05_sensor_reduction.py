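"""How many sensors does the array actually need?

Cross-validates every nonempty subset of the six sensors (63 runs) and
reports the best subset of each size.  With informative transient
features, small arrays - even a single well-chosen sensor - can come
close to the full array.
"""

from dataclasses import replace

from enose import synthetic
from enose.experiments import best_per_size, sensor_subset_experiment
from enose.features import build_feature_table
from enose.model_eval import CVConfig

cfg = replace(synthetic.default_scenario(seed=9),
              sampling_rate_hz=5.0, phase_durations_s=(4.0, 20.0, 24.0),
              bottles_per_class={"HQ": 3, "AQ": 3, "LQ": 3, "Ea": 3},
              samples_per_bottle=(6, 8))
table = build_feature_table(synthetic.generate_dataset(cfg))

results = sensor_subset_experiment(table, CVConfig(n_repeats=10, seed=0))
print(f"evaluated {len(results)} sensor subsets\n")
print("best subset per array size:")
for r in best_per_size(results):
    sensors = "+".join(map(str, r.sensor_subset))
    print(f"  {len(r.sensor_subset)} sensor(s) [{sensors:11s}] "
          f"accuracy {r.mean_accuracy:.3f} +- {r.std_accuracy:.3f} "
          f"({r.n_features_used} features)")
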