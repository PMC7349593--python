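"""Extract the 828-feature catalogue from one transient measurement.

Each measurement is reduced to 23 curve-shape features per (sensor,
signal, segment) cell: 6 sensors x 2 baseline-normalized signals (R/R0,
G/G0) x 3 segments (adsorption, desorption, full) x 23 = 828 columns.
"""

from enose import synthetic
from enose.features import extract_features

cfg = synthetic.default_scenario(seed=1)
dataset = synthetic.generate_dataset(cfg)
meas = dataset.measurements[0]

vec, ids = extract_features(meas)
print(f"feature vector length: {len(vec)}")

print("\nfeatures of sensor 1, conductance, adsorption segment:")
for fid, v in zip(ids, vec):
    if fid.sensor == 1 and fid.signal == "G" and fid.segment == "ads":
        print(f"  {fid.render():35s} = {v: .4f}")
# G/G0 peaks well above 1 for a responding sensor; the exponential-fit
# tau is the adsorption time constant in seconds, and the t_frac* values
# are the times to reach 10/25/50% of the response range.
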