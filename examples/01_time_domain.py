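"""Time-domain indices of a single synthetic recording.

Generates a 10-minute beat series with realistic resting variability,
computes the ten time-domain indices and prints them with units.
"""

from easyhrv import compute_time_indices
from easyhrv.synthetic import SyntheticSpec, gen_rr

series, _ = gen_rr(SyntheticSpec(duration_s=600.0, seed=1))
ti = compute_time_indices(series)

print(f"{len(series)} beats over {series.duration_s:.0f} s")
for name, value in ti.as_dict().items():
    unit = {"pNN50": "%", "HRVi": ""}.get(name, "ms")
    print(f"  {name:8s} {value:8.2f} {unit}")

# SDNN is the overall variability; rMSSD/pNN50/SDSD capture beat-to-beat
# (vagally mediated) variability; SDANN/SDNNIDX split variability into
# between- and within-5-minute-window components; TINN and HRVi describe
# the RR histogram geometry.
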