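"""Adaptive artifact filtering of a corrupted beat series.

Injects 5% false detections and 2% missed detections into a clean
recording, runs the filter, and scores it against the corruption map.
"""

import numpy as np

from easyhrv import filter_beats
from easyhrv.synthetic import SyntheticSpec, corrupt, gen_rr

clean, _ = gen_rr(SyntheticSpec(duration_s=900.0, seed=4))
noisy, cmap = corrupt(clean, artifact_rate=0.05, deletion_rate=0.02, seed=5)
filtered, log = filter_beats(noisy)

labels = np.array(cmap["labels"])
removed = np.zeros(len(noisy.rr), dtype=bool)
for entry in log.entries:
    removed[entry["beat_index"]] = True

spurious = labels == "spurious"
clean_iv = labels == "clean"
print(f"{len(noisy.rr)} intervals, {cmap['n_inserted']} inserted, "
      f"{cmap['n_deleted']} deleted")
print(f"filter removed {len(log)} beats")
print(f"  spurious caught: {(removed & spurious).sum()}/{spurious.sum()}")
print(f"  clean removed:   {(removed & clean_iv).sum()}/{clean_iv.sum()}")

# A good filter catches nearly all injected artifacts while losing well
# under 2% of untouched intervals; the removal log (reason per beat) can
# be exported with log.to_frame(recording_id).
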