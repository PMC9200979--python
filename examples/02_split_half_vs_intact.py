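"""Why crown volumes are measured on split halves.

Injects a blind-area defect (the unphotographable patch where a crown
rests on the background sheet) into densely packed synthetic crowns,
repairs them, and compares two volume protocols against the voxel
oracle: measuring the repaired intact crown, and splitting first then
repairing each half.  The intact repair amalgamates inter-root crevices
at a voxel size tied to the whole crown's bounding box; halves are
remeshed at finer resolution, so their summed volume is less biased.
"""

import numpy as np

from crownpheno import (generate_crown, inject_blind_area_defect,
                        random_crown_spec, signed_volume)
from crownpheno.prep import close_holes, remove_stem
from crownpheno.traits import crown_volume_split

print("crown   oracle   intact(err%)    split(err%)")
wins = 0
n = 6
for seed in range(1, n + 1):
    spec = random_crown_spec(seed, n_roots=(10, 14),
                             length_range=(12.0, 20.0),
                             basal_radius_range=(2.2, 3.2),
                             hub_radius_cm=5.0)
    full, truth = generate_crown(spec)
    crown = remove_stem(full)
    defect = inject_blind_area_defect(crown, truth.support_normal, 1.5)
    intact = signed_volume(close_holes(defect))
    split = crown_volume_split(defect, support_normal=truth.support_normal)
    o = truth.oracle_volume
    e_i, e_s = 100 * (intact - o) / o, 100 * (split - o) / o
    wins += abs(e_s) < abs(e_i)
    print(f"{seed:5d} {o:8.0f} {intact:8.0f} ({e_i:+5.2f}) "
          f"{split:8.0f} ({e_s:+5.2f})")
print(f"\nsplit-half closer to truth on {wins}/{n} crowns; positive "
      "intact errors are the\ncrevice amalgamation the split protocol "
      "suppresses.")
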