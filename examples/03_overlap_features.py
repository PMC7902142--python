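"""Extract the two-element deviation feature that the classifier uses.

The F-GEI is thresholded (Otsu) into a high-energy mask; each subject's
per-frame overlap with that mask is summarized as (mean, std). Normal
walkers cover the mask consistently; a posturally deviant walker does not.
"""

import numpy as np

from gaitanomaly import CohortSpec, generate_cohort
from gaitanomaly.energy import compute_fgei_batch, compute_gei
from gaitanomaly.features import (
    feature_vector,
    overlap_vector,
    segment_energy_mask,
    select_threshold,
)
from gaitanomaly.preprocess import clean_sequence

seqs, _ = generate_cohort(
    CohortSpec(n_normal=10, n_abnormal=4, effect_size=3.0, seed=2, shuffle=False)
)
clean = [clean_sequence(s) for s in seqs]
fgei = compute_fgei_batch([compute_gei(s) for s in clean])
T = select_threshold(fgei, "otsu")
mask = segment_energy_mask(fgei, T)
print(f"Otsu threshold T = {T:.1f}; energy mask covers {mask.n_on} pixels")

print(f"{'subject':>8} {'label':>9} {'mean':>7} {'std':>7}")
for s in clean:
    v = feature_vector(overlap_vector(s, mask))
    print(f"{s.subject_id:>8} {s.true_label:>9} {v.mean:7.3f} {v.std:7.3f}")
print(
    "Normal subjects overlap ~95% of the mask every frame; the leaning "
    "walkers sit well below — the gap in 'mean' is the classification signal."
)
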