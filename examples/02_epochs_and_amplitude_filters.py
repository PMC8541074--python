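"""Cut labeled trial windows and apply the two amplitude filters.

Each mark yields a 40 × 2048 epoch (≈4.1 s).  Stage 1 rejects broken
epochs (non-finite values, dead channels, grossly saturated totals);
stage 2 trims everything above the 95th percentile of the total absolute
amplitude, so roughly 5% of the surviving epochs go.
"""

import numpy as np

from silentspeech import (
    SynthConfig, extract_epochs, filter_stage1, filter_stage2, generate_recording,
)

cfg = SynthConfig(n_subjects=1, sessions_per_subject=10, seed=2)
rec, _ = generate_recording(cfg)
es = extract_epochs(rec)
print(f"extracted {len(es)} epochs of shape {es[0].data.shape}")

# sabotage a couple of epochs the way real acquisitions fail
es[3].data[7, 100] = np.nan          # amplifier glitch
es[11].data[2, :] = 0.0              # dead electrode

after1 = filter_stage1(es)
after2 = filter_stage2(after1)
s1, s2 = after2.provenance["stage1"], after2.provenance["stage2"]
print(f"stage 1: {s1['input']} -> {s1['output']} "
      f"(non-finite {s1['removed_nonfinite']}, dead channel {s1['removed_zero_channel']}, "
      f"over cap {s1['removed_over_cap']})")
print(f"stage 2: {s2['input']} -> {s2['output']} "
      f"(cutoff = 95th percentile of total |amplitude| = {s2['cutoff']:.3g} µV·samples)")
# The provenance dict documents exactly what each filter removed and why.
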