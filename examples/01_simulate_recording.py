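"""Generate a synthetic multichannel recording with planted coupling.

Builds a two-entry coupling plan (constant-lag alpha1 phase coupling and
theta->gamma phase-amplitude modulation), writes the recording to the
native HDF5 container, reads it back, and prints the per-band relative
power of each channel.
"""

import numpy as np

from dicmflex import (
    BAND_NAMES,
    CouplingEntry,
    gen_recording,
    read_recording,
    relative_power,
    write_recording,
)

plan = [
    CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9),
    CouplingEntry((2, 3), "pac", "theta", "gamma", strength=1.0),
]
rec = gen_recording(4, fs=170.0, duration_s=20.0, plan=plan, seed=7)

path = write_recording(rec, "scratch_recording.h5")
back = read_recording(path)
print(f"wrote and re-read {back.n_channels} channels x {back.n_samples} "
      f"samples at {back.fs:g} Hz")

rp = relative_power(back)
print("\nrelative power (fraction of 0.5-45 Hz power per band):")
print("band     " + "  ".join(f"{ch:>6}" for ch in back.channel_names))
for b, name in enumerate(BAND_NAMES):
    print(f"{name:<8} " + "  ".join(f"{rp[b, c]:6.3f}"
                                    for c in range(back.n_channels)))
print("\nEvery channel carries the full 8-band background; the planted "
      "couplings shift extra power into alpha1 (ch0/ch1), theta (ch2) "
      "and gamma (ch3).")
np.testing.assert_allclose(back.data, rec.data, atol=1e-9)
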