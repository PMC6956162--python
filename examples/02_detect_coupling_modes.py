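"""Identify the dominant coupling mode of a sensor pair, window by window.

A depth-1.0 theta->gamma phase-amplitude coupling is planted on a channel
pair; the pipeline band-filters the recording, slides 2-s windows in 0.2-s
steps, tests every estimator x frequency-code candidate against 200
circular-shift surrogates, FDR-filters at q=0.01, and keeps up to two
coupling-mode records per window.
"""

from collections import Counter

from dicmflex import (
    CouplingEntry,
    Estimator,
    bands_of_code,
    BAND_NAMES,
    cross_code,
    gen_recording,
)
from dicmflex.preprocessing import filterbank, make_windows
from dicmflex.surrogate_stats import dicm_pipeline

rec = gen_recording(
    2, fs=170.0, duration_s=12.0,
    plan=[CouplingEntry((0, 1), "pac", "theta", "gamma", strength=1.0)],
    seed=3,
)
banded = filterbank(rec)
scheme = make_windows(rec)
print(f"{scheme.T} temporal segments of {scheme.window_s:g}s "
      f"(step {scheme.step_s:g}s)")

tensor, diag = dicm_pipeline(banded, scheme, n_surr=200, seed=4)
print(f"surrogate-tested candidates: {diag.n_candidates}; "
      f"FDR-retained: {diag.n_fdr_retained}")


def describe(est, code):
    lo, hi = bands_of_code(int(code))
    band = (BAND_NAMES[lo] if hi is None
            else f"{BAND_NAMES[lo]}->{BAND_NAMES[hi]}")
    return f"{Estimator(int(est)).name} {band}"


counts = Counter()
for t in range(tensor.T):
    for slot in range(2):
        if tensor.code[slot, t, 0] > 0:
            counts[describe(tensor.est[slot, t, 0],
                            tensor.code[slot, t, 0])] += 1

print("\nretained coupling-mode records on the pair (windows):")
for mode, n in counts.most_common(5):
    print(f"  {mode:<22} {n:3d} / {tensor.T}")

target = cross_code("theta", "gamma")
hit = ((tensor.est == 3) & (tensor.code == target)).any(axis=0)[:, 0]
print(f"\nplanted PAC theta->gamma retained in {hit.mean():.0%} of windows")
print("The directed phase-lag index flags the same planted phase relation "
      "(the modulation is applied in quadrature), so both records "
      "typically co-occur — the two-slot design of the mode tensor.")
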