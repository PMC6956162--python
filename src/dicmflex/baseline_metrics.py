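"""Static comparison measures: relative power, imaginary coherence,
multiscale entropy.

These are the conventional non-dynamic baselines against which the
coupling-mode features are benchmarked: band-wise relative spectral power
(Welch, 2-s segments, 50% overlap, normalized by total 0.5-45 Hz power),
the magnitude of the imaginary part of coherency averaged over band bins
(insensitive to zero-lag mixing), and multiscale sample entropy
(non-overlapping coarse-graining, m = 2, tolerance r = 0.2 x the original
signal's standard deviation — the literature defaults, exposed as
parameters).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .codes import BANDS, N_BANDS
from .signal_io import LobarLayout, Recording

TOTAL_RANGE = (0.5, 45.0)


def _welch(rec: Recording, x: np.ndarray | None = None):
    nperseg = min(int(round(2.0 * rec.fs)), rec.n_samples)
    data = rec.data if x is None else x
    return sps.welch(data, fs=rec.fs, nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def relative_power(rec: Recording) -> np.ndarray:
    """Band x channel relative power within the total 0.5-45 Hz range."""
    if rec.duration_s < 4.0:
        raise ValueError("relative power needs at least 4 s of data")
    freqs, psd = _welch(rec)
    # rectangular bin summation: half-open bands tile the axis without
    # double counting, unlike trapezoids whose endpoints are halved
    total_mask = (freqs >= TOTAL_RANGE[0]) & (freqs < TOTAL_RANGE[1])
    total = psd[:, total_mask].sum(axis=-1)
    out = np.empty((N_BANDS, rec.n_channels))
    for b, (_, lo, hi) in enumerate(BANDS):
        mask = (freqs >= lo) & (freqs < hi)
        out[b] = psd[:, mask].sum(axis=-1) / np.maximum(total, 1e-300)
    return out


def imaginary_coherence(rec: Recording, pair: tuple[int, int],
                        band: tuple[float, float] | int | str) -> float:
    """|Im coherency| of a channel pair over one band.

    Per-bin imaginary coherency magnitudes are averaged with cross-power
    weights so that bins carrying actual signal dominate the band value.
    """
    if rec.duration_s < 4.0:
        raise ValueError("imaginary coherence needs at least 4 s of data")
    if isinstance(band, str):
        from .codes import BAND_INDEX

        band = BAND_INDEX[band]
    if isinstance(band, (int, np.integer)):
        _, lo, hi = BANDS[int(band)]
    else:
        lo, hi = band
    i, j = pair
    nperseg = min(int(round(2.0 * rec.fs)), rec.n_samples)
    freqs, sxy = sps.csd(rec.data[i], rec.data[j], fs=rec.fs,
                         nperseg=nperseg, noverlap=nperseg // 2)
    _, sxx = sps.welch(rec.data[i], fs=rec.fs, nperseg=nperseg,
                       noverlap=nperseg // 2)
    _, syy = sps.welch(rec.data[j], fs=rec.fs, nperseg=nperseg,
                       noverlap=nperseg // 2)
    weight = np.sqrt(np.maximum(sxx * syy, 1e-300))
    coherency = sxy / weight
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) contains no spectral bins")
    im = np.abs(np.imag(coherency[mask]))
    return float(np.sum(im * weight[mask]) / np.sum(weight[mask]))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln of the conditional template-match probability.

    ``r`` defaults to 0.2 x sd(x).  A constant signal has entropy 0 (every
    template matches); zero m+1 matches yields +inf.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    if r is None:
        r = 0.2 * np.std(x)
    if r == 0.0 and np.ptp(x) == 0.0:
        return 0.0  # constant signal: all templates match at any tolerance

    def count_matches(length: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, length)
        d = pdist(emb, metric="chebyshev")
        return int(np.sum(d <= r))

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0:
        return float("inf")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def multiscale_entropy(
    x: np.ndarray,
    m: int = 2,
    r_factor: float = 0.2,
    scales: range | tuple[int, ...] = range(1, 11),
) -> np.ndarray:
    """Sample entropy of non-overlapping coarse-grained series per scale.

    The tolerance is ``r_factor`` x the *original* signal's sd at every
    scale, the standard convention.  Requires at least 100 x max(scale)
    samples.
    """
    x = np.asarray(x, dtype=float)
    scales = list(scales)
    if len(x) < 100 * max(scales):
        raise ValueError(
            f"need at least {100 * max(scales)} samples for scale "
            f"{max(scales)}, got {len(x)}"
        )
    r = r_factor * np.std(x)
    out = []
    for s in scales:
        n_blocks = len(x) // s
        coarse = x[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)
        if np.ptp(coarse) == 0.0:
            out.append(0.0)
            continue
        out.append(sample_entropy(coarse, m=m, r=r))
    return np.array(out)


def lobe_average(values: np.ndarray, rec: Recording,
                 layout: LobarLayout) -> dict[tuple[str, str], np.ndarray]:
    """Average per-channel features over each lobe-hemisphere group."""
    out = {}
    for (lobe, hemi), _ in layout.groups().items():
        idx = layout.indices(rec.channel_names, lobe, hemi)
        if len(idx):
            out[(lobe, hemi)] = np.asarray(values)[..., idx].mean(axis=-1)
    return out


def baseline_feature_table(rec: Recording, layout: LobarLayout | None = None,
                           mse_channel_limit: int | None = None) -> dict[str, float]:
    """A flat feature dictionary (plugs into the age-prediction models)."""
    feats: dict[str, float] = {}
    rp = relative_power(rec)
    for b, name in enumerate(n[0] for n in BANDS):
        for c, ch in enumerate(rec.channel_names):
            feats[f"rp_{name}_{ch}"] = float(rp[b, c])
    channels = range(rec.n_channels if mse_channel_limit is None
                     else min(rec.n_channels, mse_channel_limit))
    for c in channels:
        mse = multiscale_entropy(rec.data[c], scales=range(1, 6))
        for s, v in enumerate(mse, start=1):
            feats[f"mse_{rec.channel_names[c]}_s{s}"] = float(v)
    return feats
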