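"""Filterbank decomposition, downsampling and sliding-window segmentation.

Band-limited versions of each channel are obtained with a 3rd-order
Butterworth band-pass applied forward and backward (zero-phase; effective
order 6), and the analytic signal (Hilbert transform) supplies amplitude
envelopes and instantaneous phases.  Coupling statistics are evaluated in
2-s windows advanced in 0.2-s steps: a 3-min recording at 170 Hz (30,600
samples, step 34) or at 150 Hz (27,000 samples, step 30) yields exactly
T = 900 temporal segments.  Windows overrunning the end of the recording
are truncated at the last sample rather than wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .codes import BANDS, N_BANDS
from .signal_io import Recording

#: Default window and step, in seconds.  The window equals two cycles of
#: the slowest (delta) activity so that delta-paced cross-frequency
#: modulation is preserved within every segment.
WINDOW_S = 2.0
STEP_S = 0.2


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_fs``.

    The rational resampling factor is taken exactly from the two rates;
    the output is trimmed to ``round(duration_s * target_fs)`` samples.
    """
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample: target {target_fs} > fs {rec.fs}")
    if target_fs == rec.fs:
        return Recording(rec.data.copy(), rec.fs, list(rec.channel_names), rec.system)
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(
        rec.fs
    ).limit_denominator(10**6)
    out = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    n_expected = int(round(rec.duration_s * target_fs))
    out = out[:, :n_expected]
    return Recording(out, float(target_fs), list(rec.channel_names), rec.system)


@dataclass
class BandedSignalSet:
    """Per band x channel: filtered signal, Hilbert envelope and phase.

    Arrays have shape (n_bands, n_channels, n_samples).
    """

    filtered: np.ndarray
    envelope: np.ndarray
    phase: np.ndarray
    fs: float
    channel_names: list[str]

    @property
    def n_bands(self) -> int:
        return self.filtered.shape[0]

    @property
    def n_channels(self) -> int:
        return self.filtered.shape[1]

    @property
    def n_samples(self) -> int:
        return self.filtered.shape[2]


def band_sos(lo: float, hi: float, fs: float, order: int = 3) -> np.ndarray:
    """Butterworth band-pass second-order sections for one band."""
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def filterbank(rec: Recording, order: int = 3) -> BandedSignalSet:
    """Decompose a recording into the 8 canonical bands.

    Each band is filtered with a zero-phase Butterworth band-pass and
    Hilbert-transformed.  Requires a Nyquist frequency above the top of
    the gamma band (45 Hz).
    """
    if rec.fs / 2.0 <= BANDS[-1][2]:
        raise ValueError(
            f"fs={rec.fs} too low for the {BANDS[-1][0]} band "
            f"({BANDS[-1][1]}-{BANDS[-1][2]} Hz)"
        )
    n_ch, n_samp = rec.data.shape
    filtered = np.empty((N_BANDS, n_ch, n_samp))
    for b, (_, lo, hi) in enumerate(BANDS):
        sos = band_sos(lo, hi, rec.fs, order)
        filtered[b] = sps.sosfiltfilt(sos, rec.data, axis=1)
    analytic = sps.hilbert(filtered, axis=2)
    return BandedSignalSet(
        filtered=filtered,
        envelope=np.abs(analytic),
        phase=np.angle(analytic),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )


@dataclass
class WindowScheme:
    """Sliding-window segmentation: start/stop sample indices per segment."""

    starts: np.ndarray
    stops: np.ndarray
    window_s: float
    step_s: float
    fs: float

    @property
    def T(self) -> int:
        """Number of temporal segments."""
        return len(self.starts)

    def slices(self) -> list[slice]:
        return [slice(int(a), int(b)) for a, b in zip(self.starts, self.stops)]


def make_windows(
    n_samples: int | Recording,
    fs: float | None = None,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> WindowScheme:
    """Build the sliding-window scheme over ``n_samples`` at rate ``fs``.

    ``T = floor(n_samples / step_samples)``; trailing windows are truncated
    at the final sample.  A recording shorter than one window is an error.
    """
    if isinstance(n_samples, Recording):
        fs = n_samples.fs
        n_samples = n_samples.n_samples
    if fs is None:
        raise TypeError("fs is required when n_samples is an integer")
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if step < 1:
        raise ValueError(f"step {step_s}s is below one sample at fs={fs}")
    if n_samples < win:
        raise ValueError(
            f"recording of {n_samples} samples is shorter than one "
            f"{window_s}-s window ({win} samples)"
        )
    T = n_samples // step
    starts = np.arange(T, dtype=int) * step
    stops = np.minimum(starts + win, n_samples)
    return WindowScheme(starts=starts, stops=stops, window_s=window_s,
                        step_s=step_s, fs=float(fs))
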