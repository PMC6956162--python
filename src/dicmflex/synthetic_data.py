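"""Synthetic recordings and cohorts with planted coupling structure.

Every downstream stage of the pipeline is exercised on data whose coupling
content is known by construction: band-limited background activity with a
1/f-like spectral envelope, onto which the generator superimposes

* shared-modulator amplitude-envelope coupling (AEC),
* constant-lag phase coupling (iPLV),
* phase-amplitude modulation of a high-band carrier by a low-band phase
  (PAC) — applied in quadrature by default, representing a propagation lag,
  because strictly zero-lag modulation is invisible to an imaginary-part
  phase-locking detector,
* delayed directed coupling (dSTE),
* delayed phase-lead coupling (dPLI),

optionally restricted to an active time range, and switching between whole
coupling regimes every ``dwell_s`` seconds to drive the flexibility index.
Cohorts follow a quadratic flexibility-age curve with Gaussian noise; the
default curve peaks near age 40 and the default age distribution follows
six age-group bins (8-12, 13-17, 18-27, 28-37, 38-50, 51-60 years) with
sizes proportional to a 178-participant reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .codes import BAND_INDEX, BANDS
from .signal_io import Recording

MODES = ("aec", "iplv", "pac", "dste", "dpli")

#: 1/f-like per-band amplitude weights for the background mixture
_BAND_CENTERS = np.array([(lo + hi) / 2.0 for _, lo, hi in BANDS])
_BAND_WEIGHTS = (1.0 / np.sqrt(_BAND_CENTERS))
_BAND_WEIGHTS = _BAND_WEIGHTS / np.linalg.norm(_BAND_WEIGHTS)


def _band_range(band: int | str) -> tuple[float, float]:
    i = BAND_INDEX[band] if isinstance(band, str) else int(band)
    return BANDS[i][1], BANDS[i][2]


def gen_band_noise(
    band: tuple[float, float] | int | str,
    fs: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean, unit-variance noise with its power confined to ``band``.

    Synthesized in the frequency domain (random phases on the in-band
    Fourier bins), so essentially all spectral power lies inside the band.
    """
    if isinstance(band, (int, str)) and not isinstance(band, bool):
        lo, hi = _band_range(band)
    else:
        lo, hi = band
    if hi >= fs / 2.0:
        raise ValueError(f"band upper edge {hi} Hz at or above Nyquist ({fs / 2})")
    if lo <= 0 or lo >= hi:
        raise ValueError(f"invalid band ({lo}, {hi})")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError(f"duration {duration_s}s too short at fs={fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spectrum = np.zeros(len(freqs), dtype=complex)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) contains no Fourier bins at n={n}")
    phases = rng.uniform(0, 2 * np.pi, size=mask.sum())
    spectrum[mask] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass(frozen=True)
class CouplingEntry:
    """One planted coupling: a channel pair, a mode and its parameters."""

    pair: tuple[int, int]
    mode: str                         # one of MODES
    low_band: int | str = "alpha1"
    high_band: int | str | None = None   # PAC / cross-band dSTE only
    strength: float = 1.0
    delay: int = 3                    # samples (dste / dpli)
    phase_lag: float = np.pi / 2      # radians (iplv)
    mod_phase: float = np.pi / 2      # modulation phase offset (pac)
    snr: float = 8.0                  # planted-to-background amplitude ratio
    active: tuple[float, float] | None = None  # seconds; None = whole record


@dataclass
class CouplingPlan:
    entries: list[CouplingEntry] = field(default_factory=list)

    def validate(self, n_channels: int, duration_s: float) -> None:
        spans: list[tuple[frozenset, int, float, float]] = []
        for e in self.entries:
            if e.mode not in MODES:
                raise ValueError(f"unknown coupling mode {e.mode!r}")
            if not 0.0 <= e.strength <= 1.0:
                raise ValueError(f"strength must be in [0,1], got {e.strength}")
            i, j = e.pair
            if not (0 <= i < n_channels and 0 <= j < n_channels and i != j):
                raise ValueError(f"invalid channel pair {e.pair}")
            lo = BAND_INDEX[e.low_band] if isinstance(e.low_band, str) else e.low_band
            if not 0 <= lo < len(BANDS):
                raise ValueError(f"unknown band {e.low_band!r}")
            if e.high_band is not None:
                hb = (BAND_INDEX[e.high_band] if isinstance(e.high_band, str)
                      else e.high_band)
                if hb <= lo:
                    raise ValueError("high band must lie above the low band")
            t0, t1 = e.active if e.active else (0.0, duration_s)
            if not (0.0 <= t0 < t1 <= duration_s + 1e-9):
                raise ValueError(f"active range {e.active} outside the recording")
            key = (frozenset(e.pair), lo, t0, t1)
            for other in spans:
                if other[0] == key[0] and other[1] == lo and not (
                    t1 <= other[2] or t0 >= other[3]
                ):
                    raise ValueError(
                        f"conflicting plan entries on pair {e.pair}, band {lo}"
                    )
            spans.append((frozenset(e.pair), lo, t0, t1))


def _flat_carrier(band: int, fs: float, duration_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Constant-envelope carrier: cos of the Hilbert phase of band noise.

    The phase noise is confined to the middle third of the band and the
    intrinsic envelope fluctuations are removed, so multiplicative
    modulation (AEC and PAC entries) imposes exactly the planted envelope
    and the modulation sidebands stay inside the band's filter.
    """
    lo, hi = _band_range(band)
    width = hi - lo
    x = gen_band_noise((lo + width / 3.0, hi - width / 3.0), fs, duration_s, rng)
    return np.cos(np.angle(sps.hilbert(x)))


def _active_mask(n: int, fs: float, active: tuple[float, float] | None) -> np.ndarray:
    if active is None:
        return np.ones(n)
    mask = np.zeros(n)
    mask[int(round(active[0] * fs)): int(round(active[1] * fs))] = 1.0
    return mask


def gen_recording(
    n_channels: int,
    fs: float,
    duration_s: float,
    plan: CouplingPlan | list[CouplingEntry] | None = None,
    seed: int = 0,
    background_scale: float = 1.0,
    channel_names: list[str] | None = None,
) -> Recording:
    """Generate a multichannel recording with planted coupling structure.

    Each channel carries an independent 8-band background mixture; every
    plan entry superimposes its coupling on the designated pair, scaled so
    that the planted component dominates the corresponding band at
    ``strength`` near 1 and drowns in background at ``strength`` near 0.
    """
    if plan is None:
        plan = CouplingPlan()
    elif isinstance(plan, list):
        plan = CouplingPlan(entries=plan)
    plan.validate(n_channels, duration_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    data = np.zeros((n_channels, n))
    for c in range(n_channels):
        for b in range(len(BANDS)):
            data[c] += background_scale * _BAND_WEIGHTS[b] * gen_band_noise(
                b, fs, duration_s, rng
            )
    for e in plan.entries:
        i, j = e.pair
        lo = BAND_INDEX[e.low_band] if isinstance(e.low_band, str) else int(e.low_band)
        hb = None
        if e.high_band is not None:
            hb = (BAND_INDEX[e.high_band] if isinstance(e.high_band, str)
                  else int(e.high_band))
        mask = _active_mask(n, fs, e.active)
        w_lo = background_scale * _BAND_WEIGHTS[lo]
        amp = e.snr * e.strength * w_lo
        if e.mode == "iplv":
            base = gen_band_noise(lo, fs, duration_s, rng)
            za = sps.hilbert(base)
            data[i] += amp * mask * np.real(za)
            data[j] += amp * mask * np.real(za * np.exp(-1j * e.phase_lag))
        elif e.mode == "dpli":
            base = gen_band_noise(lo, fs, duration_s, rng)
            data[i] += amp * mask * base
            data[j] += amp * mask * np.roll(base, e.delay)
        elif e.mode == "aec":
            bj = lo if hb is None else hb
            w_hi = background_scale * _BAND_WEIGHTS[bj]
            mod = gen_band_noise((0.5, 2.0), fs, duration_s, rng)
            mi = gen_band_noise((0.5, 2.0), fs, duration_s, rng)
            mj = gen_band_noise((0.5, 2.0), fs, duration_s, rng)
            rho = np.sqrt(e.strength)
            env_i = np.clip(1.0 + 0.45 * (rho * mod + np.sqrt(1 - rho**2) * mi), 0.05, None)
            env_j = np.clip(1.0 + 0.45 * (rho * mod + np.sqrt(1 - rho**2) * mj), 0.05, None)
            data[i] += e.snr * w_lo * mask * env_i * _flat_carrier(lo, fs, duration_s, rng)
            data[j] += e.snr * w_hi * mask * env_j * _flat_carrier(bj, fs, duration_s, rng)
        elif e.mode == "pac":
            if hb is None:
                raise ValueError("PAC entries need a high band")
            w_hi = background_scale * _BAND_WEIGHTS[hb]
            driver = gen_band_noise(lo, fs, duration_s, rng)
            phi = np.angle(sps.hilbert(driver))
            carrier = _flat_carrier(hb, fs, duration_s, rng)
            d = e.strength
            envelope = 1.0 - d + d * (1.0 + np.cos(phi - e.mod_phase)) / 2.0
            data[i] += e.snr * w_lo * mask * driver
            data[j] += e.snr * w_hi * mask * envelope * carrier
        elif e.mode == "dste":
            src = gen_band_noise(lo, fs, duration_s, rng)
            data[i] += amp * mask * src
            if hb is None:
                noise = gen_band_noise(lo, fs, duration_s, rng)
                data[j] += amp * mask * (np.roll(src, e.delay) + 0.3 * noise)
            else:
                # directed cross-frequency flow: delayed low-band activity
                # modulates the high-band carrier of the target channel
                w_hi = background_scale * _BAND_WEIGHTS[hb]
                carrier = _flat_carrier(hb, fs, duration_s, rng)
                phi = np.angle(sps.hilbert(np.roll(src, e.delay)))
                envelope = 1.0 - e.strength + e.strength * (1.0 + np.cos(phi)) / 2.0
                data[j] += e.snr * w_hi * mask * envelope * carrier
    names = channel_names or [f"ch{c}" for c in range(n_channels)]
    return Recording(data=data, fs=fs, channel_names=names, system="synthetic")


def gen_switching_recording(
    n_channels: int,
    fs: float,
    duration_s: float,
    modes: list[CouplingPlan | list[CouplingEntry]],
    dwell_s: float,
    seed: int = 0,
    window_s: float = 2.0,
    background_scale: float = 1.0,
) -> Recording:
    """Recording whose coupling regime switches between ``modes``.

    Regime ``k`` of the cycle is active during dwell segment ``k``; the
    dwell time must be at least one analysis window long.
    """
    if dwell_s < window_s:
        raise ValueError(
            f"dwell {dwell_s}s is shorter than the analysis window {window_s}s"
        )
    plans = [p if isinstance(p, CouplingPlan) else CouplingPlan(entries=p)
             for p in modes]
    entries: list[CouplingEntry] = []
    n_seg = int(np.ceil(duration_s / dwell_s))
    for s in range(n_seg):
        t0 = s * dwell_s
        t1 = min((s + 1) * dwell_s, duration_s)
        if t1 <= t0:
            break
        for e in plans[s % len(plans)].entries:
            entries.append(replace(e, active=(t0, t1)))
    return gen_recording(n_channels, fs, duration_s, CouplingPlan(entries),
                         seed=seed, background_scale=background_scale)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Age-group bins (years) and reference sizes of the 178-participant cohort.
AGE_BINS: tuple[tuple[int, int], ...] = (
    (8, 12), (13, 17), (18, 27), (28, 37), (38, 50), (51, 60)
)
AGE_BIN_SIZES: tuple[int, ...] = (24, 26, 43, 43, 28, 14)

#: Default quadratic flexibility-age curve FI = a*age^2 + b*age + c; peaks
#: at age -b/(2a) = 40 years.
DEFAULT_FI_CURVE = (-0.0002, 0.016, 0.1)


@dataclass
class CohortPlan:
    """Parameters of a synthetic cohort."""

    n: int = 178
    fi_curve: tuple[float, float, float] = DEFAULT_FI_CURVE
    noise_sd: float = 0.02
    group: str = "HP"
    fi_offset: float = 0.0            # additive group shift of FI
    n_features: int = 22
    feature_shift: float = 0.0        # per-age-group mean separation, in sd
    age_sampler: object = None        # callable (rng, size) -> ages, optional

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")


def _default_ages(rng: np.random.Generator, size: int) -> np.ndarray:
    counts = np.array(AGE_BIN_SIZES, dtype=float)
    probs = counts / counts.sum()
    bins = rng.choice(len(AGE_BINS), size=size, p=probs)
    lo = np.array([b[0] for b in AGE_BINS])[bins]
    hi = np.array([b[1] for b in AGE_BINS])[bins]
    return lo + rng.uniform(0, 1, size=size) * (hi - lo)


def age_group_of(ages: np.ndarray) -> np.ndarray:
    """Index of the age bin each age falls into (clipped to the bin range)."""
    edges = np.array([b[0] for b in AGE_BINS[1:]])
    return np.searchsorted(edges, ages, side="right")


def gen_cohort(plan: CohortPlan, seed: int = 0) -> pd.DataFrame:
    """Sample a cohort table: id, age, group, age_group, FI and features.

    The fast path used throughout: FI follows the quadratic age curve with
    Gaussian noise (clamped to [0, 1]) and feature vectors are Gaussian with
    per-age-group mean shifts of ``feature_shift`` standard deviations.
    """
    rng = np.random.default_rng(seed)
    sampler = plan.age_sampler or _default_ages
    ages = np.asarray(sampler(rng, plan.n), dtype=float)
    a, b, c = plan.fi_curve
    fi = a * ages**2 + b * ages + c + plan.fi_offset
    fi = fi + rng.normal(0.0, plan.noise_sd, size=plan.n)
    fi = np.clip(fi, 0.0, 1.0)
    groups = age_group_of(ages)
    table = pd.DataFrame({
        "id": [f"{plan.group}{k:04d}" for k in range(plan.n)],
        "age": ages,
        "group": plan.group,
        "age_group": groups,
        "fi": fi,
    })
    if plan.n_features:
        means = plan.feature_shift * groups[:, None]
        feats = means + rng.normal(0.0, 1.0, size=(plan.n, plan.n_features))
        for f in range(plan.n_features):
            table[f"feat_{f:02d}"] = feats[:, f]
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("feat_")]
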