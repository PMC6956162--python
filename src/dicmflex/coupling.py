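"""The five windowed coupling estimators.

Estimator ids (see :mod:`dicmflex.codes`):

1. AEC   — amplitude envelope correlation: Pearson correlation of Hilbert
   envelopes, within or across bands; strength = |r|.
2. iPLV  — same-frequency imaginary phase-locking value
   ``|Im mean_t exp(i(phi_a - phi_b))|``; insensitive to zero-lag coupling.
3. PAC   — phase-amplitude coupling via cross-frequency iPLV: the high-band
   envelope is re-filtered within the low band, Hilbert-phase extracted, and
   phase-locked against the low-band phase.
4. dSTE  — delay symbolic transfer entropy on neural-gas-symbolized state
   vectors, scanned over a grid of delays; reports strength, direction, delay.
5. dPLI  — directed phase-lag index: probability that one phase leads the
   other (0.5 = no lead); strength = 2|dPLI - 0.5|.  Cross-band dPLI uses the
   PAC-style envelope phase.

All strengths are normalized to [0, 1].  Fast "all circular shifts at once"
variants back the surrogate null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .codes import (
    ADMISSIBLE_CODES,
    BANDS,
    N_CODES,
    Estimator,
    bands_of_code,
)
from .preprocessing import BandedSignalSet, WindowScheme, band_sos

_MIN_LEN = 8


def _check_len(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < _MIN_LEN:
        raise ValueError(f"need at least {_MIN_LEN} samples, got {len(a)}")


# ---------------------------------------------------------------------------
# Analytic estimators
# ---------------------------------------------------------------------------

def aec(env_a: np.ndarray, env_b: np.ndarray) -> float:
    """Pearson correlation of two amplitude envelopes (NaN if degenerate)."""
    _check_len(env_a, env_b)
    sa, sb = np.std(env_a), np.std(env_b)
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((env_a - env_a.mean()) * (env_b - env_b.mean())) / (sa * sb))


def iplv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Imaginary phase-locking value, in [0, 1]."""
    _check_len(phase_a, phase_b)
    return float(np.abs(np.imag(np.mean(np.exp(1j * (phase_a - phase_b))))))


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into [-pi, pi)."""
    return np.mod(dphi + np.pi, 2.0 * np.pi) - np.pi


def dpli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Directed phase-lag index: mean Heaviside of the wrapped phase
    difference, with H(0) = 0.5.  1 = a leads, 0 = b leads, 0.5 = no lead."""
    _check_len(phase_a, phase_b)
    d = wrap_phase(np.asarray(phase_a) - np.asarray(phase_b))
    return float(np.mean(np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))))


def dpli_strength(value: float) -> float:
    """Map a dPLI value to a symmetric coupling strength in [0, 1]."""
    return float(2.0 * abs(value - 0.5))


def envelope_band_phase(
    env: np.ndarray, low_band: tuple[float, float] | int, fs: float, order: int = 3
) -> np.ndarray:
    """Hilbert phase of a high-band envelope re-filtered within a low band.

    This is the cross-frequency carrier used by PAC and cross-band dPLI.
    """
    if isinstance(low_band, (int, np.integer)):
        _, lo, hi = BANDS[int(low_band)]
    else:
        lo, hi = low_band
    sos = band_sos(lo, hi, fs, order)
    filt = sps.sosfiltfilt(sos, env, axis=-1)
    return np.angle(sps.hilbert(filt, axis=-1))


def pac(
    phase_low: np.ndarray,
    env_high: np.ndarray,
    low_band: tuple[float, float] | int,
    fs: float,
) -> float:
    """Phase-amplitude coupling strength: iPLV between the low-band phase of
    one sensor and the low-band phase of the other sensor's high-band
    envelope."""
    if isinstance(low_band, (int, np.integer)):
        b_lo = int(low_band)
        _, lo, hi = BANDS[b_lo]
    else:
        lo, hi = low_band
    # high band must lie above the modulating band for PAC to be defined
    return iplv(phase_low, envelope_band_phase(env_high, (lo, hi), fs))


# ---------------------------------------------------------------------------
# Row-vectorized estimators (surrogate machinery)
#
# Surrogates circularly shift one channel of a pair over the *whole*
# recording and re-window, so each surrogate window keeps its natural
# within-window autocorrelation (no wrap seam inside a window) while the
# cross-channel alignment is destroyed.  The helpers below evaluate each
# estimator for a stack of shifted windows at once.
# ---------------------------------------------------------------------------

def shifted_window_indices(sl: slice, shifts: np.ndarray, n_total: int) -> np.ndarray:
    """(n_shifts, window) sample indices of the window slid by each shift."""
    return (np.arange(sl.start, sl.stop)[None, :]
            + np.asarray(shifts, dtype=int)[:, None]) % n_total


def iplv_rows(za_rows: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """iPLV of each phasor row against the fixed phasor window ``zb``."""
    return np.abs(np.imag(np.mean(za_rows * np.conj(zb)[None, :], axis=1)))


def aec_rows(ea_rows: np.ndarray, eb: np.ndarray) -> np.ndarray:
    """Pearson r of each envelope row against the fixed window ``eb``."""
    sb = eb.std()
    sa = ea_rows.std(axis=1)
    cov = (ea_rows * eb[None, :]).mean(axis=1) - ea_rows.mean(axis=1) * eb.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / (sa * sb)


def dpli_rows(pa_rows: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """dPLI of each phase row against the fixed phase window ``pb``."""
    d = wrap_phase(pa_rows - pb[None, :])
    return np.mean(np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5)), axis=1)


# ---------------------------------------------------------------------------
# Neural gas symbolization and delay symbolic transfer entropy
# ---------------------------------------------------------------------------

def neural_gas_codebook(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_epochs: int = 5,
    eps: tuple[float, float] = (0.5, 0.01),
    lam: tuple[float, float] | None = None,
    refine_iters: int = 5,
) -> np.ndarray:
    """Neural-gas vector quantization: ``k`` prototypes for state vectors X.

    Prototypes are updated by rank of distance to each presented sample with
    exponentially annealed step size ``eps`` and neighbourhood range ``lam``,
    then polished with a few batch (Lloyd) iterations.  ``k=1`` reduces to the
    exact quantization-error minimizer, the global mean.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x dims)")
    n_unique = len(np.unique(X, axis=0))
    if n_unique < k:
        raise ValueError(f"need at least k={k} distinct state vectors, got {n_unique}")
    if k == 1:
        return X.mean(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    # distinct initial prototypes
    init_idx = rng.choice(len(X), size=len(X), replace=False)
    seen: list[int] = []
    for i in init_idx:
        if not any(np.array_equal(X[i], X[j]) for j in seen):
            seen.append(i)
        if len(seen) == k:
            break
    W = X[seen].copy()
    if lam is None:
        lam = (k / 2.0, 0.01)
    t_max = max(1, n_epochs * len(X))
    order = rng.integers(0, len(X), size=t_max)
    for t, i in enumerate(order):
        frac = t / t_max
        eps_t = eps[0] * (eps[1] / eps[0]) ** frac
        lam_t = lam[0] * (lam[1] / lam[0]) ** frac
        d = np.linalg.norm(W - X[i], axis=1)
        ranks = np.argsort(np.argsort(d))
        W += (eps_t * np.exp(-ranks / lam_t))[:, None] * (X[i] - W)
    for _ in range(refine_iters):
        assign = np.argmin(cdist(X, W), axis=1)
        for j in range(k):
            members = X[assign == j]
            if len(members):
                W[j] = members.mean(axis=0)
    return W


def embed(x: np.ndarray, dim: int = 3, lag: int = 1) -> np.ndarray:
    """Time-delay embedding: rows ``[x_t, x_{t+lag}, ..., x_{t+(dim-1)lag}]``."""
    x = np.asarray(x, dtype=float)
    m = len(x) - (dim - 1) * lag
    if m < 1:
        raise ValueError("series too short for the requested embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (dim - 1) * lag + 1)[:, ::lag]


def symbolize(x: np.ndarray, codebook: np.ndarray, dim: int = 3, lag: int = 1) -> np.ndarray:
    """Map a continuous series to nearest-prototype symbol indices."""
    E = embed(x, dim, lag)
    return np.argmin(cdist(E, codebook), axis=1).astype(np.int64)


def _te_from_counts(counts: np.ndarray, k: int) -> np.ndarray:
    """Transfer entropy (nats / log k) from joint counts of shape
    (..., k, k, k) indexed (target future, target past, source past)."""
    n = counts.sum(axis=(-1, -2, -3), keepdims=True).astype(float)
    p = counts / np.maximum(n, 1.0)
    p_b0a = p.sum(axis=-3, keepdims=True)          # (.., 1, k, k)
    p_b1b0 = p.sum(axis=-1, keepdims=True)         # (.., k, k, 1)
    p_b0 = p.sum(axis=(-1, -3), keepdims=True)     # (.., 1, k, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log(p * p_b0 / (p_b0a * p_b1b0))
    log_term[~np.isfinite(log_term)] = 0.0
    te = (p * log_term).sum(axis=(-1, -2, -3))
    return np.maximum(te, 0.0) / np.log(k)


def symbolic_te(src: np.ndarray, tgt: np.ndarray, k: int, delay: int = 1) -> float:
    """TE(src -> tgt) at the given delay, on symbol series from a shared or
    per-band codebook of size ``k``; normalized to [0, 1] by log k."""
    return float(symbolic_te_many(src[None, :], tgt[None, :], k, delay)[0])


def symbolic_te_profile(
    src: np.ndarray, tgt: np.ndarray, k: int, delays
) -> np.ndarray:
    """TE(src -> tgt) for every delay in one pass.

    All delays share the common valid time range of the largest delay, so
    the profile is comparable across delays.
    """
    src = np.asarray(src)
    tgt = np.asarray(tgt)
    delays = np.asarray(list(delays), dtype=int)
    n = len(src)
    d_max = int(delays.max())
    t = np.arange(d_max - 1, n - 1)
    if len(t) < 4:
        raise ValueError("series too short for this delay grid")
    base = (tgt[t + 1] * k + tgt[t]) * k
    joint = base[None, :] + src[t[None, :] + 1 - delays[:, None]]
    offsets = (np.arange(len(delays)) * k**3)[:, None]
    counts = np.bincount((joint + offsets).ravel(), minlength=len(delays) * k**3)
    return _te_from_counts(counts.reshape(len(delays), k, k, k), k)


def _te_of_joint(joint: np.ndarray, k: int) -> np.ndarray:
    """TE per row of a (rows, time) joint-state index array."""
    rows = joint.shape[0]
    offsets = (np.arange(rows) * k**3)[:, None]
    counts = np.bincount((joint + offsets).ravel(), minlength=rows * k**3)
    return _te_from_counts(counts.reshape(rows, k, k, k), k)


def symbolic_te_many(
    src: np.ndarray, tgt: np.ndarray, k: int, delay: int = 1
) -> np.ndarray:
    """Vectorized TE over rows of ``src``/``tgt`` (broadcast on axis 0)."""
    src = np.atleast_2d(np.asarray(src))
    tgt = np.atleast_2d(np.asarray(tgt))
    S = max(src.shape[0], tgt.shape[0])
    src = np.broadcast_to(src, (S, src.shape[1]))
    tgt = np.broadcast_to(tgt, (S, tgt.shape[1]))
    n = src.shape[1]
    t = np.arange(delay - 1, n - 1)
    if len(t) < 4:
        raise ValueError("series too short for this delay")
    joint = (tgt[:, t + 1] * k + tgt[:, t]) * k + src[:, t + 1 - delay]
    return _te_of_joint(joint, k)


@dataclass
class DsteResult:
    strength: float
    direction: int      # +1: a -> b, -1: b -> a, 0: degenerate
    delay: int
    te_ab: float
    te_ba: float
    delay_ab: int
    delay_ba: int
    degenerate: bool = False


def dste(
    sym_a: np.ndarray,
    sym_b: np.ndarray,
    k: int,
    delays: range | tuple[int, ...] = range(1, 11),
) -> DsteResult:
    """Delay symbolic transfer entropy between two symbol series.

    Scans TE in both directions over the delay grid; the direction is the
    larger best-delay TE and the net strength is ``|TE_ab - TE_ba| / max``.
    Constant symbol series are flagged degenerate with zero strength.
    """
    sym_a = np.asarray(sym_a)
    sym_b = np.asarray(sym_b)
    if len(np.unique(sym_a)) < 2 or len(np.unique(sym_b)) < 2:
        return DsteResult(0.0, 0, 0, 0.0, 0.0, 0, 0, degenerate=True)
    te_ab = symbolic_te_profile(sym_a, sym_b, k, delays)
    te_ba = symbolic_te_profile(sym_b, sym_a, k, delays)
    d_list = list(delays)
    i_ab, i_ba = int(np.argmax(te_ab)), int(np.argmax(te_ba))
    best_ab, best_ba = float(te_ab[i_ab]), float(te_ba[i_ba])
    top = max(best_ab, best_ba)
    if top <= 0.0:
        return DsteResult(0.0, 0, 0, best_ab, best_ba, d_list[i_ab], d_list[i_ba])
    strength = abs(best_ab - best_ba) / top
    direction = 1 if best_ab >= best_ba else -1
    delay = d_list[i_ab] if direction == 1 else d_list[i_ba]
    return DsteResult(strength, direction, delay, best_ab, best_ba,
                      d_list[i_ab], d_list[i_ba])


def te_pair_at(
    src: np.ndarray,
    tgt: np.ndarray,
    k: int,
    delay_ab: int,
    delay_ba: int,
    d_max: int,
) -> tuple[float, float]:
    """TE in both directions at fixed delays over a shared time range."""
    n = len(src)
    t = np.arange(d_max - 1, n - 1)
    if len(t) < 4:
        raise ValueError("series too short for this delay grid")
    joint_ab = ((tgt[t + 1] * k + tgt[t]) * k + src[t + 1 - delay_ab])[None, :]
    joint_ba = ((src[t + 1] * k + src[t]) * k + tgt[t + 1 - delay_ba])[None, :]
    te = _te_of_joint(np.concatenate([joint_ab, joint_ba]), k)
    return float(te[0]), float(te[1])


def dste_strength_rows(
    a_rows: np.ndarray,
    sym_b: np.ndarray,
    k: int,
    delay_ab: int,
    delay_ba: int,
    d_max: int | None = None,
) -> np.ndarray:
    """Net dSTE strength per shifted symbol row at fixed per-direction
    delays — the surrogate statistic matching the fixed-delay observed
    statistic of the windowed pipeline."""
    a_rows = np.atleast_2d(np.asarray(a_rows))
    S, n = a_rows.shape
    if d_max is None:
        d_max = max(delay_ab, delay_ba)
    t = np.arange(d_max - 1, n - 1)
    if len(t) < 4:
        raise ValueError("series too short for this delay grid")
    b1b0 = (sym_b[t + 1] * k + sym_b[t]) * k
    joint_ab = b1b0[None, :] + a_rows[:, t + 1 - delay_ab]
    joint_ba = (a_rows[:, t + 1] * k + a_rows[:, t]) * k + sym_b[t + 1 - delay_ba]
    te = _te_of_joint(np.concatenate([joint_ab, joint_ba]), k)
    te_ab, te_ba = te[:S], te[S:]
    top = np.maximum(np.maximum(te_ab, te_ba), 1e-300)
    return np.abs(te_ab - te_ba) / top


# ---------------------------------------------------------------------------
# Dense candidate evaluation across windows / pairs / estimators / codes
# ---------------------------------------------------------------------------

@dataclass
class DsteConfig:
    """Symbolization and delay-scan parameters for dSTE.

    ``lag=None`` selects a band-adaptive embedding lag of about a quarter
    period of the band's upper edge (at least one sample), so embedded
    state vectors of slow, heavily oversampled bands are not collinear.
    """

    dim: int = 3
    lag: int | None = None
    k: int = 8
    delays: tuple[int, ...] = tuple(range(1, 11))
    train_size: int = 2000  # state vectors subsampled for codebook training

    def lag_for(self, band: int, fs: float) -> int:
        if self.lag is not None:
            return int(self.lag)
        f_hi = BANDS[band][2]
        return max(1, int(round(fs / (4.0 * f_hi))))


@dataclass
class PrecomputedBands:
    """Shared per-recording caches used by the estimators.

    ``env_phase[(lo_band, hi_band)]`` holds, per channel, the Hilbert phase
    of the hi-band envelope re-filtered within the lo band (full length, so
    windows are obtained by slicing); ``symbols[band]`` holds per-channel
    neural-gas symbol series.
    """

    banded: BandedSignalSet
    env_phase: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    symbols: dict[int, np.ndarray] = field(default_factory=dict)
    codebooks: dict[int, np.ndarray] = field(default_factory=dict)
    lags: dict[int, int] = field(default_factory=dict)
    dste_config: DsteConfig = field(default_factory=DsteConfig)
    _dste_params: dict = field(default_factory=dict)
    _phasor: dict[int, np.ndarray] = field(default_factory=dict)
    _env_phasor: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def get_env_phase(self, lo_band: int, hi_band: int) -> np.ndarray:
        key = (lo_band, hi_band)
        if key not in self.env_phase:
            self.env_phase[key] = envelope_band_phase(
                self.banded.envelope[hi_band], int(lo_band), self.banded.fs
            )
        return self.env_phase[key]

    def phasor(self, band: int) -> np.ndarray:
        """exp(i * phase) per channel for one band (cached, full length)."""
        if band not in self._phasor:
            self._phasor[band] = np.exp(1j * self.banded.phase[band])
        return self._phasor[band]

    def env_phasor(self, lo_band: int, hi_band: int) -> np.ndarray:
        key = (lo_band, hi_band)
        if key not in self._env_phasor:
            self._env_phasor[key] = np.exp(1j * self.get_env_phase(lo_band, hi_band))
        return self._env_phasor[key]

    def symbol_offset(self, band: int) -> int:
        """Samples consumed by the embedding of one band's symbol series."""
        cfg = self.dste_config
        return (cfg.dim - 1) * self.lags.get(band, 1)

    def dste_pair_params(self, i: int, j: int, lo: int, hb: int):
        """Recording-level dSTE parameters of one pair and band combination.

        The channel-to-band assignment and the per-direction delays are
        selected once from the full-length symbol series (argmax of the TE
        profile) and then held fixed for every window, so the windowed
        statistic involves no per-window selection and its surrogate null
        is exactly the same fixed-delay statistic.
        """
        key = (i, j, lo, hb)
        if key in self._dste_params:
            return self._dste_params[key]
        cfg = self.dste_config
        delays = list(cfg.delays)
        best = None
        for swap in ([False] if lo == hb else [False, True]):
            sa = self.symbols[hb][i] if swap else self.symbols[lo][i]
            sb = self.symbols[lo][j] if swap else self.symbols[hb][j]
            m = min(len(sa), len(sb))
            te_ab = symbolic_te_profile(sa[:m], sb[:m], cfg.k, delays)
            te_ba = symbolic_te_profile(sb[:m], sa[:m], cfg.k, delays)
            ia, ib = int(np.argmax(te_ab)), int(np.argmax(te_ba))
            top = max(te_ab[ia], te_ba[ib])
            net = abs(te_ab[ia] - te_ba[ib]) / top if top > 0 else 0.0
            cand = (net, swap, delays[ia], delays[ib])
            if best is None or cand[0] > best[0]:
                best = cand
        self._dste_params[key] = (best[1], best[2], best[3])
        return self._dste_params[key]


def precompute(
    banded: BandedSignalSet,
    estimators: tuple[int, ...] = (1, 2, 3, 4, 5),
    dste_config: DsteConfig | None = None,
    seed: int = 0,
) -> PrecomputedBands:
    """Build the per-recording caches (envelope phases lazily; symbols now).

    One neural-gas codebook is trained per band, common across all channels
    and windows of the recording, on a subsample of embedded state vectors.
    """
    pre = PrecomputedBands(banded=banded, dste_config=dste_config or DsteConfig())
    if int(Estimator.DSTE) in estimators:
        cfg = pre.dste_config
        rng = np.random.default_rng(seed)
        for b in range(banded.n_bands):
            lag = cfg.lag_for(b, banded.fs)
            pre.lags[b] = lag
            vecs = np.concatenate(
                [embed(banded.filtered[b, c], cfg.dim, lag)
                 for c in range(banded.n_channels)]
            )
            if len(vecs) > cfg.train_size:
                vecs = vecs[rng.choice(len(vecs), cfg.train_size, replace=False)]
            cb = neural_gas_codebook(vecs, cfg.k, seed=int(rng.integers(2**31)))
            pre.codebooks[b] = cb
            pre.symbols[b] = np.stack(
                [symbolize(banded.filtered[b, c], cb, cfg.dim, lag)
                 for c in range(banded.n_channels)]
            )
    return pre


def pair_indices(n_channels: int) -> list[tuple[int, int]]:
    """Upper-triangle channel pair list, the pair axis of all result arrays."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def candidate_strength(
    pre: PrecomputedBands,
    sl: slice,
    i: int,
    j: int,
    est: int,
    code: int,
) -> tuple[float, dict]:
    """Observed strength for one (window, pair, estimator, code) candidate.

    Returns ``(strength, meta)``; meta carries direction/delay for the
    directed estimators.  NaN marks a degenerate (zero-variance) window.
    """
    banded = pre.banded
    lo, hi = bands_of_code(code)
    meta: dict = {}
    hb_chk = lo if hi is None else hi
    if (banded.envelope[lo, i, sl].max() < 1e-12
            or banded.envelope[hb_chk, j, sl].max() < 1e-12):
        meta["degenerate"] = True
        return np.nan, meta  # zero-amplitude window: no meaningful coupling
    if est == Estimator.AEC:
        hb = lo if hi is None else hi
        r = aec(banded.envelope[lo, i, sl], banded.envelope[hb, j, sl])
        return (abs(r) if np.isfinite(r) else np.nan), meta
    if est == Estimator.IPLV:
        return iplv(banded.phase[lo, i, sl], banded.phase[lo, j, sl]), meta
    if est == Estimator.PAC:
        # both directions: phase of i vs envelope of j, and vice versa
        s_ij = iplv(banded.phase[lo, i, sl], pre.get_env_phase(lo, hi)[j, sl])
        s_ji = iplv(banded.phase[lo, j, sl], pre.get_env_phase(lo, hi)[i, sl])
        meta["direction"] = 1 if s_ij >= s_ji else -1
        return max(s_ij, s_ji), meta
    if est == Estimator.DPLI:
        if hi is None:
            v = dpli(banded.phase[lo, i, sl], banded.phase[lo, j, sl])
        else:
            v = dpli(banded.phase[lo, i, sl], pre.get_env_phase(lo, hi)[j, sl])
        meta["dpli_value"] = v
        meta["direction"] = 1 if v >= 0.5 else -1
        return dpli_strength(v), meta
    if est == Estimator.DSTE:
        cfg = pre.dste_config
        hb = lo if hi is None else hi
        off = max(pre.symbol_offset(lo), pre.symbol_offset(hb))
        d_max = max(cfg.delays)
        if (sl.stop - sl.start - off) < d_max + 8:
            meta["degenerate"] = True
            return np.nan, meta  # window too short for the delay grid
        swap, d_ab, d_ba = pre.dste_pair_params(i, j, lo, hb)
        ssl = slice(sl.start, sl.stop - off)
        if swap:
            src, tgt = pre.symbols[hb][i, ssl], pre.symbols[lo][j, ssl]
        else:
            src, tgt = pre.symbols[lo][i, ssl], pre.symbols[hb][j, ssl]
        if len(np.unique(src)) < 2 or len(np.unique(tgt)) < 2:
            meta["degenerate"] = True
            return np.nan, meta
        te_ab, te_ba = te_pair_at(src, tgt, cfg.k, d_ab, d_ba, d_max)
        top = max(te_ab, te_ba)
        meta.update(assignment="high_first" if swap else "low_first",
                    direction=1 if te_ab >= te_ba else -1,
                    delay=d_ab if te_ab >= te_ba else d_ba,
                    delay_ab=d_ab, delay_ba=d_ba)
        return (abs(te_ab - te_ba) / top if top > 0 else 0.0), meta
    raise ValueError(f"unknown estimator id {est}")


def surrogate_strengths(
    pre: PrecomputedBands,
    sl: slice,
    i: int,
    j: int,
    est: int,
    code: int,
    shifts: np.ndarray,
    meta: dict,
) -> np.ndarray:
    """Surrogate strengths for one candidate.

    Channel i's band-specific series is circularly shifted over the whole
    recording by each offset in ``shifts`` and the estimator is recomputed
    against channel j's unshifted window, so every surrogate window retains
    its natural within-window autocorrelation.
    """
    banded = pre.banded
    n_total = banded.n_samples
    lo, hi = bands_of_code(code)
    idx = shifted_window_indices(sl, shifts, n_total)
    if est == Estimator.AEC:
        hb = lo if hi is None else hi
        r = aec_rows(banded.envelope[lo, i][idx], banded.envelope[hb, j, sl])
        return np.abs(np.nan_to_num(r))
    if est == Estimator.IPLV:
        return iplv_rows(pre.phasor(lo)[i][idx], pre.phasor(lo)[j, sl])
    if est == Estimator.PAC:
        # replicate the observed statistic's max over the two directions
        s_ij = iplv_rows(pre.phasor(lo)[i][idx], pre.env_phasor(lo, hi)[j, sl])
        s_ji = iplv_rows(pre.env_phasor(lo, hi)[i][idx], pre.phasor(lo)[j, sl])
        return np.maximum(s_ij, s_ji)
    if est == Estimator.DPLI:
        pa_rows = banded.phase[lo, i][idx]
        pb = (banded.phase[lo, j, sl] if hi is None
              else pre.get_env_phase(lo, hi)[j, sl])
        v = dpli_rows(pa_rows, pb)
        return 2.0 * np.abs(v - 0.5)
    if est == Estimator.DSTE:
        cfg = pre.dste_config
        hb = lo if hi is None else hi
        off = max(pre.symbol_offset(lo), pre.symbol_offset(hb))
        ssl = slice(sl.start, sl.stop - off)
        swap, d_ab, d_ba = pre.dste_pair_params(i, j, lo, hb)
        if swap:
            src_all, tgt = pre.symbols[hb][i], pre.symbols[lo][j, ssl]
        else:
            src_all, tgt = pre.symbols[lo][i], pre.symbols[hb][j, ssl]
        m = src_all.shape[-1]
        pos = np.arange(ssl.start, ssl.stop)[None, :]
        s_col = np.asarray(shifts, dtype=int)[:, None]
        return dste_strength_rows(src_all[(pos + s_col) % m], tgt, cfg.k,
                                  d_ab, d_ba, d_max=max(cfg.delays))
    raise ValueError(f"unknown estimator id {est}")


def estimate_all(
    banded: BandedSignalSet,
    scheme: WindowScheme,
    estimators: tuple[int, ...] = (1, 2, 3, 4, 5),
    dste_config: DsteConfig | None = None,
    seed: int = 0,
    pre: PrecomputedBands | None = None,
) -> dict[int, np.ndarray]:
    """Dense raw candidate strengths for every window, pair and code.

    Returns ``{estimator id: array (T, n_pairs, N_CODES + 1)}`` where column
    ``c`` holds the strength of frequency code ``c`` (column 0 unused);
    inadmissible codes are NaN, as are degenerate windows.
    """
    if pre is None:
        pre = precompute(banded, estimators, dste_config, seed)
    pairs = pair_indices(banded.n_channels)
    out: dict[int, np.ndarray] = {}
    for est in estimators:
        arr = np.full((scheme.T, len(pairs), N_CODES + 1), np.nan)
        for t, sl in enumerate(scheme.slices()):
            for p, (i, j) in enumerate(pairs):
                for code in ADMISSIBLE_CODES[est]:
                    arr[t, p, code], _ = candidate_strength(pre, sl, i, j, est, code)
        out[est] = arr
    return out
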