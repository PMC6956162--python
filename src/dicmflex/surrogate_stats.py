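"""Surrogate-null significance, FDR control and dominant-coupling selection.

For every window, channel pair, estimator and admissible frequency code the
observed coupling strength is ranked against strengths recomputed after
circularly shifting one channel of the pair (a null that preserves each
signal's spectrum and envelope statistics while destroying cross-channel
alignment).  Two p-values are carried per candidate:

* the raw surrogate proportion ``#{surr >= obs} / n_surr``, which reaches
  zero when the observation beats every surrogate — this is the p-value the
  procedure is defined on: it feeds Benjamini-Hochberg FDR control and the
  stricter multi-estimator threshold (0.01/4 = 0.0025), and
* the add-one estimator ``(1 + #{surr >= obs}) / (1 + n_surr)``, never zero,
  stored in the result records and convenient for calibration checks.

The raw proportion matters at practical surrogate counts: with n_surr in
the hundreds the add-one p-value is bounded below by ~1/n_surr, which sits
above every BH step-up threshold at q = 0.01 once a pair/window carries
more than a handful of frequency candidates, and above 0.0025 always.

Selection keeps, per cell, the max-strength FDR-significant candidate of the
single significant estimator, or up to two estimator-best candidates
(smallest p, ties broken by larger strength) when several estimators pass
the stricter threshold.  Cells with nothing significant carry frequency
code 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .codes import ADMISSIBLE_CODES
from .coupling import (
    DsteConfig,
    PrecomputedBands,
    candidate_strength,
    pair_indices,
    precompute,
    surrogate_strengths,
)
from .preprocessing import BandedSignalSet, WindowScheme, make_windows

MULTI_ESTIMATOR_ALPHA = 0.0025  # 0.01 / 4


def make_surrogates(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    stat,
    n_surr: int,
    seed: int = 0,
    min_shift: int | None = None,
    fs: float | None = None,
) -> np.ndarray:
    """Surrogate strength distribution by circular time-shift of ``sig_a``.

    ``stat(a_shifted, b)`` recomputes the estimator.  Shifts are drawn
    uniformly from ``[min_shift, n - min_shift]``; the minimum shift
    defaults to ``fs`` samples (one second) when the sampling rate is
    given, else to ``n // 8``.  A series shorter than twice the minimum
    shift is an error.
    """
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    n = len(sig_a)
    if min_shift is None:
        min_shift = int(round(fs)) if fs else max(1, n // 8)
    if n < 2 * min_shift:
        raise ValueError(
            f"series of {n} samples is shorter than twice the minimum "
            f"shift ({min_shift})"
        )
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift + 1, size=n_surr)
    return np.array([stat(np.roll(sig_a, -int(s)), sig_b) for s in shifts])


def surrogate_pvalue(observed: float, surrogates: np.ndarray) -> float:
    """Add-one surrogate p-value: ``(1 + #{surr >= obs}) / (1 + n)``."""
    surrogates = np.asarray(surrogates)
    if surrogates.size == 0:
        raise ValueError("surrogate distribution is empty")
    ge = int(np.sum(surrogates >= observed))
    return (1 + ge) / (1 + surrogates.size)


def fdr_filter(pvals: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``; boolean retention mask."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


@dataclass
class Candidate:
    """One (estimator, frequency code) coupling candidate of a cell."""

    est: int
    code: int
    strength: float
    p: float                 # add-one p-value (used by FDR)
    p_raw: float             # raw surrogate proportion (multi-estimator test)
    meta: dict = field(default_factory=dict)
    significant: bool = False


def select_dicm(
    candidates: list[Candidate],
    multi_alpha: float = MULTI_ESTIMATOR_ALPHA,
) -> list[Candidate]:
    """Select the representative coupling mode(s) of one cell.

    ``candidates`` are the FDR-significant candidates of a pair/window.  If a
    single estimator is represented, its max-strength candidate is kept.  If
    several estimators are represented, each estimator's best candidate is
    screened at the stricter ``multi_alpha`` threshold (on the raw surrogate
    proportion) and up to two survivors are kept, smallest p first (ties by
    larger strength).  An empty result means frequency code 0.
    """
    if not candidates:
        return []
    best_per_est: dict[int, Candidate] = {}
    for c in candidates:
        cur = best_per_est.get(c.est)
        if cur is None or (c.strength, -c.p) > (cur.strength, -cur.p):
            best_per_est[c.est] = c
    bests = list(best_per_est.values())
    if len(bests) == 1:
        return bests
    eligible = [c for c in bests if c.p_raw < multi_alpha]
    eligible.sort(key=lambda c: (c.p, -c.strength))
    return eligible[:2]


@dataclass
class DicmTensor:
    """Per window x pair: up to two coupling-mode records.

    Record arrays have shape (2, T, n_pairs); slot 0 is the smaller-p
    record.  ``code == 0`` marks "no significant coupling" (est, strength
    and p are 0/NaN there).  ``pairs`` maps the pair axis to channel index
    tuples.
    """

    est: np.ndarray
    code: np.ndarray
    strength: np.ndarray
    pval: np.ndarray
    direction: np.ndarray
    delay: np.ndarray
    pairs: list[tuple[int, int]]
    channel_names: list[str]

    @property
    def T(self) -> int:
        return self.est.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.est.shape[2]

    @staticmethod
    def empty(T: int, pairs: list[tuple[int, int]],
              channel_names: list[str]) -> "DicmTensor":
        P = len(pairs)
        return DicmTensor(
            est=np.zeros((2, T, P), dtype=np.int16),
            code=np.zeros((2, T, P), dtype=np.int16),
            strength=np.full((2, T, P), np.nan),
            pval=np.full((2, T, P), np.nan),
            direction=np.zeros((2, T, P), dtype=np.int8),
            delay=np.zeros((2, T, P), dtype=np.int16),
            pairs=pairs,
            channel_names=channel_names,
        )

    def set_records(self, t: int, p: int, records: list[Candidate]) -> None:
        for slot, c in enumerate(records[:2]):
            self.est[slot, t, p] = c.est
            self.code[slot, t, p] = c.code
            self.strength[slot, t, p] = c.strength
            self.pval[slot, t, p] = c.p
            self.direction[slot, t, p] = int(c.meta.get("direction", 0))
            self.delay[slot, t, p] = int(c.meta.get("delay", 0))

    def clear_cell(self, t: int, p: int) -> None:
        self.est[:, t, p] = 0
        self.code[:, t, p] = 0
        self.strength[:, t, p] = np.nan
        self.pval[:, t, p] = np.nan
        self.direction[:, t, p] = 0
        self.delay[:, t, p] = 0

    def primary_labels(self) -> np.ndarray:
        """(T, n_pairs) integer labels ``est*100 + code`` of the smaller-p
        record; 0 where no coupling was retained."""
        return np.where(
            self.code[0] > 0,
            self.est[0].astype(np.int32) * 100 + self.code[0],
            0,
        )

    def primary_strength_matrix(self, t: int) -> np.ndarray:
        """Symmetric n x n strength matrix of window ``t`` (0 where empty)."""
        n = len(self.channel_names)
        W = np.zeros((n, n))
        for p, (i, j) in enumerate(self.pairs):
            if self.code[0, t, p] > 0:
                W[i, j] = W[j, i] = self.strength[0, t, p]
        return W


@dataclass
class PipelineDiagnostics:
    n_candidates: int = 0
    n_fdr_retained: int = 0
    n_cells: int = 0
    n_cells_retained: int = 0
    n_skipped_windows: int = 0

    @property
    def fdr_retained_fraction(self) -> float:
        return self.n_fdr_retained / max(self.n_candidates, 1)


def dicm_pipeline(
    banded: BandedSignalSet,
    scheme: WindowScheme | None = None,
    estimators: tuple[int, ...] = (1, 2, 3, 4, 5),
    codes: tuple[int, ...] | None = None,
    n_surr: int = 200,
    q: float = 0.01,
    multi_alpha: float = MULTI_ESTIMATOR_ALPHA,
    min_shift: int | None = None,
    seed: int = 0,
    apply_omst: bool = True,
    dste_config: DsteConfig | None = None,
    fdr_scope: str = "pair",
    pre: PrecomputedBands | None = None,
) -> tuple[DicmTensor, PipelineDiagnostics]:
    """Run estimation, surrogate testing, FDR and dominant-mode selection.

    ``codes`` optionally restricts the frequency-code space (intersected
    with each estimator's admissible codes).  ``fdr_scope`` is ``"pair"``
    (correct across the frequency candidates of each pair/window, per
    estimator) or ``"recording"`` (pool all cells per estimator).  With
    ``apply_omst`` the per-window graph of retained strengths is
    topologically filtered and pruned cells are reset to code 0.
    """
    from .topology import omst_filter  # local import to avoid cycle

    if scheme is None:
        scheme = make_windows(banded.n_samples, banded.fs)
    if pre is None:
        pre = precompute(banded, estimators, dste_config, seed)
    pairs = pair_indices(banded.n_channels)
    rng = np.random.default_rng(seed)
    diag = PipelineDiagnostics(n_cells=scheme.T * len(pairs))
    cells: dict[tuple[int, int], list[Candidate]] = {}

    n_total = banded.n_samples
    ms = min_shift if min_shift is not None else int(round(banded.fs))
    if n_total <= 2 * ms:
        raise ValueError(
            f"recording of {n_total} samples is too short for circular "
            f"shifts of at least {ms} samples"
        )
    for t, sl in enumerate(scheme.slices()):
        w = sl.stop - sl.start
        if w < 16:
            diag.n_skipped_windows += 1
            continue
        shifts = rng.integers(ms, n_total - ms + 1, size=n_surr)
        for p, (i, j) in enumerate(pairs):
            cands: list[Candidate] = []
            for est in estimators:
                est_codes = ADMISSIBLE_CODES[est]
                if codes is not None:
                    est_codes = tuple(c for c in est_codes if c in codes)
                for code in est_codes:
                    obs, meta = candidate_strength(pre, sl, i, j, est, code)
                    if not np.isfinite(obs):
                        continue
                    surr = surrogate_strengths(pre, sl, i, j, est, code,
                                               shifts, meta)
                    ge = int(np.sum(surr >= obs))
                    cands.append(Candidate(
                        est=est, code=code, strength=float(obs),
                        p=(1 + ge) / (1 + n_surr), p_raw=ge / n_surr,
                        meta=meta,
                    ))
            cells[(t, p)] = cands
            diag.n_candidates += len(cands)

    # FDR per estimator within each scope group
    if fdr_scope == "pair":
        groups = [[key] for key in cells]
    elif fdr_scope == "recording":
        groups = [list(cells)]
    else:
        raise ValueError(f"unknown fdr_scope: {fdr_scope}")
    for group in groups:
        for est in estimators:
            flat = [c for key in group for c in cells[key] if c.est == est]
            if not flat:
                continue
            mask = fdr_filter(np.array([c.p_raw for c in flat]), q)
            for c, keep in zip(flat, mask):
                c.significant = bool(keep)
    diag.n_fdr_retained = sum(
        c.significant for cands in cells.values() for c in cands
    )

    tensor = DicmTensor.empty(scheme.T, pairs, banded.channel_names)
    for (t, p), cands in cells.items():
        records = select_dicm([c for c in cands if c.significant], multi_alpha)
        if records:
            tensor.set_records(t, p, records)
    diag.n_cells_retained = int((tensor.code[0] > 0).sum())

    if apply_omst and banded.n_channels > 2:
        for t in range(scheme.T):
            W = tensor.primary_strength_matrix(t)
            if (W > 0).sum() == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, _ = omst_filter(W)
            for p, (i, j) in enumerate(pairs):
                if tensor.code[0, t, p] > 0 and kept[i, j] == 0:
                    tensor.clear_cell(t, p)
        diag.n_cells_retained = int((tensor.code[0] > 0).sum())

    return tensor, diag
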